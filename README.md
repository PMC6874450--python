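# immunoflux

Multi-assay analysis of mitochondrial function and autophagy in CD4+ T
cells from young versus old donors.

Aging CD4+ T cells show a striking discordance: mitochondrial
electron-transport-chain **proteins accumulate** in cells from older
donors while the corresponding **gene sets are transcriptionally
down-regulated** — and mitochondrial respiration is impaired.  The
resolution is defective autophagy: damaged mitochondria are sequestered
into autophagosomes but not degraded, so immature autophagic vacuoles
(and their protein cargo) pile up.  `immunoflux` implements the
computational arms that establish this picture, each usable on its own
tabular inputs and each exercisable end to end on seeded synthetic data
with planted ground truth:

| arm | module | core statistic |
|---|---|---|
| iTRAQ 8plex proteomics | `immunoflux.proteomics` | reference-channel normalization; old/young ratio r = x̄ₒ/x̄ᵧ; Student t; fold/p/evidence screen (1.3/0.7, 0.05, ≥2 peptides, ion > 30) |
| microarray transcriptomics | `immunoflux.enrichment` | array-wise Z-transform; per-gene Z-ratio; PAGE Z = (S_m − μ)·√m/δ; top-K young-vs-old pathway contrast |
| high-resolution respirometry | `immunoflux.respirometry` | ROUTINE/LEAK/ETS/ROX plateau fluxes; BHI = log₁₀[(reserve × ATP-linked)/(non-mito × proton leak)]; memory-fraction-adjusted Welch comparison |
| TEM morphometry | `immunoflux.morphometry` | rule-based AP/AL classification; AV = AP + AL; maturation = 100·AL/AV; stratified Student tests |
| mitophagy-dye cytometry | `immunoflux.mitophagy` | control-derived lo/int/hi gates; bin percentages; age and paired drug contrasts |
| synthetic studies | `immunoflux.simulate` | seeded generators for all five modalities with ground-truth sidecars |

Shared statistical primitives (Welch and Student t, Benjamini–Hochberg
FDR, normal tails) live in `immunoflux.stats`; plain-text I/O in
`immunoflux.io`; orchestration and the cross-assay report in
`immunoflux.pipeline`.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data.  Generate a study and run the proteomics and enrichment arms:

```sh
python analysis/01_simulate_study.py --seed 0 --out-dir results/synthetic_study
python analysis/02_proteomics_ratios.py
python analysis/03_transcriptome_enrichment.py
```

prints (seed 0):

```
cascade counts (input, ratio, p, evidence): (600, 60, 60, 54)
54 proteins up in old; 54 of them mitochondrial
...
OXPHOS sets (mean pathway Z, young vs old):
              mean_z_young  mean_z_old  z_difference  selected
OXPHOS_SET_2        -0.573      -3.191         2.617      True
OXPHOS_SET_3        -0.268      -2.844         2.576      True
OXPHOS_SET_1        -1.759      -4.291         2.532      True
```

Of 600 simulated proteins, 60 carry a planted 1.5-fold mitochondrial
up-shift in old donors; 54 survive the three-stage screen (the missing
six mostly fail the simulated evidence stage), and no null protein
survives.  In the same synthetic study the three planted OXPHOS gene
sets come out strongly *negative* in old donors (mean pathway Z about
−3 vs −0.9 in young), reproducing the protein-up / transcript-down
discordance.  The respirometry driver then shows the functional side:

```
python analysis/04_respirometry_bhi.py
young: mean BHI 1.945, reserve 83.3, non-mito 6.0 pmol/s/1e6 cells
old:   mean BHI 1.618, reserve 47.3, non-mito 9.9 pmol/s/1e6 cells
memory-adjusted BHI means: young 1.921 vs old 1.642 (group p = 0.0347)
```

i.e. lower BHI and reserve capacity and higher non-mitochondrial
respiration in the old group, significant after adjusting for each
donor's memory-cell percentage.  `analysis/05_tem_morphometry.py` and
`analysis/06_mitophagy_gating.py` complete the picture (inflated
autophagosome counts in old naive cells, p ≈ 1e-6 at the simulated
effect size; an enlarged intermediate-intensity dye bin in old), and
`analysis/07_cross_assay_report.py` runs everything from one seed and
prints the combined summary.  The same pipeline is available as a CLI
(`immunoflux simulate|proteomics|enrich|respire|morpho|mitophagy|report`)
over the same text formats.

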
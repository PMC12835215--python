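# pcsurf

**Plasma-cell surfaceome target discovery for multiple myeloma, as a tested
pipeline.**

Multiple myeloma is a malignancy of bone-marrow plasma cells (PCs). CAR-T and
antibody therapies need antigens that sit on the PC surface and are scarce
elsewhere; finding them from single-cell RNA-seq means running the same
discovery recipe consistently across many heterogeneous cohorts: filter
low-quality cells, label cell types, rank genes by PC-vs-rest differential
expression in *every* dataset, keep only genes that replicate everywhere and
encode surface/CD molecules, then characterise the hits by disease stage
(HD → MGUS → SMM → MM → RRMM), cytogenetic background and survival.

`pcsurf` implements that recipe end-to-end for researchers who want to audit,
reuse or stress-test it. Because the real cohorts are hundreds of thousands of
cells behind controlled access, the package ships a synthetic bone-marrow
generator that plants every property the pipeline is supposed to recover —
a 15-gene PC surface panel, stage-dependent candidate expression, mito/low-
complexity contamination, four cytogenetic archetypes, prognostic effects with
known signs — so each stage is validated against ground truth.

## The statistics at the core

- **QC**: mitochondrial band filter (1–10%), then per-dataset OLS of
  log₁₀(genes) on log₁₀(UMIs); cells with |residual| > k·SD are excluded,
  plus hard bounds (> 200 genes, < 30,000 UMIs).
- **Wilcoxon rank-sum** per gene per dataset on log-normalised values,
  W = Σ ranks of the PC group with midranks, tie-corrected
  σ²_W = (n₁n₂/12)[(N+1) − Σ(t³−t)/(N(N−1))], exact enumeration at small N;
  BH-adjusted within dataset; strict cross-dataset intersection; surface/CD
  filter.
- **Kruskal–Wallis** omnibus and pairwise stage contrasts with BH correction.
- **Pseudobulk clustering**: mean log-normalised expression over 100 sampled
  PCs per patient; Ward linkage on z-scored cytogenetic proxies (FGFR3,
  CCND1, CCND2, CCND3, MAF, MAFB, MCL1, IL6R); k by silhouette; Welch
  t-tests between clusters.
- **Survival**: median split, Kaplan–Meier with Greenwood variance, log-rank
  test, and univariate Cox fitted by Newton–Raphson on the Breslow partial
  likelihood, L(β) = Π_t [exp(β·Σ x_events) / (Σ_risk e^{βx})^{d_t}].

The rank, survival and t statistics are implemented from their defining
formulas (scipy/lifelines appear only as cross-check oracles in the tests).
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from pcsurf import PipelineConfig, SimConfig, run_all

cfg = PipelineConfig(
    sim=SimConfig(
        n_datasets=3,
        stages_per_dataset={"HD": 2, "MGUS": 2, "SMM": 2, "MM": 3, "RRMM": 2},
        cells_per_patient=(150, 220),
    ),
    survival_n=1000,
    seed=7,
)
report = run_all(cfg)
print(report["consensus_panel"])
print(report["staging"]["CD320"]["stage_medians"])
print(report["survival"]["CD320"]["hr"], report["survival"]["TNFRSF13B"]["hr"])
```

prints

```
['CD320', 'SLC44A1', 'CD59', 'FCGR2B', 'BST2', 'TNFRSF13B', 'TNFRSF17',
 'BSG', 'SLAMF7', 'CD63', 'CD38', 'ICAM3', 'SDC1', 'FCRL5', 'CD79B']
{'HD': 3.456795, 'MGUS': 3.741052, 'SMM': 4.105549, 'MM': 4.665756, 'RRMM': 4.927491}
1.433539 0.69701
```

Reading those numbers: the consensus surface panel is exactly the 15 genes
planted as PC-specific (QC removed the planted junk cells first — e.g. dataset
DS00 kept 1,885 of 2,078 cells — and the intracellular PC markers MZB1/XBP1/…
were discovered but dropped by the surface filter). CD320's median
log-normalised PC expression rises monotonically across the five stages
(omnibus Kruskal–Wallis p ≈ 6e-81 here), matching its planted ×1.5-per-stage
trend. In the survival cohort, high CD320 is adverse (HR ≈ 1.43 per SD) and
high TNFRSF13B favourable (HR ≈ 0.70 per SD), recovering the planted hazard
signs. The same run also clusters the MM patients into k = 4 proxy-gene
groups matching the planted archetypes.

Every stage is also available on its own (`simulate_cohort`, `run_qc`,
`score_cell_types`, `rank_pc_markers`, `build_consensus_panel`,
`stage_compare`, `make_pseudobulk`/`cluster_pseudobulk`, `km_estimate`/
`cox_univariate`), and as a CLI:

```bash
pcsurf simulate --out cohort/ --seed 7
pcsurf qc --input cohort/DS00 --out qc.tsv
pcsurf run-all --seed 7 --out report.json
```

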
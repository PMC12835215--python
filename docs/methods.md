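# Methods

`pcsurf` re-implements, as a tested and reusable pipeline, a multi-cohort
single-cell discovery procedure for plasma-cell-restricted surface antigens in
multiple myeloma: quality control, cell-type annotation, consensus differential
ranking with surface/CD filtering, pseudobulk cytogenetic clustering, and
survival stratification. Every stage is driven by a synthetic bone-marrow data
generator with planted ground truth, so the whole procedure is testable without
downloading any cohort.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not any
particular real dataset.

**Cell population.** Each dataset holds patients in five disease stages (HD,
MGUS, SMM, MM, RRMM; by default 3 patients per stage per dataset and 200–250
cells per patient). Each cell is assigned a type: plasma cell (PC) with a
stage-dependent probability (5% in HD rising to 35% in RRMM), otherwise one of
eight bone-marrow lineages (B, CD4 T, CD8 T, NK, monocyte, DC, erythroid,
HSPC) in fixed proportions.

**Counts.** Gene baseline abundances are log-normal (σ = 1) over a
2,000-gene universe, drawn once per cohort; per-cell library sizes are uniform
on 1,200–6,000 UMIs. Counts are negative binomial in the mean/dispersion
parameterisation (shared dispersion α = 0.3), sampled as the exact
gamma–Poisson mixture. Each non-PC lineage carries 30 private marker genes at
fold ×6 so annotation has signal to work with.

**Planted plasma-cell biology.** Fifteen surface genes (TNFRSF17/BCMA,
SDC1/CD138, CD63, FCRL5, CD38, SLAMF7, TNFRSF13B/TACI, CD59, BST2, BSG,
SLC44A1/CD92, FCGR2B/CD32B, CD79B, CD320, ICAM3) are multiplied ×8 in PC
cells, alongside five intracellular PC genes (MZB1, XBP1, JCHAIN, PRDM1,
DERL3) at the same fold that exist purely to exercise the surface filter.
The five candidates get additional stage folds (×1.5 per stage step):
CD320 and SLC44A1 monotone increasing HD→RRMM; TNFRSF13B and FCGR2B elevated
in MM/RRMM only; CD59 elevated from SMM onward. Baseline abundances of the
planted and proxy genes are floored (weight ≥ 1.5) so they are reliably
detectable at these library sizes.

**Mitochondrial content.** Thirteen `MT-` genes receive a per-cell share
constructed so that a good cell's realised mitochondrial fraction lies inside
the configured band (2–6%) *exactly*: the mitochondrial total `m` is chosen so
`m/(m+T)` hits a uniform draw from the band, then clamped to the band's
integer-feasible range.

**Low-quality cells.** A configurable fraction (10%) of cells is planted as
low quality, split evenly between two kinds so each QC filter has its own
recoverable sub-population: *high-mito* cells (mitochondrial fraction
uniform on 15–35%, otherwise normal) and *low-complexity* cells (in-band
mito, but all transcripts concentrated into a random 10% gene subset, which
collapses their detected-gene count below the complexity regression).

**Cytogenetic archetypes.** MM patients are assigned one of four archetypes
in a balanced rotation, expressed through fold changes on the eight proxy
genes: CCND1+MCL1 ×6 (t(11;14)-like); FGFR3+MCL1 ×6 with CCND2 ×3
(t(4;14)-like); MAF+MAFB ×6 with CCND2 ×3 (t(14;16)/t(14;20)-like); and a
hyperdiploid-like group with IL6R ×3 and CCND1 ×2. The secondary CCND2/IL6R
signatures follow the standard translocation/cyclin-D picture of myeloma, and
they matter operationally: a proxy gene with no subtype association at all
carries only sampling noise across patients, which the per-gene z-scoring
step inflates to unit variance, creating nuisance dimensions for the
clustering. CCND3 is deliberately left subtype-neutral (cyclin-D3-driven
disease is a rare group outside the four modelled), so one such nuisance
dimension remains and k-selection keeps a realistic, small failure rate.
Two archetype→candidate couplings are planted (CD320 ×2 in the FGFR3 group,
TNFRSF13B ×2 in the CCND1 group).

**Survival cohorts.** Per-patient expression is standard normal per gene;
event times are exponential with hazard h₀·exp(Σ β_g x_g), h₀ = 0.1.
Default log-hazards encode the planted prognostic structure: TNFRSF13B −0.5,
CD59 −0.3, FCGR2B −0.3 (favourable), SLC44A1 +0.35, CD320 +0.5 (adverse).
Censoring is independent uniform; its scale is solved (Brent root-finding) so
the expected censored fraction equals the request given the drawn event times.

**What the generator does not emulate** (and hence what passing tests do not
show about real data): ambient RNA, doublets, batch effects between datasets
(baselines are shared across a cohort's datasets), UMI saturation, clonal
substructure within a patient, and correlated gene–gene noise. Recovery
results here demonstrate the pipeline's correctness under its own model
assumptions, not performance on real cohorts.

## Quality control

Two steps, mirroring common scRNA-seq practice. First a uniform mitochondrial
band: cells keep 1–10% mitochondrial UMIs, inclusive at both ends. Second,
dataset-specific complexity filtering: ordinary least squares of
log10(genes + 1) on log10(UMIs + 1) — the +1 keeps zero-count cells finite —
fitted per dataset over the cells passing the mito band only, so contaminated
cells do not drag the line. A cell fails the complexity criterion when its
absolute residual exceeds k·SD (k = 3 by default); the exclusion is two-sided
because deviation from the line is unsigned. Hard bounds complete the filter:
> 200 genes and < 30,000 UMIs per cell, strict at the boundary. A degenerate
fit (residual SD ≈ 0) defines no deviation and passes every cell. The mask is
a pure function of (metrics, fit, parameters) and each dataset is filtered
independently.

## Annotation

A nearest-centroid classifier: each cell is log-normalised
(value = ln(1 + 10⁴·count/total)) and scored by cosine similarity against
per-type centroid profiles over the shared genes (≥ 50 required). The label is
the arg-max type if the score clears 0.1, else "Unassigned"; ties break
lexicographically. This is a defined, order-free stand-in for
reference-embedding projection, whose internals are out of scope; any centroid
table can be plugged in. For synthetic cohorts the bundled reference is
computed analytically from the generative model's own expected type profiles
(`reference_signatures`), with the PC centroid averaged over stages and free
of archetype folds.

## Consensus markers

Per dataset, each gene is scored PC-vs-rest with a Wilcoxon rank-sum test on
log-normalised values: midranks for ties, tie-corrected normal standardisation,
and exact enumeration of the rank-sum distribution for pooled N ≤ 20 without
ties. The implementation is zero-aware: the implicit zeros of a sparse gene
share one tie group, so only stored values are sorted. BH adjustment is within
dataset, matching per-dataset list semantics. A dataset's list keeps genes
with adj p ≤ 0.05, logFC ≥ 0.5 (difference of group means of log-normalised
values) and positive z — these cuts are package defaults, exposed in
`SelectionParams`, since reasonable pipelines differ here. Lists are then
intersected strictly across datasets (a `min_datasets` relaxation exists) and
restricted to genes flagged as surface/CD molecules in the bundled annotation
table; unknown genes count as non-surface and are dropped with a warning.

## Stage comparison

PCs are pooled across datasets within stage. Per candidate gene: a
Kruskal–Wallis omnibus test (midranks, tie correction, chi-square reference)
plus all pairwise two-group contrasts — two-group Kruskal–Wallis, which is
algebraically the squared tie-corrected Wilcoxon z — BH-corrected across the
contrasts per gene, with the conventional star tiers (p < 0.05 *, < 0.01 **,
< 0.001 ***, < 0.0001 ****). A gene's trend is monotone when per-stage medians
are non-decreasing in HD < MGUS < SMM < MM < RRMM order.

## Cytogenetic clustering

Per patient, up to 100 annotated PCs are sampled without replacement
(patients with fewer keep all their cells, with a warning; patients with none
are excluded) and averaged into a pseudobulk profile of mean log-normalised
expression. Patients are clustered with Ward-linkage hierarchical clustering
on Euclidean distances over the eight proxy genes, z-scored across patients
per gene. k is chosen to maximise mean silhouette over k = 2..8 unless fixed.
Ward was chosen for compact-group recovery; complete/average linkage are easy
substitutions. Candidate genes are contrasted between clusters with pairwise
Welch t-tests (Welch–Satterthwaite df), BH-corrected across pairs; pairs
involving a cluster of fewer than two patients are reported NA.

## Survival

Patients are dichotomised at the median by default (mean and quantile splits
available; an optimal-cut search is deliberately not implemented). Groups are
summarised with the Kaplan–Meier product-limit estimator and Greenwood
variance and compared with the log-rank test (hypergeometric variance per
distinct event time). The continuous association is estimated by univariate
Cox proportional hazards, maximising the Breslow partial likelihood by
Newton–Raphson with closed-form score and information; Breslow ties were
chosen over Efron for their simpler closed forms, adequate at the tie rates
the generator produces. Convergence at |Δβ| < 1e-8 (max 50 iterations);
divergence (monotone likelihood / separation) is an error, not a number. At
tied timestamps events precede censorings: a cell censored at t is still at
risk for the events at t. The reported Cox fit uses continuous expression;
the split drives the curves and the log-rank test.

## Reproducibility and problem sizes

All randomness flows from one global seed through named substreams
(`SeedSequence([seed, crc32(name)])`), so adding a stage never shifts another
stage's draws and identical configs give bit-identical outputs. Default
problem sizes — 11 datasets × 15 patients × 200–250 cells for discovery,
54 MM patients × 340–500 cells for the clustering experiment, n = 1,000–2,000
for survival — were chosen so that every planted effect is recoverable with
comfortable margins while a full multi-seed replication of the pipeline runs
in minutes on a single CPU.

## Known limitations

- The annotation stage is a deliberate simplification of reference-mapping
  workflows; its accuracy on real data depends entirely on the supplied
  centroid table.
- Selection thresholds before intersection are conventions, not estimates;
  on real cohorts they should be examined per dataset.
- Silhouette-based k selection on z-scored proxies can over-split when a
  proxy gene carries no subtype signal (see above); `fixed_k` exists for
  exactly that situation.
- The survival generator draws independent standard-normal expression per
  gene; correlated expression, non-proportional hazards and multivariate
  adjustment are out of scope.
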
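# Methods

This note documents the models and procedures behind `organofit`, the
defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## 1. Expression-inferred copy number

scRNA-seq measures transcripts, not DNA, but chromosome-scale dosage changes
shift the expression of many adjacent genes coherently. The profile of cell
*i* over genomic windows is computed as:

1. drop genes with mean count < 0.1 (default) — near-undetected genes carry
   no dosage information;
2. centre each gene's log2-normalised expression
   (`log2(1 + 10^4 · x / libsize)`) on the mean over *reference* cells —
   immune and stromal cells, assumed diploid; with multiple patients the
   centring is per patient against that patient's own reference, while gene
   retention and window layout stay global so profiles remain comparable
   across patients;
3. clip to ±1.5 — bounds the influence of extreme single genes;
4. per chromosome, flat moving average over *w* = 51 genes, truncated at
   chromosome ends, stored every *w*/2 positions; chromosomes with fewer
   than *w*/2 retained genes are skipped;
5. subtract the per-cell median (removes cell-level offsets), then re-centre
   each window on the reference mean, making reference profiles ≈ 0 by
   construction.

The window is flat rather than tapered and narrower than the common 101-gene
choice because the desk-scale gene universe carries ~90 genes per
chromosome; both are configurable. Genes with strong cell-state-specific
regulation (cell-type markers, hypoxia/proliferation/stemness program genes)
vary with a cell's state rather than its genome; when such panels are known,
the pipeline excludes them from windowing (`infer_cnv(exclude=...)`). This
matters: a strongly program-active subpopulation otherwise imprints on the
windows of whatever chromosomes host those genes and can masquerade as a
CNV clone.

**Malignancy.** CNV burden = mean squared profile value. Epithelial cells
are split per patient by 2-means on *log* burden; burden is a positive
mean-square whose aneuploid cluster is wide on the raw scale, and the log
keeps a rare benign compartment separable from it. In one dimension the
optimal 2-means partition is a threshold on the sorted values, so it is
found exactly by a prefix-sum scan — deterministic and
initialisation-free. The split is accepted only when the cluster-centre gap
exceeds both an absolute floor (0.02) and three pooled within-cluster
standard deviations (roughly what splitting a single unimodal cloud
produces); otherwise the patient is flagged as having no malignant
compartment. Cells in the accepted high-burden cluster must additionally
correlate with the high-burden centroid (r > 0.3) to be called malignant.

## 2. Clones, deviation scores, retention

**Clones** are Ward/Euclidean hierarchical clusters of malignant primary
profiles; *k* ∈ [2, 6] maximises mean silhouette, with a single-clone
fallback for degenerate (near-identical) profiles. Clone ids are ordered by
size so the partition is stable under cell-order permutation.

**Deviation scores.** For organoid malignant cell *c* of patient *p*,
`D = 1 − max_r` over a centroid set: the patient's own clones (paired), all
other patients' clones (background), or the patient's clones against
window-permuted copies of *c* (random; fresh permutation per draw, 100
draws averaged, one named RNG substream). D ∈ [0, 2]. Window-constant
cells (undefined correlation) are excluded and counted. Two-sided Student's
t-tests compare paired vs background and paired vs random per patient; a
Mann–Whitney check of stochastic dominance is kept in the test suite.

**Retention.** Organoid malignant cells are assigned to the
argmax-correlation primary clone when r ≥ τ = 0.5; a clone is retained when
its assigned cells number ≥ max(5, 1% of organoid malignant cells); the
retention rate is the primary-cell-weighted fraction of retained clones.
This definition has an exact identity — feeding the primary cells back as
the "organoid" yields retention 1.0 — which the test suite asserts, and is
monotone in designed clone loss by construction. "Preserved" =
retention ≥ 0.5 (configurable). Event-level preservation is reported
separately as per-sample fractions of amplified (> 0.15), deleted
(< −0.15) and neutral (cell, window) entries.

**Clone trees.** Primary and organoid malignant cells of one patient are
re-clustered jointly; neighbour-joining runs on Euclidean distances among
clone centroids plus an all-zero diploid profile, rooted at the diploid.
NJ rather than UPGMA because CNV accumulation is not clock-like. Tiny
negative NJ branch lengths are clamped to zero. A sidecar table carries
per-clone PBC/BCO cell counts and mean burden; on synthetic studies burden
increases along ≥ 80% of root-to-leaf orderings (tested, not guaranteed).

## 3. Composition, subtype, signatures

Cell types come from argmax of mean marker-panel expression (tie tolerance
10⁻⁶ → "unknown"); downstream statistics only need the three-way
epithelial/immune/stromal label, so no graph clustering is involved.
Composition shifts are per-patient log2 fold changes of proportions with an
ε = 10⁻³ pseudo-proportion, tested per cell type with one-sample t-tests
and BH adjustment.

Subtype calls correlate (Spearman) the malignant pseudobulk with a
user-supplied centroid table over shared genes (≥ 10 required); max r < 0.2
flags low confidence. The signature scorer bins genes into 25
mean-expression bins (by rank, so bins stay filled regardless of the
expression distribution) and draws 100 control genes per signature gene
from its bin; score = mean(signature) − mean(controls). The scored set is
never eligible as control, and callers scoring several programs on the same
cells should pass the union of program genes as `exclude`: a co-regulated
program inside a control pool biases the control mean and attenuates
between-score correlations (measurably — see §5). A single random gene
set's mean score fluctuates with the within-bin spread of its draw; the
scorer is unbiased in expectation, which is what the test suite asserts.

Stem clusters are k-means (k = 6 on top-50 PCs) clusters of TNBC malignant
cells that are simultaneously CD44-high (≥ 75th percentile of cluster
means) and ALDH1A2-low (≤ 25th); PBC vs BCO membership is compared by
two-proportion z-test. The hypoxia–stemness coupling is Pearson r with the
regression t-test `t = r·√((n−2)/(1−r²))`, plus a Student's t-test of
hypoxia scores between sources.

## 4. The synthetic generator

Counts are negative binomial, `NB(mean = L_i · m_ij / Σ_j m_ij, θ)` with
log-normal library size `L_i` (mean 6,000) and dispersion θ = 10
(Var = μ + μ²/θ; BCV ≈ 0.32, typical of UMI data — heavier overdispersion
measurably degrades score-level statistics below what the pipeline's own
validation demands). The multiplier `m_ij` is baseline relative abundance
(log-normal, σ = 1) times:

- clone dosage `copy_ratio^α` (α = 1) on segment genes — malignant cells
  only; presets use whole-chromosome one-copy gains (2.0) and losses (0.5);
- cell-type marker boost (8×, 25 genes/panel) and malignant subtype-marker
  boost (4×, 30 genes incl. ESR1 / ERBB2);
- program multipliers `exp(0.7 · a)` on 150 hypoxia and 150
  stem-cell-division genes, with latent activities
  `a_h = 1 + z_h`, `a_s = 0.5 + z_s`, `(z_h, z_s)` bivariate normal at
  ρ = 0.5; organoid culture multiplies the whole hypoxia activity by
  δ_h = 0.5 (oxygen-rich medium); stem-flagged clones add +1.5 to both
  latents and are CD44-high/ALDH1A2-low;
- proliferation boost (2×; ×1.5 extra in organoid malignant cells),
  claudin-low suppression (0.3×) in TNBC, ESR1 attenuation (0.5×) in
  HR-positive organoid cells.

Row-normalising `m` makes realised depth a technical property of the cell.
CNV events live on chr1–chr14; markers and signatures on chr15–chr22, so
state programs and dosage signal are separable by construction (the
generator warns if a design violates this). Marker genes draw abundance
from the upper half of the log-normal; signature genes from a full
log-normal (ties from flooring would pack expression bins with signature
genes and corrupt control matching).

**The preset study**: six patients (2 HR-positive, 2 HER2-positive,
2 TNBC), 500 PBC + 450 BCO cells each, primary compositions ~45% epithelial
/ 30% immune / 15% stromal and organoids ~98% epithelial. Every clone
carries a truncal pair of events (always the recurrent chr8 gain) plus two
private events — equal CNV load per clone, related-but-distinct profiles
across patients, which is what gives the background null its intermediate
correlation. Designed retentions (1.00, .80, .80, .55, .75, .45) place one
TNBC patient below the preservation threshold; both TNBC patients lose a
stem/hypoxia-high clone entirely in culture.

**What the generator does not emulate**: UMI/read-level noise, doublets,
ambient RNA, batch effects beyond the PBC/BCO split, sub-chromosomal
segment boundaries in the presets (supported by the types, unused),
cell-cycle structure, real gene-gene covariance. Passing tests therefore
show the statistics recover designed structure under realistic count noise
— not that the pipeline is robust to every artefact of real data.

## 5. Numerical choices and calibration

- θ = 10, 150-gene signatures and β = 0.7 were fixed together during
  generator design from a pilot decomposition of score-correlation
  attenuation: score noise scales as 1/√(n_genes · θ-dependent per-gene
  noise), and compositional cross-talk between co-scored programs scales
  with their library share — control-pool exclusion cancels most of the
  cross-talk, and the remaining attenuation at these defaults keeps
  score-level correlation recovery within ±0.05 of the designed latent
  correlation at n = 2000 cells.
- All randomness flows from one integer seed through named substreams
  (CRC-32 of the stream name into `SeedSequence`), so the permutation null,
  the simulator and the scorer are independently reproducible; the CLI run
  twice with one seed is byte-identical.
- Degenerate inputs are first-class: constant profiles are excluded and
  counted; indistinguishable burden clusters flag
  `no_malignant_compartment`; silhouette-undefined clone clustering falls
  back to a single clone; empty organoids flag zero retention; subtype ties
  break by column order with a warning.
- Problem sizes (2,000 genes, 300–800 cells/sample, 100 permutations) are
  chosen so the full suite and the acceptance script each run in minutes on
  one CPU while leaving ≥ 30 genes per CNV window after exclusions.

## 6. Known limitations

Expression-inferred CNV is a proxy — allele-specific or DNA-based
validation is out of scope. The deviation/retention definitions are one
concrete, configurable instantiation of "clonal preservation"; published
studies rarely state theirs precisely enough to match. The subtype caller
is a reduced nearest-centroid classifier, not the full PAM50 assay. The
malignancy caller assumes a CNV-quiet benign compartment; tumours with
near-diploid malignant cells would need the correlation gate and thresholds
re-tuned.
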
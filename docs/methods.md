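# Methods

`rh1coev` detects intramolecular coevolution with a focal residue of a
visual pigment (rhodopsin site 122 in bovine numbering by convention) by
intersecting four independent lines of evidence, and adds the two in-vitro
readouts used to characterize candidate sites functionally. This note
records the models, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices
that affect results.

## Codon substitution models

The substitution process is a GY94-type codon model on the 61 sense codons
of the standard code. Off-diagonal rates are zero for multi-nucleotide
changes and otherwise proportional to the target codon frequency π_j,
multiplied by κ for transitions and by ω = dN/dS for nonsynonymous changes.
The chain is reversible; likelihoods use Felsenstein pruning with
per-pattern scaling, pattern compression, and transition matrices from an
eigendecomposition of the symmetrized generator (scaling-and-squaring as a
fallback).

Site-to-site ω variation is a finite mixture:

* M0 (one ω), M1a (ω0<1, ω1=1), M2a (adds ωp≥1), M3 (three free ω),
  M7 (beta), M8 (beta + ωp≥1), M8a (beta + ωp=1), M2a_rel (ω2 free);
* Clade Model C (CmC): classes ω0<1 and ω1=1 shared across the tree, plus
  a divergent class whose ωd takes a separate value in each named
  foreground partition (a clade = MRCA subtree including its stem, or a
  single ancestral branch) and in the background. Constraining all ωd
  equal recovers M2a_rel, giving the standard LRT with df = number of
  extra ωd parameters.

Defaults and rationale:

* **Codon frequencies**: F3x4 estimated from the data (position-specific
  nucleotide frequencies), the common default of codon-model software;
  F61 and uniform are options. Recovery suites pass the known simulation
  π explicitly so that frequency estimation noise does not enter the
  comparison.
* **Beta discretization**: equal-probability categories with the median ω
  per bin; 10 categories by default. Benchmark-scale fits in the test
  suite use 3–5 categories — the discretization count is a resolution
  choice, not part of the model's identity, and simulator and fitter
  always share it.
* **Branch lengths**: taken from the input tree; a single scale factor is
  re-optimized per model (fast path). Full branch-length optimization is
  available but not used by the benchmark suites.
* **Rate scaling**: within each branch category (background and each
  foreground partition) the mixture-mean substitution rate is normalized
  to 1, so branch lengths read as expected substitutions per codon on
  every branch. The simulators use the identical convention; mixing
  conventions (e.g. simulating components scaled separately) makes ω
  ratios and absolute rates inconsistent and is the main way to build a
  misleading benchmark.
* **Optimizer**: L-BFGS-B on log/logit-transformed parameters (ω in (0,1)
  via logit, ωp = 1 + e^u, proportions via pinned softmax), with ≥1
  documented warm start and random restarts; convergence at |ΔlnL| below
  the optimizer's tolerance. For the M8-vs-M8a test the M8 fit is always
  warm-started from the M8a optimum both at the boundary (ωp→1) and just
  inside it (ωp≈1.14): the boundary start guarantees lnL(M8) ≥ lnL(M8a),
  while the interior start gives the optimizer usable curvature in ωp.
* **Parameter counting**: n_free_params = model parameters + 1 (κ) + 1
  (branch scale). Only *differences* in k are meaningful (they set LRT df
  and ΔAIC offsets), and those are convention-independent.
* **LRT boundary null**: M8 vs M8a constrains ωp to the boundary value 1,
  so the conventional 50:50 mixture of χ²₀ and χ²₁ is used; plain χ²
  tails are the default elsewhere.
* **Site classification**: naive empirical Bayes at the MLEs (posterior
  over classes per site). Full Bayes empirical Bayes integration over
  parameter uncertainty is out of scope; outputs are flagged `NEB`.
  Posterior-mean ω uses each class's background-category ω.

Known small-sample property: in the CmC recovery benchmark (30 taxa,
Table-like truth ω0=0.02, ωd 0.24 background / 0.13 foreground) the
foreground ωd ML estimate is biased upward by ≈+0.01 at 300 codons; the
bias is gone by 500 codons. The recovery suite therefore uses 500 codons
for this scenario and 300 for M0/M8.

## Mutual-information covariation scan

Columns of the translated alignment are compared by mutual information in
nats, computed from sequence-weighted, pseudocount-smoothed pair
frequencies. Weights are 1/(cluster size) under single-linkage clustering
at 62% identity; the pair-frequency smoothing is
J' = (1−λ)J + λ·(marginal outer product) with λ = 0.05 — the constants of
the corrected-MI literature, since the method this follows names the tool
but not its constants. The average-product correction removes the shared
background term (row mean × column mean / grand mean). z-scores
standardize the corrected MI against a null of within-column shuffles of
the whole alignment (100 by default; weights are computed once per dataset
and reused across its shuffles, which preserve column composition).
Dataset-level significance uses z* = the maximum |z| over all pairs across
fully randomized datasets (150 by default, per the randomization-cutoff
practice for intrafamily alignments); a pair is significant iff z > z*.

Limitation (inherent, and the reason this line of evidence is qualitative):
within-column shuffling destroys phylogenetic correlation in the null, so
on strongly tree-structured alignments background pairs can exceed z*.
Sequence weighting absorbs only part of this. The planted-pair benchmark
therefore evolves columns on a star phylogeny, where inter-column
covariation is exactly zero unless planted — this isolates the property
being tested (a planted bijective coupling attains MI = H(column) and is
uniquely detected) from the tree-correlation bias that the published
method itself treats only qualitatively.

## Correlated evolution of binary traits

Each candidate site is coded consensus (0) / variant (1) — consensus being
the most frequent residue, ties broken alphabetically, gaps missing — and
tested against the focal-site trait under the two-trait Markov model:
joint states {00, 01, 10, 11}, single-trait transitions only, 4 free rates
when each trait's gain/loss is independent of the other's state, 8 when
state-dependent. Root state probabilities default to the stationary
distribution of the fitted chain (equal probabilities are an option).
Rates live in [1e-6, 100] per unit tree height (the tree is rescaled
internally). The likelihood kernel is numba-compiled because the
Monte-Carlo test refits both models on every simulated replicate.

The Monte-Carlo p-value is a parametric bootstrap: simulate n_sim trait
pairs (≥1000 by default) under the independent model at its MLEs, refit
both models per replicate with the same optimizer settings as the
observed fit, and report p = (1 + #{sim LRT ≥ observed LRT})/(n_sim + 1) —
never zero by construction. Significance across a scan uses the Bonferroni
threshold α/m with m always reported (α = 0.05 over 25 candidate sites
gives the 0.002 threshold). Monomorphic traits are reported untestable,
not silently dropped. The asymptotic df-4 p-value is reported alongside
for reference only.

## Structural neighborhood

Distances are minimum Euclidean distances over all heavy-atom
(non-hydrogen) pairs of two residues, first alternate location only,
single chain — the convention most consistent with published contact
distances for the metarhodopsin-II structure. The focal neighborhood is
all residues with minimum distance ≤ radius (6 Å default, the range of
direct Van der Waals/hydrophobic contact); focal±1 and ±2 sequence
neighbors are always added to the scan set with their distances recorded
separately, since covalent adjacency is not a through-space contact.
Min-distances deliberately violate the triangle inequality; no metric
structure is assumed.

## Photochemistry

λmax is fit by least squares of (scale × A1 template) to a dark spectrum:
the standard rhodopsin α-band template (the Govardovskii-type exponential
sum with its λmax-dependent shape constant) plus the β-band Gaussian
(A_β = 0.26, λ_mβ = 189 + 0.315·λmax, b_β = −40.5 + 0.195·λmax). Scale is
profiled out analytically, λmax grid-searched over the window (450–550 nm,
0.1 nm) then refined locally; the fit is exactly invariant to overall
absorbance scaling.

Retinal-release fluorescence traces are fit to y = y0 + a(1 − e^(−bt)) by
nonlinear least squares (starts: y0 = first point, a = range, b from the
log-linearized tail; b bounded in (1e-4, 10) per minute). t½ = ln2/b holds
exactly by construction. Fits with r² ≤ 0.95 are flagged as failing the
quality gate; flat traces and rate constants at the bounds are errors, not
numbers. Replicates are summarized as mean ± standard error with n, and
groups compared with Welch's two-tailed t test (Welch–Satterthwaite df),
with */**/*** stars at 0.05/0.01/0.001.

## Synthetic data

All generators are pure functions of their parameters and a seed:

* codon alignments evolved along a tree under any of the site-class
  mixtures above (root codons from π, class drawn per site, clade shifts
  switch the divergent class's ω on foreground branches), returning true
  class labels;
* planted covarying column pairs: column j rewritten as a residue-level
  bijection of column i (exact mode; H(j) becomes H(i) and MI(i,j) =
  H(i)) or with a keep-original noise probability;
* correlated binary trait pairs sampled exactly through per-branch
  transition probabilities of the joint chain;
* release traces (30 s sampling by default) and A1-template spectra with
  i.i.d. Gaussian noise.

The default benchmark tree is a 30-taxon balanced ultrametric tree of unit
height split into two named clades — a desk-scale stand-in for a
teleost/tetrapod-style partition. The generators deliberately do not
emulate indels, alignment error, sequencing error, codon-usage bias beyond
π, or lineage-specific rate variation beyond the clade-model shifts;
passing tests therefore demonstrate correctness of the machinery under the
stated models, not robustness of the biology to misalignment or model
violation.

## Benchmark sizes

The test suite runs everything at documented desk scales: likelihood
oracles on ≤4-taxon trees (full state enumeration); ω recovery at 30 taxa
with 300 codons (M0, M8) and 500 codons (CmC, see above); type-I
calibration of M8-vs-M8a over 200 null replicates at 6 taxa × 50 codons
with 3 beta categories and κ and branch scale held at their known
simulation values for both models; Pagel Monte-Carlo calibration over 200
null replicates on a 12-leaf tree with n_sim = 199 and identical
(deliberately matched) optimizer settings for observed and simulated
fits; the MI planted pair over 100 replicates of 40 sequences × 12 columns
with 60 randomized datasets per replicate (family-wise control of the
cutoff scales with the number of randomized datasets). Rejection-rate checks use the 95% binomial band around 0.05.

## Known limitations

* NEB rather than BEB site classification (flagged in outputs).
* MI is tree-aware only through sequence weighting; the randomization
  cutoff does not model shared-branch correlation (see above).
* CmC assumes the divergent class is the same set of sites in all
  partitions; no branch-site switching within a class.
* The A1 template constants are fixed; no A2 pigment template.
* Ancestral reconstruction is marginal per node; no joint reconstruction
  or sampling.
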
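# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic benchmarks demonstrate.

## Problem and model

The task is binary classification of human proteins into
plasma/blood-secretory versus non-secretory, from sequence-derived
information only. The classifier is deliberately simple — L2-penalised
logistic regression on standardized features — so that the weights
remain interpretable; the modelling effort sits in the encoding and in
wrapper feature selection.

### The 470-dimensional encoding

Block order is fixed: RAAC (20) | SS (39) | EC (400) | PP (11).

* **RAAC.** Per-protein relative amino-acid composition
  `(f_a − bg_a)/bg_a` against a Swiss-Prot-like background table
  shipped with the package (overridable). A `raac_mode="raw"` option
  substitutes the raw composition; the relative form is the default
  because the enrichment signal (Thr, Cys up; Lys, Gln, Arg down in
  secretory proteins) is what carries class information.
* **SS.** From a three-state secondary structure (PSIPRED `.ss2` or a
  plain H/E/C string): three state-content values (mean per-residue
  probabilities when available, otherwise state fractions, order C, H,
  E), then for each of the 12 ordered run-triplet motifs XYZ with X≠Y,
  Y≠Z in lexicographic order (CEC, CEH, CHC, CHE, ECE, ECH, EHC, EHE,
  HCE, HCH, HEC, HEH): the fraction of residues covered by at least one
  occurrence of the motif, the motif's share of all run-triplet windows
  (all 12 shares sum to 1, or all are 0 when there are fewer than three
  runs), and the mean motif span divided by L. Counting *distinct*
  covered residues keeps the residue fraction in [0, 1] even when two
  occurrences of the same motif type overlap in a run. The
  3 + 12×3 = 39 layout is chosen so the total feature count is exactly
  470 with the other three blocks fixed.
* **EC.** `S_ij = Σ_{pos: residue(pos)=i} pssm[pos, j]` over the
  PSI-BLAST log-odds block (not the percentage block: the entries of
  the profile matrix are substitution scores, which is the log-odds
  semantics), then `1/(1 + exp(−S_ij/L))`. The division by sequence
  length L inside the logistic makes the encoding exactly invariant
  under duplicating a sequence and stacking its profile — this is the
  property that pins down "logistic normalisation against length"
  as an explicit formula, and it is enforced by a test.
* **PP.** Eleven residue classes as binary memberships (aliphatic
  {A,G,I,L,P,V}, sulfur {C,M}, aromatic {F,W,Y,H}, hydrophobic
  {A,C,F,I,L,M,V,W}, charged {D,E,K,R,H}, polar {D,E,H,K,N,Q,R,S,T,Y},
  positive {K,R,H}, acidic {D,E}, small {A,C,D,G,N,P,S,T,V}, tiny
  {A,C,G,S,T}, hydroxylic {S,T,Y}); the feature is the class fraction
  of the sequence. Exact numeric hydropathy-style scales would also
  fit the same interface, but class memberships are the standard
  reading of these eleven property names.

Non-canonical residues (B, Z, J, U, O) are mapped to X on input; X
positions are excluded from composition denominators, from EC sums and
from the effective length, keeping all 470 features defined on the
20-letter alphabet without inventing property values.

### Wrapper selection: discrete firefly algorithm

Subset fitness is `f = 0.55·MCC + 0.45·(1 − n/N)`, with MCC from an
internal stratified cross-validation of the logistic model restricted
to the subset. The internal folds are fixed by a dedicated
`fitness_fold_seed` independent of the run seed, so every optimizer
run — and the exhaustive oracle — optimises the *same* deterministic
fitness function, and subset evaluations are memoized by mask.
Because a wrapper search runs thousands of evaluations against the same
partition, it can overfit the partition's noise — lucky noise features
displace genuinely informative ones. `fitness_cv_repeats` therefore
averages the MCC over several independent fold partitions (the
high-dimensional experiments use two); this measurably cleans the
selected masks on planted data.

Movement follows the standard attraction form
`x ← x + β₀ e^(−γ r²)(s_j − s_i) + α ε` (ε standard Gaussian), with the
attraction pointing *towards* the brighter firefly; discretisation is
stochastic (`sigmoid(x_k)` against an independent uniform draw), and an
all-zero mask is repaired to a random single bit because the sparsity
term would otherwise make the empty subset — whose MCC is undefined —
a strong attractor. The brightest firefly performs a pure random walk.
The global best subset is retained across generations, which is what
makes every best-fitness trace non-decreasing.

Defaults follow the published configuration (α = 0.9, γ = 0.5,
population 50, 3000 generations, weights 0.55/0.45; GA crossover 0.6,
mutation 0.033; PSO c₁ = 1, c₂ = 2, inertia 0.9). β₀ = 1 is the
standard convention, as the base attractiveness is not otherwise
specified.

**Absorption scaling.** With bit-mask distances, `r² = Hamming`, and a
random pair of masks over N features sits at `r² ≈ N/2`. At γ = 0.5 and
N = 100 the attraction factor is `e^(−25) ≈ 10⁻¹¹`: the swarm degrades
into independent random walks and only elitism accumulates progress.
We therefore scale the absorption coefficient with the problem
dimension in the high-dimensional experiments, `γ = 1/N`, which puts
`γ·r²` at order 1 at typical inter-firefly distances — the standard
firefly-algorithm guidance of choosing γ by the characteristic length
scale of the search domain. The low-dimensional oracle-equivalence
experiment keeps γ = 0.5.

**Known behaviour under sparsity pressure.** On planted data the
fitness optimum need not contain *all* informative features: once the
cross-validated MCC saturates, the marginal MCC gain of one more
informative feature can drop below the sparsity cost ω_β/N, and the
selector — correctly optimising its objective — prunes it. Recovery
percentages on planted benchmarks should be read with this in mind:
they measure the fitness's preference structure as much as the
optimizer's competence.

### Evaluation protocol

Repeated balanced undersampling: per repeat, draw equal-size class
samples without replacement, run stratified k-fold CV fitting the whole
pipeline (standardization, any selection, the classifier) on training
folds only, pool the out-of-fold predictions into one metric report,
then aggregate mean ± sample standard deviation (ddof = 1) over
repeats. All pipelines under comparison see identical repeat samples
and fold splits, so per-repeat metrics are paired; the significance
gate runs Shapiro–Wilk on the paired differences at α = 0.05 and then a
paired *t*-test (normal) or Wilcoxon signed-rank (otherwise),
two-sided. All-equal differences return p = 1 with a degeneracy flag.

MCC uses the standard square-root denominator
`√((TP+FN)(TP+FP)(TN+FP)(TN+FN))`. Any zero metric denominator yields
0 with a flag rather than an exception, keeping swarm fitness total.
AUC is computed by the mid-rank statistic, which equals the trapezoidal
area under the stepwise ROC curve, ties counted half; the equivalence
is verified against an independent trapezoidal computation in the
tests. Classification threshold is 0.5 (configurable), and the default
L2 strength is 1.0 on standardized features.

## Synthetic data: what it emulates, and what it does not

* **Planted feature matrices** are class-conditional spherical
  Gaussians: informative dimensions shift the positive class by
  `effect_size · noise_sd`, everything else is exchangeable noise, and
  exact column duplicates can be planted. The Bayes AUC of the
  informative-sum score is `Φ(effect·√k/√2)`, giving closed-form
  calibration targets.
* **Secretory-like corpora** draw residues i.i.d. from a composition
  tilted in log-fold units (defaults: T +0.38, C +0.10, K −0.10,
  Q −0.12, R −0.14 — the direction, not the magnitude, of the known
  secretory enrichment pattern), secondary structure from a first-order
  Markov chain with geometric run lengths (default means H 8, E 5, C 6
  residues — typical helix/strand/coil scales), and PSSM-like profiles
  scoring `+7·conservation` on the true residue and `−2·conservation`
  elsewhere plus integer-rounded Gaussian noise clamped to [−10, 12].

These generators exercise every file format and every code path, and
they carry a genuine class signal through the RAAC/EC blocks. They do
*not* contain signal peptides, domain architecture, phylogenetic
correlation between positions, or realistic length/composition
coupling — so a high AUC on synthetic corpora demonstrates that the
pipeline extracts the signal its feature blocks are designed for, not
that the predictor would reach the same performance on real proteomes.
The published benchmark datasets are not redistributable here, which is
why all quantitative acceptance is property- and simulation-based.

## Problem sizes in the shipped experiments

The default test and acceptance runs use deliberately compact problem
sizes chosen as the smallest at which each property is cleanly
measurable: oracle equivalence at N = 10, n = 60 (1,023 enumerable
subsets; firefly at population 30, 200 generations, 10 seeds); planted
recovery at N = 100, k = 8, effect 1.5, n = 200 (population 20, 30
generations, γ = 1/100, fitness averaged over two 5-fold partitions,
3 seeds); the end-to-end corpus at 80 + 80
proteins with conservation 0.8 (population 20, 100 generations,
γ = 1/470, 3-fold fitness CV, then 10×5-fold undersampling CV at 64 +
64 per repeat). The full published-scale configuration (population 50,
3000 generations, 250 + 250 samples) is available through the same
configuration objects.

## Known limitations

* The fitness MCC from a single fixed fold partition is a noisy
  estimate; wrapper selection can overfit it (selection bias), which is
  why held-out evaluation always re-fits the pipeline inside CV folds.
* Run-triplet motif statistics are length-biased for short proteins
  (few runs → zero motif blocks); the encoder defines those values as 0
  rather than missing.
* `group_raac`'s pooled bootstrap treats sequences as exchangeable
  units; it is a dataset-level descriptive tool, not a per-protein
  feature.
* The GA and BPSO comparators are faithful baselines, not tuned rivals.
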
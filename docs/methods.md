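# Methods

## Model

A binding-site classifier is a soft-margin SVM with the linear kernel
applied to an explicit, sparse feature map. For a sequence *s* over
{A,C,G,U}, the k-spectrum block contains the count of every substring of
every length k in [K1, K2] (the union over lengths, so a (7,9) model mixes
7-, 8- and 9-mers). Because the feature map is explicit, the primal weight
vector w = Σᵢ αᵢ yᵢ Φ(sᵢ) is recovered exactly from the dual solution, and
each feature's weight is its signed contribution to the decision function
f(x) = ⟨w, Φ(x)⟩ + b. Ranked weights are how motifs are read out of the
model. The dual is solved with an exact SMO solver (scikit-learn's `SVC`,
linear kernel); a test asserts that the explicit-weight decision values
match the solver's kernel-form decision function to 1e-6, so the contract
is the decision function, not the solver.

Counts are raw integers, not length-normalized and not kernel-normalized
(cosine normalization is available behind a flag). The engineered
composition block holds seven length-normalized features: the four base
frequencies (aCount…cCount), the number of maximal homopolymer runs of A
or U of length ≥ 2 (aRepeatedCount, uRepeatedCount; an alternative "total
bases inside runs" reading is selectable via `run_mode`), and the count of
overlapping AU-rich dimers AA/AU/UA/UU (auCount), each divided by sequence
length L. These are concatenated unscaled with the integer spectrum counts;
their [0,1] scale is why they attract large weights when informative.

## Model selection

Grid search iterates K1 ≤ K2 over 7..13 (28 pairs) and C over 1e-10..1e4 in
powers of ten (15 values; 420 cells). Each cell is scored by the mean ROC
AUC of a 10-fold stratified cross-validation on an 80% training split, with
one seeded fold assignment reused across cells so cells differ only in
their parameters. Ties break toward smaller C, then narrower [K1,K2], then
smaller K1 — prefer the simpler model. The winner is refit on the full
training split and reported on the untouched 20% holdout. All splits and
folds are seeded; identical seeds and data give identical results.
Degenerate folds cannot arise because the precondition `class count ≥ folds`
is enforced before stratification.

## Metrics

Success rate, balanced success rate ((sensitivity + specificity)/2, the
headline number under class imbalance), sensitivity, PPV, and ROC AUC, all
on a 0–100 scale. ROC AUC uses midrank tie handling and therefore equals
the scaled Mann–Whitney U statistic; the test suite asserts this identity
against `scipy.stats.mannwhitneyu` to 1e-9. A decision value of exactly 0
predicts negative. With a single class present, ROC is undefined and
reported as `None` while the confusion-derived metrics are still returned.

## Domain adaptation

The combined model M_B is built by (1) training per-domain models M_H and
M_T independently; (2) taking the union of their nonzero-weight features as
candidates; (3) restricting each record's vector to the candidates and
duplicating every entry under its domain prefix (feature augmentation: one
shared copy plus one domain-specific copy, both carrying the same numeric
value — no 1/√2 scaling, which gives the clean kernel identities
⟨aug_d x, aug_d y⟩ = 2⟨x,y⟩ and ⟨aug_d x, aug_e y⟩ = ⟨x,y⟩); (4) training
one SVM on the pooled augmented data. A feature with most of its weight on
the shared copy transfers across domains; weight on a prefixed copy is
domain-specific. When scoring with M_B, test records are augmented with
their own domain tag first.

## Cluster partitioning and scenarios

Two interval sets are partitioned with a 1-bp minimum-overlap rule, same
chromosome and strand (interval trees; verified against a brute-force
all-pairs oracle). An A-set cluster overlapping any B-set cluster
represents the "common" category; the overlapped B clusters are consumed;
remainders form the exclusive categories. The four scenarios reassemble
{HuR-only, TTP-only, common} into positive/negative contrasts (e.g.
scenario 4 = HuR-only vs TTP-only; scenario 3 = common vs both exclusives)
and run the full grid-search pipeline per contrast with a shared seed for
comparability.

## PFM scoring

Position frequency matrices (MEME-minimal text input, hand-parsed because
the available minimal-format readers reject the ACGU alphabet) are scored
as the best window sum of log2((p + ε)/0.25) with pseudocount ε = 1e-3,
forward strand only. Classification calls a record positive when its best
score exceeds `fraction` × the maximum achievable (consensus) score; an
exact tie at the threshold also passes, so the consensus itself is always
recovered at fraction 1. Note that log-odds scores can be negative, so as
fraction → 0 the threshold tends to 0, not −∞: only records with a
positively-scoring window are called.

## Synthetic data

The generator emulates the statistical structure of PAR-CLIP cluster sets:

- **Lengths** follow a shifted geometric law truncated to [min, max], with
  the decay rate calibrated by bisection so the truncated mean hits the
  target. Presets: HuR-like (mean 56, range 19–243), TTP-like (mean 26,
  range 21–172). The geometric choice reflects the strong right skew of
  real cluster lengths (mean far below max).
- **Composition**: HuR-like sequences are U-heavy (A/C/G/U =
  .15/.10/.10/.65), TTP-like are AU-balanced (.35/.08/.07/.50), background
  is mildly AU-rich 3′UTR-like (.28/.18/.18/.36). The preset probabilities
  are package choices, configurable per `GeneratorSpec`.
- **Motifs** are embedded independently per sequence with probability 0.4
  each at a uniform offset, overwriting background (at most one embedding
  per motif; later embeddings may overwrite earlier ones): poly-U variants
  for HuR (UUUUUUUUU, UUUAUUUUU, CUUUUUUUU), AUUUA-repeat variants for TTP
  (AUUUAUUUA, UAUUUAUUU, UUAUUUAUU).
- **Toy bundles** plant these clusters inside 3′UTR transcripts on a
  generated genome, overlap a configured fraction of TTP clusters with HuR
  clusters (co-bound sites), add cluster-free transcripts for control
  sampling, and record a ground-truth table. All intervals are on the plus
  strand for clarity of the truth table; strand handling is exercised
  separately by the extraction tests.

Every generator output is a pure function of its spec including the seed.

What passing on synthetic data does and does not show: the generator plants
composition differences plus literal motifs in otherwise i.i.d. background,
so it validates the machinery (counting, optimization, weight readout,
partition bookkeeping, augmentation algebra) and the qualitative behaviors
(U-rich features top the HuR model, AUUUA-family features mark TTP,
exclusive sets separate better than the co-bound set). It does not
reproduce the correlation structure, shared flanking context, or conversion
artifacts of real CLIP clusters, so headline numbers on synthetic data are
not estimates of performance on real data.

One observed consequence: on 1000 U-rich positives vs 1000 background with
a reduced K ∈ {5, 7} grid, cross-validated ROC slightly prefers K = 5 — the
composition signal makes 5-mers sufficient — so the selected model's top
features are 5-mers rather than the longer U-tracts a K = 7 model reports.
The motif-length readout on synthetic data is therefore sensitive to the
grid offered, which is itself consistent with composition (not long-range
structure) carrying most of the class signal here.

## Controls

For each positive, a negative of identical length is sampled from a
transcript chosen uniformly among annotated 3′UTR transcripts that are long
enough and overlap no positive cluster, at a uniform start offset; one
seeded stream drives all draws. By default only the same protein's positive
set is excluded (configurable by passing a combined interval list).

## Numerical and degenerate-input choices

- Mean lengths are reported rounded to the nearest integer (half away from
  zero).
- k-mers spanning a non-ACGU character are skipped, not errors; windows of
  valid characters on either side still count.
- Missing BED strand defaults to "+"; missing names are auto-generated as
  `chrom:start-end`.
- Sequences shorter than k contribute nothing at that k; a vector may be
  engineered-only.
- Features absent from a model's support contribute 0 to its decision
  value.

## Problem sizes

Test-suite and acceptance-script experiments use 1000 + 1000 sequences for
motif recovery with the reduced grid (K1 = K2 ∈ {5,7}, C ∈ {0.01, 1, 100},
10-fold CV), 250 + 250 toy-bundle clusters for the scenario contrast, and
500 + 500 per domain for the combined model — sizes at which the planted
effects are comfortably detectable and a full run of the suite completes in
about a minute on one CPU.

## Known limitations

- Linear spectrum kernel only: no mismatch/gapped/wildcard kernels, no
  secondary-structure features.
- The grid search refits per cell without warm starts; very large grids on
  large datasets are compute-bound.
- The common-category representative is the first-argument (A-set)
  interval; counts of common clusters therefore depend on argument order
  when overlap groups are many-to-many.
- PFM scoring does not scan the reverse strand (RNA) and does not compute
  E-values.
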
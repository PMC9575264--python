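# Methods

## Problem setting

Confirmed miRNA–disease associations are positive-only; the complement
of the catalogue mixes true negatives with undiscovered positives. The
package screens that unlabelled set **U** for pairs that can safely be
treated as negatives when training a supervised association predictor.
Its two stages both rest on one assumption: functionally similar miRNAs
tend to associate with semantically similar diseases, so a pair's
similarity profile — the miRNA's row of the miRNA–miRNA similarity
matrix concatenated with the disease's row of the disease–disease
matrix, miRNA scores first — carries a signal separating plausible
associations from implausible ones.

## The screen

**Stage 1 (semi-supervised k-means).** Two centroids are seeded from
the labelling itself: c₁ = mean of the positive features, c₂ = mean of
all unlabelled features (including whatever hidden positives U
contains — deliberately, since only the labelling is known). The first
assignment is by cosine similarity; all refinements recompute both
centroids from the current split and reassign by squared Euclidean
distance. The metric switch is intentional and kept: the first pass
judges orientation of the similarity profile, the refinements behave as
ordinary 2-means. The loop stops when assignments repeat, when the
larger of the two centroid movements is ≤ `tol` (default 1e−6), or at
`max_iter` (default 100). No step is randomised, so stage 1 is exactly
reproducible.

**Stage 2 (Rocchio).** Round 1 compares each likely negative to a
global prototype pair built from P (in-class weight α = 16) and LN1
(out-class weight β = 4) after L2-normalising every member; the class
whose prototype has the larger cosine wins. Round 2 splits LN2 into
K = 3 subsets by k-means (k-means++ with 10 restarts under a fixed
seed) and repeats the prototype test locally per subset, which is the
round's purpose: a global prototype blurs heterogeneous negatives, a
local one does not.

## Interpretation choices the procedure leaves open

These were genuinely open design points; each is a config switch with
the reasoning here.

- **Round-2 acceptance rule** (`rocchio2_rule`, default `nearest`): the
  local test is applied to the subset the sample belongs to. Requiring
  the negative prototype to win against *every* subset's pair (`all`)
  is provably degenerate once the subsets are genuinely distinct
  clusters — a sample is cosine-close only to its own cluster's
  negative prototype, so unanimity empties RN; `any` is equivalent to
  `nearest` in practice because the winning subset is almost always the
  sample's own. Both alternatives remain available.
- **Tie-breaks**: stage-1 ties (both metrics) go to the likely-negative
  side — the stage exists to screen negatives conservatively, and an
  ambiguous pair should not be called likely positive. Round-1 Rocchio
  ties go to the positive side (the positive branch is the "otherwise"
  of the rule); round-2 requires a strict win, so ties are excluded
  from RN.
- **Zero-norm profiles**: cosine against a zero vector is defined as −1,
  never NaN; an empty profile carries no evidence of positivity, falls
  to LN1 in stage 1, is excluded from prototype means, and is never
  admitted to RN.
- **Empty cluster during refinement**: the empty side keeps its previous
  centroid and the run continues; a run that ends with one empty side
  returns it empty with a warning rather than aborting.
- **Reliable positives** (`positive_rule`, default `rp1_and_lp1`): a
  pair must look positive to both screens — it lies in LP1 *and* the
  round-1 prototype pair scores it positive. Note that taking a literal
  intersection of LP1 with the round-1 positive flags of LN1 members
  would always be empty (those flags are defined on LN1, which is
  disjoint from LP1), so the "both screens" reading applies the
  prototype test to LP1. `lp1_only` and `rp1_only` are the one-screen
  alternatives.
- **Similarity matrices are used raw** — no row normalisation, no
  clipping of out-of-range values (they are rejected as malformed
  input), and an off-1 diagonal only warns.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha`, `beta` | 16, 4 | in-/out-class prototype weights; the 4:1 ratio keeps prototypes anchored to their own class while pushing away from the other |
| `k_subsets` | 3 | local subsets in round 2; more subsets localise harder but thin each prototype's support |
| `tol`, `max_iter` | 1e−6, 100 | stage-1 stopping; `tol=inf` reduces stage 1 to the single cosine assignment |
| `kmeans_seed` | 0 | the only randomness in the screen (round-2 clustering) |

All quantities are unitless (similarities in [0, 1]).

## Synthetic data: what it emulates and what it does not

The generator plants the method's assumption directly: miRNAs and
diseases are assigned to `n_blocks` aligned blocks; similarity is
`within_block_sim` inside a block and `between_block_sim` across
(symmetrised Gaussian noise `sim_noise_sd` added, clipped to [0, 1],
unit diagonal); a pair is truly positive with probability
`pos_rate_in_block` when its two members share a block and
`pos_rate_out_block` otherwise; `hide_frac` of the true positives are
removed from the observed table but stay positive in truth. The hidden
positives are the stressor — they are exactly the pairs a naive random
negative draw would mislabel.

Block sizes halve from block to block (sizes ∝ 2^−a). This skew is
deliberate and load-bearing: real association catalogues are
long-tailed (a few large disease/miRNA clusters carry most known
associations), and with equal blocks and uniform rates the positive
class's feature mean coincides with the unlabelled mean — the planted
structure becomes a pure interaction invisible to any centroid- or
prototype-based screen, which would misrepresent the data the method is
designed for.

Defaults: 60 miRNAs × 40 diseases, 3 blocks, similarities 0.8/0.2 with
noise sd 0.05, positive rates 0.5 (within) / 0.02 (across), 20% of
positives hidden. At these conditions a dataset has ≈ 530 true
positives, ≈ 425 observed, and U is ≈ 95% truly negative.

What the generator does *not* model: per-entity degree heterogeneity
inside a block, overlapping or hierarchical disease clusters,
similarity matrices estimated with correlated (non-i.i.d.) noise, and
any biological structure beyond block membership. Passing tests
therefore show that the screen exploits block-structured similarity
under label hiding — not that it ranks negatives correctly in any real
catalogue.

## Evaluation harness

Negatives selected by a strategy (`kr_nssm`, `ss_kmeans_only`,
`rocchio_only`, `random`, `kmeans_cluster_random`) are balanced 1:1
against the observed positives — reliable positives are reported but
never recycled into training — and scored by stratified fivefold
cross-validation on AUC, AUPR, precision, recall, F1 and accuracy
(0.5 decision threshold for the last four; folds are stratified rather
than plain random splits to avoid degenerate folds at desk scale).
Logistic regression (standardised features, lbfgs) is the benchmark
classifier; boosted trees (1000 trees, learning rate 0.05), RBF-kernel
SVM, random forest and an MLP are available presets behind the same
interface. `negative_purity` — the fraction of a selected set that is
truly negative under synthetic truth — is the direct, classifier-free
measure of reliability.

Problem sizes: the test suite and the acceptance script run the full
screen on the 60×40 default grid (2400 pairs, 100-dim features) and
its properties on 30×20 grids, with 10 replicate seeds for the
directional claims (purity and AUC of the screen vs random selection,
combined screen vs single stages). The structure-sensitivity check is
run in the noise-limited regime (similarity gap comparable to the noise
sd, between = 0.4, sd = 0.2): at the default low noise the block
structure is already fully detectable at tiny gaps — the profile
aggregates the gap over dozens of coordinates — and purity saturates,
leaving no ordering to observe.

## Known limitations

- The screen is first-moment based; planted structure that only shows
  up in interactions (e.g., perfectly balanced co-clusters) is
  invisible to it, a limit inherited from the method, not the code.
- With strong, well-separated structure, stage 2 often confirms stage 1
  wholesale (LN2 = LN1 = RN); the Rocchio rounds earn their keep when
  stage 1 under-screens, and on their own (`rocchio_only`) when no
  k-means pre-screen is applied.
- `build_feature_matrix` materialises all m·d profiles; at 495×383 this
  is ≈ 1.3 GB of float64 — acceptable on a workstation, but a chunked
  path would be needed for much larger catalogues.
- Reliable-positive selection shares stage 1's assumptions and is
  reported without any external validation hook.
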
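# negsel — reliable negative selection for miRNA–disease association prediction

Databases of miRNA–disease associations record only confirmed links.
Supervised link predictors therefore face a positive–unlabelled (PU)
problem: the "negative" training examples must be mined from the vast
unlabelled pair universe, which silently contains undiscovered true
associations. Training on randomly drawn "negatives" injects label noise
and caps prediction accuracy.

`negsel` implements a two-stage screen that distils *reliable negatives*
(and reliable positives) from the unlabelled pairs, plus the evaluation
harness to quantify what that buys a downstream classifier.

## The method

Each pair (miRNA *i*, disease *j*) is represented by its similarity
profile: row *i* of an m×m miRNA functional-similarity matrix
concatenated with row *j* of a d×d disease semantic-similarity matrix
(feature length m+d; 495 + 383 = 878 at the scale of the standard
benchmark). Known associations form the positive set **P**; all other
pairs form the unlabelled set **U**.

**Stage 1 — semi-supervised two-centroid k-means.** Centroids are seeded
as c₁ = mean(P) and c₂ = mean(U). The first assignment of each u ∈ U
maximises cosine similarity, x = argmax_k cos(u, c_k); every later
iteration recomputes the centroids from the current split and reassigns
by squared Euclidean distance, x = argmin_k ‖u − l_k‖², until the
centroids are stable. The result splits U into likely positives **LP1**
and likely negatives **LN1**.

**Stage 2 — two rounds of Rocchio prototype classification.** Round 1
builds a prototype pair from L2-normalised members,

    c⁺ = α·mean_{x∈P} x/‖x‖ − β·mean_{x∈LN1} x/‖x‖,
    c⁻ = α·mean_{x∈LN1} x/‖x‖ − β·mean_{x∈P} x/‖x‖,

with α = 16, β = 4, and keeps a likely negative when cos(x, c⁺) <
cos(x, c⁻), giving **LN2**. Round 2 splits LN2 into K = 3 k-means
subsets N_j, forms a local prototype pair (n_j, p_j) from each subset
against P by the same formula, and retains in the final reliable
negative set **RN** only samples whose local negative prototype wins
strictly. Reliable positives **RP** are the LP1 members the round-1
prototypes also call positive.

Negatives drawn from RN replace random draws when building a balanced
training set for any downstream classifier.

## Worked example

Everything is testable without any download: the synthetic generator
plants the structure the method assumes (similar miRNAs associate with
similar diseases, as aligned similarity blocks) and hides 20% of the
true positives inside U so that ground truth is known.

```python
import numpy as np
from negsel import (SyntheticConfig, generate, kr_nssm,
                    sample_balanced_negatives, negative_purity)

assoc, sim_mirna, sim_disease, truth = generate(SyntheticConfig(seed=0))
result = kr_nssm(assoc, sim_mirna, sim_disease)
s = result.sets
print({n: np.asarray(getattr(s, n)).size
       for n in ("P", "U", "LP1", "LN1", "LN2", "RN", "RP")})
neg = sample_balanced_negatives(result, np.asarray(s.P).size, seed=0)
print(f"screened purity {negative_purity(neg, truth):.4f}  "
      f"unlabelled baseline {negative_purity(s.U, truth):.4f}")
```

prints

```
{'P': 438, 'U': 1962, 'LP1': 1042, 'LN1': 920, 'LN2': 920, 'RN': 920, 'RP': 1042}
screened purity 0.9749  unlabelled baseline 0.9439
```

Of the 2400 pairs on the 60×40 grid, 438 are observed positives; the
screen calls 920 of the 1962 unlabelled pairs reliably negative, and
97.5% of a balanced draw from them are truly negative versus 94.4% of
the unlabelled pool at large — the hidden positives were preferentially
routed to the likely-positive side. Feeding these negatives to a
logistic-regression benchmark under stratified fivefold cross-validation
(seed 0) gives AUC 0.9525 against 0.6173 with randomly drawn negatives;
the combined screen is also at least as good as either stage alone
(`negsel.evaluation.ablation_table` reproduces the three-arm
comparison).

The same workflow is available from the shell:

```bash
negsel simulate --seed 0 --out data/
negsel select --assoc data/associations.csv --sim-mirna data/sim_mirna.tsv \
    --sim-disease data/sim_disease.tsv --out run/
negsel ablate --assoc data/associations.csv --sim-mirna data/sim_mirna.tsv \
    --sim-disease data/sim_disease.tsv --out ablation.csv
```

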
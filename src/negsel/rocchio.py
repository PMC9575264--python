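"""Rocchio prototype screening: likely negatives -> reliable negatives.

Round 1 builds one prototype pair from the positives P (in-class weight
``alpha``) and the likely negatives LN1 (out-class weight ``beta``):

    c+ = alpha * mean_{x in P} x/||x||  -  beta * mean_{x in LN1} x/||x||
    c- = alpha * mean_{x in LN1} x/||x||  -  beta * mean_{x in P} x/||x||

A likely negative whose cosine to c+ is strictly below its cosine to c-
becomes a round-1 reliable negative (LN2); otherwise it is flagged
positive (ties included — the "otherwise" side is positive).

Round 2 guards against round-1 errors: k-means splits LN2 into
``k_subsets`` local subsets N_j, each paired with P to form a local
prototype pair (n_j, p_j) by the same formula, and a sample survives
into the final reliable negative set RN only if the negative prototype
wins strictly. By default the test is local (``rule='nearest'``: the
sample is judged against its own subset's pair — that localisation is
what the round exists for). ``'any'`` and ``'all'`` are offered as
alternatives; note ``'all'`` (unanimity) empties RN whenever the
subsets are genuinely distinct clusters, because a sample is only
cosine-close to its own cluster's negative prototype.

Defaults alpha=16, beta=4, k_subsets=3. ||.|| is the Euclidean norm;
zero-norm members are excluded from prototype means, and a zero-norm
sample is never admitted to RN — an empty similarity profile cannot be
"reliably" anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .sskmeans import _cosine_to

__all__ = [
    "RocchioConfig",
    "PrototypePair",
    "RocchioScreen",
    "prototype_pair",
    "rocchio1",
    "kmeans_partition",
    "rocchio2",
]


@dataclass
class RocchioConfig:
    """Weights and sub-clustering settings for the two Rocchio rounds."""

    alpha: float = 16.0
    beta: float = 4.0
    k_subsets: int = 3
    kmeans_seed: int = 0
    rule: str = "nearest"  # rocchio2 acceptance: {'nearest', 'any', 'all'}

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.k_subsets < 1:
            raise ValueError("k_subsets must be >= 1")
        if self.rule not in ("all", "any", "nearest"):
            raise ValueError(f"rule must be 'all', 'any' or 'nearest', got {self.rule!r}")


@dataclass
class PrototypePair:
    """A (positive, negative) Rocchio prototype vector pair."""

    c_pos: np.ndarray
    c_neg: np.ndarray


def _normalised_mean(X: np.ndarray) -> np.ndarray:
    """Mean of L2-normalised rows; zero-norm rows excluded with a warning."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("cannot build a prototype from an empty collection")
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0.0
    n_zero = int((~ok).sum())
    if n_zero:
        warnings.warn(
            f"excluded {n_zero} zero-norm vector(s) from prototype mean", stacklevel=3
        )
        if not ok.any():
            raise ValueError("all members have zero norm; prototype undefined")
    return (X[ok] / norms[ok, None]).mean(axis=0)


def prototype_pair(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    alpha: float = 16.0,
    beta: float = 4.0,
) -> PrototypePair:
    """Weighted difference of normalised-member means, both orientations."""
    mp = _normalised_mean(pos_features)
    mn = _normalised_mean(neg_features)
    return PrototypePair(c_pos=alpha * mp - beta * mn, c_neg=alpha * mn - beta * mp)


def rocchio1(
    P_features: np.ndarray,
    LN1_features: np.ndarray,
    cfg: RocchioConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Round 1: classify each likely negative against the global prototypes.

    Returns (ln2_mask, rp1_mask, margin) over rows of ``LN1_features``:
    ln2 where cosine to c+ is strictly below cosine to c-; margin is
    cosine(x, c+) - cosine(x, c-) (positive margin = looks positive).
    """
    cfg = cfg or RocchioConfig()
    if LN1_features.shape[0] == 0:
        warnings.warn("empty candidate set for Rocchio round 1", stacklevel=2)
        empty = np.zeros(0, dtype=bool)
        return empty, empty.copy(), np.zeros(0)
    pp = prototype_pair(P_features, LN1_features, cfg.alpha, cfg.beta)
    margin = _cosine_to(LN1_features, pp.c_pos) - _cosine_to(LN1_features, pp.c_neg)
    ln2 = margin < 0.0
    return ln2, ~ln2, margin


def kmeans_partition(
    LN2_features: np.ndarray, k: int, seed: int = 0
) -> list[np.ndarray]:
    """Euclidean k-means split into k index arrays (10 seeded restarts).

    If fewer samples than k, k is reduced to the sample count with a
    warning.
    """
    n = LN2_features.shape[0]
    if n == 0:
        return []
    if n < k:
        warnings.warn(f"only {n} samples for k={k}; reducing k to {n}", stacklevel=2)
        k = n
    if k == 1:
        return [np.arange(n)]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(LN2_features)
    return [np.flatnonzero(km.labels_ == j) for j in range(k)]


def rocchio2(
    P_features: np.ndarray,
    LN2_features: np.ndarray,
    cfg: RocchioConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Round 2: local prototype pairs over k-means subsets of LN2.

    For each subset N_j the local pair is n_j = alpha*nm(N_j) - beta*nm(P),
    p_j = alpha*nm(P) - beta*nm(N_j). A sample enters RN iff the
    negative prototype wins strictly under ``cfg.rule``:

    - 'all': cosine(x, n_j) > cosine(x, p_j) for every subset j;
    - 'any': for at least one j;
    - 'nearest': for the subset the sample itself belongs to.

    Returns (rn_mask, margin) over rows of ``LN2_features``; margin is
    min_j [cosine(x, n_j) - cosine(x, p_j)] — a ranking score where
    larger means more confidently negative.
    """
    cfg = cfg or RocchioConfig()
    n = LN2_features.shape[0]
    if n == 0:
        warnings.warn("empty candidate set for Rocchio round 2", stacklevel=2)
        return np.zeros(0, dtype=bool), np.zeros(0)
    subsets = kmeans_partition(LN2_features, cfg.k_subsets, cfg.kmeans_seed)
    neg_margins = np.empty((len(subsets), n))
    member_of = np.zeros(n, dtype=int)
    for j, idx in enumerate(subsets):
        if idx.size == 0:  # pragma: no cover - sklearn kmeans leaves none empty
            warnings.warn(f"subset {j} empty; skipped", stacklevel=2)
            neg_margins[j] = np.inf
            continue
        member_of[idx] = j
        pp = prototype_pair(LN2_features[idx], P_features, cfg.alpha, cfg.beta)
        # pp.c_pos is the local negative prototype n_j (its in-class is N_j)
        neg_margins[j] = _cosine_to(LN2_features, pp.c_pos) - _cosine_to(
            LN2_features, pp.c_neg
        )
    wins = neg_margins > 0.0
    if cfg.rule == "all":
        rn = wins.all(axis=0)
    elif cfg.rule == "any":
        rn = wins.any(axis=0)
    else:  # nearest
        rn = wins[member_of, np.arange(n)]
    zero = np.linalg.norm(LN2_features, axis=1) == 0.0
    rn &= ~zero
    return rn, neg_margins.min(axis=0)


class RocchioScreen(BaseEstimator):
    """Two-round Rocchio screen of candidate negatives against positives.

    ``fit(X, y)`` takes PU labels (1 = positive seed, 0 = candidate).
    Candidates are screened in two rounds; fitted index arrays (into the
    candidate rows, in order) expose the stages.

    Attributes
    ----------
    round1_negative_ : ndarray — candidate positions surviving round 1 (LN2)
    round1_positive_ : ndarray — candidate positions flagged positive (RP1)
    reliable_negative_ : ndarray — positions in the final RN
    negative_margin_ : ndarray over LN2 rows — min-over-subsets margin
    positive_margin_ : ndarray over all candidates — round-1 margin
    """

    def __init__(
        self,
        alpha: float = 16.0,
        beta: float = 4.0,
        k_subsets: int = 3,
        rule: str = "nearest",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.k_subsets = k_subsets
        self.rule = rule
        self.random_state = random_state

    def _config(self) -> RocchioConfig:
        return RocchioConfig(
            alpha=self.alpha,
            beta=self.beta,
            k_subsets=self.k_subsets,
            kmeans_seed=self.random_state,
            rule=self.rule,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RocchioScreen":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cfg = self._config()
        P = X[y == 1]
        cand = X[y == 0]
        if P.shape[0] == 0:
            raise ValueError("need at least one positive seed")
        ln2_mask, rp1_mask, margin1 = rocchio1(P, cand, cfg)
        ln2_pos = np.flatnonzero(ln2_mask)
        rn_mask, margin2 = rocchio2(P, cand[ln2_mask], cfg) if ln2_pos.size else (
            np.zeros(0, dtype=bool),
            np.zeros(0),
        )
        self.round1_negative_ = ln2_pos
        self.round1_positive_ = np.flatnonzero(rp1_mask)
        self.reliable_negative_ = ln2_pos[rn_mask]
        self.negative_margin_ = margin2
        self.positive_margin_ = margin1
        return self
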
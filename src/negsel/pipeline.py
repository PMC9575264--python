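"""End-to-end orchestration: features -> k-means screen -> Rocchio rounds.

``TwoStageNegativeSelector`` is the top-level estimator; ``kr_nssm`` wraps
it for labelled inputs (association table + two similarity matrices) and
returns a :class:`PipelineResult` carrying every staged set, per-sample
ranking margins and a config snapshot sufficient to re-run bit-identically.

Reliable positives: a pair must look positive to BOTH screens — it sits
in LP1 (the k-means screen) and the round-1 Rocchio prototypes also call
it positive. Alternative readings are available via ``positive_rule``:
``'rp1_only'`` (likely negatives that Rocchio flags positive) and
``'lp1_only'`` (the whole k-means likely-positive set).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .data import (
    AssociationTable,
    SampleSets,
    SimilarityMatrix,
    build_feature_matrix,
    partition_samples,
)
from .rocchio import RocchioConfig, RocchioScreen, prototype_pair
from .sskmeans import SemiSupervisedKMeans, _cosine_to

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "TwoStageNegativeSelector",
    "kr_nssm",
    "sample_balanced_negatives",
    "write_outputs",
]

POSITIVE_RULES = ("rp1_and_lp1", "rp1_only", "lp1_only")


@dataclass
class PipelineConfig:
    """Every tunable of the two-stage screen, with the method defaults."""

    tol: float = 1e-6
    max_iter: int = 100
    alpha: float = 16.0
    beta: float = 4.0
    k_subsets: int = 3
    kmeans_seed: int = 0
    rocchio2_rule: str = "nearest"
    positive_rule: str = "rp1_and_lp1"

    def __post_init__(self) -> None:
        if self.positive_rule not in POSITIVE_RULES:
            raise ValueError(
                f"positive_rule must be one of {POSITIVE_RULES}, got {self.positive_rule!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """All staged sets plus ranking scores and the exact configuration."""

    sets: SampleSets
    rn_scores: dict[int, float]
    rp_scores: dict[int, float]
    config_snapshot: dict = field(default_factory=dict)


class TwoStageNegativeSelector(BaseEstimator):
    """Select reliable negatives from PU-labelled samples.

    ``fit(X, y)`` with y = 1 for known positives and 0 for unlabelled
    rows runs the full screen. Fitted attributes are index arrays into
    the rows of X:

    - ``lp1_`` / ``ln1_`` : the k-means split of the unlabelled rows;
    - ``ln2_`` : round-1 reliable negatives;
    - ``rn_`` : final reliable negatives;
    - ``rp_`` : reliable positives under ``positive_rule``;
    - ``rn_score_`` / ``rp_score_`` : margins aligned with ``rn_`` / ``rp_``
      (larger = more confidently negative / positive).
    """

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 100,
        alpha: float = 16.0,
        beta: float = 4.0,
        k_subsets: int = 3,
        rocchio2_rule: str = "nearest",
        positive_rule: str = "rp1_and_lp1",
        random_state: int = 0,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.beta = beta
        self.k_subsets = k_subsets
        self.rocchio2_rule = rocchio2_rule
        self.positive_rule = positive_rule
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TwoStageNegativeSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.positive_rule not in POSITIVE_RULES:
            raise ValueError(f"unknown positive_rule {self.positive_rule!r}")
        pos_idx = np.flatnonzero(y == 1)
        unl_idx = np.flatnonzero(y == 0)

        km = SemiSupervisedKMeans(tol=self.tol, max_iter=self.max_iter)
        try:
            km.fit(X, y)
        except ValueError as e:
            raise ValueError(f"[stage ss_kmeans] {e}") from e
        lp1 = unl_idx[km.unlabelled_labels_]
        ln1 = unl_idx[~km.unlabelled_labels_]

        screen = RocchioScreen(
            alpha=self.alpha,
            beta=self.beta,
            k_subsets=self.k_subsets,
            rule=self.rocchio2_rule,
            random_state=self.random_state,
        )
        y2 = np.full(X.shape[0], -1)
        y2[pos_idx] = 1
        y2[ln1] = 0
        keep = y2 >= 0
        try:
            screen.fit(X[keep], y2[keep])
        except ValueError as e:
            raise ValueError(f"[stage rocchio] {e}") from e
        ln2 = ln1[screen.round1_negative_]
        rn = ln1[screen.reliable_negative_]
        rp1 = ln1[screen.round1_positive_]
        rn_mask_in_ln2 = np.isin(screen.round1_negative_, screen.reliable_negative_)
        rn_score = screen.negative_margin_[rn_mask_in_ln2]

        # Reliable positives: margin of LP1 members against the round-1
        # prototype pair (built from P vs LN1); ties count as positive.
        if ln1.size and lp1.size:
            pp = prototype_pair(X[pos_idx], X[ln1], self.alpha, self.beta)
            lp1_margin = _cosine_to(X[lp1], pp.c_pos) - _cosine_to(X[lp1], pp.c_neg)
        else:
            lp1_margin = np.zeros(lp1.size)
        if self.positive_rule == "rp1_and_lp1":
            keep_pos = lp1_margin >= 0.0
            rp, rp_score = lp1[keep_pos], lp1_margin[keep_pos]
        elif self.positive_rule == "lp1_only":
            rp, rp_score = lp1, lp1_margin
        else:  # rp1_only
            rp = rp1
            rp_score = screen.positive_margin_[screen.round1_positive_]
        if rn.size == 0:
            warnings.warn("reliable negative set is empty", stacklevel=2)

        self.lp1_, self.ln1_, self.ln2_ = lp1, ln1, ln2
        self.rn_, self.rp_ = rn, rp
        self.rn_score_, self.rp_score_ = rn_score, rp_score
        self.rp1_ = rp1
        self.n_iter_kmeans_ = km.n_iter_
        for name, arr in (("U", unl_idx), ("LP1", lp1), ("LN1", ln1),
                          ("LN2", ln2), ("RN", rn), ("RP", rp)):
            logger.info("stage %s: %d pairs", name, arr.size)
        return self


def kr_nssm(
    assoc: AssociationTable,
    simM: SimilarityMatrix,
    simD: SimilarityMatrix,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full two-stage screen on labelled inputs."""
    cfg = cfg or PipelineConfig()
    X = build_feature_matrix(simM, simD)
    sets = partition_samples(assoc, simM, simD)
    y = np.zeros(X.shape[0], dtype=int)
    y[sets.P] = 1
    sel = TwoStageNegativeSelector(
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        alpha=cfg.alpha,
        beta=cfg.beta,
        k_subsets=cfg.k_subsets,
        rocchio2_rule=cfg.rocchio2_rule,
        positive_rule=cfg.positive_rule,
        random_state=cfg.kmeans_seed,
    ).fit(X, y)
    sets.LP1, sets.LN1, sets.LN2 = sel.lp1_, sel.ln1_, sel.ln2_
    sets.RN, sets.RP = sel.rn_, sel.rp_
    sets.check_invariants()
    return PipelineResult(
        sets=sets,
        rn_scores={int(i): float(s) for i, s in zip(sel.rn_, sel.rn_score_)},
        rp_scores={int(i): float(s) for i, s in zip(sel.rp_, sel.rp_score_)},
        config_snapshot=asdict(cfg),
    )


def sample_balanced_negatives(
    result: PipelineResult,
    n: int,
    seed: int = 0,
    mode: str = "random",
) -> np.ndarray:
    """Draw n reliable negatives to balance against the positives.

    ``mode='random'`` draws uniformly with the seed (the standard usage);
    ``'top_margin'`` takes the n most confidently negative by margin.
    Returns all of RN with a warning if it holds fewer than n pairs.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mode not in ("random", "top_margin"):
        raise ValueError(f"mode must be 'random' or 'top_margin', got {mode!r}")
    rn = np.asarray(result.sets.RN)
    if rn.size <= n:
        if rn.size < n:
            warnings.warn(
                f"requested {n} negatives but only {rn.size} reliable ones; returning all",
                stacklevel=2,
            )
        return np.sort(rn)
    if mode == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(rn, size=n, replace=False))
    order = sorted(rn, key=lambda i: (-result.rn_scores[int(i)], i))
    return np.sort(np.asarray(order[:n]))


def write_outputs(
    result: PipelineResult,
    simM: SimilarityMatrix,
    simD: SimilarityMatrix,
    outdir: str | Path,
) -> None:
    """Export stages.csv, negatives.csv, positives.csv and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = result.sets
    sets.stage_frame(simM, simD).to_csv(outdir / "stages.csv", index=False)
    d = sets.n_disease
    for fname, idx, scores in (
        ("negatives.csv", sets.RN, result.rn_scores),
        ("positives.csv", sets.RP, result.rp_scores),
    ):
        rows = [
            (simM.labels[k // d], simD.labels[k % d], scores.get(int(k), float("nan")))
            for k in np.sort(np.asarray(idx))
        ]
        pd.DataFrame(rows, columns=["mirna", "disease", "margin"]).to_csv(
            outdir / fname, index=False
        )
    manifest = {
        "config": result.config_snapshot,
        "stage_sizes": {
            s: int(np.asarray(getattr(sets, s)).size)
            for s in ("P", "U", "LP1", "LN1", "LN2", "RN", "RP")
            if getattr(sets, s) is not None
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
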
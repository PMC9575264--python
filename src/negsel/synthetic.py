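"""Block-structured synthetic miRNA-disease data with hidden ground truth.

The screen rests on one assumption: functionally similar miRNAs tend to
associate with semantically similar diseases. The generator instantiates
it directly as a stochastic co-cluster model. miRNAs and diseases are
assigned to ``n_blocks`` aligned blocks; similarity is high within a
block and low across blocks (plus Gaussian noise, symmetrised, clipped
to [0, 1], unit diagonal); a pair is a true positive with high
probability when its miRNA and disease share a block and with low
probability otherwise. A fraction ``hide_frac`` of the true positives is
hidden: removed from the observed association table but still positive
in truth. These hidden positives contaminate U and are the stressor the
screen must avoid — negative purity measures how well it does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import AssociationTable, SimilarityMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "negative_purity"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a clearly separated, noisy
    3-block structure at desk scale (60 x 40 pairs)."""

    n_mirna: int = 60
    n_disease: int = 40
    n_blocks: int = 3
    within_block_sim: float = 0.8
    between_block_sim: float = 0.2
    sim_noise_sd: float = 0.05
    pos_rate_in_block: float = 0.5
    pos_rate_out_block: float = 0.02
    hide_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 1 or self.n_disease < 1 or self.n_blocks < 1:
            raise ValueError("entity and block counts must be positive")
        if self.n_blocks > min(self.n_mirna, self.n_disease):
            raise ValueError("more blocks than entities leaves empty blocks")
        if not (0.0 <= self.between_block_sim < self.within_block_sim <= 1.0):
            raise ValueError("need 0 <= between_block_sim < within_block_sim <= 1")
        if self.sim_noise_sd < 0:
            raise ValueError("sim_noise_sd must be non-negative")
        for p in (self.pos_rate_in_block, self.pos_rate_out_block, self.hide_frac):
            if not (0.0 <= p <= 1.0):
                raise ValueError("rates and hide_frac must be probabilities")


@dataclass
class SyntheticTruth:
    """Hidden labels: which pairs are truly positive, and which of those
    were hidden into the unlabelled set."""

    true_positive: np.ndarray  # bool over canonical pair indices
    hidden_positive: set[int]
    u_indices: set[int]
    mirna_blocks: np.ndarray = field(default=None)
    disease_blocks: np.ndarray = field(default=None)


def _blocks(n: int, k: int) -> np.ndarray:
    """Contiguous block assignment with sizes halving block to block.

    Real association catalogues are long-tailed: a few large disease /
    miRNA clusters carry most known associations. Sizes proportional to
    2^-a reproduce that skew; with equal blocks the positive class's
    feature mean would coincide with the unlabelled mean and the planted
    structure would be invisible to any centroid- or prototype-based
    screen.
    """
    w = 2.0 ** np.arange(k)[::-1]
    bounds = np.floor(np.cumsum(w / w.sum()) * n).astype(int)
    out = np.full(n, k - 1, dtype=int)
    start = 0
    for a, b in enumerate(bounds):
        out[start:b] = a
        start = b
    return out


def _block_similarity(
    blocks: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    n = blocks.size
    base = np.where(
        blocks[:, None] == blocks[None, :], cfg.within_block_sim, cfg.between_block_sim
    ).astype(float)
    noise = rng.normal(0.0, cfg.sim_noise_sd, size=(n, n))
    sim = base + (noise + noise.T) / 2.0
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def generate(
    cfg: SyntheticConfig | None = None,
) -> tuple[AssociationTable, SimilarityMatrix, SimilarityMatrix, SyntheticTruth]:
    """Draw one dataset; the same config (incl. seed) gives the same data."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    mb = _blocks(cfg.n_mirna, cfg.n_blocks)
    db = _blocks(cfg.n_disease, cfg.n_blocks)
    simM = SimilarityMatrix(
        labels=[f"miR-{i:03d}" for i in range(cfg.n_mirna)],
        values=_block_similarity(mb, cfg, rng),
    )
    simD = SimilarityMatrix(
        labels=[f"disease-{j:03d}" for j in range(cfg.n_disease)],
        values=_block_similarity(db, cfg, rng),
    )
    same_block = mb[:, None] == db[None, :]
    rate = np.where(same_block, cfg.pos_rate_in_block, cfg.pos_rate_out_block)
    true_pos = rng.random(rate.shape) < rate
    tp_flat = true_pos.reshape(-1)

    tp_idx = np.flatnonzero(tp_flat)
    n_hide = int(round(cfg.hide_frac * tp_idx.size))
    hidden = rng.choice(tp_idx, size=n_hide, replace=False) if n_hide else np.empty(0, int)
    observed = np.setdiff1d(tp_idx, hidden)

    d = cfg.n_disease
    assoc = AssociationTable(
        pairs=[(simM.labels[k // d], simD.labels[k % d]) for k in observed]
    )
    all_idx = np.arange(cfg.n_mirna * d)
    u = np.setdiff1d(all_idx, observed)
    truth = SyntheticTruth(
        true_positive=tp_flat,
        hidden_positive=set(int(k) for k in hidden),
        u_indices=set(int(k) for k in u),
        mirna_blocks=mb,
        disease_blocks=db,
    )
    return assoc, simM, simD, truth


def negative_purity(selected, truth: SyntheticTruth) -> float:
    """Fraction of a selected unlabelled subset that is truly negative.

    The operational meaning of "reliable": a selection untouched by the
    hidden positives scores 1.0. An empty selection scores 1.0 by
    convention (with a warning).
    """
    selected = [int(k) for k in selected]
    outside = [k for k in selected if k not in truth.u_indices]
    if outside:
        raise ValueError(f"selected pairs outside U: {outside[:5]}")
    if not selected:
        warnings.warn("empty selection; purity 1.0 by convention", stacklevel=2)
        return 1.0
    n_neg = sum(1 for k in selected if not truth.true_positive[k])
    return n_neg / len(selected)
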
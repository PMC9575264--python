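"""Semi-supervised two-centroid k-means screen of the unlabelled set.

The positive set P seeds one centroid (c1, the mean of P's feature
vectors) and the whole unlabelled set U seeds the other (c2, the mean of
U). The first assignment of each unlabelled sample maximises cosine
similarity to the two centroids; every later iteration recomputes the
centroids from the current split and reassigns by (squared) Euclidean
distance. The loop stops when assignments repeat or centroid movement
falls below ``tol``. The output is a partition of U into likely
positives (LP1) and likely negatives (LN1).

Conventions where the procedure is underdetermined, chosen once and
fixed: ties on either metric go to the negative side (this stage exists
to screen negatives conservatively); a zero-norm vector has cosine -1 to
everything, so empty similarity profiles fall to LN1; if a side empties
during refinement its centroid is frozen at its previous value.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "CentroidPair",
    "SemiSupervisedKMeans",
    "centroid",
    "cosine_similarity",
    "initial_assign",
    "refine_assign",
    "run_ss_kmeans",
]


class CentroidPair:
    """A (positive, negative) centroid pair of common dimension."""

    def __init__(self, c_pos: np.ndarray, c_neg: np.ndarray):
        self.c_pos = np.asarray(c_pos, dtype=float)
        self.c_neg = np.asarray(c_neg, dtype=float)
        if self.c_pos.shape != self.c_neg.shape:
            raise ValueError("centroid pair members must share a dimension")
        if not (np.isfinite(self.c_pos).all() and np.isfinite(self.c_neg).all()):
            raise ValueError("centroids must be finite")


def centroid(features: np.ndarray) -> np.ndarray:
    """Componentwise arithmetic mean of a non-empty vector collection."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("cannot form the centroid of an empty collection")
    return features.mean(axis=0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between u and v; -1 if either has zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return -1.0
    return float(np.dot(u, v) / (nu * nv))


def _cosine_to(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Row-wise cosine of X against c, with the zero-norm -> -1 policy."""
    norms = np.linalg.norm(X, axis=1)
    nc = np.linalg.norm(c)
    out = np.full(X.shape[0], -1.0)
    if nc == 0.0:
        return out
    ok = norms > 0.0
    out[ok] = (X[ok] @ c) / (norms[ok] * nc)
    return out


def initial_assign(
    U_features: np.ndarray, c_pair: CentroidPair
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine assignment of each unlabelled sample to LP1 or LN1.

    A sample joins LP1 only if its cosine to the positive centroid
    strictly exceeds its cosine to the negative one; ties go to LN1.
    Returns boolean masks (lp_mask, ln_mask) over rows of ``U_features``.
    """
    sim_pos = _cosine_to(U_features, c_pair.c_pos)
    sim_neg = _cosine_to(U_features, c_pair.c_neg)
    lp = sim_pos > sim_neg
    return lp, ~lp


def refine_assign(
    U_features: np.ndarray, l_pair: CentroidPair
) -> tuple[np.ndarray, np.ndarray]:
    """Squared-Euclidean assignment to the refined centroids; ties to LN."""
    d_pos = ((U_features - l_pair.c_pos) ** 2).sum(axis=1)
    d_neg = ((U_features - l_pair.c_neg) ** 2).sum(axis=1)
    lp = d_pos < d_neg
    return lp, ~lp


class SemiSupervisedKMeans(BaseEstimator):
    """Two-centroid semi-supervised k-means over a PU-labelled sample set.

    Parameters
    ----------
    tol : float, default=1e-6
        Maximum Euclidean centroid movement below which the loop stops.
    max_iter : int, default=100
        Hard iteration cap.

    Attributes
    ----------
    unlabelled_labels_ : ndarray of bool
        For each unlabelled row (``y == 0``), True if assigned likely
        positive (LP1), False if likely negative (LN1).
    centroids_ : CentroidPair
        Final (positive, negative) centroids.
    n_iter_ : int
    converged_ : bool

    Notes
    -----
    Deterministic: there is no randomness anywhere in this stage.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SemiSupervisedKMeans":
        """Fit on features X with PU labels y (1 = positive, 0 = unlabelled)."""
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        pos = X[y == 1]
        unl = X[y == 0]
        if pos.shape[0] < 1:
            raise ValueError("need at least one positive sample to seed c1")
        if unl.shape[0] < 2:
            raise ValueError("need at least two unlabelled samples to screen")

        c_pos, c_neg = centroid(pos), centroid(unl)
        lp, ln = initial_assign(unl, CentroidPair(c_pos, c_neg))
        n_iter, converged = 1, False
        for _ in range(self.max_iter - 1):
            new_pos = centroid(unl[lp]) if lp.any() else c_pos
            new_neg = centroid(unl[ln]) if ln.any() else c_neg
            movement = max(
                float(np.linalg.norm(new_pos - c_pos)),
                float(np.linalg.norm(new_neg - c_neg)),
            )
            c_pos, c_neg = new_pos, new_neg
            if movement <= self.tol:
                converged = True
                break
            new_lp, new_ln = refine_assign(unl, CentroidPair(c_pos, c_neg))
            n_iter += 1
            if np.array_equal(new_lp, lp):
                lp, ln = new_lp, new_ln
                converged = True
                break
            lp, ln = new_lp, new_ln
        if not lp.any() or not ln.any():
            warnings.warn("one side of the k-means screen is empty", stacklevel=2)

        self.unlabelled_labels_ = lp
        self.centroids_ = CentroidPair(c_pos, c_neg)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def fit_predict(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        self.fit(X, y)
        return self.unlabelled_labels_

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"requires_y": True}


def run_ss_kmeans(
    sets,
    features: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Functional wrapper: screen ``sets.U`` into (LP1, LN1) pair indices.

    ``features`` is the full canonical feature matrix (row k = pair k).
    Returns (LP1 indices, LN1 indices, iterations, converged).
    """
    y = np.full(features.shape[0], -1)
    y[sets.P] = 1
    y[sets.U] = 0
    keep = y >= 0
    est = SemiSupervisedKMeans(tol=tol, max_iter=max_iter).fit(features[keep], y[keep])
    check_is_fitted(est)
    lp_mask = est.unlabelled_labels_
    U = np.asarray(sets.U)
    return U[lp_mask], U[~lp_mask], est.n_iter_, est.converged_
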
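"""Shape space of landmark configurations: PCA, PC selection, PERMANOVA, screens.

Normalized pseudo-landmark configurations are flattened to vectors and
eigendecomposed about their mean.  Group structure in the resulting scores is
tested with pairwise distance-based PERMANOVA (Anderson's pseudo-F with
permutation p-values, Bonferroni-corrected over pairs), after screening each PC
for normality (Shapiro-Wilk) and variance homogeneity (Fligner-Killeen).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .outlines import LandmarkConfiguration

__all__ = [
    "ShapeSpaceModel",
    "PermanovaResult",
    "ScreenReport",
    "fit_shape_pca",
    "select_pcs",
    "permanova_pairwise",
    "pseudo_f",
    "assumption_screen",
]


@dataclass(frozen=True)
class ShapeSpaceModel:
    """PCA of flattened configurations: mean, orthonormal eigenbasis, variances.

    ``eigenvectors`` has one principal axis per column; new specimens project via
    ``(x - mean) @ eigenvectors``.  Eigenvalues are sample variances (ddof=1),
    descending.
    """

    mean: np.ndarray  # (p,)
    eigenvectors: np.ndarray  # (p, m) columns
    eigenvalues: np.ndarray  # (m,) descending
    training_scores: np.ndarray  # (n, m)
    labels: list[str]

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-12) or np.any(ev < -1e-12):
            raise ValueError("eigenvalues must be descending and non-negative")
        V = np.asarray(self.eigenvectors, dtype=float)
        if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-9):
            raise ValueError("eigenvectors must be orthonormal")

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else np.zeros_like(self.eigenvalues)

    def project(self, x: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Score coordinates of new flattened configuration(s)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.mean.size:
            raise ValueError(f"expected {self.mean.size} coordinates, got {x.shape[1]}")
        s = (x - self.mean) @ self.eigenvectors
        return s[:, :n_components] if n_components is not None else s

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors_row_major": self.eigenvectors.tolist(),
            "labels": list(self.labels),
            "training_scores": self.training_scores.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ShapeSpaceModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean=np.array(d["mean"]), eigenvectors=np.array(d["eigenvectors_row_major"]),
                   eigenvalues=np.array(d["eigenvalues"]),
                   training_scores=np.array(d["training_scores"]), labels=list(d["labels"]))


@dataclass(frozen=True)
class PermanovaResult:
    pair: tuple[str, str]
    F: float
    p_raw: float
    p_adjusted: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class ScreenReport:
    """Per-PC distributional screens; NaN marks a skipped degenerate case."""

    shapiro_p: pd.DataFrame  # index PC, columns group
    fligner_p: pd.Series  # index PC
    flags: list[str] = field(default_factory=list)


def fit_shape_pca(configs: list[LandmarkConfiguration], labels: list[str]) -> ShapeSpaceModel:
    """Eigendecompose the covariance of flattened normalized configurations."""
    if len(configs) < 3:
        raise ValueError("need at least 3 specimens")
    if len(configs) != len(labels):
        raise ValueError("configs and labels must align")
    if not all(c.normalized for c in configs):
        raise ValueError("all configurations must be normalized to unit centroid size")
    X = np.vstack([c.flatten() for c in configs])
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD route: numerically stable, eigenvalues = s^2/(n-1)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    m = min(X.shape[0] - 1, X.shape[1])
    eigenvalues = (s[:m] ** 2) / (X.shape[0] - 1)
    eigenvectors = vt[:m].T
    scores = Xc @ eigenvectors
    return ShapeSpaceModel(mean=mean, eigenvectors=eigenvectors, eigenvalues=eigenvalues,
                           training_scores=scores, labels=list(labels))


def select_pcs(model: ShapeSpaceModel, fraction: float) -> int:
    """Smallest k whose cumulative variance fraction reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cum = np.cumsum(model.variance_fractions)
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def pseudo_f(dist: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's distance-based pseudo-F from a full distance matrix.

    F = (SS_between/(g-1)) / (SS_within/(N-g)) with SS_total = sum of squared
    distances / N and SS_within = sum over groups of within-group squared
    distances / group size.
    """
    d2 = dist ** 2
    n = dist.shape[0]
    uniq, inv = np.unique(groups, return_inverse=True)
    g = uniq.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for gi in range(g):
        idx = np.flatnonzero(inv == gi)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova_pairwise(scores: np.ndarray, labels, n_permutations: int = 9999,
                       seed: int = 0) -> list[PermanovaResult]:
    """Pairwise two-group PERMANOVA on Euclidean distances between score rows.

    Each pair is tested on its own rows only; p_raw uses the add-one convention
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` and p_adjusted is the
    Bonferroni correction over the number of pairs tested.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    counts = {u: int(np.sum(labels == u)) for u in uniq}
    small = [u for u, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with <2 members: {small}")
    pairs = list(itertools.combinations(uniq, 2))
    results = []
    rng = np.random.default_rng(seed)
    for pair in pairs:
        sel = np.isin(labels, pair)
        sub = scores[sel]
        grp = labels[sel]
        dist = _euclidean_matrix(sub)
        f_obs = pseudo_f(dist, grp)
        count = 0
        for _ in range(n_permutations):
            if pseudo_f(dist, rng.permutation(grp)) >= f_obs:
                count += 1
        p_raw = (1 + count) / (1 + n_permutations)
        results.append(PermanovaResult(pair=tuple(pair), F=f_obs, p_raw=p_raw,
                                       p_adjusted=min(1.0, p_raw * len(pairs)),
                                       n_permutations=n_permutations, seed=seed))
    return results


def _euclidean_matrix(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(x, metric="euclidean"))


def assumption_screen(scores: np.ndarray, labels) -> ScreenReport:
    """Shapiro-Wilk per PC per group and Fligner-Killeen per PC across groups.

    Degenerate cases (group n < 3, constant values) are flagged and reported as
    NaN rather than raising.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    uniq = list(np.unique(labels))
    k = scores.shape[1]
    flags: list[str] = []
    sw = pd.DataFrame(index=pd.RangeIndex(k, name="pc"), columns=uniq, dtype=float)
    fk = pd.Series(index=pd.RangeIndex(k, name="pc"), dtype=float)
    for pc in range(k):
        samples = []
        for u in uniq:
            x = scores[labels == u, pc]
            samples.append(x)
            if x.size < 3:
                flags.append(f"pc{pc}/{u}: too few for Shapiro-Wilk")
                sw.loc[pc, u] = np.nan
            elif np.ptp(x) < 1e-12:
                flags.append(f"pc{pc}/{u}: constant scores")
                sw.loc[pc, u] = np.nan
            else:
                sw.loc[pc, u] = stats.shapiro(x).pvalue
        if all(np.ptp(s) < 1e-12 for s in samples):
            flags.append(f"pc{pc}: constant across all groups")
            fk.loc[pc] = np.nan
        else:
            try:
                fk.loc[pc] = stats.fligner(*samples).pvalue
            except ValueError:
                flags.append(f"pc{pc}: Fligner-Killeen degenerate")
                fk.loc[pc] = np.nan
    return ScreenReport(shapiro_p=sw, fligner_p=fk, flags=flags)
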
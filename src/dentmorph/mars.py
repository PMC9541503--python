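"""Multivariate adaptive regression splines (forward hinge selection + GCV pruning).

The model is a sum of hinge-function products
``f(x) = c0 + sum_m c_m * prod_j max(0, s_jm (x_vjm - t_jm))``.
The forward pass greedily adds the mirror pair of hinges (one knot ``t`` on one
predictor, both orientations) that most reduces the residual sum of squares;
the backward pass deletes terms one at a time, keeping the subset with the best
generalized cross-validation score

    GCV(M) = RSS / n / (1 - C(M)/n)^2,   C(M) = M + penalty * K,

where ``M`` counts basis functions (intercept included), ``K`` the number of
knots, and ``penalty`` the GCV cost per knot (Friedman's d, default 3).  The
fit is multi-response: with an indicator response matrix the same basis serves
as the nonlinear regression stage of flexible discriminant analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HingeTerm", "MARSRegression"]


@dataclass(frozen=True)
class HingeTerm:
    """Product of hinge factors; empty ``factors`` is the intercept."""

    factors: tuple[tuple[int, float, int], ...]  # (variable, knot, sign)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for var, knot, sign in self.factors:
            out = out * np.maximum(0.0, sign * (X[:, var] - knot))
        return out

    @property
    def degree(self) -> int:
        return len(self.factors)

    def describe(self) -> str:
        if not self.factors:
            return "1"
        parts = [f"h({'+' if s > 0 else '-'}(x{v} - {t:.4g}))" for v, t, s in self.factors]
        return " * ".join(parts)


class MARSRegression:
    """Additive-by-default MARS for single- or multi-response regression.

    Parameters
    ----------
    max_terms:
        Cap on basis functions including the intercept (default 21).
    max_degree:
        Maximum hinge-product degree; 1 gives an additive model.
    gcv_penalty_per_knot:
        Friedman's knot penalty d in the GCV effective-parameter count.
    max_candidate_knots:
        Knots are restricted to at most this many quantiles per predictor,
        bounding the forward-pass search.
    """

    def __init__(self, max_terms: int = 21, max_degree: int = 1,
                 gcv_penalty_per_knot: float = 3.0, max_candidate_knots: int = 32):
        if max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.gcv_penalty_per_knot = gcv_penalty_per_knot
        self.max_candidate_knots = max_candidate_knots
        self.terms_: list[HingeTerm] | None = None
        self.coef_: np.ndarray | None = None
        self.gcv_: float | None = None

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MARSRegression":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        terms = self._forward_pass(X, Y)
        terms = self._backward_pass(X, Y, terms)
        B = self._basis_matrix(X, terms)
        coef, rss = _lstsq_rss(B, Y)
        self.terms_ = terms
        self.coef_ = coef
        self.gcv_ = self._gcv(rss, n, terms)
        return self

    def _candidate_knots(self, x: np.ndarray, parent_mask: np.ndarray) -> np.ndarray:
        vals = np.unique(x[parent_mask])
        if vals.size <= 2:
            return vals[1:-1] if vals.size > 2 else np.empty(0)
        inner = vals[1:-1]  # endpoints give a hinge active on 0 or all points
        if inner.size > self.max_candidate_knots:
            q = np.linspace(0, 1, self.max_candidate_knots + 2)[1:-1]
            inner = np.unique(np.quantile(inner, q, method="nearest"))
        return inner

    def _forward_pass(self, X: np.ndarray, Y: np.ndarray) -> list[HingeTerm]:
        n, p = X.shape
        terms: list[HingeTerm] = [HingeTerm(())]
        B = np.ones((n, 1))
        _, rss = _lstsq_rss(B, Y)
        total_ss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
        while len(terms) + 2 <= self.max_terms:
            best = None  # (rss, new_cols, new_terms)
            for parent_idx, parent in enumerate(terms):
                if parent.degree >= self.max_degree:
                    continue
                parent_col = B[:, parent_idx]
                parent_mask = parent_col > 0
                if parent_mask.sum() < 4:
                    continue
                used_vars = {v for v, _, _ in parent.factors}
                for var in range(p):
                    if var in used_vars:
                        continue
                    for knot in self._candidate_knots(X[:, var], parent_mask):
                        bplus = parent_col * np.maximum(0.0, X[:, var] - knot)
                        bminus = parent_col * np.maximum(0.0, knot - X[:, var])
                        cand = np.column_stack([B, bplus, bminus])
                        _, cand_rss = _lstsq_rss(cand, Y)
                        if best is None or cand_rss < best[0] - 1e-14:
                            best = (cand_rss, (bplus, bminus),
                                    (HingeTerm(parent.factors + ((var, knot, 1),)),
                                     HingeTerm(parent.factors + ((var, knot, -1),))))
            if best is None:
                break
            new_rss, cols, new_terms = best
            if rss - new_rss < 1e-10 * max(total_ss, 1.0):
                break  # no meaningful improvement
            terms.extend(new_terms)
            B = np.column_stack([B, cols[0], cols[1]])
            rss = new_rss
        return terms

    def _backward_pass(self, X: np.ndarray, Y: np.ndarray,
                       terms: list[HingeTerm]) -> list[HingeTerm]:
        n = X.shape[0]
        current = list(terms)
        B = self._basis_matrix(X, current)
        _, rss = _lstsq_rss(B, Y)
        best_terms = list(current)
        best_gcv = self._gcv(rss, n, current)
        while len(current) > 1:
            sub_best = None  # (gcv, index)
            for i in range(1, len(current)):  # never drop the intercept
                keep = [j for j in range(len(current)) if j != i]
                _, sub_rss = _lstsq_rss(B[:, keep], Y)
                g = self._gcv(sub_rss, n, [current[j] for j in keep])
                if sub_best is None or g < sub_best[0]:
                    sub_best = (g, i)
            g, i = sub_best
            current.pop(i)
            B = np.delete(B, i, axis=1)
            if g < best_gcv:
                best_gcv = g
                best_terms = list(current)
        return best_terms

    def _gcv(self, rss: float, n: int, terms: list[HingeTerm]) -> float:
        m = len(terms)
        # distinct knot locations: a mirrored hinge pair shares one knot
        knots = len({(v, t) for term in terms for (v, t, _s) in term.factors})
        c = m + self.gcv_penalty_per_knot * knots
        if c >= n:
            return np.inf
        return (rss / n) / (1.0 - c / n) ** 2

    # -- prediction ---------------------------------------------------------

    def _basis_matrix(self, X: np.ndarray, terms: list[HingeTerm]) -> np.ndarray:
        return np.column_stack([t.evaluate(X) for t in terms])

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Basis-function design matrix for new data (intercept column first)."""
        self._check_fitted()
        return self._basis_matrix(np.asarray(X, dtype=float), self.terms_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        out = self.transform(X) @ self.coef_
        return out[:, 0] if out.shape[1] == 1 else out

    def _check_fitted(self) -> None:
        if self.terms_ is None:
            raise RuntimeError("model is not fitted")

    @property
    def n_knots_(self) -> int:
        self._check_fitted()
        return sum(t.degree for t in self.terms_)

    def describe(self) -> list[str]:
        self._check_fitted()
        return [t.describe() for t in self.terms_]


def _lstsq_rss(B: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, residuals, rank, _ = np.linalg.lstsq(B, Y, rcond=None)
    if residuals.size and rank == B.shape[1]:
        rss = float(np.sum(residuals))
    else:
        rss = float(np.sum((Y - B @ coef) ** 2))
    return coef, rss
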
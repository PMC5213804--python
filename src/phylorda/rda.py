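"""Redundancy analysis (RDA), partial RDA and permutation tests.

RDA is the constrained form of PCA: the response matrix Y (species x traits,
centered) is regressed on an explanatory matrix X, and the principal axes of
the fitted values ŷ = X(X'X)⁻X'Y are the canonical axes.  Total inertia is
the sum of column variances of Y; the explained fraction is ‖Ŷ‖²/‖Y‖².  With
a covariable matrix W (partial RDA) both Y and X are first residualized on W.

Constraint blocks may be rank deficient (full redundant dummy coding is the
norm here); projections go through an orthonormal basis retained at a relative
singular-value tolerance, and the constraint count q is the numerical rank.

Significance uses the permutation pseudo-F

    F = (explained / q) / (residual / df_residual),   df_residual = n - q - q_W - 1,

with rows of Y permuted freely (simple term) or residuals of the reduced
model permuted and re-added to its fit (partial term, the conditioned-test
default).  p-values follow the (hits + 1)/(m + 1) convention; a mid-p variant
(ties counted half) is also reported for use with strongly discrete nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .traits import CodedMatrix

__all__ = [
    "RDA",
    "PermutationResult",
    "fit_rda",
    "pseudo_f",
    "permutation_test",
    "axis_decomposition",
    "triplot_scores",
]

RANK_RTOL = 1e-8


def _as_frame(data, role: str) -> pd.DataFrame:
    if data is None:
        return None
    if isinstance(data, CodedMatrix):
        return data.values
    if hasattr(data, "as_coded"):  # CladeMatrix
        return data.as_coded().values
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"{role}{j}" for j in range(arr.shape[1])])


def _aligned(frame: pd.DataFrame, ref: pd.DataFrame, name: str) -> pd.DataFrame:
    """Reorder rows to match the reference index; labels must agree as sets."""
    if frame.index.equals(ref.index):
        return frame
    plain = isinstance(frame.index, pd.RangeIndex) or isinstance(ref.index, pd.RangeIndex)
    if plain:
        return frame
    if set(frame.index) != set(ref.index):
        raise ValueError(f"row labels of Y and {name} are misaligned")
    return frame.reindex(ref.index)


def _centered(frame: pd.DataFrame) -> np.ndarray:
    arr = frame.to_numpy(dtype=float)
    return arr - arr.mean(axis=0)


def _orth_basis(M: np.ndarray, ref_scale: float = 0.0) -> tuple[np.ndarray, int]:
    """Orthonormal basis of col span and numerical rank (SVD, relative tol).

    ``ref_scale`` guards residualized matrices: directions smaller than
    ``RANK_RTOL`` times the pre-residualization scale are noise, not span.
    """
    if M.size == 0 or not np.any(M):
        return np.zeros((M.shape[0], 0)), 0
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = RANK_RTOL * max(s[0], ref_scale)
    rank = int(np.sum(s > tol))
    return U[:, :rank], rank


class RDA(BaseEstimator):
    """Redundancy analysis estimator.

    Parameters
    ----------
    scaling : {"correlation"}
        Score scaling for triplots; correlation-style biplot scaling is the
        only implemented convention (arrow angles approximate correlations).

    Attributes (after :meth:`fit`)
    ------------------------------
    total_inertia_ : sum of column variances of the centered response.
    explained_inertia_ : inertia of the fitted values.
    explained_fraction_ : ``explained_inertia_ / total_inertia_`` — for
        partial fits the denominator stays the ORIGINAL total inertia, so
        unique + shared + unexplained fractions add to one.
    conditioned_inertia_ : inertia of the response after removing the
        covariables (equals ``total_inertia_`` when no covariables).
    eigenvalues_ : canonical eigenvalues, nonincreasing; they sum to
        ``explained_inertia_``.
    rank_constraints_ : numerical rank q of the (residualized) constraints.
    df_residual_ : ``n - q - q_W - 1``.
    species_scores_, response_scores_, biplot_scores_ : triplot score tables.
    """

    def __init__(self, scaling: Literal["correlation"] = "correlation"):
        self.scaling = scaling

    # ------------------------------------------------------------------ fit
    def fit(self, X, Y, W=None) -> "RDA":
        """Fit the (partial) RDA of response ``Y`` on constraints ``X``.

        ``X``, ``Y`` and optional covariables ``W`` must share aligned row
        labels when labelled.
        """
        Xf, Yf, Wf = _as_frame(X, "x"), _as_frame(Y, "y"), _as_frame(W, "w")
        if len(Xf) != len(Yf) or (Wf is not None and len(Wf) != len(Yf)):
            raise ValueError("X, Y (and W) must have the same number of rows")
        Xf = _aligned(Xf, Yf, "X")
        Wf = _aligned(Wf, Yf, "W") if Wf is not None else None
        n = len(Yf)
        if n < 3:
            raise ValueError("need at least 3 rows")

        Yc = _centered(Yf)
        Xc = _centered(Xf)
        denom = n - 1
        total = float((Yc**2).sum()) / denom
        if total <= 0:
            raise ValueError("response has zero total inertia")

        if Wf is not None:
            Wc = _centered(Wf)
            Qw, q_w = _orth_basis(Wc)
            Yr = Yc - Qw @ (Qw.T @ Yc)
            Xr = Xc - Qw @ (Qw.T @ Xc)
        else:
            Qw, q_w = np.zeros((n, 0)), 0
            Yr, Xr = Yc, Xc

        x_scale = float(np.linalg.svd(Xc, compute_uv=False)[0]) if np.any(Xc) else 0.0
        Qx, q = _orth_basis(Xr, ref_scale=x_scale)
        Yhat = Qx @ (Qx.T @ Yr)

        self.n_ = n
        self.n_covariable_dims_ = q_w
        self.rank_constraints_ = q
        self.df_residual_ = n - q - q_w - 1
        self.total_inertia_ = total
        self.conditioned_inertia_ = float((Yr**2).sum()) / denom
        self.explained_inertia_ = float((Yhat**2).sum()) / denom
        self.explained_fraction_ = self.explained_inertia_ / total
        self.residual_inertia_ = self.conditioned_inertia_ - self.explained_inertia_

        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        k = int(np.sum(s > max(RANK_RTOL * s[0], 1e-12))) if s.size and s[0] > 0 else 0
        eig = (s[:k] ** 2) / denom
        self.eigenvalues_ = eig
        axes = [f"RDA{i+1}" for i in range(k)]
        site = U[:, :k] * s[:k]
        self.species_scores_ = pd.DataFrame(site, index=Yf.index, columns=axes)
        resp = Vt[:k].T * np.sqrt(eig) if k else np.zeros((Yf.shape[1], 0))
        self.response_scores_ = pd.DataFrame(resp, index=Yf.columns, columns=axes)
        self.biplot_scores_ = self._biplot(Xf, Xr, site, axes)
        self._Yc, self._Xc = Yc, Xc
        self._Yr, self._Qx, self._Qw = Yr, Qx, Qw
        self._response_columns = list(Yf.columns)
        self._constraint_columns = list(Xf.columns)
        return self

    @staticmethod
    def _biplot(Xf, Xr, site, axes) -> pd.DataFrame:
        """Constraint arrows: correlations of constraints with site scores."""
        out = np.zeros((Xr.shape[1], len(axes)))
        for j in range(Xr.shape[1]):
            xj = Xr[:, j]
            sj = xj.std()
            if sj == 0:
                continue
            for a in range(len(axes)):
                sa = site[:, a].std()
                if sa > 0:
                    out[j, a] = float(np.corrcoef(xj, site[:, a])[0, 1])
        return pd.DataFrame(out, index=Xf.columns, columns=axes)

    # ------------------------------------------------------------- statistics
    def pseudo_f(self) -> float:
        """Permutation-test statistic: mean-explained over mean-residual inertia."""
        self._check_fitted()
        if self.df_residual_ < 1:
            raise ValueError("df_residual < 1: model is saturated")
        if self.rank_constraints_ == 0:
            return 0.0
        num = self.explained_inertia_ / self.rank_constraints_
        den = self.residual_inertia_ / self.df_residual_
        if den <= 0:
            return float("inf") if num > 0 else 0.0
        return num / den

    def axis_variation(self, k: int) -> float:
        """Cumulative fraction of canonical variation on the first k axes."""
        self._check_fitted()
        if k < 1:
            raise ValueError("k must be >= 1")
        eig = self.eigenvalues_
        if eig.size == 0:
            return 0.0
        k = min(k, eig.size)
        return float(eig[:k].sum() / eig.sum())

    def triplot_scores(self) -> dict[str, pd.DataFrame]:
        """Species points, response-variable arrows and constraint arrows."""
        self._check_fitted()
        return {
            "species": self.species_scores_,
            "responses": self.response_scores_,
            "constraints": self.biplot_scores_,
        }

    def _check_fitted(self) -> None:
        if not hasattr(self, "explained_fraction_"):
            raise ValueError("RDA instance is not fitted")


@dataclass(frozen=True)
class PermutationResult:
    """Monte-Carlo permutation test of a (partial) RDA."""

    observed_f: float
    n_permutations: int
    n_as_extreme: int
    p_value: float
    mid_p: float
    seed: int
    scheme: str


def _f_from_projections(expl_ss: float, resid_ss: float, q: int, dfr: int) -> float:
    if q == 0:
        return 0.0
    num = expl_ss / q
    den = resid_ss / dfr
    if den <= 0:
        return float("inf") if num > 0 else 0.0
    return num / den


def _tied(a: float, b: float) -> bool:
    if np.isinf(a) and np.isinf(b):
        return True
    if np.isinf(a) or np.isinf(b):
        return False
    return abs(a - b) <= 1e-9 * max(1.0, abs(b))


def permutation_test(
    Y,
    X,
    W=None,
    n_permutations: int = 9999,
    seed: int = 0,
    scheme: Literal["reduced_model", "unrestricted"] = "reduced_model",
) -> PermutationResult:
    """Monte-Carlo permutation test of the constraints in an RDA.

    Without covariables, rows of Y are permuted uniformly.  With covariables
    the default permutes residuals of the covariable-only (reduced) model and
    adds them back to its fitted values; ``scheme="unrestricted"`` permutes
    the raw rows of Y instead.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    model = RDA().fit(X, Y, W=W)
    q, dfr = model.rank_constraints_, model.df_residual_
    if dfr < 1:
        raise ValueError("df_residual < 1: cannot test a saturated model")
    f_obs = model.pseudo_f()

    Qx, Qw = model._Qx, model._Qw
    Yc = model._Yc
    has_w = Qw.shape[1] > 0
    Yres = model._Yr  # residuals of reduced model (== Yc when no covariables)
    Yfit_w = Yc - Yres

    rng = np.random.default_rng(seed)
    n = Yc.shape[0]
    n_gt = n_tie = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if scheme == "reduced_model" or not has_w:
            Yp = Yres[perm]
        elif scheme == "unrestricted":
            Yp = Yc[perm]
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        if has_w:
            Yp = Yp - Qw @ (Qw.T @ Yp)
        proj = Qx.T @ Yp
        expl = float((proj**2).sum())
        resid = float((Yp**2).sum()) - expl
        f_p = _f_from_projections(expl, resid, q, dfr)
        if _tied(f_p, f_obs):
            n_tie += 1
        elif f_p > f_obs:
            n_gt += 1
    m = n_permutations
    n_extreme = n_gt + n_tie
    return PermutationResult(
        observed_f=f_obs,
        n_permutations=m,
        n_as_extreme=n_extreme,
        p_value=(n_extreme + 1) / (m + 1),
        mid_p=(n_gt + 0.5 * (n_tie + 1)) / (m + 1),
        seed=seed,
        scheme=scheme if has_w else "unrestricted",
    )


# ------------------------------------------------------- functional wrappers
def fit_rda(Y, X, W=None) -> RDA:
    """Fit a (partial) redundancy analysis; returns the fitted :class:`RDA`."""
    return RDA().fit(X, Y, W=W)


def pseudo_f(result: RDA) -> float:
    return result.pseudo_f()


def axis_decomposition(result: RDA, k: int) -> float:
    return result.axis_variation(k)


def triplot_scores(result: RDA) -> dict[str, pd.DataFrame]:
    return result.triplot_scores()
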
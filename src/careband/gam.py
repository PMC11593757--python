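"""Quasi-Poisson trend model with cyclic P-spline seasonality.

The model for the monthly measurement count of stratum *g* in calendar
month *m* is

    log E[Y_gm] = log N_gm + alpha_0 + alpha_g + f(pos(m)) + (beta_0 + beta_g) t_m

with a log population offset, treatment-coded categorical stratum effects,
a cyclic penalized B-spline seasonal curve f over the month-of-year
position, and a linear trend in t (years relative to March 2020) with
stratum interactions.  Variance is quasi-Poisson, Var(Y) = phi * mu, with
phi estimated from Pearson residuals.  Fitting is penalized iteratively
reweighted least squares (PIRLS); the smoothing parameter is chosen by
generalized cross-validation on a grid.

Identifiability: the cyclic B-spline basis is a partition of unity, so the
seasonal block is absorbed through a sum-to-zero constraint — the k basis
columns are reparameterized onto the (k-1)-dimensional null space of their
column-mean vector, exactly as mgcv handles smooth-plus-intercept models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.special import comb

from .months import as_month, month_position, trend_index

__all__ = [
    "CyclicBasisSpec",
    "PenaltySpec",
    "FitError",
    "PredictionError",
    "cyclic_basis",
    "cyclic_penalty",
    "DesignInfo",
    "build_design",
    "fit_pirls",
    "select_lambda",
    "FittedTrendModel",
    "fit_trend_model",
    "Z_95",
]

#: Normal 97.5% quantile used for all Wald 95% intervals.
Z_95 = 1.959963984540054

DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-2, 5, dtype=float))


class FitError(RuntimeError):
    """Raised when the penalized IRLS fit cannot be completed."""


class PredictionError(ValueError):
    """Raised when prediction is requested at unseen category levels."""


@dataclass(frozen=True)
class CyclicBasisSpec:
    """Cyclic B-spline basis over the month-of-year, period 12."""

    k: int = 6
    degree: int = 3
    period: float = 12.0

    def __post_init__(self) -> None:
        if self.k < self.degree + 1:
            raise ValueError("k must be at least degree + 1")


@dataclass(frozen=True)
class PenaltySpec:
    """Cyclic difference penalty of a given order on spline coefficients."""

    order: int = 2


def cyclic_basis(m, spec: CyclicBasisSpec = CyclicBasisSpec()) -> np.ndarray:
    """Evaluate the k cyclic B-spline basis functions at month positions.

    ``m`` may be a scalar or array; values outside [0, period) are reduced
    modulo the period.  Built from an ordinary B-spline basis on equally
    spaced knots extended by ``degree`` intervals each side of the period,
    with the overhanging columns folded back (index mod k), which makes
    the basis a periodic partition of unity with degree-1 continuous
    derivatives across the wrap point.
    """
    x = np.atleast_1d(np.asarray(m, dtype=float)) % spec.period
    h = spec.period / spec.k
    knots = h * np.arange(-spec.degree, spec.k + spec.degree + 1)
    dm = BSpline.design_matrix(x, knots, spec.degree).toarray()
    out = np.zeros((len(x), spec.k))
    for j in range(dm.shape[1]):
        out[:, j % spec.k] += dm[:, j]
    return out


def cyclic_penalty(
    spec: CyclicBasisSpec = CyclicBasisSpec(), pen: PenaltySpec = PenaltySpec()
) -> np.ndarray:
    """Penalty matrix S = D'D for the cyclically wrapped difference operator.

    D has one row per coefficient, holding the ``order``-th difference
    with indices wrapped modulo k; S is symmetric PSD and annihilates the
    constant vector.
    """
    k, d = spec.k, pen.order
    if d >= k:
        raise ValueError(f"difference order {d} must be < k = {k}")
    D = np.zeros((k, k))
    coeffs = [(-1.0) ** (d - j) * comb(d, j, exact=True) for j in range(d + 1)]
    for i in range(k):
        for j, c in enumerate(coeffs):
            D[i, (i + j) % k] += c
    return D.T @ D


@dataclass
class DesignInfo:
    """Frozen description of the model design for fitting and prediction."""

    stratify: Tuple[str, ...]
    levels: Dict[str, List]
    spec: CyclicBasisSpec
    Z: np.ndarray  # (k, k-1) sum-to-zero reparameterization
    columns: List[str]
    fit_months: List[str]

    @property
    def spline_slice(self) -> slice:
        start = self.columns.index("season1")
        return slice(start, start + self.spec.k - 1)


def _category_columns(info: DesignInfo, df: pd.DataFrame) -> Dict[str, np.ndarray]:
    cols = {}
    for dim in info.stratify:
        levels = info.levels[dim]
        values = df[dim]
        unseen = set(values.dropna().unique()) - set(levels)
        if unseen:
            raise PredictionError(
                f"unseen level(s) {sorted(map(str, unseen))!r} for {dim!r}"
            )
        for lev in levels[1:]:
            cols[f"{dim}[{lev}]"] = (values == lev).to_numpy(dtype=float)
    return cols


def _design_rows(
    info: DesignInfo, df: pd.DataFrame, frozen_trend: bool = False
) -> np.ndarray:
    """Model-matrix rows for a frame with ``month`` plus stratum columns.

    With ``frozen_trend`` the trend index is clamped at 0 for months after
    March 2020 (counterfactual of an unchanged long-term trend).
    """
    months = [as_month(m) for m in df["month"]]
    t = np.array([trend_index(m) for m in months])
    if frozen_trend:
        t = np.minimum(t, 0.0)
    pos = np.array([month_position(m) for m in months], dtype=float)
    B = cyclic_basis(pos, info.spec) @ info.Z

    cats = _category_columns(info, df)
    n = len(df)
    blocks = [np.ones((n, 1))]
    blocks.extend(cats[c][:, None] for c in cats)
    blocks.append(B)
    blocks.append(t[:, None])
    blocks.extend((t * cats[c])[:, None] for c in cats)
    X = np.hstack(blocks)
    assert X.shape[1] == len(info.columns)
    return X


def build_design(
    rates: pd.DataFrame,
    spec: CyclicBasisSpec = CyclicBasisSpec(),
    stratify: Sequence[str] = (),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, DesignInfo]:
    """Build (X, y, offset, info) from a monthly-rate table.

    ``rates`` must be restricted to the fit window and contain ``month``,
    ``count``, ``denominator`` plus any stratification columns.  Columns
    of X: intercept, treatment-coded categoricals (first level reference),
    k-1 constrained spline columns, the trend index t and t × categorical
    interactions.  The offset is log(denominator).
    """
    stratify = tuple(stratify)
    if (rates["denominator"] <= 0).any():
        raise ValueError("all denominators must be positive in the fit window")
    levels = {
        dim: sorted(rates[dim].dropna().unique().tolist()) for dim in stratify
    }
    pos_grid = np.array(
        [month_position(as_month(m)) for m in rates["month"]], dtype=float
    )
    B_raw = cyclic_basis(pos_grid, spec)
    colmeans = B_raw.mean(axis=0)
    Z = null_space(colmeans[None, :])
    if Z.shape != (spec.k, spec.k - 1):  # pragma: no cover - degenerate input
        raise FitError("could not construct sum-to-zero constraint basis")

    columns = ["(Intercept)"]
    for dim in stratify:
        columns += [f"{dim}[{lev}]" for lev in levels[dim][1:]]
    columns += [f"season{j}" for j in range(1, spec.k)]
    columns += ["t"]
    for dim in stratify:
        columns += [f"t:{dim}[{lev}]" for lev in levels[dim][1:]]

    info = DesignInfo(
        stratify=stratify,
        levels=levels,
        spec=spec,
        Z=Z,
        columns=columns,
        fit_months=sorted({str(as_month(m)) for m in rates["month"]}),
    )
    X = _design_rows(info, rates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "check for empty strata or too few fit months"
        )
    y = rates["count"].to_numpy(dtype=float)
    offset = np.log(rates["denominator"].to_numpy(dtype=float))
    return X, y, offset, info


def _penalty_full(info: DesignInfo, pen: PenaltySpec) -> np.ndarray:
    """Embed the constrained spline penalty Z'SZ in the full coefficient space."""
    p = len(info.columns)
    S_full = np.zeros((p, p))
    S_z = info.Z.T @ cyclic_penalty(info.spec, pen) @ info.Z
    sl = info.spline_slice
    S_full[sl, sl] = S_z
    return S_full


def fit_pirls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    S: Optional[np.ndarray] = None,
    lam: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict:
    """Penalized IRLS for the quasi-Poisson log-link model.

    Iterates weighted least squares on the working response until the
    relative change in deviance is below ``tol`` (or ``max_iter`` is hit,
    which is reported as non-convergence).  Returns a dict with ``beta``,
    the scaled covariance ``cov`` = phi * (X'WX + lam*S)^-1, the Pearson
    dispersion ``phi``, effective degrees of freedom ``edf``, ``deviance``,
    ``pearson`` and convergence diagnostics.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n, p = X.shape
    if S is None or lam == 0.0:
        P = np.zeros((p, p))
    else:
        P = lam * S
    if y.sum() == 0:
        warnings.warn("all counts are zero; fit is degenerate", RuntimeWarning)

    mu = y + 0.5
    eta = np.log(mu) - offset
    deviance = np.inf
    converged = False
    trace: List[float] = []
    for iteration in range(1, max_iter + 1):
        mu = np.exp(eta + offset)
        W = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        F = XtW @ X + P
        try:
            beta = np.linalg.solve(F, XtW @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError(f"singular system at iteration {iteration}: {exc}")
        eta = X @ beta
        mu = np.exp(eta + offset)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        new_dev = 2.0 * dev_terms.sum()
        trace.append(new_dev)
        if not np.isfinite(new_dev):
            raise FitError(f"divergent fit at iteration {iteration}; trace={trace}")
        if abs(new_dev - deviance) < tol * (abs(new_dev) + 0.1):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev

    XtW = X.T * mu
    F = XtW @ X + P
    F_inv = np.linalg.inv(F)
    edf = float(np.trace(F_inv @ (XtW @ X)))
    pearson = float(((y - mu) ** 2 / mu).sum())
    dof = max(n - edf, 1e-8)
    phi = pearson / dof
    cov = phi * F_inv
    return {
        "beta": beta,
        "cov": cov,
        "phi": phi,
        "edf": edf,
        "deviance": float(deviance),
        "pearson": pearson,
        "converged": converged,
        "n_iter": iteration,
        "mu": mu,
    }


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    S: np.ndarray,
    grid: Sequence[float],
) -> float:
    """Choose the smoothing parameter minimizing GCV on a grid.

    GCV(lam) = n * PearsonChi2 / (n - edf)^2; ties are broken toward the
    larger (smoother) lambda.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    n = len(y)
    best_lam, best_gcv = None, np.inf
    for lam in grid:
        fit = fit_pirls(X, y, offset, S, lam)
        gcv = n * fit["pearson"] / (n - fit["edf"]) ** 2
        if gcv <= best_gcv:
            best_gcv, best_lam = gcv, lam
    return best_lam


@dataclass
class FittedTrendModel:
    """Fitted pre-pandemic quasi-Poisson trend model for one factor."""

    info: DesignInfo
    beta: np.ndarray
    cov: np.ndarray
    phi: float
    lam: float
    edf: float
    deviance: float
    converged: bool
    n_iter: int
    factor: Optional[str] = None

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.beta, index=self.info.columns)

    def predict_eta(
        self, newdata: pd.DataFrame, frozen_trend: bool = False
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Linear predictor (offset excluded) and its standard error.

        With ``frozen_trend`` the trend index is clamped at 0 after March
        2020, giving the stable-trend counterfactual.
        """
        X = _design_rows(self.info, newdata, frozen_trend=frozen_trend)
        eta = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return eta, se

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "stratify": list(self.info.stratify),
            "levels": {
                k: [v if not isinstance(v, (np.integer, np.floating)) else v.item()
                    for v in vals]
                for k, vals in self.info.levels.items()
            },
            "basis": {
                "k": self.info.spec.k,
                "degree": self.info.spec.degree,
                "period": self.info.spec.period,
            },
            "Z": self.info.Z.tolist(),
            "columns": self.info.columns,
            "fit_months": self.info.fit_months,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "phi": self.phi,
            "lambda": self.lam,
            "edf": self.edf,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedTrendModel":
        spec = CyclicBasisSpec(**d["basis"])
        info = DesignInfo(
            stratify=tuple(d["stratify"]),
            levels={k: list(v) for k, v in d["levels"].items()},
            spec=spec,
            Z=np.array(d["Z"]),
            columns=list(d["columns"]),
            fit_months=list(d["fit_months"]),
        )
        return cls(
            info=info,
            beta=np.array(d["beta"]),
            cov=np.array(d["cov"]),
            phi=d["phi"],
            lam=d["lambda"],
            edf=d["edf"],
            deviance=d["deviance"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            factor=d.get("factor"),
        )

    @classmethod
    def load(cls, path) -> "FittedTrendModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_trend_model(
    rates: pd.DataFrame,
    fit_start="2018-11",
    fit_end="2020-02",
    spec: CyclicBasisSpec = CyclicBasisSpec(),
    pen: PenaltySpec = PenaltySpec(),
    stratify: Sequence[str] = (),
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    factor: Optional[str] = None,
) -> FittedTrendModel:
    """Fit the trend model on the pre-pandemic window of a rate table.

    Restricts ``rates`` to [fit_start, fit_end], builds the design,
    selects the smoothing parameter by GCV and runs the final PIRLS fit.
    """
    months = pd.PeriodIndex([as_month(m) for m in rates["month"]])
    window = (months >= as_month(fit_start)) & (months <= as_month(fit_end))
    fit_rates = rates[window.to_numpy() if hasattr(window, "to_numpy") else window]
    if factor is not None:
        fit_rates = fit_rates[fit_rates["factor"] == factor]
    if len(fit_rates) == 0:
        raise FitError("no rows in the fit window")
    X, y, offset, info = build_design(fit_rates, spec, stratify)
    S = _penalty_full(info, pen)
    lam = select_lambda(X, y, offset, S, lambda_grid)
    fit = fit_pirls(X, y, offset, S, lam)
    if not fit["converged"]:
        warnings.warn(
            f"PIRLS did not converge in {fit['n_iter']} iterations", RuntimeWarning
        )
    return FittedTrendModel(
        info=info,
        beta=fit["beta"],
        cov=fit["cov"],
        phi=fit["phi"],
        lam=lam,
        edf=fit["edf"],
        deviance=fit["deviance"],
        converged=fit["converged"],
        n_iter=fit["n_iter"],
        factor=factor,
    )
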
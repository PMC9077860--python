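"""NIPALS PLS1 regression with model diagnostics.

Partial least squares projects autoscaled predictors onto a small number
of orthogonal latent variables (LVs) chosen to covary maximally with the
centered response, then regresses the response on those scores.  Besides
fitting and prediction this module provides the standard chemometric
diagnostics: variable importance in projection (VIP), per-component
weights and original-scale coefficients, the Hotelling T2 score-space
applicability check, and DModX (distance to the model in X-space).

Sign convention: every component is flipped, if necessary, so that its
y-loading q_a is non-negative; reported weights, loadings and scores are
therefore reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PLSModel:
    """Fitted PLS1 model on autoscaled X and centered y."""

    n_lv: int
    columns: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    W: np.ndarray          # weights, p x a
    P: np.ndarray          # X-loadings, p x a
    q: np.ndarray          # y-loadings, length a
    T: np.ndarray          # training scores, n x a
    x_var_explained: np.ndarray
    y_var_explained: np.ndarray
    train_residual_X: np.ndarray = field(repr=False)  # scaled-X residual, n x p

    # -- derived quantities --------------------------------------------------

    @property
    def coef_scaled(self) -> np.ndarray:
        """Regression coefficients on the autoscaled X / centered y scale."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.q)

    @property
    def coef_(self) -> np.ndarray:
        """Coefficients on the original descriptor scale."""
        return self.coef_scaled / self.x_sd

    @property
    def intercept_(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef_)

    @property
    def w_star(self) -> np.ndarray:
        """Weights transformed to apply directly to (deflation-free) X."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self.scale(X) @ self.w_star

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "n_lv": self.n_lv,
            "columns": self.columns,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class AdReport:
    """Applicability-domain report (DModX and/or Hotelling T2)."""

    values: pd.Series
    critical: float
    inside: pd.Series
    kind: str
    confidence: float


def fit_pls(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_lv: int,
    scale: bool = True,
) -> PLSModel:
    """Fit NIPALS PLS1 with ``n_lv`` latent variables.

    X is centered and (by default) scaled to unit variance; y is centered.
    Raises if ``n_lv`` exceeds the rank of the centered predictor matrix.
    """
    columns = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if ya.shape[0] != n:
        raise ValueError("X and y row counts differ")
    x_mean = Xa.mean(axis=0)
    x_sd = Xa.std(axis=0, ddof=1) if scale else np.ones(p)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    y_mean = float(ya.mean())

    E = (Xa - x_mean) / x_sd
    f = ya - y_mean
    rank = np.linalg.matrix_rank(E)
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds attainable rank {rank}")

    ss_x_total = float((E ** 2).sum())
    ss_y_total = float((f ** 2).sum())
    degenerate_y = ss_y_total == 0.0

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    x_var = np.zeros(n_lv)
    y_var = np.zeros(n_lv)

    for a in range(n_lv):
        if degenerate_y:
            break  # mean model: all components zero
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        pa = E.T @ t / tt
        qa = float(f @ t / tt)
        if qa < 0:  # q-positive sign convention
            w, t, pa, qa = -w, -t, -pa, -qa
        E = E - np.outer(t, pa)
        f = f - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        x_var[a] = tt * float(pa @ pa) / ss_x_total if ss_x_total > 0 else 0.0
        y_var[a] = qa ** 2 * tt / ss_y_total if ss_y_total > 0 else 0.0

    return PLSModel(
        n_lv=n_lv,
        columns=columns,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        W=W,
        P=P,
        q=q,
        T=T,
        x_var_explained=x_var,
        y_var_explained=y_var,
        train_residual_X=E,
    )


def predict(model: PLSModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predicted response for new rows (columns must align with training)."""
    if isinstance(X, pd.DataFrame):
        if list(map(str, X.columns)) != model.columns:
            raise ValueError("descriptor columns do not match the fitted model")
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X @ model.coef_ + model.intercept_


def vip(model: PLSModel) -> pd.Series:
    """Variable importance in projection.

    ``VIP_j = sqrt( p * sum_a [SSY_a (w_ja/||w_a||)^2] / sum_a SSY_a )``
    with ``SSY_a = q_a^2 t_a' t_a``; satisfies ``sum_j VIP_j^2 = p``.
    """
    p = len(model.columns)
    ssy = model.q ** 2 * (model.T ** 2).sum(axis=0)
    denom = ssy.sum()
    if denom == 0:
        return pd.Series(np.ones(p), index=model.columns, name="VIP")
    wnorm = np.linalg.norm(model.W, axis=0)
    wnorm = np.where(wnorm > 0, wnorm, 1.0)
    frac = (model.W / wnorm) ** 2
    scores = np.sqrt(p * (frac @ ssy) / denom)
    return pd.Series(scores, index=model.columns, name="VIP")


def coefficients_and_weights(model: PLSModel) -> pd.DataFrame:
    """Named table of original-scale coefficients and per-component weights."""
    out = pd.DataFrame(index=model.columns)
    out["coefficient"] = model.coef_
    out["coefficient_scaled"] = model.coef_scaled
    ws = model.w_star
    for a in range(model.n_lv):
        out[f"w_comp{a + 1}"] = model.W[:, a]
        out[f"wstar_comp{a + 1}"] = ws[:, a]
        out[f"p_comp{a + 1}"] = model.P[:, a]
    out.attrs["intercept"] = model.intercept_
    return out


def hotelling_t2(
    model: PLSModel,
    X: pd.DataFrame | np.ndarray | None = None,
    confidence: float = 0.95,
    n_components: int | None = None,
) -> AdReport:
    """Hotelling T2 of score vectors with its F-distribution critical limit.

    ``T2_i = sum_a t_ia^2 / var(t_a)``;
    ``limit = a (n - 1) / (n - a) * F(a, n - a)`` at the given confidence.
    """
    a = n_components or model.n_lv
    n = model.T.shape[0]
    var_t = model.T[:, :a].var(axis=0, ddof=1)
    var_t = np.where(var_t > 0, var_t, np.inf)
    if X is None:
        scores = model.T[:, :a]
        index = pd.RangeIndex(n)
    else:
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        scores = model.scores(np.asarray(X, dtype=float))[:, :a]
    t2 = (scores ** 2 / var_t).sum(axis=1)
    limit = a * (n - 1) / (n - a) * stats.f.ppf(confidence, a, n - a)
    t2s = pd.Series(t2, index=index, name="T2")
    return AdReport(values=t2s, critical=float(limit), inside=t2s <= limit,
                    kind="hotelling_t2", confidence=confidence)


def t2_ellipse(model: PLSModel, confidence: float = 0.95) -> tuple[float, float]:
    """Semi-axes of the 2-component Hotelling ellipse in the score plot."""
    if model.n_lv < 2:
        raise ValueError("score-plot ellipse needs at least 2 components")
    n = model.T.shape[0]
    limit = 2 * (n - 1) / (n - 2) * stats.f.ppf(confidence, 2, n - 2)
    s1, s2 = model.T[:, 0].var(ddof=1), model.T[:, 1].var(ddof=1)
    return float(np.sqrt(limit * s1)), float(np.sqrt(limit * s2))


def dmodx(
    model: PLSModel,
    X: pd.DataFrame | np.ndarray | None = None,
    confidence: float = 0.99,
) -> AdReport:
    """Normalized DModX applicability domain.

    Each row's residual SD after projection onto the model plane,
    ``s_i = sqrt(sum_j e_ij^2 / (p - a))``, is normalized by the pooled
    training residual ``s_0 = sqrt(sum_ij e_ij^2 / ((n - a - 1)(p - a)))``.
    Rows whose DModX exceeds ``sqrt(F_crit)`` at the stated confidence are
    flagged outside the applicability domain.
    """
    n, p = model.train_residual_X.shape
    a = model.n_lv
    if p <= a:
        raise ValueError("DModX undefined: no residual X dimensions left")
    dof_row = p - a
    dof_pool = (n - a - 1) * dof_row
    s0_sq = float((model.train_residual_X ** 2).sum()) / dof_pool
    if s0_sq == 0:
        raise ValueError("pooled X-residual is zero (perfect projection); DModX undefined")

    if X is None:
        E = model.train_residual_X
        index = pd.RangeIndex(n)
    else:
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(np.atleast_2d(X)))
        Z = model.scale(np.atleast_2d(np.asarray(X, dtype=float)))
        scores = Z @ model.w_star
        E = Z - scores @ model.P.T
    s_i = np.sqrt((E ** 2).sum(axis=1) / dof_row)
    d = pd.Series(s_i / np.sqrt(s0_sq), index=index, name="DModX")
    crit = float(np.sqrt(stats.f.ppf(confidence, dof_row, dof_pool)))
    return AdReport(values=d, critical=crit, inside=d <= crit,
                    kind="dmodx", confidence=confidence)


def max_components(X: pd.DataFrame | np.ndarray) -> int:
    Xa = np.asarray(X, dtype=float)
    return int(np.linalg.matrix_rank(Xa - Xa.mean(axis=0)))
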
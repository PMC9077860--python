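"""Internal/external validation statistics and Y-randomization.

Covers the standard QSAR battery: goodness of fit (R2, standard error of
estimate, F), internal predictivity (leave-one-out Q2 with full model
refit per fold), external predictivity (Q2_F1 / Q2_F2 / RMSE on a test
set never used for selection), and the Y-randomization chance-correlation
check (response permutation with R2/Q2 intercepts).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pls import PLSModel, fit_pls, predict

R2_INTERCEPT_LIMIT = 0.3   # Y-randomization acceptance bound on the R2 intercept
Q2_INTERCEPT_LIMIT = 0.05  # ... and on the Q2 intercept


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Determination coefficient 1 - RSS/TSS."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - y_hat) ** 2).sum())
    return 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    return float(np.sqrt(((y - y_hat) ** 2).mean()))


def see(y: np.ndarray, y_hat: np.ndarray, n_params: int) -> float:
    """Standard error of estimate with n - a - 1 degrees of freedom.

    ``n_params`` is the number of regression variables, for a PLS model the
    latent-variable count.
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    dof = n - n_params - 1
    if dof <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, a={n_params})")
    return float(np.sqrt(((y - np.asarray(y_hat, float)) ** 2).sum() / dof))


def f_stat(y: np.ndarray, y_hat: np.ndarray, n_params: int) -> tuple[float, tuple[int, int]]:
    """Variance ratio F = (R2/a) / ((1-R2)/(n-a-1)) with its df pair."""
    n = np.asarray(y).shape[0]
    a = n_params
    r = r2(y, y_hat)
    dof = (a, n - a - 1)
    if r >= 1.0:
        return math.inf, dof
    return (r / a) / ((1.0 - r) / (n - a - 1)), dof


def q2_loo(X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray, n_lv: int,
           scale: bool = True) -> float:
    """Leave-one-out cross-validated Q2 with full PLS refit per fold.

    Each fold re-centers and re-scales on its n-1 rows.  A fold where the
    reduced matrix no longer supports ``n_lv`` components falls back to the
    fold's training-mean prediction.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n = Xa.shape[0]
    if n < 3:
        raise ValueError("LOO cross-validation needs at least 3 rows")
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        try:
            m = fit_pls(Xa[keep], ya[keep], n_lv=n_lv, scale=scale)
            pred = float(predict(m, Xa[i:i + 1])[0])
        except ValueError:
            pred = float(ya[keep].mean())
        press += (ya[i] - pred) ** 2
    tss = float(((ya - ya.mean()) ** 2).sum())
    return 1.0 - press / tss


def q2_external(
    y_test: np.ndarray, y_hat_test: np.ndarray, y_train_mean: float
) -> tuple[float, float, float]:
    """External predictivity (Q2_F1, Q2_F2, RMSE_test).

    Q2_F1 scales the prediction error by deviations of the test responses
    from the *training* mean, Q2_F2 by deviations from the *test* mean.
    """
    y = np.asarray(y_test, float)
    y_hat = np.asarray(y_hat_test, float)
    rss = float(((y - y_hat) ** 2).sum())
    q2f1 = 1.0 - rss / float(((y - y_train_mean) ** 2).sum())
    q2f2 = 1.0 - rss / float(((y - y.mean()) ** 2).sum())
    return q2f1, q2f2, rmse(y, y_hat)


# ---------------------------------------------------------------------------
# Y-randomization
# ---------------------------------------------------------------------------

@dataclass
class YRandomizationResult:
    n_perm: int
    r2_intercept: float
    q2_intercept: float
    records: pd.DataFrame = field(repr=False)
    passes: bool = False

    def summary(self) -> dict[str, float | int | bool]:
        return {
            "n_perm": self.n_perm,
            "r2_intercept": self.r2_intercept,
            "q2_intercept": self.q2_intercept,
            "passes": self.passes,
        }


def _line_intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def y_randomization(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_lv: int,
    n_perm: int = 100,
    seed: int = 0,
    include_unpermuted: bool = True,
    scale: bool = True,
) -> YRandomizationResult:
    """Response-permutation test against chance correlation.

    For each permutation the PLS model is refitted and its R2 and LOO-Q2
    recorded against ``c = |corr(y_perm, y)|``; straight lines of R2 and Q2
    versus c (including the unpermuted model at c = 1 by default) are
    extrapolated to c = 0.  Acceptable models have an R2 intercept < 0.3
    and a Q2 intercept < 0.05.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()

    rows = []
    perms = [ya[rng.permutation(len(ya))] for _ in range(n_perm)]
    if include_unpermuted:
        perms.insert(0, ya.copy())
    for y_perm in perms:
        m = fit_pls(Xa, y_perm, n_lv=n_lv, scale=scale)
        r2_p = r2(y_perm, predict(m, Xa))
        q2_p = q2_loo(Xa, y_perm, n_lv=n_lv, scale=scale)
        c = abs(float(np.corrcoef(y_perm, ya)[0, 1]))
        rows.append({"c": c, "r2": r2_p, "q2": q2_p})
    records = pd.DataFrame(rows)
    r2_int = _line_intercept(records["c"].to_numpy(), records["r2"].to_numpy())
    q2_int = _line_intercept(records["c"].to_numpy(), records["q2"].to_numpy())
    return YRandomizationResult(
        n_perm=n_perm,
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        records=records,
        passes=(r2_int < R2_INTERCEPT_LIMIT) and (q2_int < Q2_INTERCEPT_LIMIT),
    )


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    r2: float
    q2_loo: float
    q2_f1: float | None
    q2_f2: float | None
    rmse_train: float
    rmse_test: float | None
    see: float
    f_stat: float
    df: tuple[int, int]
    n_train: int
    n_test: int
    y_rand: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["df"] = list(self.df)
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_markdown(self) -> str:
        lines = [
            "| metric | value |", "|---|---|",
            f"| R2 (train) | {self.r2:.4f} |",
            f"| Q2 (LOO) | {self.q2_loo:.4f} |",
            f"| SEE | {self.see:.4f} |",
            f"| F({self.df[0]}, {self.df[1]}) | {self.f_stat:.2f} |",
            f"| RMSE (train) | {self.rmse_train:.4f} |",
        ]
        if self.q2_f1 is not None:
            lines += [
                f"| Q2_F1 | {self.q2_f1:.4f} |",
                f"| Q2_F2 | {self.q2_f2:.4f} |",
                f"| RMSE (test) | {self.rmse_test:.4f} |",
            ]
        if self.y_rand:
            lines += [
                f"| Y-rand R2 intercept | {self.y_rand['r2_intercept']:.4f} |",
                f"| Y-rand Q2 intercept | {self.y_rand['q2_intercept']:.4f} |",
            ]
        return "\n".join(lines)


def validate_model(
    model: PLSModel,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | None = None,
    y_rand_perms: int = 0,
    seed: int = 0,
) -> ValidationReport:
    """Full validation battery for a fitted PLS model."""
    y_hat = predict(model, X_train)
    ya = np.asarray(y_train, float)
    a = model.n_lv
    f_val, dof = f_stat(ya, y_hat, a)
    q2f1 = q2f2 = rmse_te = None
    n_test = 0
    if X_test is not None and len(X_test):
        y_hat_te = predict(model, X_test)
        q2f1, q2f2, rmse_te = q2_external(np.asarray(y_test, float), y_hat_te, float(ya.mean()))
        n_test = len(X_test)
    y_rand = None
    if y_rand_perms:
        y_rand = y_randomization(X_train, y_train, n_lv=a, n_perm=y_rand_perms, seed=seed).summary()
    return ValidationReport(
        r2=r2(ya, y_hat),
        q2_loo=q2_loo(X_train, y_train, n_lv=a),
        q2_f1=q2f1,
        q2_f2=q2f2,
        rmse_train=rmse(ya, y_hat),
        rmse_test=rmse_te,
        see=see(ya, y_hat, a),
        f_stat=f_val,
        df=dof,
        n_train=len(ya),
        n_test=n_test,
        y_rand=y_rand,
    )
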
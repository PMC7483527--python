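"""Correlation machinery with bootstrap standard errors and BCa intervals.

Validation analyses of text-derived vocabulary indices are reported as
Pearson or partial correlations with a bootstrap standard error and a 95%
bias-corrected and accelerated (BCa) confidence interval, resampling
authors (rows) with replacement. The partial correlation of x and y given
controls equals the Pearson correlation of the residuals of x and y after
least-squares projection on the controls plus an intercept.

BCa construction: the bias-correction factor ``z0`` is the normal quantile
of the fraction of bootstrap replicates below the point estimate (ties
counted half, fraction clipped to [1/(2B), 1 - 1/(2B)] so z0 stays
finite), and the acceleration ``a`` comes from the jackknife skewness
formula ``a = sum(d^3) / (6 * (sum(d^2))^1.5)`` with ``d`` the deviations
of the leave-one-out statistics from their mean. Interval endpoints are
order statistics of the bootstrap distribution. Resamples on which the
statistic is undefined (non-finite) are re-drawn and counted; more than 1%
of ``n_boot`` degenerate re-draws is an error. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

__all__ = [
    "CorrelationResult",
    "BootstrapResult",
    "DegenerateResamplesError",
    "pearson_r",
    "partial_correlation",
    "bca_bootstrap",
    "correlate",
    "write_correlation_report",
]


class DegenerateResamplesError(RuntimeError):
    """Statistic undefined on more than 1% of bootstrap resamples."""


@dataclass(frozen=True)
class BootstrapResult:
    """Summary of one BCa bootstrap run."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_degenerate: int
    seed: int
    replicates: np.ndarray = field(repr=False, compare=False)


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with bootstrap SE, BCa 95% CI and p-value."""

    r: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    method: str                      # "pearson" | "partial"
    controls: tuple[str, ...]
    seed: int
    p: float
    n_degenerate: int = 0

    def __str__(self) -> str:  # compact Table-style rendering
        ctl = f" | {', '.join(self.controls)}" if self.controls else ""
        return (
            f"r = {self.r:.3f} (SE {self.se:.3f}), "
            f"95% BCa CI [{self.ci_low:.3f}, {self.ci_high:.3f}], "
            f"n = {self.n}, p = {self.p:.2g} [{self.method}{ctl}]"
        )


# -- point estimates -----------------------------------------------------


def _as_1d(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"expected 1-d vector, got shape {a.shape}")
    return a


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either input is constant."""
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xm @ ym) / denom, -1.0, 1.0))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation with pairwise-complete filtering.

    Requires at least 3 complete pairs and nonzero variance in both
    inputs.
    """
    x, y = _as_1d(x), _as_1d(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    # scipy's implementation is the reference estimate
    return float(sps.pearsonr(x, y).statistic)


def _control_matrix(controls, n: int) -> tuple[np.ndarray, list[str]]:
    if controls is None:
        return np.empty((n, 0)), []
    if isinstance(controls, pd.DataFrame):
        names = [str(c) for c in controls.columns]
        c = controls.to_numpy(dtype=float)
    else:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        names = [f"c{i}" for i in range(c.shape[1])]
    if c.shape[0] != n:
        raise ValueError(
            f"controls have {c.shape[0]} rows, expected {n}")
    return c, names


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x: Sequence[float], y: Sequence[float],
                        controls) -> float:
    """Partial correlation of x and y given a matrix of control variables.

    Rows with any missing value are dropped listwise; the result is the
    Pearson correlation of the residuals of x and y after least-squares
    projection on the controls plus an intercept. With zero controls this
    equals :func:`pearson_r` exactly. Rank-deficient controls raise a
    ``ValueError`` naming the collinear columns.
    """
    x, y = _as_1d(x), _as_1d(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    c, names = _control_matrix(controls, x.shape[0])
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(c), axis=1)
    x, y, c = x[keep], y[keep], c[keep]
    k = c.shape[1]
    if x.size <= k + 2:
        raise ValueError(
            f"need n > n_controls + 2 ({k + 2}), have n = {x.size}")
    if k == 0:
        return pearson_r(x, y)
    design = np.column_stack([np.ones(x.size), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient controls: {bad}")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    r = _pearson(rx, ry)
    if np.isnan(r):
        raise ValueError("constant input after residualization")
    return r


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name control columns lying (numerically) in the span of the others."""
    bad = []
    for j in range(1, design.shape[1]):      # column 0 is the intercept
        others = np.delete(design, j, axis=1)
        resid = _residualize(design[:, j], others)
        scale = np.linalg.norm(design[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(names[j - 1])
    return bad or names


# -- bootstrap -----------------------------------------------------------


def _rows(data):
    if isinstance(data, pd.DataFrame):
        return data.to_numpy()
    return np.asarray(data)


def bca_bootstrap(statistic: Callable[[np.ndarray], float], data,
                  n_boot: int = 2000, seed: int = 0,
                  alpha: float = 0.05) -> BootstrapResult:
    """Bootstrap a row-resampleable statistic and form its BCa interval.

    ``statistic`` maps an (n, k) array of resampled rows to a number;
    ``data`` is an array or DataFrame whose rows are the resampling units
    (authors/documents). Returns the point estimate, bootstrap SE
    (standard deviation of the replicates), the BCa interval at level
    ``1 - alpha``, and the count of degenerate re-drawn resamples.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    arr = _rows(data)
    n = arr.shape[0]
    theta_hat = float(statistic(arr))
    if not np.isfinite(theta_hat):
        raise ValueError("statistic undefined on the full sample")

    rng = np.random.default_rng(seed)
    max_degenerate = max(1, int(np.ceil(0.01 * n_boot)))
    boot = np.empty(n_boot)
    n_degenerate = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            val = float(statistic(arr[idx]))
            if np.isfinite(val):
                boot[b] = val
                break
            n_degenerate += 1
            if n_degenerate > max_degenerate:
                raise DegenerateResamplesError(
                    f"statistic undefined on > 1% of resamples "
                    f"({n_degenerate} redraws for n_boot={n_boot})"
                )

    se = float(boot.std(ddof=1))

    # bias correction: fraction of replicates below the point estimate
    frac_below = (np.sum(boot < theta_hat)
                  + 0.5 * np.sum(boot == theta_hat)) / n_boot
    frac_below = float(np.clip(frac_below,
                               1.0 / (2 * n_boot), 1 - 1.0 / (2 * n_boot)))
    z0 = ndtri(frac_below)

    # acceleration via jackknife skewness
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(arr[mask])
        mask[i] = True
    if not np.all(np.isfinite(jack)):
        raise ValueError("statistic undefined on a jackknife sample")
    d = jack.mean() - jack
    denom = 6.0 * np.sum(d * d) ** 1.5
    a = float(np.sum(d ** 3) / denom) if denom > 0 else 0.0

    z_lo, z_hi = ndtri(alpha / 2), ndtri(1 - alpha / 2)
    alpha1 = float(ndtr(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo))))
    alpha2 = float(ndtr(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi))))

    boot_sorted = np.sort(boot)
    lo_i = int(np.clip(np.floor(alpha1 * n_boot), 0, n_boot - 1))
    hi_i = int(np.clip(np.ceil(alpha2 * n_boot) - 1, 0, n_boot - 1))
    return BootstrapResult(
        estimate=theta_hat, se=se,
        ci_low=float(boot_sorted[lo_i]), ci_high=float(boot_sorted[hi_i]),
        n_boot=n_boot, n_degenerate=n_degenerate, seed=seed,
        replicates=boot,
    )


# -- high-level interface ------------------------------------------------


def correlate(data: pd.DataFrame, x: str, y: str,
              controls: Sequence[str] = (), n_boot: int = 2000,
              seed: int = 0) -> CorrelationResult:
    """Correlate two columns of a table, optionally partialling controls.

    Rows with missing values in any involved column are dropped listwise.
    Returns the (partial) Pearson estimate with bootstrap SE, 95% BCa CI
    and a two-tailed p-value from the t transformation of r with
    ``n - 2 - n_controls`` degrees of freedom.
    """
    controls = tuple(controls)
    cols = [x, y, *controls]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    arr = sub.to_numpy(dtype=float)
    n, k = arr.shape[0], len(controls)
    if n <= k + 2:
        raise ValueError(
            f"need n > n_controls + 2 ({k + 2}), have n = {n}")

    if k == 0:
        def statistic(rows: np.ndarray) -> float:
            return _pearson(rows[:, 0], rows[:, 1])
        method = "pearson"
        r = pearson_r(arr[:, 0], arr[:, 1])
    else:
        def statistic(rows: np.ndarray) -> float:
            design = np.column_stack([np.ones(rows.shape[0]), rows[:, 2:]])
            rx = _residualize(rows[:, 0], design)
            ry = _residualize(rows[:, 1], design)
            return _pearson(rx, ry)
        method = "partial"
        r = partial_correlation(arr[:, 0], arr[:, 1], arr[:, 2:])

    bres = bca_bootstrap(statistic, arr, n_boot=n_boot, seed=seed)
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        r=r, se=bres.se, ci_low=bres.ci_low, ci_high=bres.ci_high,
        n=n, n_boot=n_boot, method=method, controls=controls,
        seed=seed, p=p, n_degenerate=bres.n_degenerate,
    )


def write_correlation_report(results: Iterable[tuple[str, CorrelationResult]],
                             path: Union[str, Path]) -> pd.DataFrame:
    """Write a TSV correlation report (one row per variable pair)."""
    rows = []
    for pair, res in results:
        rows.append({
            "pair": pair,
            "method": res.method,
            "controls": ",".join(res.controls),
            "r": res.r,
            "se": res.se,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n": res.n,
            "n_boot": res.n_boot,
            "p": res.p,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
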
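"""Cross-cutting environmental statistics.

Pearson correlations with Fisher-z confidence bands, variance partitioning
(adjusted-R2 commonality analysis over up to three predictors), the ammonia
dissociation equilibrium (free NH3 from total ammoniacal nitrogen, pH and
temperature) and the potential nitrification rate (OLS slope of NO2+NO3
accumulation over time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def correlate(x, y, method: str = "pearson") -> dict:
    """Correlation with two-sided p and Fisher-z 95% CI.

    Returns ``{"r", "p", "ci95"}``.  Requires n >= 4 finite values; zero
    variance in either input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(r)
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(len(x) - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return {"r": r, "p": float(p), "ci95": ci}


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VpaResult:
    """Adjusted-R2 variance partition over up to three predictors.

    ``unique_fracs`` are the "Individual" fractions (explained only by that
    predictor); ``shared_fracs`` map frozensets of predictor names to their
    common fraction; ``residual = 1 - adjR2(full)``.  Fractions may be
    slightly negative (adjusted-R2 convention) and are reported as-is.
    """

    predictors: list
    unique_fracs: dict
    shared_fracs: dict
    residual: float
    full_adj_r2: float
    marginal_adj_r2: dict
    subset_adj_r2: dict


def _adj_r2(y: np.ndarray, x: np.ndarray) -> float:
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    r2 = 1.0 - (resid**2).sum() / sst
    if n - p - 1 <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(y, X: pd.DataFrame, adjusted: bool = True) -> VpaResult:
    """Commonality partition of variance in ``y`` over 1-3 predictors.

    Fits OLS for every non-empty predictor subset; unique fractions are
    ``R2(full) - R2(full minus predictor)`` and shared fractions follow by
    inclusion-exclusion, so unique + shared + residual reconstructs 1
    exactly.  Adjusted R2 by default (``adjusted=False`` for raw R2).
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    names = list(X.columns)
    p = len(names)
    if not 1 <= p <= 3:
        raise ValueError("variance_partition supports 1-3 predictors")
    n = len(y)
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    mat = X.to_numpy(dtype=float)
    cond = np.linalg.cond(np.column_stack([np.ones(n), mat])) if p > 1 else 1.0
    if cond > 1e8:
        warnings.warn("predictors nearly collinear; fractions unstable")

    def r2_of(subset):
        cols = [names.index(s) for s in subset]
        raw = mat[:, cols]
        if adjusted:
            return _adj_r2(y, raw)
        design = np.column_stack([np.ones(n), raw])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sst = ((y - y.mean()) ** 2).sum()
        return 1.0 - (resid**2).sum() / sst if sst else 0.0

    r2 = {}
    for k in range(1, p + 1):
        for sub in combinations(names, k):
            r2[frozenset(sub)] = r2_of(sub)
    full = frozenset(names)
    r_full = r2[full]

    unique = {
        nm: r_full - (r2[full - {nm}] if p > 1 else 0.0) for nm in names
    }
    shared = {}
    if p == 2:
        a, b = names
        shared[frozenset((a, b))] = r2[frozenset((a,))] + r2[frozenset((b,))] - r_full
    elif p == 3:
        a, b, c = names
        r1, r2_, r3 = (r2[frozenset((nm,))] for nm in (a, b, c))
        r12 = r2[frozenset((a, b))]
        r13 = r2[frozenset((a, c))]
        r23 = r2[frozenset((b, c))]
        shared[frozenset((a, b))] = r13 + r23 - r3 - r_full
        shared[frozenset((a, c))] = r12 + r23 - r2_ - r_full
        shared[frozenset((b, c))] = r12 + r13 - r1 - r_full
        shared[frozenset((a, b, c))] = r_full - r12 - r13 - r23 + r1 + r2_ + r3
    return VpaResult(
        predictors=names,
        unique_fracs=unique,
        shared_fracs=shared,
        residual=1.0 - r_full,
        full_adj_r2=r_full,
        marginal_adj_r2={nm: r2[frozenset((nm,))] for nm in names},
        subset_adj_r2={tuple(sorted(k)): v for k, v in r2.items()},
    )


# ---------------------------------------------------------------------------
# free ammonia and nitrification rate
# ---------------------------------------------------------------------------

def free_ammonia(total_ammonium_n: float, ph: float, temperature_c: float) -> float:
    """Free NH3 (mol/L) from total ammoniacal N by the dissociation equilibrium.

    ``NH3 = TAN / (1 + 10**(pKa - pH))`` with the Emerson (1975)
    temperature-dependent acid constant ``pKa = 0.09018 + 2729.92 / T_K``.
    At pH = pKa exactly half the TAN is free ammonia.
    """
    if not np.isfinite([total_ammonium_n, ph, temperature_c]).all():
        raise ValueError("inputs must be finite")
    if total_ammonium_n < 0:
        raise ValueError("total ammoniacal nitrogen must be >= 0")
    if not 0 <= temperature_c <= 60:
        raise ValueError("temperature must be within [0, 60] degC")
    t_k = 273.15 + temperature_c
    pka = 0.09018 + 2729.92 / t_k
    return total_ammonium_n / (1.0 + 10.0 ** (pka - ph))


def nitrification_rate(time_days, nox) -> dict:
    """OLS slope of (NO2 + NO3) against time, with fit R^2.

    ``nox`` is the summed nitrite+nitrate concentration series; at least 3
    distinct time points are required.
    """
    t = np.asarray(time_days, dtype=float)
    y = np.asarray(nox, dtype=float)
    if t.shape != y.shape or len(t) < 3:
        raise ValueError("need >= 3 (time, concentration) points")
    if len(np.unique(t)) < 2:
        raise ValueError("time points are all identical")
    res = stats.linregress(t, y)
    return {"slope": float(res.slope), "r2": float(res.rvalue**2),
            "intercept": float(res.intercept), "stderr": float(res.stderr)}
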
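"""Population- and single-cell-level statistics for siderophore expression.

Plate-reader layer: trapezoidal growth/expression integrals, OD-normalized
expression, per-capita expression with low-OD masking, lag / maximal growth
rate extraction, dose-response scaling.

Single-cell layer: heterogeneity (sample SD of log expression), on-fraction
at a log-expression threshold, a formal bimodality call via 1- vs
2-component Gaussian-mixture BIC, Pearson cross-gene correlation, trend
regressions from a start hour, general linear models (Type-II ANOVA /
ANCOVA), and paired comparison of correlation coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.mixture import GaussianMixture

__all__ = [
    "curve_integral",
    "normalized_expression_integral",
    "per_capita_expression",
    "growth_parameters",
    "dose_response_relative",
    "heterogeneity_sd",
    "on_fraction",
    "BimodalityResult",
    "bimodality_call",
    "pairwise_correlation",
    "trend_regression",
    "linear_model",
    "paired_r_comparison",
]


# ---------------------------------------------------------------------------
# plate-reader layer
# ---------------------------------------------------------------------------

def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def curve_integral(values, times) -> float:
    """Trapezoidal area under the curve over the full time range (value·h)."""
    t = _check_times(times)
    v = np.asarray(values, dtype=float)
    if v.shape != t.shape:
        raise ValueError("values and times must have equal length")
    return float(np.trapezoid(v, t))


def normalized_expression_integral(rfu, od, times) -> float:
    """Area under the RFU curve divided by the area under the OD600 curve."""
    denom = curve_integral(od, times)
    if denom == 0:
        raise ValueError("OD integral is zero; cannot normalize expression")
    return curve_integral(rfu, times) / denom


def per_capita_expression(rfu, od, *, od_floor: float = 0.01) -> np.ndarray:
    """RFU/OD600 time series with values masked (NaN) where OD ≤ floor.

    The mask guards against the inflation caused by dividing by near-zero
    OD600 readings early in growth.
    """
    r = np.asarray(rfu, dtype=float)
    o = np.asarray(od, dtype=float)
    if r.shape != o.shape:
        raise ValueError("rfu and od must have equal length")
    out = np.full_like(r, np.nan)
    ok = o > od_floor
    out[ok] = r[ok] / o[ok]
    return out


def growth_parameters(od, times, *, window: int = 5, baseline: float | None = None) -> dict:
    """Lag time, maximal specific growth rate and integral of an OD curve.

    ``mu_max`` is the maximum slope of ln(OD) over a sliding OLS window
    (default 5 points); the lag is where the tangent at that point meets the
    inoculum baseline (ln of the first OD value unless given).  A
    non-growing curve reports ``mu_max ≈ 0`` and a missing (NaN) lag.
    """
    t = _check_times(times)
    o = np.asarray(od, dtype=float)
    if np.any(o <= 0):
        raise ValueError("OD values must be positive for log-slope estimation")
    if window < 2 or window > t.size:
        raise ValueError("window must be between 2 and the number of points")
    ln = np.log(o)
    best_mu, best_i = -np.inf, 0
    for i in range(t.size - window + 1):
        slope, intercept = np.polyfit(t[i:i + window], ln[i:i + window], 1)
        if slope > best_mu:
            best_mu, best_i, best_b = slope, i, intercept
    base = np.log(o[0]) if baseline is None else np.log(baseline)
    integral = curve_integral(o, t)
    if best_mu <= 1e-6:
        return {"lag_h": float("nan"), "mu_max_per_h": float(max(best_mu, 0.0)),
                "integral": integral}
    lag = (base - best_b) / best_mu
    return {"lag_h": float(lag), "mu_max_per_h": float(best_mu), "integral": integral}


def dose_response_relative(integrals_by_dose: dict, reference_dose) -> dict:
    """Scale every dose's integral by the reference dose's integral."""
    if reference_dose not in integrals_by_dose:
        raise ValueError(f"reference dose {reference_dose!r} not present")
    ref = integrals_by_dose[reference_dose]
    if ref == 0:
        raise ValueError("reference integral is zero")
    return {d: v / ref for d, v in integrals_by_dose.items()}


# ---------------------------------------------------------------------------
# single-cell layer
# ---------------------------------------------------------------------------

def heterogeneity_sd(log_values) -> float:
    """Sample SD (n−1 denominator) of log-transformed expression values."""
    x = np.asarray(log_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cells for an SD")
    return float(np.std(x, ddof=1))


def on_fraction(log_values, threshold_log: float = 1.0) -> float:
    """Share of cells whose log expression is at or above the threshold."""
    x = np.asarray(log_values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least 1 cell")
    return float(np.mean(x >= threshold_log))


@dataclass
class BimodalityResult:
    bimodal: bool
    delta_bic: float
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    converged: bool = True


def bimodality_call(
    log_values,
    *,
    min_cells: int = 100,
    delta_bic_threshold: float = 10.0,
    separation_factor: float = 2.0,
    min_weight: float = 0.05,
    random_state: int = 0,
) -> BimodalityResult:
    """1- vs 2-component Gaussian-mixture comparison on log expression.

    Bimodal iff BIC favours 2 components by more than ``delta_bic_threshold``
    AND the component means are separated by more than
    ``separation_factor · √(mean within-component variance)`` AND the minor
    weight exceeds ``min_weight``.  Non-convergence is reported as
    not-bimodal with ``converged=False``.
    """
    x = np.asarray(log_values, dtype=float).reshape(-1, 1)
    if x.shape[0] < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {x.shape[0]}")
    try:
        g1 = GaussianMixture(1, random_state=random_state).fit(x)
        g2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(x)
        if not (g1.converged_ and g2.converged_):
            raise ValueError("EM did not converge")
    except (ValueError, np.linalg.LinAlgError):
        return BimodalityResult(False, float("nan"), (1.0,),
                                (float(np.mean(x)),), (float(np.std(x)),),
                                converged=False)
    delta_bic = float(g1.bic(x) - g2.bic(x))  # >0 favours 2 components
    w = g2.weights_.ravel()
    mu = g2.means_.ravel()
    var = g2.covariances_.ravel()
    sep = abs(mu[1] - mu[0])
    within = float(np.sqrt(np.mean(var)))
    bimodal = (
        delta_bic > delta_bic_threshold
        and sep > separation_factor * within
        and float(w.min()) > min_weight
    )
    order = np.argsort(mu)
    return BimodalityResult(
        bool(bimodal), delta_bic,
        tuple(float(v) for v in w[order]),
        tuple(float(v) for v in mu[order]),
        tuple(float(np.sqrt(v)) for v in var[order]),
    )


def pairwise_correlation(values_a, values_b) -> dict:
    """Pearson r between two genes' log expression across cells, with p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 cells")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the channels")
    r, p = sps.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n": int(a.size)}


def trend_regression(values, times, *, start_h: float = 9.0) -> dict:
    """OLS of value on time, restricted to time points ≥ ``start_h``.

    Works both on single cells (Fig.-3-style per-cell trend) and on
    per-time-point summaries (heterogeneity / correlation trends) — the
    caller supplies whichever pairs it wants regressed.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("values and times must have equal length")
    keep = t >= start_h
    t, v = t[keep], v[keep]
    if np.unique(t).size < 3:
        raise ValueError(f"need at least 3 distinct time points >= {start_h} h")
    res = sps.linregress(t, v)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue), "n": int(t.size)}


def linear_model(
    data: pd.DataFrame,
    response: str,
    factors: list[str] | None = None,
    covariates: list[str] | None = None,
    *,
    interactions: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """General linear model with Type-II F tests per term.

    ``factors`` enter as categorical terms, ``covariates`` as continuous;
    ``interactions`` as pairs of term names.  Raises on rank-deficient
    designs, naming the aliased terms.
    """
    factors = factors or []
    covariates = covariates or []
    terms = [f"C({f})" for f in factors] + list(covariates)
    terms += [
        f"{f'C({a})' if a in factors else a}:{f'C({b})' if b in factors else b}"
        for a, b in (interactions or [])
    ]
    if not terms:
        raise ValueError("specify at least one factor or covariate")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify columns linearly dependent on the preceding ones
        aliased = []
        for j in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog[:, : j + 1]) == np.linalg.matrix_rank(exog[:, :j]):
                aliased.append(model.exog_names[j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(fit, typ=2)
    return table


def paired_r_comparison(r_values_a, r_values_b, pairing_keys=None) -> dict:
    """Paired t-test on correlation coefficients matched by stratum.

    ``pairing_keys``, if given, are per-element stratum identifiers; only
    strata present in both vectors are kept (unmatched dropped with a
    warning).  df = n_pairs − 1.  A constant nonzero difference with zero
    variance is reported as t = ±inf, p = 0.
    """
    a = np.asarray(r_values_a, dtype=float)
    b = np.asarray(r_values_b, dtype=float)
    if pairing_keys is not None:
        ka = list(pairing_keys[0]) if isinstance(pairing_keys, tuple) else list(pairing_keys)
        if isinstance(pairing_keys, tuple):
            kb = list(pairing_keys[1])
        else:
            kb = ka
        da = dict(zip(ka, a))
        db = dict(zip(kb, b))
        common = [k for k in da if k in db]
        dropped = (set(da) | set(db)) - set(common)
        if dropped:
            warnings.warn(f"dropping unmatched strata: {sorted(map(str, dropped))}",
                          stacklevel=2)
        a = np.array([da[k] for k in common])
        b = np.array([db[k] for k in common])
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length after matching")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "n_pairs": n}
        return {"t": float(np.sign(diff[0]) * np.inf), "df": n - 1, "p": 0.0,
                "n_pairs": n}
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "df": n - 1, "p": float(p), "n_pairs": n}
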
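"""Single-break detection in monthly EVI series.

Each series is modelled as a piecewise-linear trend plus an annual harmonic
seasonal term of order ``k``:

    y_t = alpha_s + beta_s t + sum_p [a_p sin(2 pi p t / 12) +
                                      b_p cos(2 pi p t / 12)] + e_t

with segment-specific intercept and slope and seasonal coefficients shared
across segments. The single most influential break is the candidate month
minimizing the two-segment residual sum of squares; a break is reported only
when an OLS-MOSUM test on the no-break residuals is significant AND the
one-break fit improves the Bayesian Information Criterion (the conjunction
is switchable). When the seasonal regression is rank-deficient the seasonal
component is removed by a periodic decomposition and a trend-only model is
fitted instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .config import BreakDetectionConfig
from .preprocess import EviSeries

log = logging.getLogger(__name__)

STATUS_BREAK = "break"
STATUS_UNCHANGED = "unchanged"
STATUS_UNDETECTABLE = "undetectable"

_RANK_TOL = 1e-8


@dataclass
class BreakModelFit:
    """Fitted segmented harmonic-trend model for one series.

    Trend coefficients are expressed in relative time (months since the
    series start ``t0``); ``break_month`` is calendar-anchored (months since
    Jan 1982). ``seas_coefs`` holds the linear sine/cosine coefficients, from
    which amplitude/phase pairs are recoverable.
    """

    site_id: str
    status: str
    t0: int = 0
    n_obs: int = 0
    k: int = 0
    used_seasonal: bool = True
    break_month: Optional[int] = None
    alpha1: float = np.nan
    beta1: float = np.nan
    alpha2: float = np.nan
    beta2: float = np.nan
    seas_coefs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mosum_stat: float = np.nan
    mosum_p: float = np.nan
    bic0: float = np.nan
    bic1: float = np.nan
    rss0: float = np.nan
    rss1: float = np.nan
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    resid_months: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def has_break(self) -> bool:
        return self.status == STATUS_BREAK

    def seasonal_value(self, t_rel) -> np.ndarray:
        """Shared seasonal component evaluated at relative months."""
        t = np.asarray(t_rel, dtype=float)
        out = np.zeros_like(t)
        for p in range(1, self.k + 1):
            w = 2 * np.pi * p * t / 12.0
            out = out + self.seas_coefs[2 * (p - 1)] * np.sin(w) \
                + self.seas_coefs[2 * (p - 1) + 1] * np.cos(w)
        return out

    def trend_value(self, t_rel, segment: int) -> float:
        """Trend component alpha_s + beta_s t at a relative month."""
        a, b = (self.alpha1, self.beta1) if segment == 1 else \
            (self.alpha2, self.beta2)
        return a + b * np.asarray(t_rel, dtype=float)

    def amplitude_phase(self):
        """Per-harmonic (amplitude, phase) pairs equivalent to seas_coefs."""
        out = []
        for p in range(1, self.k + 1):
            a = self.seas_coefs[2 * (p - 1)]
            b = self.seas_coefs[2 * (p - 1) + 1]
            out.append((float(np.hypot(a, b)), float(np.arctan2(b, a))))
        return out


# ---------------------------------------------------------------------------
# design matrices and OLS helpers
# ---------------------------------------------------------------------------

def build_harmonic_design(months, k: int, period_months: int = 12) -> np.ndarray:
    """Design with intercept, linear trend and sin/cos pairs for p = 1..k.

    ``months`` are (relative) month indices at non-missing observations;
    rows are emitted only there. Raises when there are fewer rows than
    columns (insufficient data for the harmonic fit, triggering fallback).
    """
    t = np.asarray(months, dtype=float)
    cols = [np.ones_like(t), t]
    for p in range(1, k + 1):
        w = 2 * np.pi * p * t / period_months
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    X = np.column_stack(cols)
    if X.shape[0] < X.shape[1]:
        raise ValueError(
            f"insufficient data: {X.shape[0]} rows for {X.shape[1]} columns")
    return X


def _ols(X, y):
    coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid), rank, resid


def gaussian_bic(rss: float, n: int, n_params: int) -> float:
    """BIC under a Gaussian likelihood with the variance profiled out."""
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + n_params * np.log(n)


# ---------------------------------------------------------------------------
# MOSUM test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _mosum_null_table(n: int, nh: int, nsim: int = 2000) -> tuple:
    """Monte-Carlo null distribution of the MOSUM supremum statistic.

    Simulated once per (series length, bandwidth) under i.i.d. Gaussian
    residuals with a fixed internal seed and cached.
    """
    rng = np.random.default_rng([915283, n, nh])
    stats = np.empty(nsim)
    block = 500
    for s in range(0, nsim, block):
        e = rng.standard_normal((min(block, nsim - s), n))
        cs = np.cumsum(e, axis=1)
        cs = np.concatenate([np.zeros((e.shape[0], 1)), cs], axis=1)
        mov = cs[:, nh:] - cs[:, :-nh]
        sig = e.std(axis=1, ddof=0)
        stats[s:s + e.shape[0]] = np.abs(mov).max(axis=1) / (sig * np.sqrt(n))
    return tuple(np.sort(stats))


def mosum_test(residuals, h_fraction: float, alpha: float = 0.05):
    """OLS-based MOSUM test for a structural change in the residual mean.

    The statistic is the supremum over windows of ``ceil(h_fraction * n)``
    consecutive residuals of the absolute scaled moving sum; the p-value is
    read from a cached Monte-Carlo table of the Gaussian null. Returns
    ``(statistic, p_value)``; a window below 4 points is not testable and
    raises ValueError.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    nh = int(np.ceil(h_fraction * n))
    if nh < 4:
        raise ValueError(f"MOSUM window of {nh} points is below the minimum of 4")
    nh = min(nh, n)
    sig = e.std(ddof=0)
    if sig <= 0:
        return 0.0, 1.0
    cs = np.concatenate([[0.0], np.cumsum(e)])
    mov = cs[nh:] - cs[:-nh]
    stat = float(np.abs(mov).max() / (sig * np.sqrt(n)))
    table = np.asarray(_mosum_null_table(n, nh))
    p = float((1 + np.sum(table >= stat)) / (table.size + 1))
    return stat, p


# ---------------------------------------------------------------------------
# breakpoint search
# ---------------------------------------------------------------------------

def _segment_columns(t, tb):
    """Extra design columns of a break at tb: level step and slope ramp."""
    post = (t >= tb).astype(float)
    return np.column_stack([post, post * (t - tb)])


def admissible_breaks(t_obs: np.ndarray, min_segment: int) -> np.ndarray:
    """Candidate break months: each segment keeps >= min_segment observations."""
    t_obs = np.asarray(t_obs)
    n = t_obs.size
    if n < 2 * min_segment:
        return np.array([], dtype=t_obs.dtype)
    # break at observed month t means segment 2 starts at t
    return t_obs[min_segment:n - min_segment + 1]


def select_breakpoint(t_obs, y, X0, min_segment: int):
    """Exhaustive scan for the RSS-minimizing single break.

    ``X0`` is the shared (no-break) design at the observed months. For every
    admissible candidate the two extra segment columns are projected against
    the QR basis of ``X0``, so each candidate costs O(n p). Ties in RSS break
    to the earliest month. Returns ``(t_break, rss1)`` or ``(None, None)``
    when no admissible candidate has full column rank.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    y = np.asarray(y, dtype=float)
    cands = admissible_breaks(t_obs, min_segment)
    if cands.size == 0:
        return None, None
    Q, _ = np.linalg.qr(X0)
    r0 = y - Q @ (Q.T @ y)
    rss_base = float(r0 @ r0)
    best_t, best_rss = None, np.inf
    for tb in cands:
        C = _segment_columns(t_obs, tb)
        Cq = C - Q @ (Q.T @ C)
        # 2x2 normal equations on the orthogonalized columns
        G = Cq.T @ Cq
        if np.linalg.cond(G) > 1 / _RANK_TOL:
            continue
        rhs = Cq.T @ r0
        a = np.linalg.solve(G, rhs)
        rss = rss_base - float(rhs @ a)
        if rss < best_rss - 1e-12:
            best_rss, best_t = rss, float(tb)
    if best_t is None:
        return None, None
    return best_t, max(best_rss, 0.0)


# ---------------------------------------------------------------------------
# seasonal fallback
# ---------------------------------------------------------------------------

def stl_deseasonalize(t_obs, y, period_months: int = 12,
                      n_iter: int = 2) -> np.ndarray:
    """Remove a periodic seasonal component, tolerant of missing months.

    Backfits a linear trend and per-month-of-cycle means (the periodic limit
    of a loess-smoothed seasonal): seasonal sub-series means of the
    detrended values, centred to zero. Defined at observed months only.
    Requires at least two full years of observations.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2 * period_months:
        raise ValueError("seasonal decomposition needs >= 2 full years of data")
    phase = np.mod(t_obs, period_months).astype(int)
    seasonal = np.zeros_like(y)
    for _ in range(n_iter):
        # linear trend on the seasonally adjusted series
        A = np.column_stack([np.ones_like(t_obs), t_obs])
        coef, *_ = np.linalg.lstsq(A, y - seasonal, rcond=None)
        detr = y - A @ coef
        means = np.zeros(period_months)
        for m in range(period_months):
            sel = phase == m
            if sel.any():
                means[m] = detr[sel].mean()
        means -= means[np.unique(phase)].mean()
        seasonal = means[phase]
    return y - seasonal


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------

def detect_single_break(series: EviSeries,
                        config: BreakDetectionConfig = None) -> BreakModelFit:
    """Detect the single most influential abrupt change in a monthly series.

    Fits the no-break harmonic-trend model (falling back to a deseasonalized
    trend-only model on rank deficiency), runs the MOSUM test on its
    residuals, scans for the RSS-optimal break, and reports a break iff the
    MOSUM p-value is below ``alpha`` and (when ``require_bic``) the
    one-break BIC improves on the no-break BIC.
    """
    config = (config or BreakDetectionConfig()).validate()
    n_months = series.values.size
    obs = ~np.isnan(series.values)
    n_obs = int(obs.sum())
    t_rel = np.flatnonzero(obs).astype(float)
    y = series.values[obs]

    def _dead(reason):
        log.info("site %s: %s", series.site_id, reason)
        return BreakModelFit(series.site_id, STATUS_UNDETECTABLE,
                             t0=series.start, n_obs=n_obs)

    if n_months == 0 or n_obs < 2 * config.min_segment_months:
        return _dead("insufficient data for two minimal segments")
    if 1.0 - n_obs / n_months > config.max_missing_fraction:
        return _dead("missing fraction exceeds tolerance")

    # no-break fit, with seasonal fallback
    k, used_seasonal = config.k, True
    try:
        X0 = build_harmonic_design(t_rel, k, config.period_months)
        coef0, rss0, rank, resid = _ols(X0, y)
        if rank < X0.shape[1] or not np.all(np.isfinite(coef0)):
            raise ValueError("rank-deficient seasonal fit")
        yfit = y
    except ValueError:
        try:
            yfit = stl_deseasonalize(t_rel, y, config.period_months)
        except ValueError:
            return _dead("seasonal fallback impossible")
        k, used_seasonal = 0, False
        X0 = build_harmonic_design(t_rel, 0)
        coef0, rss0, rank, resid = _ols(X0, yfit)
        if rank < X0.shape[1]:
            return _dead("trend-only fit rank-deficient")

    h_frac = config.h_fraction if config.h_fraction is not None \
        else min(0.499, config.period_months / n_months)
    try:
        stat, pval = mosum_test(resid, h_frac, config.alpha)
    except ValueError:
        return _dead("MOSUM window too short")

    p0 = 2 + 2 * k + 1            # intercept, slope, seasonal pairs, variance
    bic0 = gaussian_bic(rss0, n_obs, p0)

    tb, rss1 = select_breakpoint(t_rel, yfit, X0, config.min_segment_months)

    fit = BreakModelFit(series.site_id, STATUS_UNCHANGED, t0=series.start,
                        n_obs=n_obs, k=k, used_seasonal=used_seasonal,
                        mosum_stat=stat, mosum_p=pval, rss0=rss0, bic0=bic0,
                        residuals=resid, resid_months=t_rel)
    # no-break trend coefficients (single segment)
    fit.alpha1, fit.beta1 = float(coef0[0]), float(coef0[1])
    fit.seas_coefs = np.asarray(coef0[2:], dtype=float)

    if tb is None:
        return fit

    Xb = np.column_stack([X0, _segment_columns(t_rel, tb)])
    coefb, rss1_full, rankb, _ = _ols(Xb, yfit)
    rss1 = rss1_full
    p1 = p0 + 3                   # extra intercept, slope, break position
    bic1 = gaussian_bic(rss1, n_obs, p1)
    fit.rss1, fit.bic1 = rss1, bic1

    is_break = pval < config.alpha and (not config.require_bic or bic1 < bic0)
    if not is_break:
        return fit

    b0, b1 = float(coefb[0]), float(coefb[1])
    c_step, c_ramp = float(coefb[-2]), float(coefb[-1])
    fit.status = STATUS_BREAK
    fit.break_month = int(series.start + tb)
    fit.alpha1, fit.beta1 = b0, b1
    fit.alpha2 = b0 + c_step - c_ramp * tb
    fit.beta2 = b1 + c_ramp
    fit.seas_coefs = np.asarray(coefb[2:2 + 2 * k], dtype=float)
    return fit


def detect_all(series_index: dict, config: BreakDetectionConfig = None) -> dict:
    """Run the detector over a {site_id: EviSeries} mapping."""
    return {sid: detect_single_break(s, config)
            for sid, s in sorted(series_index.items())}


def fits_to_frame(fits: dict) -> "pd.DataFrame":
    """Serialize fits into the breaks table."""
    import pandas as pd
    from .months import index_to_ym
    rows = []
    for sid, f in sorted(fits.items()):
        rows.append({
            "site_id": sid,
            "status": f.status,
            "has_break": f.has_break,
            "break_year_month": index_to_ym(f.break_month)
            if f.break_month is not None else "",
            "series_start": index_to_ym(f.t0),
            "mosum_p": f.mosum_p, "bic0": f.bic0, "bic1": f.bic1,
            "alpha_1": f.alpha1, "beta_1": f.beta1,
            "alpha_2": f.alpha2, "beta_2": f.beta2,
            "used_seasonal": f.used_seasonal,
        })
    return pd.DataFrame(rows)


def fits_from_frame(df: "pd.DataFrame") -> dict:
    """Rebuild minimal fits (trend components only) from a breaks table."""
    from .months import ym_to_index
    fits = {}
    for _, r in df.iterrows():
        f = BreakModelFit(
            r["site_id"],
            r["status"] if "status" in r else
            (STATUS_BREAK if r["has_break"] else STATUS_UNCHANGED),
            t0=ym_to_index(r["series_start"]),
            used_seasonal=bool(r["used_seasonal"]),
            alpha1=float(r["alpha_1"]), beta1=float(r["beta_1"]),
            alpha2=float(r["alpha_2"]), beta2=float(r["beta_2"]),
            mosum_p=float(r["mosum_p"]),
            bic0=float(r["bic0"]), bic1=float(r["bic1"]))
        if f.status == STATUS_BREAK and isinstance(r["break_year_month"], str) \
                and r["break_year_month"]:
            f.break_month = ym_to_index(r["break_year_month"])
        elif f.status == STATUS_BREAK:
            f.break_month = int(r["break_year_month"])
        fits[r["site_id"]] = f
    return fits
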
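"""Attributes of detected abrupt changes: magnitude shift, trend difference,
time passed -- and their binned labels."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import binning
from .binning import UC
from .breaks import BreakModelFit
from .months import ym_to_index

log = logging.getLogger(__name__)

_DENOM_TOL = 1e-6


def magnitude_shift(fit: BreakModelFit, magnitude_from: str = "trend") -> float:
    """Relative immediate shift in predicted EVI across the break.

    (y_hat_j - y_hat_{j-1}) / |y_hat_{j-1}|, where y_hat_{j-1} is the model
    prediction one month before the break (pre-break segment) and y_hat_j the
    first prediction after it (post-break segment). By default predictions
    use the trend component only, so month-to-month phenology does not
    contaminate the step; ``magnitude_from='full'`` adds the shared seasonal
    term.
    """
    if not fit.has_break:
        raise ValueError("fit has no break")
    tb = fit.break_month - fit.t0
    y_pre = float(fit.trend_value(tb - 1, segment=1))
    y_post = float(fit.trend_value(tb, segment=2))
    if magnitude_from == "full":
        y_pre += float(fit.seasonal_value(tb - 1))
        y_post += float(fit.seasonal_value(tb))
    if abs(y_pre) < _DENOM_TOL:
        log.info("site %s: pre-break level ~ 0, magnitude undefined", fit.site_id)
        return np.nan
    return (y_post - y_pre) / abs(y_pre)


def trend_difference(fit: BreakModelFit) -> float:
    """Post-break minus pre-break linear slope (EVI/month)."""
    if not fit.has_break:
        raise ValueError("fit has no break")
    return float(fit.beta2 - fit.beta1)


def time_passed(break_month, sample_start) -> int:
    """Months between the break (t_j) and the start of sampling (t_n): t_n - t_j.

    Accepts month indices or ISO year-month strings. Negative when sampling
    preceded the break; such sites are treated as unchanged downstream.
    """
    tj = ym_to_index(break_month) if isinstance(break_month, str) else int(break_month)
    tn = ym_to_index(sample_start) if isinstance(sample_start, str) else int(sample_start)
    return tn - tj


def bin_attributes(attrs: pd.DataFrame) -> pd.DataFrame:
    """Attach bin labels to an attribute table.

    Expects columns ``magnitude``, ``trend_diff``, ``time_passed_months``
    (NaN for unchanged sites). A negative time passed (break after sampling
    started) demotes the site to UC in every bin.
    """
    attrs = attrs.copy()
    post_sampling = attrs["time_passed_months"].notna() & \
        (attrs["time_passed_months"] < 0)
    if post_sampling.any():
        log.info("%d sites with a post-sampling break treated as unchanged",
                 int(post_sampling.sum()))
    mag = attrs["magnitude"].where(~post_sampling)
    trd = attrs["trend_diff"].where(~post_sampling)
    tim = attrs["time_passed_months"].where(~post_sampling)
    attrs["magnitude_bin"] = [binning.bin_magnitude(m) for m in mag]
    attrs["trend_bin"] = [binning.bin_trend(d) for d in trd]
    attrs["time_bin"] = [binning.bin_time(t) for t in tim]
    return attrs


def attributes_table(fits: dict, sites: pd.DataFrame,
                     magnitude_from: str = "trend") -> pd.DataFrame:
    """Per-site change attributes with bins, joined to the site table.

    Sites whose fit reports no break (or an undefined magnitude) carry NaN
    attributes and UC bins.
    """
    start = sites.set_index("site_id")["sample_start"]
    rows = []
    for sid, fit in sorted(fits.items()):
        if sid not in start.index:
            continue
        row = {"site_id": sid, "magnitude": np.nan, "trend_diff": np.nan,
               "time_passed_months": np.nan}
        if fit.has_break:
            m = magnitude_shift(fit, magnitude_from)
            if np.isfinite(m):
                row["magnitude"] = m
                row["trend_diff"] = trend_difference(fit)
                row["time_passed_months"] = float(
                    time_passed(fit.break_month, start[sid]))
        rows.append(row)
    return bin_attributes(pd.DataFrame(rows))
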
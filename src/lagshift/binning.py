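"""Attribute bin vocabularies and binning rules.

Detected abrupt changes are summarized by three attributes -- relative shift
in magnitude, difference in linear trend, and time passed between the change
and the start of biodiversity sampling -- each discretized into ordered bins.
Sites without a detected change carry the label ``UC`` (unchanged) in every
bin field and act as the reference class in all downstream models.
"""

from __future__ import annotations

import numpy as np

UC = "UC"

#: Magnitude bins, ordered from most severe loss to largest gain.
MAGNITUDE_BINS = (
    "loss>50%",
    "loss 25-50%",
    "loss <=25%",
    "gain <=25%",
    "gain 25-50%",
    "gain>50%",
)

#: Trend-difference bins (EVI/month), same severity ordering.
TREND_BINS = (
    "lower>0.05",
    "lower 0.01-0.05",
    "lower <=0.01",
    "higher <=0.01",
    "higher 0.01-0.05",
    "higher>0.05",
)

#: Time-passed bins (years between change and sampling).
TIME_BINS = ("<5y", "5-10y", ">10y")

#: Loss-side magnitude bins ordered by increasing severity.
MAGNITUDE_LOSS_ORDER = ("loss <=25%", "loss 25-50%", "loss>50%")


def bin_magnitude(m: float) -> str:
    """Bin a signed relative magnitude shift.

    Upper edges are inclusive, matching the ``<=25%`` / ``25--50%`` labels;
    a shift of exactly 0 with a reported break falls in ``gain <=25%``.
    """
    if m is None or not np.isfinite(m):
        return UC
    a = abs(m)
    side = "loss" if m < 0 else "gain"
    if a <= 0.25:
        return f"{side} <=25%"
    if a <= 0.50:
        return f"{side} 25-50%"
    return f"{side}>50%"


def bin_trend(d: float) -> str:
    """Bin a trend difference (post- minus pre-break slope, EVI/month)."""
    if d is None or not np.isfinite(d):
        return UC
    a = abs(d)
    side = "lower" if d < 0 else "higher"
    if a <= 0.01:
        return f"{side} <=0.01"
    if a <= 0.05:
        return f"{side} 0.01-0.05"
    return f"{side}>0.05"


def bin_time(months: float) -> str:
    """Bin time passed in months: [0,60) -> <5y, [60,120] -> 5-10y, else >10y.

    Negative values (break after sampling started) are treated as unchanged.
    """
    if months is None or not np.isfinite(months) or months < 0:
        return UC
    if months < 60:
        return "<5y"
    if months <= 120:
        return "5-10y"
    return ">10y"
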
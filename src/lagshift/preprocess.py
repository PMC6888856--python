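"""From raw reflectance streams to clean monthly EVI series and site filters.

Per-site pipeline (order fixed): cloud/negative masking of the buffer-mean
observations, robust MAD outlier screening of the surviving values, monthly
maximum-value compositing, and truncation of series containing gaps of five
or more consecutive years of missing data. Site-table preparation handles
interpolation of missing sampling extents (MLE) and the extent/usability
filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .months import TRUNCATION_MONTH, index_to_ym, ym_to_index

log = logging.getLogger(__name__)

QC_OK = "ok"
QC_MISSING = "missing"
QC_OUTLIER = "outlier"

#: Inclusive upper bound (metres) on the sampling extent of retained sites.
MLE_MAX_M = 3000.0


# ---------------------------------------------------------------------------
# series container
# ---------------------------------------------------------------------------

@dataclass
class EviSeries:
    """A per-site monthly EVI series on a contiguous calendar grid.

    ``values`` holds the monthly composites (NaN where missing) for months
    ``start .. start + len(values) - 1`` (indices since Jan 1982); ``flags``
    records per-month provenance. ``top_percent_applied`` guards the forced
    top-1% outlier rule so it runs exactly once per series.
    """

    site_id: str
    start: int
    values: np.ndarray
    flags: np.ndarray = None
    top_percent_applied: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.where(np.isnan(self.values), QC_MISSING, QC_OK)
        self.flags = np.asarray(self.flags, dtype=object)

    @property
    def months(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.values.size)

    @property
    def n_obs(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    @property
    def n_years(self) -> float:
        return self.values.size / 12.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_id": self.site_id,
            "year_month": [index_to_ym(m) for m in self.months],
            "evi": self.values,
            "qc_flag": self.flags,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EviSeries":
        df = df.sort_values("year_month")
        months = df["year_month"].map(ym_to_index).to_numpy()
        if months.size == 0:
            raise ValueError("empty series frame")
        start, stop = int(months[0]), int(months[-1])
        values = np.full(stop - start + 1, np.nan)
        flags = np.full(stop - start + 1, QC_MISSING, dtype=object)
        values[months - start] = df["evi"].to_numpy()
        if "qc_flag" in df:
            flags[months - start] = df["qc_flag"].to_numpy()
        else:
            flags[months - start] = np.where(
                np.isnan(values[months - start]), QC_MISSING, QC_OK)
        return cls(df["site_id"].iloc[0], start, values, flags)


# ---------------------------------------------------------------------------
# observation-level operations
# ---------------------------------------------------------------------------

def compute_evi2(nir, red):
    """Two-band Enhanced Vegetation Index: 2.5 (NIR - Red) / (NIR + 2.4 Red + 1).

    Accepts scalars or arrays of surface reflectances in [0, 1] and
    vectorizes elementwise.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any((nir < 0) | (nir > 1)) or np.any((red < 0) | (red > 1)):
        raise ValueError("reflectances must lie in [0, 1]")
    out = 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)
    return float(out) if out.ndim == 0 else out


def mask_invalid(obs: pd.DataFrame) -> pd.DataFrame:
    """Drop cloud-flagged observations and strictly negative EVI values.

    EVI 0 is kept: only negative values (snow/water) are masked. Adds an
    ``evi`` column when the input carries reflectances instead.
    """
    obs = obs.copy()
    if "evi" not in obs.columns:
        obs["evi"] = compute_evi2(obs["nir"].clip(0, 1), obs["red"])
    keep = (~obs["cloud_flag"].astype(bool)) & (obs["evi"] >= 0)
    return obs.loc[keep].reset_index(drop=True)


def mad_outlier_mask(values: np.ndarray, min_n_for_top: int = 24):
    """Robust outlier flags for one series of values.

    A value is flagged when its absolute deviation from the series median
    exceeds two (unscaled) MADs, or when that deviation lies strictly above
    the 99th percentile of all deviations. The forced top-1% rule is skipped
    for series with fewer than ``min_n_for_top`` finite values (it would
    otherwise always delete data). Returns ``(mask, top_rule_used)``.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    mask = np.zeros(v.size, dtype=bool)
    if finite.sum() < 3:
        return mask, False
    med = np.nanmedian(v)
    d = np.abs(v - med)
    mad = np.nanmedian(d)
    if mad > 0:
        with np.errstate(invalid="ignore"):
            mask |= finite & (d / mad > 2.0)
    else:
        log.warning("constant series: MAD is zero, only the top-1%% rule applies")
    top_used = finite.sum() >= min_n_for_top
    if top_used:
        q99 = np.nanpercentile(d[finite], 99)
        with np.errstate(invalid="ignore"):
            mask |= finite & (d > q99)
    return mask, top_used


def mad_filter_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Apply the MAD outlier rule to a single site's observation stream."""
    if len(obs) == 0:
        return obs
    mask, _ = mad_outlier_mask(obs["evi"].to_numpy())
    return obs.loc[~mask].reset_index(drop=True)


def aggregate_monthly_max(obs: pd.DataFrame, site_id=None,
                          start=None, end=None) -> EviSeries:
    """Monthly maximum-value composites of surviving observations.

    Months without any surviving observation are missing. The calendar span
    defaults to the first..last observed month; pass ``start``/``end`` month
    indices to pin it.
    """
    if site_id is None:
        site_id = obs["site_id"].iloc[0] if len(obs) else "unknown"
    if len(obs) == 0:
        if start is None or end is None:
            raise ValueError("empty observation stream with no span given")
        return EviSeries(site_id, start, np.full(end - start + 1, np.nan))
    midx = obs["date"].str.slice(0, 7).map(ym_to_index)
    lo = int(midx.min()) if start is None else start
    hi = int(midx.max()) if end is None else end
    values = np.full(hi - lo + 1, np.nan)
    grouped = obs.groupby(midx)["evi"].max()
    for m, v in grouped.items():
        if lo <= m <= hi:
            values[m - lo] = v
    return EviSeries(site_id, lo, values)


# ---------------------------------------------------------------------------
# series-level operations
# ---------------------------------------------------------------------------

def mad_outlier_filter(series: EviSeries) -> EviSeries:
    """MAD outlier rule applied to a monthly series (flagged months -> missing).

    The forced top-1% rule is applied at most once per series, guarded by
    ``top_percent_applied``.
    """
    if series.n_obs < 12:
        raise ValueError("MAD filter requires >= 12 non-missing values")
    min_n = np.inf if series.top_percent_applied else 24
    mask, top_used = mad_outlier_mask(series.values, min_n_for_top=min_n)
    values = series.values.copy()
    flags = series.flags.copy()
    values[mask] = np.nan
    flags[mask] = QC_OUTLIER
    return EviSeries(series.site_id, series.start, values, flags,
                     top_percent_applied=series.top_percent_applied or top_used)


def truncate_gaps(series: EviSeries, gap_months: int = 60) -> EviSeries:
    """Truncate series containing >= 5-year runs of consecutive missing months.

    When such a gap exists the series is restricted to months from Jan 1999
    onward; otherwise it is returned unchanged.
    """
    missing = np.isnan(series.values)
    run = longest = 0
    for m in missing:
        run = run + 1 if m else 0
        longest = max(longest, run)
    if longest < gap_months:
        return series
    cut = max(TRUNCATION_MONTH, series.start)
    i = cut - series.start
    if i >= series.values.size:
        return EviSeries(series.site_id, cut, np.array([np.nan]),
                         np.array([QC_MISSING], dtype=object),
                         series.top_percent_applied)
    return EviSeries(series.site_id, cut, series.values[i:].copy(),
                     series.flags[i:].copy(), series.top_percent_applied)


def preprocess_site(obs: pd.DataFrame, start=None, end=None) -> EviSeries:
    """Full per-site chain: mask -> MAD filter -> monthly max -> truncate."""
    masked = mask_invalid(obs)
    filtered = mad_filter_observations(masked)
    site_id = obs["site_id"].iloc[0] if len(obs) else "unknown"
    series = aggregate_monthly_max(filtered, site_id=site_id,
                                   start=start, end=end)
    series.top_percent_applied = True  # rule consumed at observation level
    return truncate_gaps(series)


# ---------------------------------------------------------------------------
# site-table operations
# ---------------------------------------------------------------------------

def interpolate_mle(sites: pd.DataFrame) -> pd.DataFrame:
    """Fill missing sampling extents (MLE) from group means.

    Missing values take the mean MLE of sites sharing (taxon_group,
    sampling_method); when no such donor exists, the mean within the taxon
    group; sites with no donor at either level keep a missing MLE and are
    dropped later by :func:`filter_sites`.
    """
    sites = sites.copy()
    reported = sites.loc[sites["mle_m"].notna()]
    by_method = reported.groupby(["taxon_group", "sampling_method"])["mle_m"].mean()
    by_taxon = reported.groupby("taxon_group")["mle_m"].mean()
    missing = sites["mle_m"].isna()
    for i in sites.index[missing]:
        key = (sites.at[i, "taxon_group"], sites.at[i, "sampling_method"])
        if key in by_method.index:
            sites.at[i, "mle_m"] = by_method[key]
            sites.at[i, "mle_interpolated"] = True
        elif key[0] in by_taxon.index:
            sites.at[i, "mle_m"] = by_taxon[key[0]]
            sites.at[i, "mle_interpolated"] = True
        else:
            log.info("site %s: no MLE donor at method or taxon level",
                     sites.at[i, "site_id"])
    return sites


def validate_mle_interpolation(sites: pd.DataFrame,
                               holdout_fraction: float = 0.25,
                               seed: int = 0) -> float:
    """Hold out a fraction of reported MLEs, re-interpolate, return Pearson r."""
    rng = np.random.default_rng(seed)
    reported_idx = sites.index[sites["mle_m"].notna()
                               & ~sites["mle_interpolated"].astype(bool)]
    n_hold = int(round(holdout_fraction * reported_idx.size))
    if n_hold < 3:
        raise ValueError("fewer than 3 held-out MLE values")
    held = rng.choice(reported_idx, size=n_hold, replace=False)
    masked = sites.copy()
    truth = masked.loc[held, "mle_m"].to_numpy()
    masked.loc[held, "mle_m"] = np.nan
    refilled = interpolate_mle(masked)
    est = refilled.loc[held, "mle_m"].to_numpy()
    ok = np.isfinite(est)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 interpolated hold-out values")
    return float(np.corrcoef(truth[ok], est[ok])[0, 1])


def filter_sites(sites: pd.DataFrame, series_index: dict) -> pd.DataFrame:
    """Drop sites with MLE > 3000 m (boundary inclusive: 3000 kept), missing
    MLE, or no usable EVI series after truncation; logs counts per reason."""
    sites = sites.copy()
    usable = sites["site_id"].map(
        lambda s: s in series_index and series_index[s].n_obs > 0)
    no_mle = sites["mle_m"].isna()
    too_big = sites["mle_m"] > MLE_MAX_M
    keep = usable & ~no_mle & ~too_big
    log.info("filter_sites: dropped %d (no MLE), %d (MLE > %g m), "
             "%d (no usable series); kept %d of %d",
             int(no_mle.sum()), int(too_big.sum()), int((~usable).sum()),
             int(keep.sum()), len(sites))
    return sites.loc[keep].reset_index(drop=True)


def preprocess_all(evi_raw: pd.DataFrame, sites: pd.DataFrame,
                   start=None, end=None, exclude: set = ()):
    """Run the full preprocessing stage over a landscape.

    Returns ``(monthly, sites_clean, series_index)`` where ``monthly`` is the
    long-format composite table. ``exclude`` is an optional collection of
    study ids removed wholesale (e.g. known-bad studies or water-masked ones).
    """
    if exclude:
        sites = sites.loc[~sites["study_id"].isin(set(exclude))]
    series_index = {}
    for site_id, obs in evi_raw.groupby("site_id", sort=True):
        try:
            series_index[site_id] = preprocess_site(obs, start=start, end=end)
        except ValueError as e:
            log.info("site %s: unusable series (%s)", site_id, e)
    sites2 = interpolate_mle(sites)
    clean = filter_sites(sites2, series_index)
    keep = set(clean["site_id"])
    monthly = pd.concat(
        [s.to_frame() for sid, s in sorted(series_index.items()) if sid in keep],
        ignore_index=True) if keep else pd.DataFrame(
        columns=["site_id", "year_month", "evi", "qc_flag"])
    return monthly, clean, {k: v for k, v in series_index.items() if k in keep}
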
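"""Seeded synthetic landscapes: site tables, raw EVI streams and assemblages.

The generator emulates the statistical structure of a multi-study field
campaign in which local assemblages are sampled once per study while the
surrounding vegetation is monitored monthly by satellite: studies hold
several sites, a subset of sites experiences a single abrupt change in their
EVI signal (a step in level and a change in trend at a known month), and the
assemblage at a changed site responds multiplicatively -- on the log scale
used by the downstream models -- through bin-specific ground-truth effects
on richness, abundance, evenness and species turnover.

Randomness is routed through counter-based substreams of one global seed
(``default_rng([seed, stream, unit_index])``), so that generating more sites
never perturbs the draws of existing ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import UC, bin_magnitude
from .config import BinEffect, SimulationConfig
from .months import index_to_ym, ym_to_index

# substream tags
_STUDY, _SITE, _EVI, _POOL, _ASSEMBLAGE = 0, 1, 2, 3, 4

LAND_USES = ("PV", "SV", "HDV")
CLIMATE_ZONES = ("tropical", "arid", "temperate", "continental")
TAXON_GROUPS = (
    "plants", "fungi", "ground-dwelling invertebrates", "flying invertebrates",
    "amphibians", "reptiles", "birds", "mammals",
)
#: typical maximum linear extent (m) of a sampling footprint, by method;
#: the overall median lands near the 70 m scale typical of field plots
METHOD_MLE_BASE = {
    "quadrat survey": 30.0, "transect survey": 200.0, "fruitbody census": 40.0,
    "pitfall trapping": 50.0, "malaise trapping": 60.0,
    "visual encounter": 100.0, "point count": 150.0, "mist netting": 250.0,
    "camera trapping": 500.0, "live trapping": 300.0,
}

SAMPLING_METHODS = {
    "plants": ("quadrat survey", "transect survey"),
    "fungi": ("quadrat survey", "fruitbody census"),
    "ground-dwelling invertebrates": ("pitfall trapping", "quadrat survey"),
    "flying invertebrates": ("malaise trapping", "transect survey"),
    "amphibians": ("visual encounter", "pitfall trapping"),
    "reptiles": ("visual encounter", "pitfall trapping"),
    "birds": ("point count", "mist netting"),
    "mammals": ("camera trapping", "live trapping"),
}


def _rng(config: SimulationConfig, stream: int, index: int):
    return np.random.default_rng([int(config.seed) % (2**31), stream, index])


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def simulate_landscape(config: SimulationConfig):
    """Generate the site table and the aligned ground-truth table.

    Returns ``(sites, truth)`` DataFrames joined one-to-one on ``site_id``.
    Every study has at least two sites and, when it contains changed sites,
    at least one unchanged site to serve as the within-study reference.
    """
    config.validate()
    if config.sites_per_study < 2:
        raise ValueError(
            "invalid SimulationConfig.sites_per_study: each study needs >= 2 sites")
    b_lo, b_hi = (ym_to_index(x) for x in config.break_time_range)
    s_lo, s_hi = (ym_to_index(x) for x in config.sample_start_range)

    site_rows, truth_rows = [], []
    for si in range(config.n_studies):
        srng = _rng(config, _STUDY, si)
        study_id = f"ST{si:03d}"
        climate = srng.choice(CLIMATE_ZONES)
        taxon = srng.choice(TAXON_GROUPS)
        method = srng.choice(SAMPLING_METHODS[taxon])
        metric = ("occurrence"
                  if srng.random() < config.occurrence_study_fraction
                  else "abundance")
        n_blocks = int(srng.integers(2, 5))
        # study footprint: method-typical extent with log-normal scatter
        study_mle = float(METHOD_MLE_BASE[method]
                          * np.exp(srng.normal(0.0, 0.5)))
        sample_start = int(srng.integers(s_lo, s_hi + 1))

        n = config.sites_per_study
        n_changed = int(round(config.prop_changed_sites * n))
        if n_changed > 0:
            n_changed = min(n_changed, n - 1)  # keep >=1 unchanged reference
        changed = np.zeros(n, dtype=bool)
        changed[srng.choice(n, size=n_changed, replace=False)] = True

        for j in range(n):
            g = si * config.sites_per_study + j
            rng = _rng(config, _SITE, g)
            site_id = f"S{si:03d}_{j:03d}"
            mle = float(study_mle * np.exp(rng.normal(0.0, 0.3)))
            if rng.random() < config.mle_missing_rate:
                mle = np.nan
            site_rows.append({
                "site_id": site_id,
                "study_id": study_id,
                "study_index": si,
                "block_id": f"{study_id}_B{int(rng.integers(n_blocks)):02d}",
                "land_use": str(rng.choice(LAND_USES)),
                "climate_zone": str(climate),
                "taxon_group": str(taxon),
                "sampling_method": str(method),
                "metric_type": metric,
                "mle_m": mle,
                "mle_interpolated": False,
                "effort": float(rng.uniform(0.5, 1.0)),
                "sample_start": index_to_ym(sample_start),
            })
            if changed[j]:
                tb = int(rng.integers(b_lo, b_hi + 1))
                mag = float(rng.uniform(*config.magnitude_range))
                td = float(rng.uniform(*config.trend_diff_range))
                bin_label = bin_magnitude(mag)
                eff = config.effect_table.get(bin_label, BinEffect())
                truth_rows.append({
                    "site_id": site_id, "has_break": True,
                    "true_break_month": index_to_ym(tb),
                    "true_magnitude": mag, "true_trend_diff": td,
                    "true_effect_bin": bin_label,
                    "richness_multiplier": eff.richness,
                    "abundance_multiplier": eff.abundance,
                    "evenness_shift": eff.evenness_shift,
                    "turnover_fraction": eff.turnover,
                })
            else:
                truth_rows.append({
                    "site_id": site_id, "has_break": False,
                    "true_break_month": None,
                    "true_magnitude": np.nan, "true_trend_diff": np.nan,
                    "true_effect_bin": UC,
                    "richness_multiplier": 1.0, "abundance_multiplier": 1.0,
                    "evenness_shift": 0.0, "turnover_fraction": 0.0,
                })
    return pd.DataFrame(site_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# EVI observation streams
# ---------------------------------------------------------------------------

_RED = 0.08  # reference red reflectance used to invert EVI2 into (nir, red)


def evi_signal(months: np.ndarray, base: float, base_trend: float,
               amplitude: float, phase: float, phase2: float,
               break_month=None, magnitude: float = 0.0,
               trend_diff: float = 0.0, t0: int = 0) -> np.ndarray:
    """Noise-free EVI signal: broken linear trend plus two annual harmonics.

    The trend component is continuous in expectation with the stated break
    semantics: the trend value at the break month equals ``(1 + magnitude)``
    times the trend value one month earlier, and the slope changes by
    ``trend_diff`` (EVI/month).
    """
    months = np.asarray(months, dtype=float)
    trend = base + base_trend * (months - t0)
    if break_month is not None:
        tb = float(break_month)
        pre_level = base + base_trend * (tb - 1 - t0)
        post = pre_level * (1.0 + magnitude) + (base_trend + trend_diff) * (
            months - tb)
        trend = np.where(months >= tb, post, trend)
    seas = amplitude * (np.sin(2 * np.pi * months / 12.0 + phase)
                        + 0.3 * np.sin(4 * np.pi * months / 12.0 + phase2))
    return trend + seas


def _evi_to_nir(evi: np.ndarray) -> np.ndarray:
    # invert EVI2 = 2.5 (nir - red) / (nir + 2.4 red + 1) at red = _RED
    evi = np.clip(evi, -0.15, 0.98)
    return (evi * (2.4 * _RED + 1.0) + 2.5 * _RED) / (2.5 - evi)


def simulate_evi_observations(truth_row, config: SimulationConfig,
                              site_index: int) -> pd.DataFrame:
    """Raw per-site observation stream: (site_id, date, nir, red, cloud_flag).

    The underlying monthly signal is a (possibly broken) linear trend plus a
    two-harmonic annual cycle; ``obs_per_month`` noisy observations are laid
    down per month, a fraction is cloud-flagged, spike outliers are injected
    at ``outlier_rate`` and one contiguous block of months may be dropped to
    emulate archive gaps.
    """
    config.validate()
    t0 = ym_to_index(config.series_start)
    t1 = ym_to_index(config.series_end)
    has_break = bool(truth_row["has_break"])
    tb = None
    if has_break:
        tb = ym_to_index(truth_row["true_break_month"])
        if not t0 < tb <= t1:
            raise ValueError(
                f"break month {truth_row['true_break_month']} outside the "
                f"series span {config.series_start}..{config.series_end}")

    rng = _rng(config, _EVI, site_index)
    base = float(rng.uniform(*config.baseline_evi_range))
    btr = float(rng.uniform(*config.base_trend_range))
    phase = float(rng.uniform(0, 2 * np.pi))
    phase2 = float(rng.uniform(0, 2 * np.pi))

    months = np.arange(t0, t1 + 1)
    signal = evi_signal(
        months, base, btr, config.seasonal_amplitude, phase, phase2,
        break_month=tb, magnitude=truth_row.get("true_magnitude", 0.0) or 0.0,
        trend_diff=truth_row.get("true_trend_diff", 0.0) or 0.0, t0=t0)

    # contiguous missing block
    missing = np.zeros(months.size, dtype=bool)
    if rng.random() < config.missing_block_rate and months.size > 2:
        blk = min(config.missing_block_length_months, months.size - 2)
        start = int(rng.integers(0, months.size - blk))
        missing[start:start + blk] = True

    k = config.obs_per_month
    rows = {"site_id": [], "date": [], "nir": [], "red": [], "cloud_flag": []}
    for m, sig, miss in zip(months, signal, missing):
        if miss:
            continue
        ym = index_to_ym(m)
        noise = rng.normal(0.0, config.noise_sd, size=k) if config.noise_sd > 0 \
            else np.zeros(k)
        evi = sig + noise
        spikes = rng.random(k) < config.outlier_rate
        if spikes.any():
            evi = evi + spikes * rng.uniform(0.3, 0.6, size=k) * \
                rng.choice([-1.0, 1.0], size=k)
        clouds = rng.random(k) < config.cloud_fraction
        for i in range(k):
            rows["site_id"].append(truth_row["site_id"])
            rows["date"].append(f"{ym}-{5 + 10 * i:02d}")
            rows["nir"].append(float(_evi_to_nir(np.array(evi[i]))))
            rows["red"].append(_RED)
            rows["cloud_flag"].append(bool(clouds[i]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assemblages
# ---------------------------------------------------------------------------

def study_species_pool(config: SimulationConfig, study_index: int):
    """Deterministic per-study species pool: ids and mean abundances.

    Mean abundances follow a log-normal species-abundance distribution with
    shape ``lognormal_sd`` around ``mean_abundance``.
    """
    rng = _rng(config, _POOL, study_index)
    n = config.species_pool_size
    ids = np.array([f"ST{study_index:03d}_sp{i:03d}" for i in range(n)])
    lam = np.exp(rng.normal(np.log(config.mean_abundance),
                            config.lognormal_sd, size=n))
    return ids, lam


def simulate_assemblage(site_row, truth_row, config: SimulationConfig,
                        site_index: int) -> pd.DataFrame:
    """Draw one site's assemblage (site_id, species_id, abundance).

    Species occur independently with an abundance-weighted occupancy
    probability (common species are found at most sites of a study, rare
    ones at few -- which gives unchanged sites of a study a shared
    compositional core) scaled by the site's richness multiplier, so the
    expected species count is exactly multiplicative. Conditional abundances
    are shifted-Poisson draws whose means scale with sampling effort and
    with the abundance-to-richness multiplier ratio; the evenness shift
    tilts mean abundances toward dominance at fixed total;
    ``turnover_fraction`` of the occurring species identities are swapped
    for absent pool members, eroding that shared core.
    """
    if config.species_pool_size < 1:
        raise ValueError("empty species pool")
    ids, lam = study_species_pool(config, int(site_row["study_index"]))
    rng = _rng(config, _ASSEMBLAGE, site_index)

    r_mult = float(truth_row.get("richness_multiplier", 1.0))
    a_mult = float(truth_row.get("abundance_multiplier", 1.0))
    shift = float(truth_row.get("evenness_shift", 0.0))
    turnover = float(truth_row.get("turnover_fraction", 0.0))

    if shift > 0:
        tilted = lam ** (1.0 + shift)
        lam = tilted * (lam.sum() / tilted.sum())

    p_base = np.clip(config.occupancy * lam / lam.mean(), 0.0, 0.95)
    present = rng.random(lam.size) < np.clip(p_base * r_mult, 0.0, 0.95)
    idx = np.flatnonzero(present)

    # conditional mean scaled so total abundance is multiplicative in a_mult
    scale = (a_mult / r_mult) * float(site_row.get("effort", 1.0))
    counts = 1 + rng.poisson(np.maximum(lam[idx] * scale - 1.0, 0.0))

    if turnover > 0 and idx.size:
        absent = np.flatnonzero(~present)
        swap = np.flatnonzero(rng.random(idx.size) < turnover)
        n_swap = min(swap.size, absent.size)
        if n_swap:
            repl = rng.choice(absent, size=n_swap, replace=False)
            idx = idx.copy()
            idx[swap[:n_swap]] = repl

    return pd.DataFrame({
        "site_id": site_row["site_id"],
        "species_id": ids[idx],
        "abundance": counts.astype(float),
    })


# ---------------------------------------------------------------------------
# whole-landscape convenience
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> dict:
    """Generate every table of a landscape: sites, truth, evi_raw, assemblages."""
    sites, truth = simulate_landscape(config)
    tmap = truth.set_index("site_id")
    evi_frames, asm_frames = [], []
    for _, site in sites.iterrows():
        g = int(site["study_index"]) * config.sites_per_study + \
            int(site["site_id"].rsplit("_", 1)[1])
        trow = tmap.loc[site["site_id"]].to_dict()
        trow["site_id"] = site["site_id"]
        evi_frames.append(simulate_evi_observations(trow, config, g))
        asm_frames.append(simulate_assemblage(site, trow, config, g))
    return {
        "sites": sites,
        "truth": truth,
        "evi_raw": pd.concat(evi_frames, ignore_index=True),
        "assemblages": pd.concat(asm_frames, ignore_index=True),
    }


def write_outputs(tables: dict, outdir) -> dict:
    """Write the landscape tables as CSVs; returns {name: path}."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in ("sites", "truth", "evi_raw", "assemblages"):
        p = os.path.join(outdir, f"{name}.csv")
        tables[name].to_csv(p, index=False)
        paths[name] = p
    return paths
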
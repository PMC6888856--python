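"""Site-level biodiversity measures: richness, effort-adjusted abundance,
evenness (PIE) and compositional similarity (Sørensen)."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def species_richness(abundances) -> int:
    """Number of species with positive abundance (or recorded presence)."""
    a = np.asarray(list(abundances), dtype=float)
    return int(np.sum(a > 0))


def effort_adjusted_log_abundance(abundances, effort: float,
                                  max_effort: float,
                                  log_offset: float = 1.0) -> float:
    """log10 of effort-adjusted total abundance.

    Relative effort is the site's effort divided by the maximum effort in
    its study (so it lies in (0, 1]); the total count is divided by it and
    passed through log10 with a +``log_offset`` shift so empty assemblages
    map to 0.
    """
    if effort <= 0 or max_effort <= 0:
        raise ValueError("sampling effort must be positive")
    rel = effort / max_effort
    total = float(np.sum(np.asarray(list(abundances), dtype=float)))
    return float(np.log10(total / rel + log_offset))


def pie(abundances) -> float:
    """Arcsine-square-root transformed probability of interspecific encounter.

    PIE = (N / (N - 1)) (1 - sum_i (n_i / N)^2): the probability that two
    individuals drawn without replacement belong to different species.
    Returns NaN (site excluded from the evenness model) when the total
    abundance N <= 1.
    """
    n = np.asarray(list(abundances), dtype=float)
    n = n[n > 0]
    N = n.sum()
    if N <= 1:
        return np.nan
    p = n / N
    raw = (N / (N - 1.0)) * (1.0 - np.sum(p ** 2))
    return float(np.arcsin(np.sqrt(np.clip(raw, 0.0, 1.0))))


def sorensen(species_a, species_b) -> float:
    """Sørensen similarity 2a / (2a + b + c) on presence/absence.

    NaN when both sets are empty.
    """
    sa, sb = set(species_a), set(species_b)
    if not sa and not sb:
        return np.nan
    shared = len(sa & sb)
    return 2.0 * shared / (2.0 * shared + len(sa - sb) + len(sb - sa))


def site_measures(assemblages: pd.DataFrame, sites: pd.DataFrame,
                  log_offset: float = 1.0) -> pd.DataFrame:
    """Per-site measures table (richness, log abundance, asin-sqrt PIE).

    Occurrence-type studies contribute richness (and, via the pair table,
    Sørensen) but no abundance or evenness values.
    """
    max_effort = sites.groupby("study_id")["effort"].max()
    meta = sites.set_index("site_id")
    grouped = {sid: g["abundance"].to_numpy()
               for sid, g in assemblages.groupby("site_id")}
    rows = []
    for sid in meta.index:
        ab = grouped.get(sid, np.zeros(0))
        is_abund = meta.at[sid, "metric_type"] == "abundance"
        rows.append({
            "site_id": sid,
            "richness": species_richness(ab),
            "log_abund": effort_adjusted_log_abundance(
                ab, meta.at[sid, "effort"],
                max_effort[meta.at[sid, "study_id"]], log_offset)
            if is_abund else np.nan,
            "pie_asin": pie(ab) if is_abund else np.nan,
        })
    return pd.DataFrame(rows)


def pairwise_similarity(assemblages: pd.DataFrame,
                        sites: pd.DataFrame) -> pd.DataFrame:
    """Sørensen similarity for every unordered pair of sites sharing a
    (study, land-use) group; deterministic ordering site_a < site_b."""
    species = {sid: set(g.loc[g["abundance"] > 0, "species_id"])
               for sid, g in assemblages.groupby("site_id")}
    rows = []
    for (study, lu), grp in sites.groupby(["study_id", "land_use"], sort=True):
        ids = sorted(grp["site_id"])
        for a, b in itertools.combinations(ids, 2):
            rows.append({
                "study_id": study, "land_use": lu,
                "site_a": a, "site_b": b,
                "sorensen": sorensen(species.get(a, ()), species.get(b, ())),
            })
    return pd.DataFrame(rows,
                        columns=["study_id", "land_use", "site_a", "site_b",
                                 "sorensen"])
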
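"""End-to-end orchestration: simulate -> preprocess -> detect -> attributes
-> diversity -> model -> compose, with a reproducibility manifest.

Each stage reads the previous stage's flat CSV files from the run directory
and writes its own, so any stage is runnable standalone; ``run_all`` chains
them and records content digests, row counts and wall-clock per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .attributes import attributes_table
from .binning import UC
from .breaks import detect_all, fits_from_frame, fits_to_frame
from .config import BreakDetectionConfig, SimulationConfig
from .composition import cluster_bins, mean_similarity_by_bin, relative_to_uc
from .diversity import pairwise_similarity, site_measures
from .models import (DEFAULT_CANDIDATES, build_design, fit_glmm, lrt,
                     percent_difference, select_random_structure, wald_tests)
from .months import ym_to_index
from .preprocess import EviSeries, preprocess_all
from .synthetic import simulate_all, write_outputs

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "detect", "attributes", "diversity",
          "model", "compose")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending file."""

    def __init__(self, stage, message, path=None):
        self.stage, self.path = stage, path
        where = f" ({path})" if path else ""
        super().__init__(f"stage {stage!r} failed{where}: {message}")


_REQUIRED_COLS = {
    "evi_raw.csv": ("site_id", "date", "cloud_flag"),
    "sites.csv": ("site_id", "study_id", "mle_m"),
    "evi_monthly.csv": ("site_id", "year_month", "evi"),
    "sites_clean.csv": ("site_id", "study_id", "sample_start"),
    "breaks.csv": ("site_id", "status", "break_year_month"),
    "attributes.csv": ("site_id", "magnitude_bin"),
    "assemblages.csv": ("site_id", "species_id", "abundance"),
    "measures.csv": ("site_id", "richness"),
    "pairs.csv": ("site_a", "site_b", "sorensen"),
    "model_results.csv": ("response", "bin", "p"),
    "model_meta.csv": ("response", "p_lrt"),
}


def _read(stage: str, outdir: str, name: str) -> pd.DataFrame:
    path = os.path.join(outdir, name)
    if not os.path.exists(path):
        raise StageError(stage, "missing upstream file", path)
    try:
        df = pd.read_csv(path)
    except Exception as e:   # noqa: BLE001
        raise StageError(stage, f"unreadable file: {e}", path) from e
    missing = [c for c in _REQUIRED_COLS.get(name, ()) if c not in df.columns]
    if missing:
        raise StageError(stage, f"corrupt file, missing columns {missing}",
                         path)
    return df


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: SimulationConfig, outdir: str) -> list:
    tables = simulate_all(config)
    paths = write_outputs(tables, outdir)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return list(paths.values()) + [os.path.join(outdir, "config.yaml")]


def _series_span(outdir):
    cfg_path = os.path.join(outdir, "config.yaml")
    if os.path.exists(cfg_path):
        cfg = SimulationConfig.from_yaml(cfg_path)
        return ym_to_index(cfg.series_start), ym_to_index(cfg.series_end)
    return None, None


def stage_preprocess(outdir: str, exclude=()) -> list:
    evi_raw = _read("preprocess", outdir, "evi_raw.csv")
    sites = _read("preprocess", outdir, "sites.csv")
    start, end = _series_span(outdir)
    monthly, clean, _ = preprocess_all(evi_raw, sites, start=start, end=end,
                                       exclude=exclude)
    p1 = os.path.join(outdir, "evi_monthly.csv")
    p2 = os.path.join(outdir, "sites_clean.csv")
    monthly.to_csv(p1, index=False)
    clean.to_csv(p2, index=False)
    return [p1, p2]


def stage_detect(outdir: str, det_config: BreakDetectionConfig = None) -> list:
    monthly = _read("detect", outdir, "evi_monthly.csv")
    series = {sid: EviSeries.from_frame(g)
              for sid, g in monthly.groupby("site_id")}
    fits = detect_all(series, det_config)
    path = os.path.join(outdir, "breaks.csv")
    fits_to_frame(fits).to_csv(path, index=False)
    return [path]


def stage_attributes(outdir: str, magnitude_from: str = "trend") -> list:
    breaks = _read("attributes", outdir, "breaks.csv")
    sites = _read("attributes", outdir, "sites_clean.csv")
    fits = fits_from_frame(breaks)
    attrs = attributes_table(fits, sites, magnitude_from)
    path = os.path.join(outdir, "attributes.csv")
    attrs.to_csv(path, index=False)
    return [path]


def stage_diversity(outdir: str) -> list:
    asm = _read("diversity", outdir, "assemblages.csv")
    sites = _read("diversity", outdir, "sites_clean.csv")
    measures = site_measures(asm, sites)
    pairs = pairwise_similarity(asm, sites)
    p1 = os.path.join(outdir, "measures.csv")
    p2 = os.path.join(outdir, "pairs.csv")
    measures.to_csv(p1, index=False)
    pairs.to_csv(p2, index=False)
    return [p1, p2]


def stage_model(outdir: str, responses=("richness", "abundance", "pie"),
                attribute_kinds=("magnitude", "trend", "time", "presence"),
                candidates=DEFAULT_CANDIDATES) -> list:
    measures = _read("model", outdir, "measures.csv")
    attrs = _read("model", outdir, "attributes.csv")
    sites = _read("model", outdir, "sites_clean.csv")
    results, meta = [], []
    for response in responses:
        # the random structure is selected once per response on the
        # presence design and reused across attribute kinds
        base = build_design(measures, attrs, sites, "presence")
        structure = select_random_structure(base, response,
                                            candidates=candidates)
        for kind in attribute_kinds:
            data = build_design(measures, attrs, sites, kind)
            full = fit_glmm(data, response, structure=structure)
            null = fit_glmm(data, response, structure=structure,
                            null_model=True)
            chi2, df_lrt, p_lrt = lrt(full, null)
            wald = wald_tests(full)
            for _, row in wald.iterrows():
                pct, pct_se = percent_difference(full, row["bin"])
                results.append({
                    "response": response, "attribute_kind": kind,
                    "bin": row["bin"], "coef": row["coef"], "se": row["se"],
                    "z": row["z"], "p": row["p"],
                    "pct": pct, "pct_se": pct_se,
                })
            meta.append({
                "response": response, "attribute_kind": kind,
                "aic": full.aic, "loglik": full.loglik,
                "chi2": chi2, "df": df_lrt, "p_lrt": p_lrt,
                "structure": "+".join(full.structure),
                "convergence": full.fit.converged,
            })
    p1 = os.path.join(outdir, "model_results.csv")
    p2 = os.path.join(outdir, "model_meta.csv")
    pd.DataFrame(results).to_csv(p1, index=False)
    pd.DataFrame(meta).to_csv(p2, index=False)
    return [p1, p2]


def stage_compose(outdir: str, attribute: str = "magnitude",
                  study_weighted: bool = False) -> list:
    pairs = _read("compose", outdir, "pairs.csv")
    attrs = _read("compose", outdir, "attributes.csv")
    mat = mean_similarity_by_bin(pairs, attrs, attribute=attribute,
                                 study_weighted=study_weighted)
    rel = relative_to_uc(mat)
    p1 = os.path.join(outdir, "similarity_matrix.csv")
    p2 = os.path.join(outdir, "similarity_relative.csv")
    p3 = os.path.join(outdir, "dendrogram.json")
    mat.to_frame().to_csv(p1)
    rel.to_frame().to_csv(p2)
    try:
        tree = cluster_bins(rel)
    except ValueError as e:
        tree = {"error": str(e)}
    with open(p3, "w") as fh:
        json.dump(tree, fh, indent=1, sort_keys=True)
    return [p1, p2, p3]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(config: SimulationConfig, outdir: str,
            det_config: BreakDetectionConfig = None,
            candidates=DEFAULT_CANDIDATES) -> dict:
    """Run every stage; returns (and writes) the run manifest.

    Halts on the first stage error, writing a partial manifest whose last
    entry names the failing stage.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {"lagshift": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": [],
        "counts": {},
    }
    runners = {
        "simulate": lambda: stage_simulate(config, outdir),
        "preprocess": lambda: stage_preprocess(outdir),
        "detect": lambda: stage_detect(outdir, det_config),
        "attributes": lambda: stage_attributes(outdir),
        "diversity": lambda: stage_diversity(outdir),
        "model": lambda: stage_model(outdir, candidates=candidates),
        "compose": lambda: stage_compose(outdir),
    }
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            try:
                outputs = runners[stage]()
            except StageError:
                raise
            except Exception as e:   # noqa: BLE001
                raise StageError(stage, str(e)) from e
            manifest["stages"].append({
                "stage": stage,
                "outputs": {os.path.basename(p): _digest(p) for p in outputs},
                "seconds": round(time.perf_counter() - t0, 3),
            })
        manifest["counts"] = _run_counts(outdir)
    finally:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_counts(outdir: str) -> dict:
    counts = {}
    sites = pd.read_csv(os.path.join(outdir, "sites.csv"))
    clean = pd.read_csv(os.path.join(outdir, "sites_clean.csv"))
    breaks = pd.read_csv(os.path.join(outdir, "breaks.csv"))
    meta = pd.read_csv(os.path.join(outdir, "model_meta.csv"))
    counts["sites_in"] = int(len(sites))
    counts["sites_clean"] = int(len(clean))
    counts["breaks_detected"] = int(breaks["has_break"].sum())
    counts["sites_undetectable"] = int((breaks["status"] == "undetectable").sum())
    counts["models_fitted"] = int(len(meta))
    return counts


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_run(outdir: str) -> str:
    """Human-readable per-response effect tables with significance stars."""
    results = _read("summarize", outdir, "model_results.csv")
    meta = _read("summarize", outdir, "model_meta.csv")
    lines = []
    for (response, kind), grp in results.groupby(
            ["response", "attribute_kind"], sort=True):
        m = meta.loc[(meta["response"] == response)
                     & (meta["attribute_kind"] == kind)].iloc[0]
        lines.append(f"== {response} ~ {kind} "
                     f"(LRT chi2={m['chi2']:.2f}, df={int(m['df'])}, "
                     f"p={m['p_lrt']:.3g}{stars(m['p_lrt'])}; "
                     f"AIC={m['aic']:.1f}; random: {m['structure']}) ==")
        for _, r in grp.iterrows():
            lines.append(
                f"  {r['bin']:<18} {r['pct']:+7.2f}% "
                f"(SE {r['pct_se']:.2f}%) {stars(r['p'])}")
    return "\n".join(lines)
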
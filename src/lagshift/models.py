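"""Paired hierarchical models of biodiversity versus abrupt-change bins.

Changed and unchanged (UC) sites are compared within studies: the binned
change attribute enters as a fixed factor with UC as the reference level,
random-effect structures are chosen by AIC among nested candidates, species
richness uses a Poisson family with an observation-level random effect
(OLRE) to absorb overdispersion, and log abundance and arcsine-sqrt PIE use
Gaussian families. All fits are ML (never REML), so AICs and likelihood
ratio tests are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .binning import MAGNITUDE_BINS, TIME_BINS, TREND_BINS, UC
from .glmm import GLMMFit, RandomTerm, fit_mixed

log = logging.getLogger(__name__)

RESPONSES = {"richness": "richness", "abundance": "log_abund", "pie": "pie_asin"}
_BIN_ORDER = {"magnitude": list(MAGNITUDE_BINS), "trend": list(TREND_BINS),
              "time": list(TIME_BINS), "presence": ["changed"]}
_BIN_COLUMN = {"magnitude": "magnitude_bin", "trend": "trend_bin",
               "time": "time_bin"}

#: Candidate random structures, simplest first; OLRE is appended per family.
DEFAULT_CANDIDATES = (
    ("study",),
    ("study", "block"),
    ("study", "block", "land_use"),
    ("study", "block", "land_use", "presence_slope"),
    ("study", "block", "land_use", "presence_slope", "climate"),
)


@dataclass
class ModelData:
    """Design table for one attribute kind: one row per usable site."""
    df: pd.DataFrame
    attribute_kind: str
    bin_levels: list    # non-reference levels present, severity-ordered


@dataclass
class FitResult:
    """A fitted hierarchical model plus its design metadata."""
    fit: GLMMFit
    response: str
    attribute_kind: str
    bin_levels: list
    structure: tuple

    @property
    def loglik(self):
        return self.fit.loglik

    @property
    def aic(self):
        return self.fit.aic

    @property
    def n_params(self):
        return self.fit.n_params

    def coef_series(self) -> pd.Series:
        return pd.Series(self.fit.coef, index=self.fit.coef_names)

    def se_series(self) -> pd.Series:
        return pd.Series(self.fit.se, index=self.fit.coef_names)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(measures: pd.DataFrame, attributes: pd.DataFrame,
                 sites: pd.DataFrame, attribute_kind: str) -> ModelData:
    """Join measures, attributes and site metadata into a model table.

    Studies containing only unchanged sites are excluded: they contribute no
    within-study contrast. The bin factor keeps UC as the reference level.
    """
    if attribute_kind not in _BIN_ORDER:
        raise ValueError(f"unknown attribute kind {attribute_kind!r}")
    df = (sites.merge(attributes, on="site_id", how="inner")
               .merge(measures, on="site_id", how="inner"))
    if attribute_kind == "presence":
        df["bin"] = np.where(df["magnitude_bin"] == UC, UC, "changed")
    else:
        df["bin"] = df[_BIN_COLUMN[attribute_kind]]
    changed_by_study = df.groupby("study_id")["bin"].apply(
        lambda b: (b != UC).any())
    if not changed_by_study.any():
        raise ValueError("no study contains a changed site; nothing to model")
    keep = df["study_id"].map(changed_by_study)
    dropped = (~keep).sum()
    if dropped:
        log.info("dropped %d sites in studies with only unchanged sites",
                 int(dropped))
    df = df.loc[keep].reset_index(drop=True)
    levels = [b for b in _BIN_ORDER[attribute_kind]
              if (df["bin"] == b).any()]
    df["changed"] = (df["bin"] != UC).astype(float)
    return ModelData(df=df, attribute_kind=attribute_kind, bin_levels=levels)


def _indicator(values) -> sp.csr_matrix:
    codes, _ = pd.factorize(values, sort=True)
    n = len(codes)
    return sp.csr_matrix((np.ones(n), (np.arange(n), codes)))


def _random_terms(df: pd.DataFrame, structure: Sequence[str],
                  olre: bool) -> list:
    terms = []
    for name in structure:
        if name == "study":
            Z = _indicator(df["study_id"])
        elif name == "block":
            Z = _indicator(df["block_id"])
        elif name == "land_use":
            Z = _indicator(df["land_use"])
        elif name == "climate":
            Z = _indicator(df["climate_zone"])
        elif name == "presence_slope":
            Z = _indicator(df["study_id"]).multiply(
                df["changed"].to_numpy()[:, None]).tocsr()
        else:
            raise ValueError(f"unknown random term {name!r}")
        terms.append(RandomTerm(name, Z))
    if olre:
        n = len(df)
        terms.append(RandomTerm("olre", sp.identity(n, format="csr")))
    return terms


def _response_design(data: ModelData, response: str, null_model: bool):
    col = RESPONSES[response]
    df = data.df.loc[data.df[col].notna()].reset_index(drop=True)
    y = df[col].to_numpy(dtype=float)
    names = ["(Intercept)"]
    cols = [np.ones(len(df))]
    if not null_model:
        for lev in data.bin_levels:
            cols.append((df["bin"] == lev).to_numpy(dtype=float))
            names.append(lev)
    return df, np.column_stack(cols), y, names


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_glmm(data: ModelData, response: str,
             structure: Sequence[str] = ("study",),
             family: Optional[str] = None,
             null_model: bool = False) -> FitResult:
    """Fit one hierarchical model.

    ``family`` defaults to ``poisson_olre`` for richness (Poisson log-link
    with an observation-level random intercept) and ``gaussian`` otherwise.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    if family is None:
        family = "poisson_olre" if response == "richness" else "gaussian"
    olre = family == "poisson_olre"
    base_family = "poisson" if olre else family
    df, X, y, names = _response_design(data, response, null_model)
    if base_family == "poisson":
        y = np.round(y)
    terms = _random_terms(df, structure, olre)
    fit = fit_mixed(X, y, terms, family=base_family, coef_names=names)
    return FitResult(fit=fit, response=response,
                     attribute_kind=data.attribute_kind,
                     bin_levels=[] if null_model else data.bin_levels,
                     structure=tuple(structure))


def select_random_structure(data: ModelData, response: str,
                            candidates: Sequence = DEFAULT_CANDIDATES,
                            family: Optional[str] = None) -> tuple:
    """Pick the random-effect structure with the lowest AIC.

    Candidates are compared on intercept-only (null) fixed structures; ties
    go to the structure with fewer variance parameters. Falls back to the
    study-intercept-only structure when every candidate fails.
    """
    candidates = list(candidates)
    if len(candidates) == 1:
        return tuple(candidates[0])
    results = []
    for cand in candidates:
        try:
            r = fit_glmm(data, response, structure=cand, family=family,
                         null_model=True)
            if np.isfinite(r.aic):
                results.append((r.aic, len(cand), tuple(cand)))
        except Exception as e:   # noqa: BLE001 - candidate failure is data-driven
            log.info("candidate %s failed: %s", cand, e)
    if not results:
        log.warning("all candidate structures failed; using study intercept only")
        return ("study",)
    best_aic = min(a for a, _, _ in results)
    in_tie = [r for r in results if r[0] <= best_aic + 1e-6]
    in_tie.sort(key=lambda r: (r[1], r[0]))
    return in_tie[0][2]


# ---------------------------------------------------------------------------
# inference and summaries
# ---------------------------------------------------------------------------

def lrt(full: FitResult, null: FitResult):
    """Likelihood ratio test of nested ML fits: (chi2, df, p)."""
    if full.fit.n_obs != null.fit.n_obs:
        raise ValueError("models fitted on different rows")
    df_diff = full.n_params - null.n_params
    if df_diff < 0:
        raise ValueError("models are not nested (full has fewer parameters)")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    if df_diff == 0:
        return chi2, 0, 1.0
    p = float(stats.chi2.sf(chi2, df_diff)) if chi2 > 0 else 1.0
    return chi2, df_diff, p


def wald_tests(fit: FitResult) -> pd.DataFrame:
    """Per-bin Wald z statistics and two-sided normal p-values."""
    rows = []
    for name, b, s in zip(fit.fit.coef_names, fit.fit.coef, fit.fit.se):
        if name == "(Intercept)":
            continue
        if s <= 0:
            log.warning("bin %s: zero standard error, p undefined", name)
            z, p = np.nan, np.nan
        else:
            z = b / s
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"bin": name, "coef": b, "se": s, "z": z, "p": p})
    return pd.DataFrame(rows, columns=["bin", "coef", "se", "z", "p"])


def percent_difference(fit: FitResult, bin_label: str):
    """Back-transform a bin coefficient to a percent difference vs UC.

    Poisson log link: 100 (e^b - 1); Gaussian on log10 abundance:
    100 (10^b - 1); Gaussian on arcsine-sqrt PIE: percent change of the
    back-transformed fitted value at the reference level. Standard errors by
    the delta method.
    """
    coef = fit.coef_series()
    se = fit.se_series()
    b, s = float(coef[bin_label]), float(se[bin_label])
    if fit.fit.family == "poisson":
        return 100.0 * (np.exp(b) - 1.0), 100.0 * np.exp(b) * s
    if fit.response == "abundance":
        return 100.0 * (10.0 ** b - 1.0), 100.0 * 10.0 ** b * np.log(10.0) * s
    # evenness: fitted PIE at reference vs reference + effect
    m0 = float(coef["(Intercept)"])
    v0 = np.sin(np.clip(m0, 0, np.pi / 2)) ** 2
    v1 = np.sin(np.clip(m0 + b, 0, np.pi / 2)) ** 2
    if v0 <= 0:
        return np.nan, np.nan
    pct = 100.0 * (v1 - v0) / v0
    pct_se = 100.0 * abs(np.sin(2.0 * np.clip(m0 + b, 0, np.pi / 2))) * s / v0
    return float(pct), float(pct_se)


def compare_attribute_models(fit_a: FitResult, fit_b: FitResult):
    """|Delta AIC| and Pearson r between severity-matched bin effects.

    Mirrors the magnitude-vs-trend comparison: the two models share the
    response and differ only in which attribute is binned, so their effect
    vectors are matched by severity rank.
    """
    ca = fit_a.coef_series().drop("(Intercept)")
    cb = fit_b.coef_series().drop("(Intercept)")
    if len(ca) != len(cb):
        raise ValueError("models have different numbers of bins")
    delta_aic = abs(fit_a.aic - fit_b.aic)
    a, b = ca.to_numpy(), cb.to_numpy()
    if np.array_equal(a, b) and np.std(a) > 0:
        r = 1.0
    elif np.allclose(a, -b) and not np.allclose(a, 0):
        r = -1.0
    elif np.std(a) == 0 or np.std(b) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return float(delta_aic), r


# ---------------------------------------------------------------------------
# approximate two-stage fallback
# ---------------------------------------------------------------------------

def fit_two_stage(data: ModelData, response: str) -> pd.DataFrame:
    """Approximate two-stage estimator: study-wise GLM contrasts pooled by
    inverse variance.

    Within each study a plain GLM (Poisson for richness, OLS otherwise) of
    response ~ bin is fitted; bin coefficients are then pooled across
    studies weighted by 1/SE^2. Intended as a cross-check or a fallback; the
    mixed-model fit is the primary estimator.
    """
    import statsmodels.api as sm
    col = RESPONSES[response]
    fam = sm.families.Poisson() if response == "richness" else \
        sm.families.Gaussian()
    per_bin = {lev: [] for lev in data.bin_levels}
    for _, g in data.df.groupby("study_id"):
        g = g.loc[g[col].notna()]
        if (g["bin"] == UC).sum() == 0:
            continue
        for lev in data.bin_levels:
            sel = g.loc[g["bin"].isin([UC, lev])]
            if (sel["bin"] == lev).sum() == 0 or len(sel) < 3:
                continue
            X = np.column_stack([np.ones(len(sel)),
                                 (sel["bin"] == lev).to_numpy(float)])
            try:
                res = sm.GLM(sel[col].to_numpy(float), X, family=fam).fit()
            except Exception:   # noqa: BLE001 - tiny-study fits may fail
                continue
            if np.isfinite(res.bse[1]) and res.bse[1] > 0:
                per_bin[lev].append((res.params[1], res.bse[1]))
    rows = []
    for lev, ests in per_bin.items():
        if not ests:
            rows.append({"bin": lev, "coef": np.nan, "se": np.nan, "n_studies": 0})
            continue
        est = np.array([e for e, _ in ests])
        w = np.array([1.0 / s**2 for _, s in ests])
        rows.append({"bin": lev, "coef": float(np.sum(w * est) / w.sum()),
                     "se": float(np.sqrt(1.0 / w.sum())),
                     "n_studies": len(ests)})
    return pd.DataFrame(rows)


def climate_zone_from_latitude(lat: float) -> str:
    """Latitude fallback for missing climate zones."""
    a = abs(float(lat))
    if a <= 23.5:
        return "tropical"
    if a <= 35:
        return "arid"
    if a <= 55:
        return "temperate"
    return "continental"
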
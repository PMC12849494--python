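"""Septile ranks and composite saccharide migration scores.

Participants are ranked into septiles (seven size-balanced bins, scores
1 = lowest to 7 = highest) separately for glucose, fructose, and
glucose + fructose in each of plasma, glandular saliva and whole saliva.
A composite migration score is the sum of one quantity's three per-fluid
septile ranks:

    GlcMig    = septile(glucose)  summed over the three fluids
    FruMig    = septile(fructose) summed over the three fluids
    GlcFruMig = septile(glucose + fructose) summed over the three fluids

Each composite therefore lies in [3, 21]; higher values indicate greater
plasma-to-saliva saccharide migration surviving intraoral consumption.

Septile cut-points are computed within a caller-chosen ranking pool
(by default the baseline cross-section) and frozen, so samples outside
the pool — e.g. post-treatment visits — are scored against the same
cut-points and remain comparable with baseline scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

FLUIDS = ("plasma", "glandular", "whole")
QUANTITIES = ("glucose", "fructose", "glucose_fructose")

__all__ = [
    "assign_septiles",
    "septile_cutpoints",
    "score_against_cutpoints",
    "compute_migration_scores",
    "regress_score_on_clinical",
    "MigrationScores",
]


def assign_septiles(values, n_bins: int = 7) -> np.ndarray:
    """Rank values into ``n_bins`` balanced bins; scores 1..n_bins.

    Ties receive the bin of their average rank; bin sizes differ by at
    most one when all values are distinct. Missing values are excluded
    (with a warning) and receive a missing rank. Fewer than ``n_bins``
    non-missing values is an error.
    """
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    n = int(mask.sum())
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} non-missing values, got {n}")
    if n < v.size:
        warnings.warn(f"{v.size - n} missing values excluded from septile ranking")
    ranks = stats.rankdata(v[mask], method="average")
    bins = np.floor((ranks - 1.0) * n_bins / n).astype(int) + 1
    bins = np.clip(bins, 1, n_bins)
    out = np.full(v.shape, np.nan)
    out[mask] = bins
    return out


def septile_cutpoints(values, n_bins: int = 7) -> list:
    """Frozen upper bin edges for scoring new values against a pool.

    Edge ``k`` (k = 1..n_bins-1) is the largest pool value assigned to a
    bin ≤ k; a new value v is scored ``1 + #{edges < v}``, so pool values
    reproduce their own bins and ties fall into the lower bin.
    """
    v = np.asarray(values, dtype=float)
    bins = assign_septiles(v, n_bins=n_bins)
    mask = np.isfinite(v)
    v, bins = v[mask], bins[mask]
    edges = []
    for k in range(1, n_bins):
        sel = v[bins <= k]
        edges.append(float(sel.max()) if sel.size else -np.inf)
    return edges


def score_against_cutpoints(values, edges) -> np.ndarray:
    """Septile of each value relative to frozen pool cut-points."""
    v = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = np.isfinite(v)
    out[mask] = 1 + (v[mask, None] > edges[None, :]).sum(axis=1)
    return out


@dataclass
class MigrationScores:
    """Per-participant septile ranks and composite migration scores.

    ``table`` has one row per participant-timepoint with columns
    ``septile_<fluid>_<quantity>`` plus ``GlcMig``, ``FruMig`` and
    ``GlcFruMig``. ``cutpoints`` maps (fluid, quantity) → frozen edges;
    ``incomplete`` lists ids missing a fluid measurement.
    """

    table: pd.DataFrame
    cutpoints: dict = field(default_factory=dict)
    incomplete: list = field(default_factory=list)
    n_bins: int = 7

    def composite(self, name: str) -> pd.Series:
        return self.table[name]


_COMPOSITE_NAMES = {"glucose": "GlcMig", "fructose": "FruMig", "glucose_fructose": "GlcFruMig"}


def compute_migration_scores(
    tables: dict,
    ranking_pool=None,
    n_bins: int = 7,
) -> MigrationScores:
    """Compute per-fluid septiles and composite migration scores.

    Parameters
    ----------
    tables : dict fluid → DataFrame
        One DataFrame per fluid in {plasma, glandular, whole}, indexed by
        sample/participant id, with columns ``glucose`` and ``fructose``
        (levels on any common scale; only ranks matter).
    ranking_pool : sequence of ids, optional
        Ids whose values define the septile cut-points (typically the
        baseline cross-section). Defaults to the ids shared by all three
        fluid tables. Ids outside the pool are scored against the frozen
        cut-points.
    """
    missing_fluids = set(FLUIDS) - set(tables)
    if missing_fluids:
        raise ValueError(f"missing fluid tables: {sorted(missing_fluids)}")

    all_ids = sorted(set().union(*(set(t.index) for t in tables.values())))
    if ranking_pool is None:
        ranking_pool = sorted(set.intersection(*(set(t.index) for t in tables.values())))
    ranking_pool = list(ranking_pool)

    out = pd.DataFrame(index=pd.Index(all_ids, name="id"))
    cutpoints: dict = {}
    incomplete: set = set()

    for fluid in FLUIDS:
        tab = tables[fluid].copy()
        for col in ("glucose", "fructose"):
            if col not in tab.columns:
                raise ValueError(f"{fluid} table lacks column {col!r}")
        tab["glucose_fructose"] = tab["glucose"] + tab["fructose"]
        absent = set(all_ids) - set(tab.index)
        incomplete |= absent
        for quantity in QUANTITIES:
            pool_ids = [i for i in ranking_pool if i in tab.index]
            pool_vals = tab.loc[pool_ids, quantity]
            edges = septile_cutpoints(pool_vals.to_numpy(), n_bins=n_bins)
            cutpoints[(fluid, quantity)] = edges
            col = f"septile_{fluid}_{quantity}"
            out[col] = np.nan
            # pool members get exact average-rank bins; outsiders use edges
            out.loc[pool_ids, col] = assign_septiles(pool_vals.to_numpy(), n_bins=n_bins)
            outsiders = [i for i in tab.index if i not in set(pool_ids) and i in out.index]
            if outsiders:
                out.loc[outsiders, col] = score_against_cutpoints(
                    tab.loc[outsiders, quantity].to_numpy(), edges
                )

    for quantity, name in _COMPOSITE_NAMES.items():
        cols = [f"septile_{fluid}_{quantity}" for fluid in FLUIDS]
        out[name] = out[cols].sum(axis=1, skipna=False)

    return MigrationScores(
        table=out, cutpoints=cutpoints, incomplete=sorted(incomplete), n_bins=n_bins
    )


def regress_score_on_clinical(
    scores: MigrationScores,
    cohort: pd.DataFrame,
    clinical_param: str,
    score: str = "GlcFruMig",
):
    """OLS of a composite migration score on one clinical parameter.

    Fits ``score ~ clinical_param + age + gender`` on complete cases and
    returns a dict with the clinical parameter's beta, SE, 95 % CI, p and
    the number of observations used. The cohort frame must be indexed (or
    indexable) by the same ids as the score table and carry ``age`` and
    ``gender`` columns.
    """
    df = scores.table[[score]].join(cohort[[clinical_param, "age", "gender"]], how="inner")
    df = df.dropna()
    if df.empty:
        raise ValueError("no complete cases for regression")
    X = pd.DataFrame({"Intercept": 1.0, "clin": df[clinical_param].astype(float)},
                     index=df.index)
    X["age"] = df["age"].astype(float)
    for col in pd.get_dummies(df["gender"], prefix="gender", drop_first=True,
                              dtype=float).items():
        X[col[0]] = col[1]
    # constant covariates carry no information and would alias the intercept
    constant = [c for c in X.columns[2:] if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.iloc[:, 1:].corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        worst = corr.stack().idxmax() if not corr.empty else ("?", "?")
        raise ValueError(f"rank-deficient design; collinear columns near {worst}")
    fit = sm.OLS(df[score].astype(float), X).fit()
    ci = fit.conf_int().loc["clin"]
    return {
        "param": clinical_param,
        "beta": float(fit.params["clin"]),
        "se": float(fit.bse["clin"]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p_value": float(fit.pvalues["clin"]),
        "n_used": int(fit.nobs),
    }
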
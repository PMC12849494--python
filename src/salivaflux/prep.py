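"""Metagenomic feature-table preparation and covariate encoding.

Species, pathway and enzyme relative-abundance tables are prefiltered
before per-feature testing: a feature is retained when it is present —
abundance at or above its level-specific threshold (0.1 % for species,
0.001 % for pathways, 0.00001 % for enzymes) — in at least 10 % of
samples. Highly redundant functional features (cross-sample Spearman
rho > 0.9) are then collapsed to the most abundant representative of
each correlation cluster; species tables pass through unchanged unless
forced. Clinical covariates are encoded as balanced tertiles (age, PISA,
caries count) and a salivary-flow dichotomy at 0.67 mL/min.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import ABUNDANCE_THRESHOLDS, FeatureTable
from .scores import assign_septiles

__all__ = [
    "prefilter",
    "PrefilterReport",
    "dedup_correlated",
    "DedupReport",
    "encode_covariates",
    "read_metaphlan",
    "read_humann",
]


@dataclass
class PrefilterReport:
    retained: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    prevalence_min: float = 0.1
    abundance_min: float = 0.0
    min_present: int = 1

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "removed": list(self.removed),
            "prevalence_min": self.prevalence_min,
            "abundance_min": self.abundance_min,
            "min_present": self.min_present,
        }


def prefilter(
    table: FeatureTable,
    prevalence_min: float = 0.1,
    abundance_min: float | None = None,
) -> tuple[FeatureTable, PrefilterReport]:
    """Prevalence/abundance prefilter mitigating zero-inflation.

    A feature counts as *present* in a sample when its relative abundance
    is at or above the level-specific threshold (``abundance_min``;
    defaults depend on the table's level). Retention requires presence in
    at least ``max(ceil(prevalence_min * n_samples), 1)`` samples, so a
    feature below the abundance threshold everywhere is removed even at
    ``prevalence_min = 0``.
    """
    level = table.level
    if abundance_min is None:
        try:
            abundance_min = ABUNDANCE_THRESHOLDS[level]
        except KeyError:
            raise ValueError(f"unknown feature level {level!r}") from None
    n = table.values.shape[1]
    present = (table.values.to_numpy() >= abundance_min).sum(axis=1)
    min_present = max(int(np.ceil(prevalence_min * n)), 1)
    keep = present >= min_present
    retained = list(table.values.index[keep])
    report = PrefilterReport(
        retained=retained,
        removed=list(table.values.index[~keep]),
        prevalence_min=prevalence_min,
        abundance_min=float(abundance_min),
        min_present=min_present,
    )
    return table.select(retained), report


@dataclass
class DedupReport:
    removed_to_representative: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)
    rho_min: float = 0.9

    def to_dict(self) -> dict:
        return {
            "removed_to_representative": dict(self.removed_to_representative),
            "clusters": [list(c) for c in self.clusters],
            "rho_min": self.rho_min,
        }


def dedup_correlated(
    table: FeatureTable,
    rho_min: float = 0.9,
    force: bool = False,
) -> tuple[FeatureTable, DedupReport]:
    """Collapse clusters of highly correlated features.

    Clusters are connected components of the graph with an edge wherever
    the cross-sample Spearman correlation exceeds ``rho_min``; each
    cluster keeps its most abundant member (ties broken by name for
    determinism). Intended for functional features; species tables are
    returned unchanged unless ``force`` is set.
    """
    report = DedupReport(rho_min=rho_min)
    if table.level == "species" and not force:
        report.clusters = [[f] for f in table.values.index]
        return table.copy(), report
    if table.values.shape[1] < 4:
        raise ValueError("need at least 4 samples for correlation-based deduplication")
    names = list(table.values.index)
    m = len(names)
    if m < 2:
        report.clusters = [[f] for f in names]
        return table.copy(), report
    rho = stats.spearmanr(table.values.to_numpy().T).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    adj = (rho > rho_min) & ~np.eye(m, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    means = table.values.mean(axis=1)
    retained = []
    for c in range(n_comp):
        members = [names[i] for i in np.flatnonzero(labels == c)]
        rep = max(members, key=lambda f: (means[f], f))
        report.clusters.append(sorted(members))
        retained.append(rep)
        for f in members:
            if f != rep:
                report.removed_to_representative[f] = rep
    retained = [f for f in names if f in set(retained)]  # preserve input order
    return table.select(retained), report


def encode_covariates(cohort: pd.DataFrame, flow_cutoff: float = 0.67) -> pd.DataFrame:
    """Encode clinical covariates for multivariable adjustment.

    Age, PISA and caries count become balanced rank-based tertiles
    (1/2/3, ties by average rank — the same convention as septiles);
    salivary flow is dichotomized at ``flow_cutoff`` (strictly above →
    "high", at or below → "low"). Missing covariates yield missing
    encodings with a warning.
    """
    out = pd.DataFrame(index=cohort.index)
    for col, enc in (("age", "age_tertile"), ("pisa", "pisa_tertile"),
                     ("caries_count", "caries_tertile")):
        if col not in cohort.columns:
            warnings.warn(f"covariate {col!r} missing; {enc} not encoded")
            out[enc] = np.nan
            continue
        vals = cohort[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            warnings.warn(f"covariate {col!r} has missing values; encodings set missing")
        out[enc] = assign_septiles(vals, n_bins=3) if np.isfinite(vals).sum() >= 3 else np.nan
    if "salivary_flow" in cohort.columns:
        flow = cohort["salivary_flow"].to_numpy(dtype=float)
        grp = np.where(flow > flow_cutoff, "high", "low")
        out["flow_group"] = pd.Series(grp, index=cohort.index).where(np.isfinite(flow))
    else:
        warnings.warn("covariate 'salivary_flow' missing; flow_group not encoded")
        out["flow_group"] = np.nan
    for passthrough in ("group", "timepoint", "participant", "gender"):
        if passthrough in cohort.columns:
            out[passthrough] = cohort[passthrough]
    return out


# ---------------------------------------------------------------------------
# readers for the standard profiler output dialects
# ---------------------------------------------------------------------------

def read_metaphlan(path_or_buffer, level: str = "species") -> FeatureTable:
    """Read a MetaPhlAn-merged abundance table, keeping one clade depth.

    Expects a tab-separated file whose first column holds full clade
    names (``k__...|p__...|...|s__Genus_species``); comment lines
    starting with '#' are skipped. Species rows are those whose deepest
    rank is ``s__``. Percent abundances are rescaled to fractions.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#", header=0)
    clade_col = df.columns[0]
    df = df.set_index(clade_col)
    df = df.apply(pd.to_numeric, errors="coerce")
    deepest = df.index.str.split("|").str[-1]
    mask = deepest.str.startswith("s__")
    sub = df.loc[mask]
    names = sub.index.str.split("|").str[-1].str.replace("s__", "", regex=False)
    phyla = [
        next((part[3:] for part in clade.split("|") if part.startswith("p__")), None)
        for clade in sub.index
    ]
    values = sub.set_axis(names, axis=0)
    if values.to_numpy().max() > 1.5:  # MetaPhlAn reports percent
        values = values / 100.0
    meta = pd.DataFrame({"level": level, "phylum": phyla}, index=values.index)
    return FeatureTable(values, meta)


def read_humann(path_or_buffer, level: str = "pathway") -> FeatureTable:
    """Read a HUMAnN pathabundance/genefamilies-style table.

    Stratified per-taxon rows (containing '|') are dropped, as are the
    UNMAPPED/UNINTEGRATED accounting rows. Columns are renormalized to
    relative abundances per sample.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", header=0)
    feat_col = df.columns[0]
    df = df.set_index(feat_col)
    df = df.apply(pd.to_numeric, errors="coerce")
    keep = ~df.index.str.contains(r"\|") & ~df.index.str.upper().str.startswith(
        ("UNMAPPED", "UNINTEGRATED", "UNGROUPED")
    )
    values = df.loc[keep]
    sums = values.sum(axis=0)
    sums = sums.replace(0, np.nan)
    values = values.div(sums, axis=1).fillna(0.0)
    meta = pd.DataFrame({"level": level, "phylum": None}, index=values.index)
    return FeatureTable(values, meta)
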
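"""In-memory containers shared across the pipeline.

All tabular data are held as pandas DataFrames with explicit index
conventions:

* :class:`MetaboliteTable` — samples (rows) × metabolites (columns),
  with per-sample metadata (fluid, participant, injection order, role,
  collected amount) and per-metabolite metadata (internal-standard flag).
* :class:`FeatureTable` — microbial features (rows) × samples (columns),
  relative abundances in [0, 1], with a feature level (species / pathway /
  enzyme) used to select level-specific filtering thresholds.

The cohort table is a plain DataFrame with one row per
participant-timepoint (columns: participant, timepoint, group, age,
gender, hba1c, fpg, ga, caries_count, pisa, plaque_index, salivary_flow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FLUIDS = ("plasma", "glandular", "whole")
ROLES = ("biological", "qc", "blank")
FEATURE_LEVELS = ("species", "pathway", "enzyme")

#: per-level relative-abundance thresholds used by the prevalence filter
ABUNDANCE_THRESHOLDS = {
    "species": 1e-3,   # 0.1 %
    "pathway": 1e-5,   # 0.001 %
    "enzyme": 1e-7,    # 0.00001 %
}


@dataclass
class MetaboliteTable:
    """Per-fluid metabolite intensity table with injection metadata.

    Parameters
    ----------
    values : DataFrame, shape (n_samples, n_metabolites)
        Nonnegative intensities; index = sample ids, columns = metabolite
        names.
    sample_meta : DataFrame indexed like ``values``
        Columns: ``fluid``, ``participant``, ``timepoint``,
        ``injection_order`` (int), ``batch``, ``role`` (biological / qc /
        blank) and ``sample_amount`` (grams or mL; collected saliva mass
        for glandular samples, NaN for qc/blank rows).
    metabolite_meta : DataFrame indexed by metabolite name
        Must carry a boolean ``internal_standard`` column with exactly one
        True entry.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the same sample index")
        if not self.values.columns.equals(self.metabolite_meta.index):
            raise ValueError("values columns and metabolite_meta index must match")

    # -- convenience selectors -------------------------------------------------
    @property
    def internal_standard(self) -> str:
        flags = self.metabolite_meta["internal_standard"].astype(bool)
        names = list(self.metabolite_meta.index[flags])
        if len(names) != 1:
            raise ValueError(
                f"expected exactly one internal-standard metabolite, found {len(names)}"
            )
        return names[0]

    def rows(self, role: str) -> pd.DataFrame:
        """Intensity rows for one sample role (biological, qc or blank)."""
        return self.values.loc[self.sample_meta["role"] == role]

    @property
    def biological(self) -> pd.DataFrame:
        return self.rows("biological")

    @property
    def qc(self) -> pd.DataFrame:
        return self.rows("qc")

    @property
    def blanks(self) -> pd.DataFrame:
        return self.rows("blank")

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        _ = self.internal_standard
        roles = set(self.sample_meta["role"])
        if not roles <= set(ROLES):
            raise ValueError(f"unknown sample roles: {sorted(roles - set(ROLES))}")
        for batch, grp in self.sample_meta.groupby("batch"):
            if grp["injection_order"].duplicated().any():
                raise ValueError(f"duplicate injection_order within batch {batch!r}")
        bio = self.sample_meta["role"] == "biological"
        amounts = self.sample_meta.loc[bio, "sample_amount"]
        if amounts.isna().any() or (amounts <= 0).any():
            bad = list(amounts.index[amounts.isna() | (amounts <= 0)])
            raise ValueError(f"nonpositive/missing sample_amount for biological samples: {bad}")

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            self.values.copy(), self.sample_meta.copy(), self.metabolite_meta.copy()
        )


@dataclass
class FeatureTable:
    """Microbial relative-abundance table (features × samples).

    ``feature_meta`` carries ``level`` (species / pathway / enzyme) and,
    for species, optionally ``phylum``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.equals(self.feature_meta.index):
            raise ValueError("values index and feature_meta index must match")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("relative abundances must be nonnegative")
        unknown = set(self.feature_meta["level"]) - set(FEATURE_LEVELS)
        if unknown:
            raise ValueError(f"unknown feature levels: {sorted(unknown)}")

    @property
    def level(self) -> str:
        levels = self.feature_meta["level"].unique()
        if len(levels) != 1:
            raise ValueError("table mixes feature levels; select one level first")
        return levels[0]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def select(self, features) -> "FeatureTable":
        features = list(features)
        return FeatureTable(self.values.loc[features], self.feature_meta.loc[features])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.feature_meta.copy())


@dataclass
class FilterReport:
    """Outcome of the metabolite feature filters.

    ``removed_blank_features`` lists features failing the sample-to-blank
    ratio rule; ``removed_cv_features`` maps feature → QC CV (%) for
    features exceeding the CV ceiling. The two removal sets are disjoint
    (blank rule applied first) and together with ``retained`` partition
    the input feature set.
    """

    removed_blank_features: list = field(default_factory=list)
    removed_cv_features: dict = field(default_factory=dict)
    retained: list = field(default_factory=list)
    cv_values: dict = field(default_factory=dict)

    @property
    def removed(self) -> list:
        return list(self.removed_blank_features) + list(self.removed_cv_features)

    def check_partition(self, all_features) -> None:
        removed = set(self.removed)
        retained = set(self.retained)
        if removed & retained:
            raise ValueError("filter report: removed and retained sets overlap")
        if removed | retained != set(all_features):
            raise ValueError("filter report: removed + retained do not cover all features")

    def to_dict(self) -> dict:
        return {
            "removed_blank_features": list(self.removed_blank_features),
            "removed_cv_features": {k: float(v) for k, v in self.removed_cv_features.items()},
            "retained": list(self.retained),
            "cv_values": {
                k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v))
                for k, v in self.cv_values.items()
            },
        }
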
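"""Metabolomics normalization and feature filtering.

The chain applied to every biofluid table, in fixed order:

1. :func:`normalize_internal_standard` — divide each sample by its
   internal-standard (ribitol) intensity;
2. :func:`lowess_drift_correct` — remove instrument signal drift by
   dividing by a LOWESS curve fitted to the pooled-QC injections,
   independently per batch and per metabolite;
3. :func:`normalize_sample_amount` — divide by collected sample amount
   (g or mL);
4. :func:`filter_features` — discard features dominated by blank signal
   and features whose QC coefficient of variation exceeds 30 %.

The full chain is scale-equivariant: multiplying all raw intensities by a
constant leaves the output unchanged, because the internal standard is
scaled with them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .containers import FilterReport, MetaboliteTable

__all__ = [
    "normalize_internal_standard",
    "lowess_drift_correct",
    "normalize_sample_amount",
    "compute_collected_volume",
    "filter_features",
    "intersect_fluids",
    "run_qc_chain",
]


def normalize_internal_standard(table: MetaboliteTable) -> MetaboliteTable:
    """Divide every sample's intensities by its internal-standard intensity.

    After normalization the internal-standard column is exactly 1.
    Raises ValueError listing offending samples if the internal standard
    is zero or missing anywhere.
    """
    out = table.copy()
    is_name = out.internal_standard
    is_values = out.values[is_name]
    bad = list(is_values.index[~(is_values > 0) | is_values.isna()])
    if bad:
        raise ValueError(f"internal standard {is_name!r} zero/missing in samples: {bad}")
    out.values = out.values.div(is_values, axis=0)
    return out


def _fit_qc_curve(orders: np.ndarray, qc_x: np.ndarray, qc_y: np.ndarray, span: float) -> np.ndarray:
    """LOWESS fit of QC intensity on injection order, evaluated at `orders`.

    Evaluation between QC injections is by linear interpolation of the
    fitted values; beyond the QC range the end segments are extended
    linearly so trailing injections are still drift-corrected.
    """
    fit = _sm_lowess(qc_y, qc_x, frac=span, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    curve = np.interp(orders, xs, ys)
    if len(xs) >= 2:
        lo = orders < xs[0]
        hi = orders > xs[-1]
        slope_lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
        slope_hi = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        curve[lo] = ys[0] + slope_lo * (orders[lo] - xs[0])
        curve[hi] = ys[-1] + slope_hi * (orders[hi] - xs[-1])
    return curve


def lowess_drift_correct(table: MetaboliteTable, span: float = 0.5) -> MetaboliteTable:
    """Remove injection-order signal drift using the pooled-QC injections.

    Per batch and per metabolite, a locally weighted regression of QC
    intensity on injection order is fitted; every sample's intensity is
    divided by the curve at its own injection order and rescaled by the
    batch QC mean, so a flat QC series leaves the data untouched.
    Batches with fewer than 3 QC injections are skipped with a warning.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    out = table.copy()
    meta = out.sample_meta
    for batch, idx in meta.groupby("batch").groups.items():
        sub_meta = meta.loc[idx]
        qc_idx = sub_meta.index[sub_meta["role"] == "qc"]
        if len(qc_idx) < 3:
            warnings.warn(
                f"batch {batch!r}: only {len(qc_idx)} QC injections, drift correction skipped"
            )
            continue
        orders = sub_meta["injection_order"].to_numpy(float)
        qc_x = sub_meta.loc[qc_idx, "injection_order"].to_numpy(float)
        block = out.values.loc[idx]
        corrected = block.to_numpy(copy=True)
        for j, met in enumerate(block.columns):
            qc_y = out.values.loc[qc_idx, met].to_numpy(float)
            qc_mean = np.nanmean(qc_y)
            if not np.isfinite(qc_mean) or qc_mean == 0:
                continue
            curve = _fit_qc_curve(orders, qc_x, qc_y, span)
            if np.any(curve <= 0):
                warnings.warn(
                    f"batch {batch!r}, metabolite {met!r}: nonpositive fitted QC curve, "
                    "drift correction skipped for this metabolite"
                )
                continue
            corrected[:, j] = block[met].to_numpy(float) / curve * qc_mean
        out.values.loc[idx] = corrected
    return out


def normalize_sample_amount(table: MetaboliteTable) -> MetaboliteTable:
    """Divide biological samples' intensities by their collected amount.

    QC and blank rows (which have no collected amount) are left unchanged.
    """
    out = table.copy()
    bio = out.sample_meta["role"] == "biological"
    amounts = out.sample_meta.loc[bio, "sample_amount"]
    if amounts.isna().any() or (amounts <= 0).any():
        bad = list(amounts.index[amounts.isna() | (amounts <= 0)])
        raise ValueError(f"missing/nonpositive sample_amount for: {bad}")
    divisor = pd.Series(1.0, index=out.values.index)
    divisor.loc[bio] = amounts.astype(float)
    out.values = out.values.div(divisor, axis=0)
    return out


def compute_collected_volume(pre_mass: float, post_mass: float, density: float = 1.0) -> float:
    """Collected saliva volume (mL) from pre/post vial masses (g).

    Masses are recorded to five decimal places on an analytical balance;
    the conversion assumes a saliva density of 1.0 g/mL.
    """
    if post_mass < pre_mass:
        raise ValueError(f"post-collection mass {post_mass} < pre-collection mass {pre_mass}")
    return (post_mass - pre_mass) / density


def _qc_cv_percent(qc_values: np.ndarray) -> float:
    """QC coefficient of variation in %, sample (n-1) standard deviation.

    Zero and missing intensities are treated as missing. Returns NaN when
    fewer than two informative QC measurements remain.
    """
    v = np.asarray(qc_values, float)
    v = v[np.isfinite(v) & (v != 0)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(v.std(ddof=1) / mean * 100.0)


def filter_features(
    table: MetaboliteTable,
    blank_ratio_min: float = 3.0,
    cv_max_pct: float = 30.0,
) -> tuple[MetaboliteTable, FilterReport]:
    """Drop blank-dominated features and features with unstable QC signal.

    A feature is blank-dominated when its mean biological intensity is
    below ``blank_ratio_min`` times its mean blank intensity (features
    absent from blanks are always kept by this rule). Of the remaining
    features, those with QC CV above ``cv_max_pct`` (default 30 %) are
    discarded. Requires QC rows; raises ValueError without them.
    """
    if len(table.qc) == 0:
        raise ValueError("filter_features requires QC rows to compute CV")
    report = FilterReport()
    bio = table.biological
    blanks = table.blanks

    features = list(table.values.columns)
    survivors = []
    for met in features:
        if len(blanks) > 0:
            blank_mean = np.nanmean(blanks[met].to_numpy(float))
            if np.isfinite(blank_mean) and blank_mean > 0:
                bio_mean = np.nanmean(bio[met].to_numpy(float))
                if bio_mean < blank_ratio_min * blank_mean:
                    report.removed_blank_features.append(met)
                    continue
        survivors.append(met)

    qc = table.qc
    for met in survivors:
        cv = _qc_cv_percent(qc[met].to_numpy(float))
        report.cv_values[met] = cv
        if np.isfinite(cv) and cv > cv_max_pct:
            report.removed_cv_features[met] = cv
        else:
            report.retained.append(met)

    report.check_partition(features)
    filtered = MetaboliteTable(
        table.values[report.retained].copy(),
        table.sample_meta.copy(),
        table.metabolite_meta.loc[report.retained].copy(),
    )
    return filtered, report


def intersect_fluids(tables) -> set:
    """Metabolite names retained in every fluid table (≥2 tables)."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    sets = [set(t.values.columns) for t in tables]
    return set.intersection(*sets)


def run_qc_chain(
    table: MetaboliteTable,
    span: float = 0.5,
    blank_ratio_min: float = 3.0,
    cv_max_pct: float = 30.0,
    drift_correct: bool = True,
) -> tuple[MetaboliteTable, FilterReport]:
    """Full normalization chain: IS → LOWESS → amount → filters."""
    t = normalize_internal_standard(table)
    if drift_correct:
        t = lowess_drift_correct(t, span=span)
    t = normalize_sample_amount(t)
    return filter_features(t, blank_ratio_min=blank_ratio_min, cv_max_pct=cv_max_pct)
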
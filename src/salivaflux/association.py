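"""Multivariable per-feature association models.

Implements the discovery-phase modelling strategy popularized by
MaAsLin2, specified directly so results are self-contained and
oracle-testable rather than delegated to the R tool:

* abundances are total-sum scaled and log2-transformed with a
  half-minimum-positive pseudocount per feature;
* each exposure is tested one feature at a time in a linear model
  adjusted for age tertile, periodontitis (PISA) tertile, caries-count
  tertile and salivary-flow group;
* p-values are Benjamini–Hochberg adjusted within each exposure's
  feature family with a discovery threshold of q < 0.25
  (** marks q < 0.05, * marks 0.05 <= q < 0.25);
* pre/post treatment contrasts use a random-intercept model with
  participant as the grouping factor. In the balanced two-timepoint
  design without covariates the fixed-effect estimate equals the mean
  within-participant difference, which serves as the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import FeatureTable
from .fluidstats import bh_qvalues

FDR_TARGET = 0.25

__all__ = [
    "transform_abundance",
    "fit_feature_model",
    "fit_paired_model",
    "significance_star",
    "AssociationResult",
    "PairedContrast",
    "FDR_TARGET",
]


def transform_abundance(values: pd.DataFrame) -> pd.DataFrame:
    """TSS + log2 transform with half-minimum-positive pseudocount.

    ``values`` is features × samples. Columns are rescaled to sum to one
    over the supplied features, then each feature is log2-transformed
    after adding half its smallest positive value, so zeros map to
    log2(half-min-positive) rather than -inf. An all-zero feature is an
    error (it should have been removed by the prevalence filter).
    """
    X = values.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    colsums = X.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("sample with zero total abundance")
    X = X / colsums[None, :]
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        row = X[i]
        positive = row[row > 0]
        if positive.size == 0:
            raise ValueError(f"feature {values.index[i]!r} is all-zero")
        pc = positive.min() / 2.0
        out[i] = np.log2(row + pc)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


@dataclass
class AssociationResult:
    feature: str
    exposure: str
    beta: float
    se: float
    p_value: float
    q_value: float
    n_used: int
    model: str
    star: str = ""


def _build_design(
    exposure: pd.Series,
    covariates: pd.DataFrame | None,
    adjust: tuple,
) -> tuple[pd.DataFrame, str]:
    parts = {"exposure": pd.to_numeric(exposure, errors="coerce")
             if exposure.dtype.kind in "bifu"
             else pd.Series(pd.factorize(exposure)[0], index=exposure.index, dtype=float)}
    terms = ["exposure"]
    if covariates is not None:
        for cov in adjust:
            if cov not in covariates.columns:
                continue
            col = covariates[cov]
            if col.dtype.kind in "bifu" and cov.endswith("_tertile"):
                col = col.astype("Int64").astype("category")
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                parts[c] = dummies[c]
            terms.append(cov)
    X = pd.DataFrame(parts)
    X.insert(0, "Intercept", 1.0)
    return X, "abundance ~ " + " + ".join(terms)


def fit_feature_model(
    table: FeatureTable,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjust: tuple = ("age_tertile", "pisa_tertile", "caries_tertile", "flow_group"),
    transformed: pd.DataFrame | None = None,
    exposure_name: str | None = None,
    fdr_target: float = FDR_TARGET,
) -> pd.DataFrame:
    """Per-feature linear model of transformed abundance on one exposure.

    Returns a DataFrame (index = feature) with beta, se, p_value,
    q_value (BH over this exposure's feature family), n_used, model
    string, significance star and a ``significant`` flag (q < target).
    Features whose design is singular on their complete cases are
    skipped with a warning.
    """
    exposure_name = exposure_name or getattr(exposure, "name", None) or "exposure"
    Y = transformed if transformed is not None else transform_abundance(table.values)
    samples = [s for s in Y.columns if s in exposure.index]
    if covariates is not None:
        samples = [s for s in samples if s in covariates.index]
    Y = Y[samples]
    X, model_str = _build_design(
        exposure.loc[samples],
        covariates.loc[samples] if covariates is not None else None,
        adjust,
    )
    complete = X.notna().all(axis=1)
    X = X.loc[complete]
    Y = Y.loc[:, complete.index[complete]]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"only {n} complete cases for {p} parameters")

    Xm = X.to_numpy(dtype=float)
    XtX = Xm.T @ Xm
    rank = np.linalg.matrix_rank(Xm)
    results: list[AssociationResult] = []
    if rank < p:
        warnings.warn(f"singular design for exposure {exposure_name!r}; all features skipped")
        return _assemble(results, fdr_target)

    XtX_inv = np.linalg.inv(XtX)
    j = list(X.columns).index("exposure")
    coefs = XtX_inv @ Xm.T @ Y.to_numpy(dtype=float).T  # p × n_features
    fitted = Xm @ coefs
    resid = Y.to_numpy(dtype=float).T - fitted
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    beta = coefs[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    for i, feat in enumerate(Y.index):
        results.append(
            AssociationResult(
                feature=str(feat), exposure=exposure_name, beta=float(beta[i]),
                se=float(se[i]), p_value=float(pvals[i]), q_value=np.nan,
                n_used=n, model=model_str,
            )
        )
    return _assemble(results, fdr_target)


def _assemble(results: list[AssociationResult], fdr_target: float) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(
            columns=["exposure", "beta", "se", "p_value", "q_value", "n_used",
                     "model", "star", "significant"]
        )
    df = pd.DataFrame([r.__dict__ for r in results]).set_index("feature")
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    df["star"] = [significance_star(q) for q in df["q_value"]]
    df["significant"] = df["q_value"] < fdr_target
    return df


@dataclass
class PairedContrast:
    feature: str
    delta: float
    se: float
    p_value: float
    q_value: float
    n_pairs: int


def fit_paired_model(
    table: FeatureTable,
    timepoint: pd.Series,
    participant: pd.Series,
    transformed: pd.DataFrame | None = None,
    baseline: str = "baseline",
    fdr_target: float = FDR_TARGET,
) -> pd.DataFrame:
    """Pre/post contrast per feature with a participant random intercept.

    Only participants with both timepoints contribute. Features with
    fewer than 3 complete pairs are skipped. When the within-pair
    differences are (numerically) constant the REML problem degenerates
    and the exact paired-difference solution is returned directly.
    """
    Y = transformed if transformed is not None else transform_abundance(table.values)
    samples = [s for s in Y.columns if s in timepoint.index and s in participant.index]
    tp = timepoint.loc[samples]
    pid = participant.loc[samples]
    if (pid.groupby([pid, tp]).size() > 1).any():
        raise ValueError("at most one sample per participant per timepoint")
    levels = sorted(tp.unique(), key=lambda x: (x != baseline, x))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 timepoints, got {levels}")
    post_level = levels[1]

    complete = [
        p for p, grp in tp.groupby(pid)
        if set(grp.unique()) == {baseline, post_level}
    ]
    keep = pid.isin(complete)
    samples = list(pd.Index(samples)[keep.to_numpy()])
    tp, pid = tp.loc[samples], pid.loc[samples]
    n_pairs = len(complete)

    rows = []
    post_ind = (tp == post_level).to_numpy(dtype=float)
    exog = sm.add_constant(post_ind)
    groups = pid.to_numpy()
    for feat, series in Y[samples].iterrows():
        y = series.to_numpy(dtype=float)
        if n_pairs < 3:
            warnings.warn(f"feature {feat!r}: fewer than 3 complete pairs, skipped")
            continue
        pre = {p: v for p, t, v in zip(groups, post_ind, y) if t == 0}
        post = {p: v for p, t, v in zip(groups, post_ind, y) if t == 1}
        diffs = np.array([post[p] - pre[p] for p in complete])
        if diffs.std(ddof=1) < 1e-12:
            d = float(diffs.mean())
            rows.append(PairedContrast(str(feat), d, 0.0, 0.0 if d != 0 else 1.0,
                                       np.nan, n_pairs))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
        rows.append(
            PairedContrast(
                str(feat), float(fit.fe_params[1]), float(fit.bse_fe[1]),
                float(fit.pvalues[1]), np.nan, n_pairs,
            )
        )
    if not rows:
        return pd.DataFrame(columns=["delta", "se", "p_value", "q_value", "n_pairs", "star"])
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    df["star"] = [significance_star(q) for q in df["q_value"]]
    df["significant"] = df["q_value"] < fdr_target
    return df


def significance_star(q: float) -> str:
    """Discovery label: '**' for q < 0.05, '*' for 0.05 <= q < 0.25."""
    if not np.isfinite(q):
        return ""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q-value out of [0, 1]: {q}")
    if q < 0.05:
        return "**"
    if q < 0.25:
        return "*"
    return ""
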
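"""Variance partitioning and correlation analyses across biofluids.

PERMANOVA follows the adonis formulation: with the Gower-centred matrix
G = -(1/2) C D^2 C (C the centring matrix) and hat matrix H of the design,
SS_model = tr(HGH), SS_total = tr(G), R^2 = SS_model / SS_total and

    pseudo-F = (SS_model / df_model) / (SS_residual / df_residual).

For a categorical grouping this reduces exactly to the classical sums

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2,

so a single implementation serves both the per-group omnibus tests and
the continuous-biomarker variance decompositions. The permutation p-value
uses the (1 + b) / (1 + m) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "PermanovaResult",
    "pareto_pca",
    "ParetoPCAResult",
    "spearman_bh",
    "alpha_diversity",
    "bh_qvalues",
]


def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity Σ|u−v| / Σ(u+v) of two nonnegative profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must have the same length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("both profiles are all-zero")
    return float(_braycurtis(u, v))


def bray_curtis_matrix(table: pd.DataFrame, shift_negative: bool = True) -> pd.DataFrame:
    """Square Bray–Curtis matrix over samples (rows of ``table``).

    Normalized metabolite intensities can dip below zero; since the
    metric requires nonnegative inputs, any feature with negative values
    is min-shifted to zero first (with a warning) when
    ``shift_negative`` is set.
    """
    X = table.to_numpy(dtype=float)
    mins = X.min(axis=0)
    if (mins < 0).any():
        if not shift_negative:
            raise ValueError("negative values present and shift_negative=False")
        warnings.warn(
            f"{int((mins < 0).sum())} features min-shifted to nonnegative scale "
            "before Bray-Curtis"
        )
        X = X - np.minimum(mins, 0.0)[None, :]
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    grouping: str
    df_model: int
    df_residual: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"R^2 out of [0,1]: {self.r_squared}")


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


def _design_matrix(grouping) -> tuple[np.ndarray, str]:
    g = np.asarray(grouping)
    if g.dtype.kind in "fiu" and len(np.unique(g)) > 2:
        X = np.column_stack([np.ones(g.size), g.astype(float)])
        kind = "continuous"
    else:
        levels, codes = np.unique(g, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("grouping must have at least 2 levels")
        counts = np.bincount(codes)
        if (counts < 2).any():
            raise ValueError("each group needs at least 2 members")
        dummies = np.eye(len(levels))[codes][:, 1:]
        X = np.column_stack([np.ones(g.size), dummies])
        kind = "categorical"
    return X, kind


def permanova(
    dist,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    grouping_name: str = "grouping",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` may be categorical labels (dummy-coded factor) or a
    numeric covariate (single-slope adonis-style model). The p-value is
    ``(1 + #{permuted F >= observed F}) / (1 + n_perm)`` under row/column
    permutation of the distance matrix.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    X, _kind = _design_matrix(grouping)
    if len(np.asarray(grouping)) != n:
        raise ValueError("grouping length must match distance matrix size")

    G = _gower_center(D)
    H = X @ np.linalg.pinv(X)
    rank = int(np.round(np.trace(H)))
    df_model = rank - 1
    df_residual = n - rank
    if df_model < 1 or df_residual < 1:
        raise ValueError("insufficient degrees of freedom for PERMANOVA")

    ss_total = float(np.trace(G))
    def _f_and_r2(Gp: np.ndarray) -> tuple[float, float]:
        ss_model = float(np.trace(H @ Gp))
        ss_resid = ss_total - ss_model
        f = (ss_model / df_model) / (ss_resid / df_residual) if ss_resid > 0 else np.inf
        return f, ss_model / ss_total

    f_obs, r2 = _f_and_r2(G)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm, _ = _f_and_r2(G[np.ix_(perm, perm)])
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        grouping=grouping_name,
        df_model=df_model,
        df_residual=df_residual,
    )


@dataclass
class ParetoPCAResult:
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    dropped_features: list


def pareto_pca(table: pd.DataFrame) -> ParetoPCAResult:
    """Principal component analysis with Pareto scaling.

    Each feature is mean-centred and divided by the square root of its
    standard deviation (a compromise between no scaling and unit-variance
    scaling that damps, without erasing, intensity differences).
    Zero-variance features are excluded with a warning.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(table.columns[~keep])
    if dropped:
        warnings.warn(f"{len(dropped)} zero-variance features excluded from PCA")
    X = X[:, keep]
    sd = sd[keep]
    Xs = (X - X.mean(axis=0)) / np.sqrt(sd)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U * s
    evr = s**2 / (s**2).sum()
    pcs = [f"PC{i+1}" for i in range(len(s))]
    return ParetoPCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=pcs),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(Vt.T, index=table.columns[keep], columns=pcs),
        dropped_features=dropped,
    )


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values stay NaN."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def spearman_bh(x_table: pd.DataFrame, y) -> pd.DataFrame:
    """Per-feature Spearman correlation with a covariate, BH-adjusted.

    ``x_table`` is features × samples. Features constant across samples
    have no defined rank correlation and are reported as missing; q-values
    are computed over the informative features only.
    """
    y = np.asarray(y, dtype=float)
    if x_table.shape[1] != y.size:
        raise ValueError("covariate length must match number of samples")
    rows = []
    for feat, series in x_table.iterrows():
        x = series.to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 4:
            raise ValueError(f"feature {feat!r}: fewer than 4 paired observations")
        if np.unique(x[mask]).size < 2 or np.unique(y[mask]).size < 2:
            rows.append((feat, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x[mask], y[mask])
        rows.append((feat, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["feature", "rho", "p_value"]).set_index("feature")
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out


def alpha_diversity(abundances, metric: str = "shannon") -> float:
    """Shannon entropy (natural log) or inverse Simpson index."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = x / total
    p = p[p > 0]
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "inverse_simpson":
        return float(1.0 / (p**2).sum())
    raise ValueError(f"unknown metric {metric!r}")
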
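"""Cohort feature table and dependency screening.

Per-sample features (five mechanical descriptors, donor age, and density /
thickness / 3DOI / main angle per channel) are screened pairwise with the
distance correlation (DC), a dependence measure in [0, 1] that is zero iff
the variables are independent and captures nonlinear association that
Pearson's r misses.  Significance comes from a permutation test of the
sample labels; 3DOI across stress regions is compared by one-way ANOVA with
Tukey HSD post hoc.

Distance correlation here is the V-statistic (biased) sample version:
double-centered Euclidean distance matrices A and B, dCov² = mean(A∘B),
dCor = dCov/√(dVar_x·dVar_y).  An unbiased (U-statistic) variant is
available behind a flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

FEATURE_COLUMNS = [
    "E1", "E2", "sigma_max", "eps_max", "eps_mid", "age",
    "D_CO", "T_CO", "OI3D_CO", "main_theta_CO",
    "D_EL", "T_EL", "OI3D_EL", "main_theta_EL",
]
DEFAULT_RESAMPLES = 2000
DEFAULT_ALPHA = 0.05


@dataclass
class DependencyResult:
    feature_x: str
    feature_y: str
    dc: float
    p_value: float
    n_resamples: int
    n_used: int
    significant: bool
    flags: tuple = ()


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema constraints (unique columns, folded angles, positive ages)."""
    if table.columns.duplicated().any():
        raise ValueError("feature table has duplicate column names")
    for col in table.columns:
        if col.startswith("main_theta"):
            vals = table[col].dropna()
            if ((vals < 0) | (vals > 90)).any():
                raise ValueError(f"{col}: main angles must be folded to [0, 90]")
    if "age" in table and (table["age"].dropna() <= 0).any():
        raise ValueError("ages must be positive")
    return table


def complete_cases(table: pd.DataFrame, features=None) -> pd.DataFrame:
    """Drop rows with any missing value among the requested features."""
    features = list(features) if features is not None else list(table.columns)
    missing_cols = [f for f in features if f not in table.columns]
    if missing_cols:
        raise KeyError(f"features not in table: {missing_cols}")
    out = table.dropna(subset=features)
    if out.empty:
        raise ValueError("complete-case filtering left an empty table")
    return out


def _centered_distances(x: np.ndarray, unbiased: bool = False) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    n = d.shape[0]
    if unbiased:
        a = d - d.sum(0) / (n - 2) - d.sum(1)[:, None] / (n - 2) + d.sum() / ((n - 1) * (n - 2))
        np.fill_diagonal(a, 0.0)
    else:
        a = d - d.mean(0) - d.mean(1)[:, None] + d.mean()
    return a


def distance_correlation(x, y, unbiased: bool = False) -> float:
    """Sample distance correlation between two vectors (V-statistic default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if x.shape[0] < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    a = _centered_distances(x, unbiased)
    b = _centered_distances(y, unbiased)
    dcov2 = float((a * b).mean())
    dvx = float((a * a).mean())
    dvy = float((b * b).mean())
    if dvx <= 0 or dvy <= 0:
        warnings.warn("constant vector: distance correlation defined as 0",
                      stacklevel=2)
        return 0.0
    dcor2 = dcov2 / np.sqrt(dvx * dvy)
    return float(np.sqrt(max(dcor2, 0.0)))


def dc_test(x, y, n_resamples: int = DEFAULT_RESAMPLES, seed=None,
            alpha: float = DEFAULT_ALPHA, method: str = "permutation",
            ) -> DependencyResult:
    """Distance-correlation independence test with a resampling p-value.

    The null distribution permutes (or, with ``method='bootstrap'``, resamples
    with replacement) the sample labels of y;
    p = (1 + #{dc_null >= dc_obs}) / (1 + n_resamples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    flags = []
    a = _centered_distances(x)
    b = _centered_distances(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    n = x.shape[0]
    dvx = float((a * a).mean())
    dvy = float((b * b).mean())
    if dvx <= 0 or dvy <= 0:
        warnings.warn("constant vector in dc_test", stacklevel=2)
        return DependencyResult("x", "y", 0.0, 1.0, n_resamples, n, False,
                                ("constant_vector",))
    dc_obs = float(np.sqrt(max((a * b).mean() / np.sqrt(dvx * dvy), 0.0)))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_resamples):
        if method == "bootstrap":
            idx = rng.integers(0, n, n)
        else:
            idx = rng.permutation(n)
        bp = b[np.ix_(idx, idx)]
        if method == "bootstrap":
            # re-center after resampling (rows are no longer centered)
            bp = bp - bp.mean(0) - bp.mean(1)[:, None] + bp.mean()
        dvy_p = float((bp * bp).mean())
        if dvy_p <= 0:
            continue
        dc_p = np.sqrt(max((a * bp).mean() / np.sqrt(dvx * dvy_p), 0.0))
        if dc_p >= dc_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_resamples)
    return DependencyResult("x", "y", dc_obs, p, n_resamples, n,
                            bool(p < alpha), tuple(flags))


def pairwise_dependencies(table: pd.DataFrame, features=None,
                          alpha: float = DEFAULT_ALPHA,
                          n_resamples: int = DEFAULT_RESAMPLES, seed=None,
                          fdr: bool = False) -> list[DependencyResult]:
    """DC tests for all unordered feature pairs on complete cases.

    No multiple-testing correction by default (raw p < alpha); pass
    ``fdr=True`` for Benjamini–Hochberg adjusted significance.
    """
    features = list(features) if features is not None else list(table.columns)
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    data = complete_cases(table[features], features)
    rng = np.random.default_rng(seed)
    results = []
    for fx, fy in itertools.combinations(features, 2):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            r = dc_test(data[fx].to_numpy(), data[fy].to_numpy(),
                        n_resamples=n_resamples, seed=sub_seed, alpha=alpha)
            r.feature_x, r.feature_y = fx, fy
        except ValueError as exc:
            r = DependencyResult(fx, fy, np.nan, np.nan, n_resamples,
                                 len(data), False, (f"error: {exc}",))
        results.append(r)
    if fdr:
        ps = [r.p_value for r in results]
        ok = np.isfinite(ps)
        rej = np.zeros(len(ps), dtype=bool)
        if ok.any():
            rej[ok], *_ = multipletests(np.asarray(ps)[ok], alpha=alpha,
                                        method="fdr_bh")[:1]
        for r, rj in zip(results, rej):
            r.significant = bool(rj)
    return results


def dependency_matrix(results: list[DependencyResult]) -> pd.DataFrame:
    """Square DC matrix (diagonal 1) from a pairwise result list."""
    names = sorted({r.feature_x for r in results} | {r.feature_y for r in results})
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for r in results:
        mat.loc[r.feature_x, r.feature_y] = r.dc
        mat.loc[r.feature_y, r.feature_x] = r.dc
    return mat


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def region_comparison(oi_by_region: dict, channel: str = "collagen") -> dict:
    """One-way ANOVA + Tukey HSD of per-sample 3DOI across stress regions.

    ``oi_by_region`` maps region name (toe/heel/linear) to a list of 3DOI
    values.  Returns the F statistic, ANOVA p, and per-pair Tukey results
    with significance stars.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in oi_by_region.items()}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    names = list(groups)
    f_stat, p_val = stats.f_oneway(*groups.values())
    values = np.concatenate([groups[k] for k in names])
    labels = np.concatenate([[k] * groups[k].size for k in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=DEFAULT_ALPHA)
    pairs = []
    for row in tukey.summary().data[1:]:
        g1, g2, mdiff, p_adj = row[0], row[1], row[2], row[3]
        pairs.append({"group1": str(g1), "group2": str(g2),
                      "mean_diff": float(mdiff), "p_adj": float(p_adj),
                      "stars": _stars(float(p_adj))})
    return {"channel": channel, "F": float(f_stat), "p": float(p_val),
            "anova_stars": _stars(float(p_val)), "tukey": pairs}
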
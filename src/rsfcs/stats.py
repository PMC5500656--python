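"""ROI-level extraction and clinical statistics.

Covers the statistics battery of a two-group imaging study: ROI means,
partial correlations controlling age/gender/education, Fisher r-to-z
comparison of two independent correlations, Bonferroni adjustment, and the
demographics table tests (normality-gated t / Mann-Whitney, chi-squared on
gender counts without continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "PartialCorrResult",
    "roi_mean",
    "partial_correlation",
    "compare_correlations",
    "bonferroni",
    "gender_chi2",
    "demographics_tests",
    "correlation_battery",
]


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int
    k_covariates: int
    x_name: str = "x"
    y_name: str = "y"

    @property
    def df(self) -> int:
        return self.n - 2 - self.k_covariates


def roi_mean(map3d: np.ndarray, cluster_voxels: np.ndarray) -> float:
    """Unweighted mean of map values over a cluster voxel set.

    ``cluster_voxels`` is a boolean 3D mask or an array of flat indices.
    """
    map3d = np.asarray(map3d, dtype=float)
    cv = np.asarray(cluster_voxels)
    vals = map3d[cv] if cv.dtype == bool else map3d.ravel()[cv]
    if vals.size == 0:
        raise ValueError("empty cluster")
    return float(vals.mean())


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, covariates=None, x_name: str = "x",
                        y_name: str = "y") -> PartialCorrResult:
    """Pearson correlation of x and y after removing shared covariates.

    Both variables are residualized on the covariates plus an intercept by
    OLS; p comes from ``t = r sqrt(df / (1 - r^2))`` on ``df = n - 2 - k``
    degrees of freedom, two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} observations for {k} covariates")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(C))):
        raise ValueError("non-finite values")
    Z = np.column_stack([np.ones(n), C])
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if rx.std() <= 1e-12 * max(1.0, np.abs(x).max()) \
            or ry.std() <= 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("constant variable after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_ ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, n=n, k_covariates=k,
                             x_name=x_name, y_name=y_name)


def compare_correlations(r1: float, n1: int, r2: float, n2: int
                         ) -> tuple[float, float]:
    """Fisher r-to-z test for two independent correlations.

    z = (arctanh r1 - arctanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),
    two-sided normal p.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); preserves ordering."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family size must be at least 1")
    return np.minimum(1.0, p * m)


def gender_chi2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 gender table, no continuity correction."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(counts), correction=False)
    return float(chi2), float(p)


def _mannwhitney_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mu) / sigma
    return u, float(z), float(res.pvalue)


def demographics_tests(table: pd.DataFrame, group_col: str = "group",
                       gender_col: str = "gender",
                       normality_alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable group-comparison tests for a clinical table.

    Continuous variables are gated by a Lilliefors-corrected
    Kolmogorov-Smirnov normality test in each group: normal in both ->
    pooled-variance two-sample t; otherwise Mann-Whitney U with its
    normal-approximation z.  Gender gets a Pearson chi-squared on the 2x2
    counts without continuity correction.  Variables constant in both
    groups are flagged and skipped.
    """
    groups = [g for g, _ in table.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValueError("table must contain exactly two groups")
    a_tab = table[table[group_col] == groups[0]]
    b_tab = table[table[group_col] == groups[1]]
    if len(a_tab) == 0 or len(b_tab) == 0:
        raise ValueError("both groups must be nonempty")

    rows = []
    if gender_col in table.columns:
        counts = pd.crosstab(table[group_col], table[gender_col]).to_numpy()
        chi2, p = gender_chi2(counts)
        rows.append({"variable": gender_col, "test": "chi2",
                     "statistic": chi2, "p": p, "note": ""})

    numeric = [c for c in table.columns
               if c not in (group_col, gender_col, "subject")
               and pd.api.types.is_numeric_dtype(table[c])]
    for var in numeric:
        a = a_tab[var].dropna().to_numpy(dtype=float)
        b = b_tab[var].dropna().to_numpy(dtype=float)
        if a.std() == 0 and b.std() == 0:
            rows.append({"variable": var, "test": "skipped",
                         "statistic": np.nan, "p": np.nan,
                         "note": "constant in both groups"})
            continue
        normal = True
        for sample in (a, b):
            if sample.std() == 0:
                normal = False
                break
            _, pn = lilliefors(sample, dist="norm")
            if pn < normality_alpha:
                normal = False
        if normal:
            res = sps.ttest_ind(a, b, equal_var=True)
            rows.append({"variable": var, "test": "t",
                         "statistic": float(res.statistic),
                         "p": float(res.pvalue), "note": ""})
        else:
            u, z, p = _mannwhitney_z(a, b)
            rows.append({"variable": var, "test": "mannwhitney",
                         "statistic": z, "p": p, "note": f"U={u:.1f}"})
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p", "note"])


def correlation_battery(roi_values: pd.DataFrame, table: pd.DataFrame,
                        targets: list[str],
                        covariates: tuple[str, ...] = ("age", "gender", "education"),
                        group_col: str = "group") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partial correlations between ROI values and clinical variables.

    ``roi_values`` is indexed by subject id with one column per ROI; rows
    must align with ``table['subject']``.  Within each group every
    (ROI, variable) pair gets a partial correlation controlling the listed
    covariates; the Bonferroni family is all pairs within one group's
    battery (m = #ROIs x #variables, printed in the output).  A second
    frame compares each pair's correlation across groups with the Fisher
    r-to-z test.
    """
    if set(roi_values.index) != set(table["subject"]):
        raise ValueError("ROI values and clinical table cover different subjects")
    aligned = roi_values.loc[table["subject"]]
    m = len(roi_values.columns) * len(targets)

    cov_cols = []
    for c in covariates:
        v = table[c]
        if v.dtype == object:
            v = (v == "M").astype(float)
        cov_cols.append(np.asarray(v, dtype=float))
    covs = np.column_stack(cov_cols) if cov_cols else None

    rows = []
    per_group: dict[tuple[str, str, str], PartialCorrResult] = {}
    for grp in sorted(table[group_col].unique()):
        sel = (table[group_col] == grp).to_numpy()
        for roi in roi_values.columns:
            for var in targets:
                res = partial_correlation(
                    aligned[roi].to_numpy(dtype=float)[sel],
                    table[var].to_numpy(dtype=float)[sel],
                    covs[sel] if covs is not None else None,
                    x_name=roi, y_name=var)
                per_group[(grp, roi, var)] = res
                rows.append({"group": grp, "roi": roi, "variable": var,
                             "r": res.r, "p": res.p,
                             "p_bonferroni": min(1.0, res.p * m),
                             "n": res.n, "m_family": m})
    tidy = pd.DataFrame(rows)

    comp_rows = []
    grps = sorted(table[group_col].unique())
    if len(grps) == 2:
        g1, g2 = grps
        for roi in roi_values.columns:
            for var in targets:
                r1, n1 = per_group[(g1, roi, var)].r, per_group[(g1, roi, var)].n
                r2, n2 = per_group[(g2, roi, var)].r, per_group[(g2, roi, var)].n
                z, p = compare_correlations(r1, n1, r2, n2)
                comp_rows.append({"roi": roi, "variable": var, "z": z, "p": p,
                                  "r_" + g1: r1, "r_" + g2: r2})
    comparison = pd.DataFrame(comp_rows)
    return tidy, comparison
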
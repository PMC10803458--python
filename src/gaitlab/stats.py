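"""Reliability, validity and stratification statistics.

* ICC(2,k) — two-way random-effects, absolute-agreement, average-measures
  intraclass correlation, from the two-way ANOVA mean squares:

      ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

  with rows = targets (n) and columns = raters/systems (k).  Qualitative
  bands follow Cicchetti: < 0.40 poor, [0.40, 0.60) fair, [0.60, 0.75) good,
  >= 0.75 excellent.

* Pearson r with the conventional strength bands (< 0.30 negligible,
  [0.30, 0.50) low, [0.50, 0.70) moderate, [0.70, 0.90) high,
  [0.90, 1.00] very high), applied to |r|.

* Welch's unequal-variance t-test, both from group summaries (mean, SD, n)
  and column-wise over a raw parameter table.

* K-means++ stratification of a parameter table (z-scored features by
  default), with clusters ordered by centroid walking speed where that
  column is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .errors import ConfigurationError, SchemaError, UndefinedStatisticError

#: canonical parameter-table columns (units in the name), plus a 'group' label
PARAMETER_COLUMNS = (
    "step_period_s",
    "step_length_mm",
    "walking_speed_mm_s",
    "knee_rom_right_deg",
    "knee_rom_left_deg",
    "knee_velocity_range_right_deg_s",
    "knee_velocity_range_left_deg_s",
    "rcomv_mm_s",
    "sagittal_deviation_range_mm",
    "coronal_deviation_range_mm",
)

#: the parameters of the gold-standard validation workflow (the measurement
#: workflow's step length and COM plane-deviation ranges are excluded there)
VALIDATION_PARAMETERS = (
    "step_period_s",
    "walking_speed_mm_s",
    "knee_rom_right_deg",
    "knee_rom_left_deg",
    "knee_velocity_range_right_deg_s",
    "knee_velocity_range_left_deg_s",
    "rcomv_mm_s",
)

GROUP_COLUMN = "group"


def cicchetti_band(icc: float) -> str:
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def correlation_band(r: float) -> str:
    a = abs(r)
    if a < 0.30:
        return "negligible"
    if a < 0.50:
        return "low"
    if a < 0.70:
        return "moderate"
    if a < 0.90:
        return "high"
    return "very high"


def icc_2k(matrix: np.ndarray) -> tuple[float, str]:
    """ICC(2,k) of an n-targets x k-raters matrix, with its Cicchetti band."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ConfigurationError("ICC needs an n x k matrix with n >= 2, k >= 2")
    if not np.all(np.isfinite(m)):
        raise ConfigurationError("ICC matrix contains non-finite values")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (ms_cols - ms_err) / n
    if ss_total <= 0 or denom == 0:
        raise UndefinedStatisticError("ICC undefined: no variance in the matrix")
    icc = float((ms_rows - ms_err) / denom)
    return icc, cicchetti_band(icc)


def pearson_validity(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Sample Pearson r, two-sided p (t transform), and strength band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("pearson needs equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), correlation_band(float(r))


def welch_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t, Welch-Satterthwaite df, and two-sided p from group summaries."""
    if sd1 < 0 or sd2 < 0:
        raise ConfigurationError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each group needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        raise UndefinedStatisticError("Welch t undefined when both SDs are zero")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_screen(
    table: pd.DataFrame,
    group_column: str = GROUP_COLUMN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Column-wise Welch tests between the two groups of a parameter table.

    Returns a frame indexed by parameter with t, df, p and a significance
    flag at the given alpha.
    """
    if group_column not in table.columns:
        raise SchemaError(f"table lacks the {group_column!r} column")
    groups = table[group_column].unique()
    if len(groups) != 2:
        raise ConfigurationError(f"welch_screen needs exactly 2 groups, got {len(groups)}")
    a = table[table[group_column] == groups[0]]
    b = table[table[group_column] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each group needs at least 2 rows")
    rows = []
    for col in table.columns:
        if col == group_column or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        res = sps.ttest_ind(a[col].to_numpy(), b[col].to_numpy(), equal_var=False)
        rows.append(
            {
                "parameter": col,
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class ClusterReport:
    """K-means++ stratification of a parameter table."""

    k: int
    seed: int
    assignments: np.ndarray
    centroids: np.ndarray  # in the (standardized) feature space
    feature_names: list[str]
    inertia: float
    standardized: bool
    #: cluster labels ordered by descending centroid walking speed, when known
    speed_order: list[int] | None = None


def kmeanspp_cluster(
    table: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    standardize: bool = True,
    feature_columns: list[str] | None = None,
) -> ClusterReport:
    """K-means++ clustering of the numeric parameter columns.

    Columns are z-scored by default (gait parameters mix mm, s and deg/s
    scales, which would otherwise dominate the distance).  Deterministic for
    a given seed; Lloyd iterations run to centroid-shift convergence
    (tol 1e-8) or 300 iterations.
    """
    if feature_columns is None:
        feature_columns = [
            c
            for c in table.columns
            if c != GROUP_COLUMN and pd.api.types.is_numeric_dtype(table[c])
        ]
    missing = [c for c in feature_columns if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks feature columns {missing}")
    X = table[feature_columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("feature columns contain missing/non-finite cells")
    if k < 1 or k > X.shape[0]:
        raise ConfigurationError(f"k must be in [1, n_rows={X.shape[0]}], got {k}")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-8,
        random_state=seed,
    ).fit(X)
    report = ClusterReport(
        k=k,
        seed=seed,
        assignments=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        feature_names=list(feature_columns),
        inertia=float(km.inertia_),
        standardized=standardize,
    )
    if "walking_speed_mm_s" in feature_columns:
        j = feature_columns.index("walking_speed_mm_s")
        report.speed_order = list(np.argsort(-report.centroids[:, j]))
    return report
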
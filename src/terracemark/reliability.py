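"""Rater-reliability statistics for repeated landmark digitizations.

Implements the validation battery used to compare landmark digitization
methods: two-item Cronbach's alpha for intra-examiner (session 1 vs 2) and
inter-examiner (examiner means) agreement, absolute per-axis and distance
differences between examiners, the paired t-test between two methods'
precision, and the exact noncentral-t sample-size computation for a paired
design.

Measurements are long-format tables ``{rater, session, subject, landmark,
x, y, z[, d]}`` in mm; ``d`` is the Euclidean distance of the point from
the reference origin and is recomputed when absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterSeries",
    "cronbach_alpha",
    "pairwise_deltas",
    "rater_differences",
    "paired_t_test",
    "paired_t_power",
    "required_sample_size_paired_t",
    "reliability_report",
]

COMPONENTS = ("x", "y", "z", "d")


@dataclass
class RaterSeries:
    """One rater/session sweep of landmark coordinates over subjects."""

    rater: str
    session: int
    table: pd.DataFrame  # index (subject, landmark), columns x, y, z, d
    validate_d: bool = True  # False for derived tables (e.g. session means)

    def __post_init__(self):
        t = self.table
        if not {"x", "y", "z"}.issubset(t.columns):
            raise ValueError("rater series needs x, y, z columns")
        if t.index.duplicated().any():
            dupes = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate (subject, landmark) keys: {dupes[:5]}")
        d = np.sqrt(t["x"] ** 2 + t["y"] ** 2 + t["z"] ** 2)
        if "d" not in t.columns:
            self.table = t.assign(d=d)
        elif self.validate_d and not np.allclose(t["d"], d, atol=1e-9):
            raise ValueError("d column inconsistent with (x, y, z) to 1e-9")

    @classmethod
    def from_long(cls, df: pd.DataFrame, rater, session) -> "RaterSeries":
        sel = df[(df["rater"] == rater) & (df["session"] == session)]
        table = sel.set_index(["subject", "landmark"])[
            [c for c in ("x", "y", "z", "d") if c in sel.columns]]
        return cls(str(rater), int(session), table)


def cronbach_alpha(measurement_1, measurement_2) -> float:
    """Two-item Cronbach's alpha between paired measurement vectors.

    ``alpha = (k / (k - 1)) * (1 - sum(item variances) / var(item sums))``
    with ``k = 2`` items and unbiased (n-1) sample variances throughout.
    Equals 1 exactly for identical non-constant vectors and 0 when the
    sample covariance is exactly zero.
    """
    m1 = np.asarray(measurement_1, dtype=float)
    m2 = np.asarray(measurement_2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1 or len(m1) < 3:
        raise ValueError("need two equal-length 1D vectors of length >= 3")
    total_var = np.var(m1 + m2, ddof=1)
    if total_var == 0:
        raise ValueError("degenerate: constant measurements")
    return float(2.0 * (1.0 - (np.var(m1, ddof=1) + np.var(m2, ddof=1)) / total_var))


def pairwise_deltas(series_a: RaterSeries, series_b: RaterSeries) -> pd.DataFrame:
    """Per-(subject, landmark) absolute differences dx, dy, dz, dd."""
    a, b = series_a.table, series_b.table
    if set(a.index) != set(b.index):
        missing = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"mismatched (subject, landmark) keys: {missing[:10]}")
    b = b.reindex(a.index)
    out = pd.DataFrame(index=a.index)
    for c in COMPONENTS:
        out[f"d{c}"] = (a[c] - b[c]).abs()
    return out


def rater_differences(series_a: RaterSeries, series_b: RaterSeries) -> pd.DataFrame:
    """Per-landmark mean and SD of the absolute differences between raters.

    Symmetric in its arguments.  Rows are landmarks; columns are a
    MultiIndex (dx/dy/dz/dd) x (mean/sd), SD across subjects with n-1.
    """
    deltas = pairwise_deltas(series_a, series_b)
    grouped = deltas.groupby(level="landmark", sort=False)
    return pd.concat({"mean": grouped.mean(), "sd": grouped.std(ddof=1)},
                     axis=1).swaplevel(axis=1).sort_index(axis=1)


def paired_t_test(deltas_method_1, deltas_method_2) -> tuple[float, float]:
    """Classical paired t-test on per-subject differences.

    Returns ``(t, two-sided p)`` with n-1 degrees of freedom.
    """
    d1 = np.asarray(deltas_method_1, dtype=float)
    d2 = np.asarray(deltas_method_2, dtype=float)
    if d1.shape != d2.shape or len(d1) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.var(d1 - d2, ddof=1) == 0:
        raise ValueError("degenerate paired test: zero-variance differences")
    res = stats.ttest_rel(d1, d2)
    return float(res.statistic), float(res.pvalue)


def paired_t_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided paired t-test at sample size ``n``.

    Noncentral-t power with noncentrality ``dz * sqrt(n)`` and ``n - 1``
    degrees of freedom (no normal approximation).
    """
    if n < 2:
        return 0.0
    df = n - 1
    ncp = effect_size * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def required_sample_size_paired_t(effect_size: float, alpha: float = 0.05,
                                  power: float = 0.80, n_max: int = 1_000_000) -> int:
    """Smallest n at which the two-sided paired t-test reaches target power."""
    if not (0 < alpha < 1 and 0 < power < 1 and effect_size > 0):
        raise ValueError("need 0 < alpha < 1, 0 < power < 1, effect_size > 0")
    for n in range(2, n_max + 1):
        if paired_t_power(n, effect_size, alpha) >= power:
            return n
    raise ValueError(f"target power not attainable within n <= {n_max}")


# ---------------------------------------------------------------------------
# Report assembly


def _session_series(df: pd.DataFrame, rater, session) -> RaterSeries:
    return RaterSeries.from_long(df, rater, session)


def intra_examiner_alpha(df: pd.DataFrame) -> pd.DataFrame:
    """Cronbach's alpha between sessions 1 and 2, per rater/landmark/component."""
    rows = []
    for rater in sorted(df["rater"].unique()):
        s1 = _session_series(df, rater, 1).table
        s2 = _session_series(df, rater, 2).table
        for lm in df["landmark"].unique():
            a = s1.xs(lm, level="landmark").sort_index()
            b = s2.xs(lm, level="landmark").sort_index()
            rows.append({"rater": rater, "landmark": lm,
                         **{c: cronbach_alpha(a[c], b[c]) for c in COMPONENTS}})
    return pd.DataFrame(rows).set_index(["rater", "landmark"])


def inter_examiner_alpha(df: pd.DataFrame) -> pd.DataFrame:
    """Cronbach's alpha between two examiners' session means, per landmark.

    Each examiner's two sessions are averaged into a representative value
    first; the alpha is computed between the two examiners' representative
    series over subjects.
    """
    raters = sorted(df["rater"].unique())
    if len(raters) != 2:
        raise ValueError(f"inter-examiner analysis needs exactly 2 raters, got {raters}")
    means = {r: df[df["rater"] == r]
             .groupby(["subject", "landmark"])[list(COMPONENTS)].mean()
             for r in raters}
    rows = []
    for lm in df["landmark"].unique():
        a = means[raters[0]].xs(lm, level="landmark").sort_index()
        b = means[raters[1]].xs(lm, level="landmark").sort_index()
        rows.append({"landmark": lm,
                     **{c: cronbach_alpha(a[c], b[c]) for c in COMPONENTS}})
    return pd.DataFrame(rows).set_index("landmark")


def reliability_report(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Full agreement report for a long-format measurement table.

    Returns ``intra`` (session-1-vs-2 alpha per rater), ``inter``
    (examiner-mean alpha) and, with exactly two raters, ``differences``
    (per-landmark mean/SD of absolute inter-examiner differences, computed
    on the session means).
    """
    if "d" not in df.columns:
        df = df.assign(d=np.sqrt(df["x"] ** 2 + df["y"] ** 2 + df["z"] ** 2))
    out = {"intra": intra_examiner_alpha(df)}
    raters = sorted(df["rater"].unique())
    if len(raters) == 2:
        out["inter"] = inter_examiner_alpha(df)
        mean_series = []
        for r in raters:
            tbl = (df[df["rater"] == r]
                   .groupby(["subject", "landmark"])[list(COMPONENTS)].mean())
            mean_series.append(RaterSeries(r, 0, tbl, validate_d=False))
        out["differences"] = rater_differences(*mean_series)
    return out
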
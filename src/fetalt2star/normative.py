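"""Normative gestational-age models of regional T2* and volume.

Two complementary summaries of a control cohort:

* polynomial growth curves — OLS on the basis {1, GA, ..., GA^degree}
  (default degree 2, since regional T2* declines faster late in
  gestation); the GA association is tested with the joint F-test of all
  GA terms, with per-coefficient t-tests also reported.
* 2-week-bin percentile tables — per (region, bin) n, mean and empirical
  5th/50th/95th percentiles using the linear-interpolation quantile
  convention (numpy default, type-7 style). Bins are half-open
  [a, a+2) weeks with the last bin closed at 40; small bins (n = 7-11)
  make the convention worth recording in output metadata.

Repeated scans of one pregnancy are treated as independent data points by
default; callers can collapse to one scan per subject for sensitivity
analysis before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .reference import BIN_EDGES, REGIONS

__all__ = [
    "GrowthModel",
    "PercentileTable",
    "fit_growth_curve",
    "make_percentile_table",
    "evaluate_centile",
    "fit_cohort_growth_curves",
]


@dataclass
class GrowthModel:
    region: str
    outcome: str  # 't2star' or 'volume'
    degree: int
    coefficients: np.ndarray  # intercept first, then GA, GA^2, ...
    p_value: float  # joint F-test of all GA terms
    coef_p_values: np.ndarray  # per-coefficient t-tests (incl. intercept)
    r_squared: float
    n_scans: int

    def predict(self, ga) -> np.ndarray:
        ga = np.asarray(ga, dtype=float)
        powers = np.vander(ga, self.degree + 1, increasing=True)
        return powers @ self.coefficients


@dataclass
class PercentileTable:
    """Per (region, GA bin) normative summary with retained raw values."""

    bin_edges: np.ndarray
    rows: pd.DataFrame  # columns: region, bin_lo, bin_hi, n, mean, p5, p50, p95
    values: dict = field(default_factory=dict)  # (region, bin index) -> sorted samples
    quantile_convention: str = "linear interpolation between order statistics"


def fit_growth_curve(ga, y, degree: int = 2, region: str = "", outcome: str = "t2star") -> GrowthModel:
    """OLS polynomial regression of ``y`` on gestational age.

    Requires n >= degree + 2. For constant ``y`` the GA coefficients are
    zero, R^2 is 0 and the F-test p-value is undefined (NaN).
    """
    ga = np.asarray(ga, dtype=float)
    y = np.asarray(y, dtype=float)
    if ga.shape != y.shape or ga.ndim != 1:
        raise ValueError("ga and y must be 1-D and the same length")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n = len(ga)
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points, got {n}")

    design = np.vander(ga, degree + 1, increasing=True)
    # statsmodels divides by the centered TSS, which is zero for constant y;
    # map the resulting non-finite diagnostics to the documented values
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y, design).fit()
        f_pvalue = float(res.f_pvalue)
        rsquared = float(res.rsquared)
        pvalues = np.asarray(res.pvalues, dtype=float)
    # all non-constant regressors are GA powers, so the regression F-test
    # is exactly the joint test of the GA association
    return GrowthModel(
        region=region,
        outcome=outcome,
        degree=degree,
        coefficients=np.asarray(res.params, dtype=float),
        p_value=f_pvalue if np.isfinite(f_pvalue) else np.nan,
        coef_p_values=pvalues,
        r_squared=rsquared if np.isfinite(rsquared) else 0.0,
        n_scans=n,
    )


def fit_cohort_growth_curves(
    records: pd.DataFrame, outcome: str = "t2star", degree: int = 2
) -> dict:
    """Fit one growth curve per region from a long-format cohort table.

    ``records`` needs columns region, ga and the outcome column
    ('t2star' or 'volume'). Returns {region: GrowthModel}.
    """
    out = {}
    for region in REGIONS:
        sub = records[records["region"] == region]
        out[region] = fit_growth_curve(
            sub["ga"].to_numpy(), sub[outcome].to_numpy(), degree=degree,
            region=region, outcome=outcome,
        )
    return out


def _bin_index(ga: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(ga, edges) - 1
    # last bin is closed at the upper edge
    idx[np.asarray(ga) == edges[-1]] = len(edges) - 2
    return idx


def make_percentile_table(
    records: pd.DataFrame,
    value_column: str = "t2star",
    bin_edges: np.ndarray | None = None,
) -> PercentileTable:
    """Build the per-region 2-week-bin percentile table from per-scan records.

    ``records`` needs columns region, ga, and ``value_column``; every GA
    must lie in [edges[0], edges[-1]]. Empty bins are emitted with n = 0
    and NaN statistics.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else BIN_EDGES, dtype=float)
    ga = records["ga"].to_numpy(dtype=float)
    if np.any(ga < edges[0]) or np.any(ga > edges[-1]):
        raise ValueError(f"all GA values must lie in [{edges[0]}, {edges[-1]}]")
    idx = _bin_index(ga, edges)

    rows = []
    values = {}
    for region in REGIONS:
        in_region = (records["region"] == region).to_numpy()
        for b in range(len(edges) - 1):
            sel = in_region & (idx == b)
            vals = np.sort(records.loc[sel, value_column].to_numpy(dtype=float))
            n = len(vals)
            if n:
                p5, p50, p95 = np.percentile(vals, [5, 50, 95])
                mean = float(vals.mean())
            else:
                mean = p5 = p50 = p95 = np.nan
            rows.append(
                dict(region=region, bin_lo=edges[b], bin_hi=edges[b + 1],
                     n=n, mean=mean, p5=p5, p50=p50, p95=p95)
            )
            values[(region, b)] = vals
    return PercentileTable(bin_edges=edges, rows=pd.DataFrame(rows), values=values)


def plot_growth_curves(records: pd.DataFrame, models: dict, path, outcome: str = "t2star"):
    """Scatter the per-scan regional values with their fitted growth curves.

    One panel per region; requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 4, figsize=(16, 7), sharex=True)
    ga_grid = np.linspace(20, 40, 100)
    for ax, region in zip(axes.ravel(), REGIONS):
        sub = records[records["region"] == region]
        ax.scatter(sub["ga"], sub[outcome], s=8, alpha=0.6)
        model = models.get(region)
        if model is not None:
            ax.plot(ga_grid, model.predict(ga_grid), "k-",
                    label=f"p={model.p_value:.1e}")
            ax.legend(fontsize=7, frameon=False)
        ax.set_title(region.replace("_", " "), fontsize=9)
        ax.set_xlabel("GA (weeks)")
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def evaluate_centile(table: PercentileTable, region: str, ga: float, value: float):
    """Fraction of the bin's control values lying below ``value``.

    Inverts the linear-interpolation quantile convention on the bin's
    empirical distribution: returns 0 below the bin minimum, 1 above the
    maximum, and e.g. 0.5 exactly at the bin median. Returns
    (fraction, defined_flag); an empty bin yields (NaN, False).
    """
    edges = table.bin_edges
    if not (edges[0] <= ga <= edges[-1]):
        raise ValueError(f"ga {ga} outside [{edges[0]}, {edges[-1]}]")
    b = int(_bin_index(np.asarray([ga]), edges)[0])
    vals = table.values.get((region, b))
    if vals is None or len(vals) == 0:
        return np.nan, False
    n = len(vals)
    if n == 1:
        return (0.0 if value < vals[0] else (0.5 if value == vals[0] else 1.0)), True
    knots = np.arange(n) / (n - 1)  # quantile positions of the order statistics
    if value <= vals[0]:
        return (0.0 if value < vals[0] else 0.0), True
    if value >= vals[-1]:
        return (1.0 if value > vals[-1] else 1.0), True
    frac = float(np.interp(value, vals, knots))
    return frac, True
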
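"""Reliability and agreement statistics for paired-observer measure tables.

Four statistics are computed per measure, following the de Vet et al.
framework for reliability studies:

* **RS** — Spearman rank correlation of the two observers' farm-level
  values (midranks for ties; reliability of the rank order).
* **ICC** — intraclass correlation, agreement form, from the variance
  components of the two-way model ``x_ij = mu + alpha_i + beta_j + e_ij``
  (objects random, observers as the second factor; with one observation
  per cell the observer-by-object interaction is absorbed into the
  residual):

  .. math:: ICC = \\frac{\\sigma^2_{obj}}{\\sigma^2_{obj} +
            \\sigma^2_{observers} + \\sigma^2_{residual}}

* **SDC** — smallest detectable change, ``1.96 * sqrt(2) * SEM`` with
  ``SEM = sqrt(sigma2_observers + sigma2_residual)``; the smallest score
  difference distinguishable from measurement error, in measure units.
* **LoA** — Bland-Altman 95 % limits of agreement of the observer
  differences, ``mean(d) +/- 1.96 * sd(d)`` with ``d = A - BC`` (positive
  means observer A scores higher).

RS and ICC measure *reliability* (can farms be distinguished despite
measurement error — both rise with between-farm spread); SDC and LoA
measure *agreement* (how close the two observers' values are) and are
independent of the between-farm spread.  Each statistic carries an
acceptability label: RS/ICC >= 0.4 acceptable and >= 0.7 good; SDC <= 0.1
and LoA within [-0.1, 0.1] acceptable on the fraction scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    ConfigError,
    InsufficientDataError,
    LayoutError,
    UndefinedStatisticError,
)
from .protocol import MeasureTable

_Z95 = 1.96  # two-sided 95 % normal quantile, as printed in the formulas


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the two-way objects-by-observers ANOVA.

    Components are method-of-moments estimates from the mean squares,
    truncated at zero; units are the measure's units squared.
    """

    sigma2_objects: float
    sigma2_observers: float
    sigma2_residual: float
    n_objects: int
    n_observers: int = 2

    def __post_init__(self) -> None:
        if min(self.sigma2_objects, self.sigma2_observers, self.sigma2_residual) < 0:
            raise ConfigError("variance components must be nonnegative")
        if self.n_objects < 3:
            raise InsufficientDataError("need at least 3 objects (visits)")

    @property
    def total(self) -> float:
        return self.sigma2_objects + self.sigma2_observers + self.sigma2_residual

    @property
    def error_variance(self) -> float:
        """Measurement-error variance: observer plus residual components."""
        return self.sigma2_observers + self.sigma2_residual


@dataclass(frozen=True)
class Thresholds:
    """Acceptability cut-offs; all inequalities are inclusive."""

    rs_acceptable: float = 0.4
    rs_good: float = 0.7
    icc_acceptable: float = 0.4
    icc_good: float = 0.7
    sdc_max: float = 0.1
    loa_bound: float = 0.1

    def __post_init__(self) -> None:
        if self.rs_acceptable > self.rs_good or self.icc_acceptable > self.icc_good:
            raise ConfigError("'acceptable' threshold must not exceed 'good'")
        if self.sdc_max <= 0 or self.loa_bound <= 0:
            raise ConfigError("SDC/LoA bounds must be positive")


@dataclass
class AgreementResult:
    """All four statistics plus labels for one measure (one report row)."""

    measure_id: str
    n: int
    mean_a: float
    mean_bc: float
    rs: float
    icc: float | None
    sdc: float
    loa_lower: float
    loa_upper: float
    mean_difference: float
    components: VarianceComponents
    labels: dict[str, str]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def spearman_rs(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with midranks for ties.

    Equivalent to the Pearson correlation of the average-assigned ranks.
    Undefined (raises) when either vector is constant, since all its ranks
    tie and the rank variance vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LayoutError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError("Spearman correlation needs >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise LayoutError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "rank correlation undefined for a constant vector"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def variance_components(table: MeasureTable) -> VarianceComponents:
    """Two-way ANOVA variance components for a complete n x 2 table.

    Decomposes the total sum of squares into rows (visits), columns
    (observers) and residual, then converts mean squares to components:

    ``sigma2_objects = (MS_rows - MS_err) / k``,
    ``sigma2_observers = (MS_cols - MS_err) / n``,
    ``sigma2_residual = MS_err``,

    with ``k = 2`` observers.  Negative method-of-moments estimates are
    truncated to zero so the derived ICC stays in [0, 1].
    """
    data = np.column_stack([table.value_a, table.value_bc]).astype(float)
    if np.isnan(data).any():
        raise LayoutError("incomplete two-way layout")
    n, k = data.shape
    if n < 3:
        raise InsufficientDataError("need at least 3 paired visits")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    return VarianceComponents(
        sigma2_objects=max((ms_rows - ms_err) / k, 0.0),
        sigma2_observers=max((ms_cols - ms_err) / n, 0.0),
        sigma2_residual=ms_err,
        n_objects=n,
        n_observers=k,
    )


def icc_agreement(c: VarianceComponents) -> float:
    """ICC, agreement form: between-object variance over total variance.

    1 means perfect reliability (all variance between farms), 0 a total
    lack of reliability.  When every component is zero the ratio is
    undefined and :class:`UndefinedStatisticError` is raised — a table of
    identical values carries no reliability information.
    """
    if c.total == 0:
        raise UndefinedStatisticError(
            "all variance components zero: ICC not computable"
        )
    return c.sigma2_objects / c.total


def sdc(c: VarianceComponents, *, literal_formula: bool = False) -> float:
    """Smallest detectable change from the error variance components.

    ``1.96 * sqrt(2) * SEM`` with ``SEM = sqrt(sigma2_observers +
    sigma2_residual)``, in the measure's units.  ``literal_formula=True``
    reproduces the dimensionally inconsistent variant
    ``1.96 * sqrt(2) * (sigma2_observers + sigma2_residual)`` that applies
    the factor to the variance itself, for comparison with sources that
    print it that way.
    """
    err = c.error_variance
    if literal_formula:
        return _Z95 * np.sqrt(2.0) * err
    return float(_Z95 * np.sqrt(2.0) * np.sqrt(err))


def limits_of_agreement(table: MeasureTable) -> tuple[float, float, float]:
    """Bland-Altman 95 % limits of agreement of the observer differences.

    Returns ``(mean_difference, lower, upper)`` with differences
    ``d = value_A - value_BC`` (positive when observer A scores higher)
    and limits ``mean(d) +/- 1.96 * sd(d)``, sample standard deviation.
    """
    if len(table) < 3:
        raise InsufficientDataError("need at least 3 paired visits for LoA")
    d = table.value_a - table.value_bc
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return mean_d, mean_d - _Z95 * sd_d, mean_d + _Z95 * sd_d


def bland_altman_points(table: MeasureTable) -> list[tuple[float, float]]:
    """Per-visit (average, difference) points for the Bland-Altman plot."""
    avg = (table.value_a + table.value_bc) / 2.0
    diff = table.value_a - table.value_bc
    return [(float(a), float(d)) for a, d in zip(avg, diff)]


def _grade(value: float, acceptable: float, good: float) -> str:
    if value >= good:
        return "good"
    if value >= acceptable:
        return "acceptable"
    return "not acceptable"


def classify(
    rs: float,
    icc: float | None,
    sdc_value: float,
    loa: tuple[float, float],
    thresholds: Thresholds = Thresholds(),
    *,
    scale_divisor: float | None = None,
) -> dict[str, str]:
    """Acceptability labels for the four statistics.

    RS and ICC are graded good / acceptable / not acceptable with
    inclusive cut-offs.  SDC and LoA are thresholded on the fraction
    scale: for non-fraction measures *scale_divisor* (e.g. the theoretical
    QBA score range, or 125 mm for raw adjectives) first maps differences
    onto that scale.  LoA is acceptable iff the whole interval lies inside
    ``[-loa_bound, +loa_bound]``.
    """
    div = scale_divisor if scale_divisor else 1.0
    labels = {
        "rs": _grade(rs, thresholds.rs_acceptable, thresholds.rs_good),
        "icc": (
            "not computable"
            if icc is None
            else _grade(icc, thresholds.icc_acceptable, thresholds.icc_good)
        ),
        "sdc": (
            "acceptable" if sdc_value / div <= thresholds.sdc_max
            else "not acceptable"
        ),
        "loa": (
            "acceptable"
            if (loa[0] / div >= -thresholds.loa_bound
                and loa[1] / div <= thresholds.loa_bound)
            else "not acceptable"
        ),
    }
    return labels


def evaluate_measure(
    table: MeasureTable, thresholds: Thresholds = Thresholds()
) -> AgreementResult:
    """Compute all four statistics and labels for one measure table.

    The composition of one report row: variance components feed the ICC
    and SDC, the raw differences feed the LoA, and the ranks feed RS.
    The result is invariant to the order of the table rows.
    """
    comps = variance_components(table)
    try:
        icc = icc_agreement(comps)
    except UndefinedStatisticError:
        icc = None
    try:
        rs = spearman_rs(table.value_a, table.value_bc)
    except UndefinedStatisticError:
        # a constant column has no rank order; perfect-duplicate constant
        # tables still deserve a defined report row
        rs = float("nan")
    sdc_value = sdc(comps)
    mean_d, lo, hi = limits_of_agreement(table)
    labels = classify(
        rs if np.isfinite(rs) else -np.inf,
        icc,
        sdc_value,
        (lo, hi),
        thresholds,
        scale_divisor=table.scale_divisor,
    )
    return AgreementResult(
        measure_id=table.measure_id,
        n=len(table),
        mean_a=float(table.value_a.mean()),
        mean_bc=float(table.value_bc.mean()),
        rs=rs,
        icc=icc,
        sdc=sdc_value,
        loa_lower=lo,
        loa_upper=hi,
        mean_difference=mean_d,
        components=comps,
        labels=labels,
    )
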
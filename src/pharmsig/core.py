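"""Shared 2x2-table machinery for disproportionality and case-crossover scores.

Both signal sources reduce a (drug, outcome) question to a 2x2 contingency
table and score it with the same odds-ratio estimator: the cross-product
ratio ``(a*d)/(b*c)`` with a Woolf (log-normal) confidence interval.  What
differs between sources is how the cells are counted and what the signal
rule is, so those live in :mod:`pharmsig.faers` and :mod:`pharmsig.emr`
while the estimator itself lives here.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

logger = logging.getLogger(__name__)

#: Default normal quantile for 95% confidence intervals.
DEFAULT_Z = 1.96


class TableContext(enum.Enum):
    """How the cells of a 2x2 table were counted."""

    REPORTS = "reports"
    CASE_CROSSOVER = "case_crossover"


class Source(enum.Enum):
    """Provenance of a signal set."""

    FAERS = "FAERS"
    EMR = "EMR"
    COMBINED = "COMBINED"


class DegenerateTableError(ValueError):
    """Raised when a table carries no information (all four cells zero)."""


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table of counts.

    For ``REPORTS`` context, rows are drug-exposed vs other reports and
    columns are with/without the adverse event; the four cells partition the
    report population.  For ``CASE_CROSSOVER`` context, the rows are the case
    (on-treatment) and control (pre-treatment) windows of the *same* patient
    cohort, so ``a + b == c + d`` must hold.
    """

    a: int
    b: int
    c: int
    d: int
    context: TableContext = TableContext.REPORTS

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"cell {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")
        if self.context is TableContext.CASE_CROSSOVER and self.a + self.b != self.c + self.d:
            raise ValueError(
                "case-crossover rows must cover the same cohort: "
                f"a+b={self.a + self.b} != c+d={self.c + self.d}"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def corrected_cells(table: ContingencyTable) -> tuple[tuple[float, float, float, float], bool]:
    """Apply the Haldane-Anscombe continuity correction when needed.

    Adds 0.5 to *all four* cells if any cell is zero; returns the (possibly
    corrected) cells and whether the correction was applied.  A table with
    all four cells zero carries no information and raises
    :class:`DegenerateTableError`.
    """
    cells = table.cells
    if all(v == 0 for v in cells):
        raise DegenerateTableError("all four cells are zero; odds ratio undefined")
    if any(v == 0 for v in cells):
        return tuple(v + 0.5 for v in cells), True  # type: ignore[return-value]
    return tuple(float(v) for v in cells), False  # type: ignore[return-value]


def odds_ratio_woolf(
    table: ContingencyTable, z: float = DEFAULT_Z
) -> tuple[float, float, float, bool]:
    """Cross-product odds ratio with a Woolf log-normal confidence interval.

    Returns ``(estimate, ci_low, ci_high, zero_corrected)`` where the
    interval is ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` on the
    (possibly Haldane-Anscombe corrected) cells.
    """
    (a, b, c, d), corrected = corrected_cells(table)
    est = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_est = math.log(est)
    return est, math.exp(log_est - z * se), math.exp(log_est + z * se), corrected


def two_sided_p(table: ContingencyTable, method: str = "auto") -> tuple[float, str]:
    """Two-sided p-value for independence on a 2x2 table.

    ``method`` is ``"chi2"`` (Pearson, no Yates correction), ``"fisher"``
    (exact), or ``"auto"`` which uses Fisher whenever any expected cell is
    below 5.  Degenerate margins (an empty row or column) carry no evidence
    and return p = 1 with the method tagged ``"degenerate"``.
    """
    a, b, c, d = table.cells
    n = table.n
    if n == 0 or min(a + b, c + d, a + c, b + d) == 0:
        logger.warning("degenerate margins in %s; p-value set to 1", table.cells)
        return 1.0, "degenerate"
    if method == "auto":
        min_expected = min(
            (a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)
        ) / n
        method = "fisher" if min_expected < 5 else "chi2"
    if method == "chi2":
        res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        return float(res.pvalue), "chi2"
    if method == "fisher":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(p), "fisher"
    raise ValueError(f"unknown p-value method {method!r}")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: ``min(1, p * m)`` over m comparisons."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    return min(1.0, p * m)


@dataclass
class SignalScore:
    """Per-(drug, outcome) score: estimate, interval, p-values, signal flag."""

    estimate: float
    ci_low: float
    ci_high: float
    is_signal: bool
    table: ContingencyTable
    p_value: Optional[float] = None
    p_bonferroni: Optional[float] = None
    p_method: Optional[str] = None
    zero_corrected: bool = False
    possible_indication_confounder: bool = False

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"interval does not bracket estimate: [{self.ci_low}, {self.ci_high}] "
                f"vs {self.estimate}"
            )


@dataclass
class SignalSet:
    """All scored outcomes for one (drug, indication) pair from one source.

    ``entries`` maps outcome CUI to its score, preserving rank order where
    the producing operation defines one.  For ``COMBINED`` sets,
    ``per_source`` retains the score each contributing source assigned.
    """

    drug: str
    indication: str
    source: Source
    entries: dict[str, SignalScore] = field(default_factory=dict)
    per_source: dict[str, dict[str, SignalScore]] = field(default_factory=dict)

    def flagged(self) -> set[str]:
        """CUIs of the outcomes whose signal rule fired."""
        return {cui for cui, s in self.entries.items() if s.is_signal}

    def __len__(self) -> int:
        return len(self.entries)
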
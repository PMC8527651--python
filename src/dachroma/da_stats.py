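"""DA/EA scoring rules and the associated statistical test battery.

Analysts score each homolog's hybridization signal on a four-level scale
(bright, medium, dim, nil). A cell is differentially accessible (DA) when
the homologs receive different scores, equivalently accessible (EA) when
both are bright or both medium; dim/dim, nil/nil and dim/nil pairs — and
any cell with a chromosome overlap at the target — are excluded. Probe
classification then asks whether DA (or EA) cells significantly outnumber
the other class, via a two-tailed binomial test with normal approximation;
between-sample, between-tissue and between-group contrasts use the
two-proportion Z, Kruskal–Wallis, Mann–Whitney U and Welch t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CATEGORIES",
    "EXCLUDED_PAIRS",
    "CellScore",
    "SampleSummary",
    "TestResult",
    "ProbeClassification",
    "score_cell",
    "binomial_test_normal",
    "classify_probe",
    "two_proportion_z",
    "mann_whitney_u",
    "kruskal_wallis",
    "welch_t",
]

CATEGORIES = ("bright", "medium", "dim", "nil")

# unordered category pairs that make a cell unscorable
EXCLUDED_PAIRS = frozenset(
    {frozenset({"dim"}), frozenset({"nil"}), frozenset({"dim", "nil"})}
)

MIN_SCORED_CELLS = 25  # protocol floor: 25+ cells scored for most samples


@dataclass
class CellScore:
    cell_id: str
    category_1: str
    category_2: str
    call: str
    exclusion_reason: Optional[str] = None


@dataclass
class SampleSummary:
    """Per-(probe, sample) DA/EA/excluded cell counts."""

    probe: str
    sample_id: str
    tissue: str
    n_da: int
    n_ea: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.n_da, self.n_ea, self.n_excluded) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_scored(self) -> int:
        return self.n_da + self.n_ea


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def score_cell(cat1: str, cat2: str, overlap: bool = False) -> str:
    """DA/EA/EXCLUDED call from the two homolog intensity categories.

    Symmetric in the homologs. Chromosome overlap at the target excludes
    the cell regardless of the scores.
    """
    for cat in (cat1, cat2):
        if cat not in CATEGORIES:
            raise ValueError(f"unknown intensity category: {cat!r}")
    if overlap:
        return "EXCLUDED"
    if frozenset({cat1, cat2}) in EXCLUDED_PAIRS:
        return "EXCLUDED"
    return "DA" if cat1 != cat2 else "EA"


def binomial_test_normal(
    k: int,
    n: int,
    p0: float = 0.5,
    continuity: bool = True,
    alpha: float = 0.05,
) -> TestResult:
    """Two-tailed binomial test by normal approximation.

    z = (k - n*p0) / sqrt(n*p0*(1-p0)), with a half-unit continuity
    correction toward the mean by default (this keeps the approximation
    within 0.02 of the exact two-sided binomial p down to n = 25);
    ``continuity=False`` gives the plain z = (k/n - p0)/sqrt(p0(1-p0)/n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    sd = np.sqrt(n * p0 * (1 - p0))
    dev = abs(k - n * p0)
    if continuity:
        dev = max(0.0, dev - 0.5)
    z = dev / sd
    if k < n * p0:
        z = -z
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return TestResult(statistic=float(z), p_value=p, method="binomial-normal", alpha=alpha)


@dataclass
class ProbeClassification:
    call: str                 # "DA", "EA" or "indeterminate"
    n_da: int
    n_ea: int
    test: TestResult
    majority_fraction: float  # fraction of scored cells in the majority class
    over_two_thirds: bool     # descriptive flag: majority class > 2/3 of cells
    warning: Optional[str] = None


def classify_probe(
    summaries: Sequence[SampleSummary] | tuple[int, int],
    alpha: float = 0.05,
    min_cells: int = MIN_SCORED_CELLS,
) -> ProbeClassification:
    """Pool a probe's samples and classify the locus as DA, EA or neither.

    DA requires a pooled DA fraction above 1/2 that is significant under
    the two-tailed binomial normal test at ``alpha`` (EA symmetrically).
    The ">2/3 of cells" heuristic is reported as a descriptive flag, not
    used as a gate. Pooled scored counts below ``min_cells`` attach a
    warning rather than silently passing.
    """
    if isinstance(summaries, tuple):
        n_da, n_ea = summaries
    else:
        n_da = sum(s.n_da for s in summaries)
        n_ea = sum(s.n_ea for s in summaries)
    n = n_da + n_ea
    if n == 0:
        raise ValueError("no scored cells to classify")
    test = binomial_test_normal(n_da, n, 0.5, alpha=alpha)
    frac_da = n_da / n
    majority = max(frac_da, 1 - frac_da)
    if frac_da > 0.5 and test.significant:
        call = "DA"
    elif frac_da < 0.5 and test.significant:
        call = "EA"
    else:
        call = "indeterminate"
    warning = None
    if n < min_cells:
        warning = f"only {n} scored cells pooled (minimum {min_cells})"
    return ProbeClassification(
        call=call,
        n_da=n_da,
        n_ea=n_ea,
        test=test,
        majority_fraction=majority,
        over_two_thirds=majority > 2 / 3,
        warning=warning,
    )


def two_proportion_z(k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05) -> TestResult:
    """Pooled-variance two-proportion Z test (two-sided, no continuity corr.)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ZeroDivisionError(
            "pooled proportion is degenerate (all successes or all failures)"
        )
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return TestResult(statistic=float(z), p_value=p, method="two-proportion-z", alpha=alpha)


_EXACT_MWU_MAX = 8


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact null by enumeration when both samples have at most 8
    observations and there are no ties; otherwise the normal approximation
    with mid-rank tie correction (no continuity correction, so that for
    two untied groups z**2 equals the Kruskal–Wallis H).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size <= _EXACT_MWU_MAX and y.size <= _EXACT_MWU_MAX:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "mann-whitney-exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "mann-whitney-normal"
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=method,
        alpha=alpha,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TestResult:
    """Kruskal–Wallis H (tie-corrected), p from chi-square with k−1 df.

    All observations identical is not an error: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if np.unique(np.concatenate(arrays)).size == 1:
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis", alpha=alpha)
    res = stats.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method="kruskal-wallis",
        alpha=alpha,
    )


def welch_t(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> TestResult:
    """Unpaired t test with Welch correction (Welch–Satterthwaite df), two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ZeroDivisionError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method="welch-t",
        alpha=alpha,
    )
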
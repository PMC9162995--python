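"""Fragility metrics for two-arm trials with dichotomous outcomes.

This module implements, in the order an analysis runs:

1.  Exact-test machinery: Fisher's exact test (two-sided, minimum-likelihood
    rule) on a 2x2 table, the Shannon S-value transform of a P value, and the
    relative risk.
2.  Fragility indices: the fragility index (FI; events added to the
    smaller-event arm of a significant result until significance collapses),
    the reverse fragility index (RFI; minimum outcome switches turning a
    nonsignificant result significant), and their quotients (index / N x 100).
3.  Exact post-hoc power of the Fisher test at the observed arm proportions,
    by full enumeration of the two binomial outcome distributions (Monte
    Carlo fallback for very large tables).
4.  Corpus I/O: a documented CSV schema for corpora of trial comparisons.
5.  Corpus statistics: branch classification (fragility vs reverse),
    medians/IQRs, bootstrap Spearman correlations, Mood's median test,
    histogram tables, and a 1:1-allocation sensitivity subset.
6.  Synthetic corpora: a generator for trial corpora with the statistical
    structure the analysis assumes (binomial event counts, sample sizes from
    a two-proportion power calculation), so the whole pipeline is testable
    without any external data.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, asdict, replace
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    # constants / config
    "DEFAULT_ALPHA", "DEFAULT_SEED", "DEFAULT_N_BOOT", "RunConfig",
    # exceptions
    "ValidationError", "SchemaError",
    # domain types
    "FourfoldTable", "FisherResult", "FragilityResult", "PowerInput",
    "PowerResult", "ComparisonRecord", "MedianIQR", "CorrelationResult",
    "MoodResult", "CorpusSummary", "TrialDesign", "CorpusConfig",
    # per-comparison operations
    "fisher_exact_p", "fisher_result", "s_value", "relative_risk",
    "fragility_index", "reverse_fragility_index", "fragility_quotient",
    "posthoc_power",
    # corpus I/O
    "CSV_COLUMNS", "read_corpus", "write_corpus", "write_results",
    "corpus_metrics",
    # corpus statistics
    "classify_comparison", "median_iqr", "spearman_bootstrap",
    "moods_median_test", "summarize_corpus",
    # synthetic corpora
    "required_sample_size", "simulate_trial", "generate_corpus",
]

logger = logging.getLogger("fragility")

# --------------------------------------------------------------------------
# Configuration & constants
# --------------------------------------------------------------------------

#: Conventional significance level; configurable per call/run.
DEFAULT_ALPHA = 0.05
#: Default seed for every stochastic component (bootstrap, Monte Carlo,
#: synthetic corpora).  Always recorded in outputs.
DEFAULT_SEED = 2014
#: Bootstrap repetitions for Spearman confidence intervals.
DEFAULT_N_BOOT = 10_000
#: Relative tolerance of the minimum-likelihood rule: point probabilities up
#: to (1 + REL_TOL) x the observed one count as "at least as extreme",
#: guarding against floating-point ties (the convention of R's fisher.test).
REL_TOL = 1e-7
#: Significance boundary guard: exact tail sums are rationals that can land
#: exactly on alpha (e.g. 91/1820 = 0.05), where float summation error would
#: otherwise decide significance.  A p within ALPHA_TOL of alpha counts as
#: at the boundary, i.e. not significant.
ALPHA_TOL = 1e-9
#: Above this many outcome pairs (size_a+1)(size_b+1), exact power switches
#: from full enumeration to seeded Monte Carlo.
ENUMERATION_LIMIT = 4_000_000
#: Monte Carlo draws used when enumeration is infeasible.
MC_DRAWS = 100_000

RFI_STRATEGIES = ("exact", "greedy-toward-separation")
OUTCOME_TIERS = ("primary", "secondary", "other")


@dataclass(frozen=True)
class RunConfig:
    """Settings for a corpus analysis run, echoed verbatim into reports."""

    alpha: float = DEFAULT_ALPHA
    n_boot: int = DEFAULT_N_BOOT
    seed: int = DEFAULT_SEED
    rfi_strategy: str = "exact"
    #: correlate post-hoc power with P across both branches (True) or within
    #: the fragility branch only (False).
    power_p_pooled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.rfi_strategy not in RFI_STRATEGIES:
            raise ValidationError(
                f"rfi_strategy must be one of {RFI_STRATEGIES}, "
                f"got {self.rfi_strategy!r}")

    def to_dict(self) -> dict:
        return asdict(self)


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class SchemaError(ValidationError):
    """A corpus file does not match the documented CSV schema."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FourfoldTable:
    """One comparison's 2x2 outcome table: events/size per arm.

    Arm A is the intervention arm, arm B the control arm; this fixes the
    orientation of the relative risk (treatment over control).
    """

    events_a: int
    size_a: int
    events_b: int
    size_b: int

    def __post_init__(self) -> None:
        for name in ("events_a", "size_a", "events_b", "size_b"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.size_a < 1 or self.size_b < 1:
            raise ValidationError("arm sizes must be >= 1")
        if not 0 <= self.events_a <= self.size_a:
            raise ValidationError(
                f"events_a={self.events_a} outside [0, {self.size_a}]")
        if not 0 <= self.events_b <= self.size_b:
            raise ValidationError(
                f"events_b={self.events_b} outside [0, {self.size_b}]")

    @property
    def total_n(self) -> int:
        return self.size_a + self.size_b

    @property
    def risk_a(self) -> float:
        return self.events_a / self.size_a

    @property
    def risk_b(self) -> float:
        return self.events_b / self.size_b

    @property
    def allocation_ratio(self) -> tuple[int, int]:
        """size_a : size_b reduced to lowest terms."""
        f = Fraction(self.size_a, self.size_b)
        return f.numerator, f.denominator

    def with_events(self, events_a: int, events_b: int) -> "FourfoldTable":
        """Same arm sizes, different event counts (total N preserved)."""
        return FourfoldTable(events_a, self.size_a, events_b, self.size_b)

    def __str__(self) -> str:
        return (f"{self.events_a}/{self.size_a} vs "
                f"{self.events_b}/{self.size_b}")


@dataclass(frozen=True)
class FisherResult:
    """Two-sided exact P, its S-value, and significance at alpha."""

    p_value: float
    s_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


@dataclass(frozen=True)
class FragilityResult:
    """An index (FI or RFI), its quotient, and the P-value trajectory.

    ``index is None`` is the "not attainable" sentinel: no table on the grid
    of admissible event counts reaches the other side of alpha.
    ``p_trajectory`` starts at the baseline P and appends one entry per
    single-patient modification.
    """

    direction: str                      # "fragility" | "reverse"
    index: int | None
    quotient: float | None              # percent of total N
    p_trajectory: tuple[float, ...]
    terminal_table: FourfoldTable
    alpha: float = DEFAULT_ALPHA
    saturated: bool = False             # FI walk had to switch arms

    @property
    def attainable(self) -> bool:
        return self.index is not None


@dataclass(frozen=True)
class PowerInput:
    """Arguments of an exact power calculation for the Fisher test."""

    size_a: int
    size_b: int
    rate_a: float
    rate_b: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.size_a < 1 or self.size_b < 1:
            raise ValidationError("arm sizes must be >= 1")
        if not (0 <= self.rate_a <= 1 and 0 <= self.rate_b <= 1):
            raise ValidationError("event rates must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_table(cls, table: FourfoldTable,
                   alpha: float = DEFAULT_ALPHA) -> "PowerInput":
        """Post-hoc use: rates are the observed arm proportions."""
        return cls(table.size_a, table.size_b,
                   table.risk_a, table.risk_b, alpha)


@dataclass(frozen=True)
class PowerResult(float):
    """Power value carrying the method that produced it."""

    value: float = 0.0
    method: str = "enumeration"         # "enumeration" | "monte-carlo"
    n_draws: int | None = None
    seed: int | None = None

    def __new__(cls, value: float = 0.0, method: str = "enumeration",
                n_draws: int | None = None, seed: int | None = None):
        return float.__new__(cls, value)


@dataclass(frozen=True)
class ComparisonRecord:
    """A trial comparison with metadata, wrapping a FourfoldTable."""

    study_id: str
    outcome_label: str
    outcome_tier: str
    table: FourfoldTable
    reported_p: float | None = None

    def __post_init__(self) -> None:
        if self.outcome_tier not in OUTCOME_TIERS:
            raise ValidationError(
                f"outcome_tier must be one of {OUTCOME_TIERS}, "
                f"got {self.outcome_tier!r}")
        if self.reported_p is not None and not 0 < self.reported_p <= 1:
            raise ValidationError(
                f"reported_p must lie in (0,1], got {self.reported_p}")

    @property
    def allocation_ratio(self) -> tuple[int, int]:
        return self.table.allocation_ratio

    @property
    def is_one_to_one(self) -> bool:
        return self.allocation_ratio == (1, 1)


@dataclass(frozen=True)
class MedianIQR:
    median: float
    q1: float
    q3: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with a percentile-bootstrap confidence interval."""

    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_boot: int
    seed: int
    degenerate: bool = False            # constant input: rho undefined


@dataclass(frozen=True)
class MoodResult:
    """Mood's median test: chi-square on counts above the grand median."""

    chi2: float
    df: int
    p_value: float
    grand_median: float
    counts: tuple[tuple[int, int], tuple[int, int]]
    all_tied: bool = False


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level results: branch sizes, medians/IQRs, correlations,
    Mood tests, histogram tables, and the 1:1-allocation sensitivity
    variant.  Carries the RunConfig for bit-identical re-runs."""

    n_publications: int
    n_comparisons: int
    branch_sizes: dict
    not_attainable: dict
    stats: dict                          # name -> MedianIQR | None
    correlations: dict                   # name -> CorrelationResult | None
    mood: dict                           # name -> MoodResult | None
    histograms: dict
    config: RunConfig
    sensitivity: "CorpusSummary | None" = None

    def to_dict(self) -> dict:
        def conv(obj):
            if obj is None or isinstance(obj, (str, int, bool)):
                return obj
            if isinstance(obj, float):
                return None if math.isnan(obj) else obj
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return conv(float(obj))
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, np.ndarray)):
                return [conv(v) for v in obj]
            if isinstance(obj, (MedianIQR, CorrelationResult, MoodResult,
                                RunConfig)):
                return conv(asdict(obj))
            if isinstance(obj, CorpusSummary):
                return obj.to_dict()
            raise TypeError(f"cannot serialise {type(obj)}")
        return {
            "n_publications": self.n_publications,
            "n_comparisons": self.n_comparisons,
            "branch_sizes": conv(self.branch_sizes),
            "not_attainable": conv(self.not_attainable),
            "stats": conv(self.stats),
            "correlations": conv(self.correlations),
            "mood": conv(self.mood),
            "histograms": conv(self.histograms),
            "config": conv(self.config),
            "sensitivity": conv(self.sensitivity),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


# --------------------------------------------------------------------------
# Exact-test machinery
# --------------------------------------------------------------------------

def _hypergeom_pmf(margin: int, total: int, size_a: int) -> tuple[np.ndarray,
                                                                  int]:
    """Point probabilities of events_a conditional on all margins.

    Returns (pmf over the support, lowest support value).
    """
    lo = max(0, size_a - (total - margin))
    hi = min(size_a, margin)
    x = np.arange(lo, hi + 1)
    return stats.hypergeom.pmf(x, total, margin, size_a), lo


def fisher_exact_p(table: FourfoldTable) -> float:
    """Two-sided conditional exact P of Fisher's test.

    Conditions on all margins, enumerates the hypergeometric distribution of
    ``events_a``, and sums point probabilities no greater than
    ``(1 + 1e-7) x`` the observed one (minimum-likelihood rule).
    """
    pmf, lo = _hypergeom_pmf(table.events_a + table.events_b,
                             table.total_n, table.size_a)
    observed = pmf[table.events_a - lo]
    p = float(pmf[pmf <= observed * (1.0 + REL_TOL)].sum())
    return min(p, 1.0)


@lru_cache(maxsize=512)
def _p_grid(size_a: int, size_b: int) -> np.ndarray:
    """Two-sided exact P for every admissible table with the given arm sizes.

    Entry [a, b] is the Fisher P of the table a/size_a vs b/size_b.  Computed
    one margin (anti-diagonal) at a time: within a margin the conditional
    distribution is shared, so sorting its pmf once gives every cell's
    tail sum via a cumulative-sum lookup.
    """
    total = size_a + size_b
    grid = np.ones((size_a + 1, size_b + 1))
    for margin in range(total + 1):
        pmf, lo = _hypergeom_pmf(margin, total, size_a)
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        ranks = np.searchsorted(pmf[order], pmf * (1.0 + REL_TOL),
                                side="right") - 1
        pvals = np.minimum(csum[ranks], 1.0)
        a = np.arange(lo, lo + pmf.size)
        grid[a, margin - a] = pvals
    grid.setflags(write=False)
    return grid


def _is_significant(p: float, alpha: float) -> bool:
    """p < alpha, treating p within ALPHA_TOL of alpha as a boundary tie
    (not significant)."""
    return p < alpha - ALPHA_TOL


def fisher_result(table: FourfoldTable,
                  alpha: float = DEFAULT_ALPHA) -> FisherResult:
    p = fisher_exact_p(table)
    return FisherResult(p, s_value(p), _is_significant(p, alpha), alpha)


def s_value(p: float) -> float:
    """Shannon transform of a P value: -log2(p), in bits of information.

    An S-value of s carries the surprisal of s consecutive heads from a fair
    coin.  Reporting layers round to 2 decimals.
    """
    if not 0 < p <= 1:
        raise ValidationError(f"p must lie in (0, 1], got {p}")
    return -math.log2(p) + 0.0  # + 0.0 normalises -0.0 at p = 1


def relative_risk(table: FourfoldTable) -> float:
    """Risk in the intervention arm over risk in the control arm.

    Undefined (raises) when the control arm has zero events; no continuity
    correction is applied.
    """
    if table.events_b == 0:
        raise ValidationError(
            "relative risk undefined: control arm has zero events")
    return table.risk_a / table.risk_b


# --------------------------------------------------------------------------
# Fragility indices
# --------------------------------------------------------------------------

def _fi_pick_arm(table: FourfoldTable) -> str:
    """Arm whose event count the FI walk increments: fewer events, tie ->
    smaller arm, still tied -> arm A."""
    if table.events_a != table.events_b:
        return "a" if table.events_a < table.events_b else "b"
    if table.size_a != table.size_b:
        return "a" if table.size_a < table.size_b else "b"
    return "a"


def fragility_index(table: FourfoldTable,
                    alpha: float = DEFAULT_ALPHA) -> FragilityResult:
    """Fragility index: events added to the smaller-event arm of a
    significant result until the exact P rises to alpha or above.

    Baseline P >= alpha gives index 0.  If the chosen arm saturates
    (events = size) before the collapse, the walk continues in the other arm
    and the result is flagged ``saturated``; if both arms saturate the index
    is the "not attainable" sentinel.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    p0 = fisher_exact_p(table)
    trajectory = [p0]
    if not _is_significant(p0, alpha):
        return FragilityResult("fragility", 0, 0.0, tuple(trajectory),
                               table, alpha)
    current = table
    saturated = False
    while True:
        arm = _fi_pick_arm(current)
        if arm == "a" and current.events_a == current.size_a:
            arm, saturated = "b", True
        elif arm == "b" and current.events_b == current.size_b:
            arm, saturated = "a", True
        if ((arm == "a" and current.events_a == current.size_a)
                or (arm == "b" and current.events_b == current.size_b)):
            return FragilityResult("fragility", None, None,
                                   tuple(trajectory), current, alpha,
                                   saturated=True)
        if arm == "a":
            current = current.with_events(current.events_a + 1,
                                          current.events_b)
        else:
            current = current.with_events(current.events_a,
                                          current.events_b + 1)
        p = fisher_exact_p(current)
        trajectory.append(p)
        if not _is_significant(p, alpha):
            k = len(trajectory) - 1
            return FragilityResult("fragility", k,
                                   fragility_quotient(k, table.total_n),
                                   tuple(trajectory), current, alpha,
                                   saturated=saturated)


def _rfi_exact(table: FourfoldTable, alpha: float) -> FourfoldTable | None:
    """Nearest significant table by L1 distance in event counts, or None.

    Ties are broken row-major: smallest events_a, then smallest events_b.
    """
    grid = _p_grid(table.size_a, table.size_b)
    sig = grid < alpha - ALPHA_TOL
    if not sig.any():
        return None
    a = np.arange(table.size_a + 1)[:, None]
    b = np.arange(table.size_b + 1)[None, :]
    dist = np.abs(a - table.events_a) + np.abs(b - table.events_b)
    dist = np.where(sig, dist, np.iinfo(np.int64).max)
    flat = int(np.argmin(dist))
    ta, tb = divmod(flat, table.size_b + 1)
    return table.with_events(int(ta), int(tb))


def _rfi_greedy(table: FourfoldTable,
                alpha: float) -> FourfoldTable | None:
    """Greedy variant: each switch pushes the arm risks further apart,
    choosing whichever admissible move yields the lower P."""
    current = table
    for _ in range(table.size_a + table.size_b):
        if current.risk_a >= current.risk_b:
            moves = []
            if current.events_a < current.size_a:
                moves.append(current.with_events(current.events_a + 1,
                                                 current.events_b))
            if current.events_b > 0:
                moves.append(current.with_events(current.events_a,
                                                 current.events_b - 1))
        else:
            moves = []
            if current.events_b < current.size_b:
                moves.append(current.with_events(current.events_a,
                                                 current.events_b + 1))
            if current.events_a > 0:
                moves.append(current.with_events(current.events_a - 1,
                                                 current.events_b))
        if not moves:
            return None
        current = min(moves, key=fisher_exact_p)
        if _is_significant(fisher_exact_p(current), alpha):
            return current
    return None


def reverse_fragility_index(table: FourfoldTable,
                            alpha: float = DEFAULT_ALPHA,
                            strategy: str = "exact") -> FragilityResult:
    """Reverse fragility index: minimum number of single-patient outcome
    switches (either arm, arm sizes fixed) turning a nonsignificant result
    significant.

    The default strategy finds the exact minimum L1 distance to any table
    with P < alpha by exhaustive search of the event-count grid;
    "greedy-toward-separation" instead walks stepwise away from equal risks.
    Baseline P < alpha gives index 0; if no admissible table is significant
    (tiny samples) the index is the "not attainable" sentinel.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if strategy not in RFI_STRATEGIES:
        raise ValidationError(f"unknown RFI strategy {strategy!r}")
    p0 = fisher_exact_p(table)
    if _is_significant(p0, alpha):
        return FragilityResult("reverse", 0, 0.0, (p0,), table, alpha)
    finder = _rfi_exact if strategy == "exact" else _rfi_greedy
    target = finder(table, alpha)
    if target is None:
        return FragilityResult("reverse", None, None, (p0,), table, alpha)
    # Replay a monotone path to the target; minimality of the target
    # guarantees every intermediate table is still nonsignificant.
    trajectory = [p0]
    current = table
    while current.events_a != target.events_a:
        step = 1 if target.events_a > current.events_a else -1
        current = current.with_events(current.events_a + step,
                                      current.events_b)
        trajectory.append(fisher_exact_p(current))
    while current.events_b != target.events_b:
        step = 1 if target.events_b > current.events_b else -1
        current = current.with_events(current.events_a,
                                      current.events_b + step)
        trajectory.append(fisher_exact_p(current))
    k = len(trajectory) - 1
    return FragilityResult("reverse", k,
                           fragility_quotient(k, table.total_n),
                           tuple(trajectory), current, alpha)


def fragility_quotient(index: int | None, total_n: int) -> float | None:
    """Index relative to the trial's sample size, x100 (percent)."""
    if total_n < 2:
        raise ValidationError("total_n must be >= 2")
    if index is None:
        return None
    if index < 0:
        raise ValidationError("index must be >= 0")
    return 100.0 * index / total_n


# --------------------------------------------------------------------------
# Exact post-hoc power
# --------------------------------------------------------------------------

def posthoc_power(inp: PowerInput, seed: int = DEFAULT_SEED) -> PowerResult:
    """Exact power of the two-sided Fisher test at the given rates.

    Sums Binom(x_a; size_a, rate_a) x Binom(x_b; size_b, rate_b) over all
    outcome pairs whose exact P falls below alpha.  Full enumeration when
    the grid has at most ``ENUMERATION_LIMIT`` cells; otherwise a seeded
    Monte Carlo estimate from ``MC_DRAWS`` simulated trials.
    """
    na, nb = inp.size_a, inp.size_b
    if (na + 1) * (nb + 1) <= ENUMERATION_LIMIT:
        grid = _p_grid(na, nb)
        wa = stats.binom.pmf(np.arange(na + 1), na, inp.rate_a)
        wb = stats.binom.pmf(np.arange(nb + 1), nb, inp.rate_b)
        power = float(np.outer(wa, wb)[grid < inp.alpha - ALPHA_TOL].sum())
        return PowerResult(power, "enumeration")
    rng = np.random.default_rng(seed)
    xa = rng.binomial(na, inp.rate_a, size=MC_DRAWS)
    xb = rng.binomial(nb, inp.rate_b, size=MC_DRAWS)
    pairs, counts = np.unique(np.stack([xa, xb], axis=1), axis=0,
                              return_counts=True)
    hits = sum(int(c) for (a, b), c in zip(pairs, counts)
               if _is_significant(
                   fisher_exact_p(FourfoldTable(int(a), na, int(b), nb)),
                   inp.alpha))
    return PowerResult(hits / MC_DRAWS, "monte-carlo", MC_DRAWS, seed)


# --------------------------------------------------------------------------
# Corpus I/O (CSV schema)
# --------------------------------------------------------------------------

#: Required columns of the corpus CSV; ``reported_p`` is optional.
CSV_COLUMNS = ("study_id", "outcome_label", "outcome_tier",
               "events_intervention", "n_intervention",
               "events_control", "n_control")

_METRIC_COLUMNS = ("fisher_p", "s_value", "fi", "fi_quotient_pct",
                   "rfi", "rfi_quotient_pct", "posthoc_power",
                   "direction", "warnings")


def _parse_count(value, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: {column}={value!r} is not a number") from None
    if not f.is_integer():
        raise ValidationError(
            f"row {row}: {column}={value!r} is not an integer count")
    return int(f)


def read_corpus(path, column_map: dict[str, str] | None = None
                ) -> list[ComparisonRecord]:
    """Read a corpus CSV into validated ComparisonRecords.

    The schema is ``study_id, outcome_label, outcome_tier,
    events_intervention, n_intervention, events_control, n_control
    [, reported_p]`` — comma-delimited, UTF-8, header mandatory, "NA" for
    missing values.  ``column_map`` renames foreign column names onto this
    schema (external-table name -> schema name), so extraction tables
    deposited under other layouts can be loaded without editing the file.

    Raises SchemaError for a missing column and ValidationError (with the
    1-based data row index) for malformed rows; duplicated
    (study_id, outcome_label) pairs are warned about and both kept.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    if column_map:
        df = df.rename(columns=column_map)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"corpus file is missing column {col!r}")
    records: list[ComparisonRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        get = lambda c: getattr(row, c)
        table = FourfoldTable(
            _parse_count(get("events_intervention"),
                         "events_intervention", i),
            _parse_count(get("n_intervention"), "n_intervention", i),
            _parse_count(get("events_control"), "events_control", i),
            _parse_count(get("n_control"), "n_control", i))
        tier = str(get("outcome_tier")).strip().lower()
        if tier not in OUTCOME_TIERS:
            raise ValidationError(
                f"row {i}: outcome_tier {get('outcome_tier')!r} not in "
                f"{OUTCOME_TIERS}")
        reported_p = None
        if "reported_p" in df.columns:
            raw = str(get("reported_p")).strip()
            if raw not in ("", "NA"):
                reported_p = float(raw)
        key = (str(get("study_id")), str(get("outcome_label")))
        if key in seen:
            warnings.warn(f"duplicate comparison {key} at row {i}; "
                          "keeping both", stacklevel=2)
        seen.add(key)
        records.append(ComparisonRecord(
            study_id=str(get("study_id")),
            outcome_label=str(get("outcome_label")),
            outcome_tier=tier, table=table, reported_p=reported_p))
    logger.info("read %d comparisons from %s", len(records), path)
    return records


def write_corpus(path, records: Sequence[ComparisonRecord]) -> None:
    """Write records in the corpus CSV schema (bit-stable round trip)."""
    rows = [{
        "study_id": r.study_id,
        "outcome_label": r.outcome_label,
        "outcome_tier": r.outcome_tier,
        "events_intervention": r.table.events_a,
        "n_intervention": r.table.size_a,
        "events_control": r.table.events_b,
        "n_control": r.table.size_b,
        "reported_p": "NA" if r.reported_p is None else repr(r.reported_p),
    } for r in records]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS) + ["reported_p"]).to_csv(
        path, index=False, encoding="utf-8")


def _fmt6(x) -> str:
    return "NA" if x is None else f"{x:.6g}"


def corpus_metrics(records: Sequence[ComparisonRecord],
                   config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Per-comparison metric table: exact P, S-value, FI, RFI, quotients,
    post-hoc power, and the branch each comparison falls into."""
    rows = []
    for r in records:
        t = r.table
        fres = fisher_result(t, config.alpha)
        fi = fragility_index(t, config.alpha)
        rfi = reverse_fragility_index(t, config.alpha, config.rfi_strategy)
        power = posthoc_power(PowerInput.from_table(t, config.alpha),
                              seed=config.seed)
        warn = []
        if fi.saturated:
            warn.append("fi_saturated")
        if not fi.attainable:
            warn.append("fi_not_attainable")
        if not rfi.attainable:
            warn.append("rfi_not_attainable")
        rows.append({
            "study_id": r.study_id,
            "outcome_label": r.outcome_label,
            "outcome_tier": r.outcome_tier,
            "events_intervention": t.events_a,
            "n_intervention": t.size_a,
            "events_control": t.events_b,
            "n_control": t.size_b,
            "total_n": t.total_n,
            "one_to_one": r.is_one_to_one,
            "fisher_p": fres.p_value,
            "s_value": fres.s_value,
            "fi": fi.index,
            "fi_quotient_pct": fi.quotient,
            "rfi": rfi.index,
            "rfi_quotient_pct": rfi.quotient,
            "posthoc_power": float(power),
            "power_method": power.method,
            "direction": ("fragility" if fres.significant else "reverse"),
            "warnings": ";".join(warn),
        })
    columns = (list(CSV_COLUMNS) + ["total_n", "one_to_one", "fisher_p",
                                    "s_value", "fi", "fi_quotient_pct",
                                    "rfi", "rfi_quotient_pct",
                                    "posthoc_power", "power_method",
                                    "direction", "warnings"])
    return pd.DataFrame(rows, columns=columns)


def write_results(path, records: Sequence[ComparisonRecord],
                  config: RunConfig = RunConfig()) -> pd.DataFrame:
    """Write the input columns plus all per-comparison metrics as CSV.

    Floats are serialised at 6 significant digits and "not attainable"
    sentinels as "NA".  Returns the (unformatted) metric frame.
    """
    frame = corpus_metrics(records, config)
    out = frame.copy()
    for col in ("fisher_p", "s_value", "fi_quotient_pct",
                "rfi_quotient_pct", "posthoc_power"):
        out[col] = [_fmt6(None if pd.isna(v) else v) for v in out[col]]
    for col in ("fi", "rfi"):
        out[col] = ["NA" if pd.isna(v) else str(int(v)) for v in out[col]]
    out.to_csv(path, index=False, encoding="utf-8")
    logger.info("wrote %d result rows to %s", len(out), path)
    return frame


# --------------------------------------------------------------------------
# Corpus statistics
# --------------------------------------------------------------------------

def classify_comparison(record: ComparisonRecord,
                        alpha: float = DEFAULT_ALPHA) -> str:
    """"fragility" if the comparison is significant under the exact test at
    alpha (the FI applies), else "reverse" (the RFI applies)."""
    return ("fragility" if _is_significant(
        fisher_exact_p(record.table), alpha) else "reverse")


def median_iqr(values: Iterable[float]) -> MedianIQR:
    """Median and quartiles by linear interpolation of order statistics
    (the type-7 convention)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or not np.isfinite(arr).all():
        raise ValidationError("median_iqr needs at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return MedianIQR(float(med), float(q1), float(q3), int(arr.size))


def spearman_bootstrap(x: Sequence[float], y: Sequence[float],
                       n_boot: int = DEFAULT_N_BOOT,
                       seed: int = DEFAULT_SEED) -> CorrelationResult:
    """Spearman's rho with a percentile-bootstrap 95% confidence interval.

    rho and its t-approximation P come from the full sample; the CI from
    ``n_boot`` paired (case) resamples, taking the 2.5th/97.5th percentiles
    of the resampled rho.  Resamples where either variable is constant
    yield no rho and are excluded from the percentiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(math.nan, math.nan, math.nan, math.nan,
                                 int(x.size), n_boot, seed, degenerate=True)
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = np.where(denom > 0, (rx * ry).sum(axis=1) / denom, np.nan)
    lo, hi = np.nanpercentile(rhos, [2.5, 97.5])
    return CorrelationResult(float(rho), float(lo), float(hi), float(p),
                             int(x.size), n_boot, seed)


def moods_median_test(sample_1: Sequence[float],
                      sample_2: Sequence[float]) -> MoodResult:
    """Mood's median test: Pearson chi-square (no continuity correction) on
    counts above vs at-or-below the pooled grand median; df = 1.

    Degenerate pooled samples (all values tied at the grand median) return
    a zero statistic with the ``all_tied`` flag set.
    """
    s1 = np.asarray(list(sample_1), dtype=float)
    s2 = np.asarray(list(sample_2), dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValidationError("both samples must be nonempty")
    grand = float(np.median(np.concatenate([s1, s2])))
    try:
        chi2, p, med, counts = stats.median_test(
            s1, s2, ties="below", correction=False)
    except ValueError:
        counts = np.array([[0, 0], [s1.size, s2.size]])
        return MoodResult(0.0, 1, 1.0, grand,
                          tuple(map(tuple, counts.astype(int).tolist())),
                          all_tied=True)
    return MoodResult(float(chi2), 1, float(p), float(med),
                      tuple(map(tuple, counts.astype(int).tolist())))


def _hist_table(values: np.ndarray, width: float) -> dict:
    """Binned counts with cumulative sums (the tabular form of a histogram
    plus its cumulative curve)."""
    if values.size == 0:
        return {"bin_edges": [], "counts": [], "cumulative": []}
    top = max(float(np.max(values)), 0.0)
    edges = np.arange(0.0, top + 2 * width, width)
    counts, edges = np.histogram(values, bins=edges)
    return {"bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts],
            "cumulative": [int(c) for c in np.cumsum(counts)]}


def _corr_or_none(x, y, n_boot, seed, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_n:
        return None
    res = spearman_bootstrap(x[ok], y[ok], n_boot=n_boot, seed=seed)
    return None if res.degenerate else res


def summarize_corpus(records: Sequence[ComparisonRecord],
                     config: RunConfig = RunConfig(),
                     _sensitivity: bool = True) -> CorpusSummary:
    """All corpus-level statistics for a set of trial comparisons.

    Comparisons (not publications) are the analysis unit.  Comparisons are
    split into the fragility branch (significant at alpha; FI applies) and
    the reverse branch (RFI applies).  "Not attainable" indices are excluded
    from medians, quotients and correlations and counted separately.
    Deterministic given (records, config.seed).
    """
    frame = corpus_metrics(records, config)
    n_comp = len(frame)
    n_pub = frame["study_id"].nunique() if n_comp else 0
    frag = frame[frame["direction"] == "fragility"]
    rev = frame[frame["direction"] == "reverse"]
    branch_sizes = {"fragility": len(frag), "reverse": len(rev)}

    fi = frag["fi"].dropna().astype(float).to_numpy()
    fiq = frag["fi_quotient_pct"].dropna().astype(float).to_numpy()
    rfi = rev["rfi"].dropna().astype(float).to_numpy()
    rfiq = rev["rfi_quotient_pct"].dropna().astype(float).to_numpy()
    not_attainable = {
        "fi": int(frag["fi"].isna().sum()),
        "rfi": int(rev["rfi"].isna().sum()),
    }

    def stat_or_none(v):
        return median_iqr(v) if v.size else None

    statd = {"fi": stat_or_none(fi), "fi_quotient_pct": stat_or_none(fiq),
             "rfi": stat_or_none(rfi),
             "rfi_quotient_pct": stat_or_none(rfiq)}

    # Correlation battery; each gets its own child seed for independence.
    nb, seed = config.n_boot, config.seed
    child = {name: int(s) for name, s in zip(
        ("fi_vs_p", "fi_vs_n", "rfi_vs_p", "rfi_vs_n",
         "power_vs_p", "power_vs_fi", "power_vs_rfi"),
        np.random.SeedSequence(seed).generate_state(7) >> 1)}
    power_p = frame if config.power_p_pooled else frag
    fa = frag.dropna(subset=["fi"])
    ra = rev.dropna(subset=["rfi"])
    correlations = {
        "fi_vs_p": _corr_or_none(fa["fi"], fa["fisher_p"], nb,
                                 child["fi_vs_p"]),
        "fi_vs_n": _corr_or_none(fa["fi"], fa["total_n"], nb,
                                 child["fi_vs_n"]),
        "rfi_vs_p": _corr_or_none(ra["rfi"], ra["fisher_p"], nb,
                                  child["rfi_vs_p"]),
        "rfi_vs_n": _corr_or_none(ra["rfi"], ra["total_n"], nb,
                                  child["rfi_vs_n"]),
        "power_vs_p": _corr_or_none(power_p["posthoc_power"],
                                    power_p["fisher_p"], nb,
                                    child["power_vs_p"]),
        "power_vs_fi": _corr_or_none(fa["posthoc_power"], fa["fi"], nb,
                                     child["power_vs_fi"]),
        "power_vs_rfi": _corr_or_none(ra["posthoc_power"], ra["rfi"], nb,
                                      child["power_vs_rfi"]),
    }

    mood = {
        "fi_vs_rfi": (moods_median_test(fi, rfi)
                      if fi.size and rfi.size else None),
        "fi_quotient_vs_rfi_quotient": (moods_median_test(fiq, rfiq)
                                        if fiq.size and rfiq.size else None),
    }

    histograms = {
        "fi": _hist_table(fi, 1.0),
        "fi_quotient_pct": _hist_table(fiq, 1.0),
        "rfi": _hist_table(rfi, 1.0),
        "rfi_quotient_pct": _hist_table(rfiq, 1.0),
    }

    summary = CorpusSummary(n_pub, n_comp, branch_sizes, not_attainable,
                            statd, correlations, mood, histograms, config)
    if _sensitivity:
        subset = [r for r in records if r.is_one_to_one]
        if len(subset) == n_comp:
            # every record 1:1-allocated: subset statistics are identical
            sens = replace(summary)
        else:
            sens = summarize_corpus(subset, config, _sensitivity=False)
        summary = replace(summary, sensitivity=sens)
    return summary


# --------------------------------------------------------------------------
# Synthetic corpora
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Parameters of one synthetic two-arm trial.

    ``n_per_group`` may be given directly or derived from the standard
    two-proportion sample-size formula at (alpha, target_power).
    """

    control_rate: float
    treatment_rate: float
    alpha: float = DEFAULT_ALPHA
    target_power: float = 0.80
    n_per_group: int | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("control_rate", "treatment_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValidationError("alpha and target_power must be in (0,1)")
        if self.n_per_group is not None and self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")

    def resolved_n(self) -> int:
        if self.n_per_group is not None:
            return self.n_per_group
        return required_sample_size(self.treatment_rate, self.control_rate,
                                    self.alpha, self.target_power)


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of a synthetic trial corpus.

    The effect mixture is (null, minimally-powered, large-effect): equal
    rates; sample size set by the two-proportion formula at 80% power and
    alpha 0.05 (so the trial is just big enough to detect its own effect);
    and a strong treatment effect (RR <= 0.2) in a deliberately small trial.
    ``size_range`` bounds the total N of every generated trial.
    """

    n_comparisons: int = 243
    size_range: tuple[int, int] = (30, 243)
    mixture: tuple[float, float, float] = (0.4, 0.4, 0.2)
    tier_mixture: tuple[float, float, float] = (0.35, 0.40, 0.25)
    alpha: float = DEFAULT_ALPHA
    target_power: float = 0.80
    n_unequal: int = 0                  # trials given a 2:1 allocation
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_comparisons < 0:
            raise ValidationError("n_comparisons must be >= 0")
        if not math.isclose(sum(self.mixture), 1.0, abs_tol=1e-9):
            raise ValidationError("effect mixture must sum to 1")
        if not math.isclose(sum(self.tier_mixture), 1.0, abs_tol=1e-9):
            raise ValidationError("tier mixture must sum to 1")
        lo, hi = self.size_range
        if lo < 4 or hi < lo:
            raise ValidationError("size_range must satisfy 4 <= lo <= hi")


def required_sample_size(p1: float, p2: float,
                         alpha: float = DEFAULT_ALPHA,
                         power: float = 0.80) -> int:
    """Per-arm sample size for detecting p1 vs p2, pooled-variance normal
    approximation, rounded up:

        n = (z_{1-a/2} sqrt(2 pbar (1-pbar))
             + z_{1-b} sqrt(p1(1-p1) + p2(1-p2)))^2 / (p1-p2)^2
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    if p1 == p2:
        raise ValidationError("zero effect size: sample size is infinite")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    pbar = (p1 + p2) / 2
    num = (za * math.sqrt(2 * pbar * (1 - pbar))
           + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    return math.ceil(num / (p1 - p2) ** 2)


def simulate_trial(design: TrialDesign, index: int = 0,
                   study_id: str = "synthetic-trial",
                   outcome_label: str = "outcome",
                   outcome_tier: str = "primary",
                   size_a: int | None = None,
                   size_b: int | None = None) -> ComparisonRecord:
    """Draw one comparison: binomial event counts in each arm.

    The event generator is seeded by (design.seed, index), so a fixed design
    and index always reproduce the same record.  ``size_a``/``size_b``
    override the 1:1 ``n_per_group`` for non-equal allocation.
    """
    n = design.resolved_n()
    na = size_a if size_a is not None else n
    nb = size_b if size_b is not None else n
    rng = np.random.default_rng([design.seed, index])
    ea = int(rng.binomial(na, design.treatment_rate))
    eb = int(rng.binomial(nb, design.control_rate))
    return ComparisonRecord(study_id, outcome_label, outcome_tier,
                            FourfoldTable(ea, na, eb, nb))


def _draw_design(rng: np.random.Generator, component: int,
                 config: CorpusConfig) -> tuple[TrialDesign, int]:
    """One trial design from a mixture component; returns (design, n/group).

    Rate distributions are a modelling choice (see the methods note): event
    risks in the ranges paediatric surgical trials typically report, and
    for the large-effect component a FETO-style order-of-magnitude risk
    reduction at small n.
    """
    lo = math.ceil(config.size_range[0] / 2)
    hi = max(config.size_range[1] // 2, lo)
    if component == 0:                  # null: equal rates
        rate = rng.uniform(0.10, 0.60)
        n = int(rng.integers(lo, hi + 1))
        design = TrialDesign(rate, rate, config.alpha, config.target_power,
                             n, config.seed)
    elif component == 1:                # minimally powered at 80% / alpha
        p2 = rng.uniform(0.20, 0.60)
        p1 = max(p2 - rng.uniform(0.15, 0.35), 0.02)
        n = required_sample_size(p1, p2, config.alpha, config.target_power)
        n = int(min(max(n, lo), hi))
        design = TrialDesign(p2, p1, config.alpha, config.target_power,
                             n, config.seed)
    else:                               # large effect, small trial
        p2 = rng.uniform(0.35, 0.70)
        p1 = p2 * rng.uniform(0.05, 0.20)
        n = int(rng.integers(lo, min(40, hi) + 1))
        design = TrialDesign(p2, p1, config.alpha, config.target_power,
                             n, config.seed)
    return design, n


def generate_corpus(config: CorpusConfig = CorpusConfig()
                    ) -> list[ComparisonRecord]:
    """Generate a synthetic corpus of trial comparisons.

    Each comparison draws a design from the effect mixture, simulates
    binomial event counts, and is assigned an outcome tier; consecutive
    comparisons are grouped into publications of 1-5 comparisons, mimicking
    corpora where one publication contributes several 2x2 tables.  The
    first ``n_unequal`` trials get a 2:1 allocation; all others are 1:1.
    Byte-identical output for identical (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    records: list[ComparisonRecord] = []
    study_no, left_in_study = 0, 0
    for i in range(config.n_comparisons):
        if left_in_study == 0:
            study_no += 1
            left_in_study = int(rng.integers(1, 6))
        left_in_study -= 1
        component = int(rng.choice(3, p=config.mixture))
        design, n = _draw_design(rng, component, config)
        tier = OUTCOME_TIERS[int(rng.choice(3, p=config.tier_mixture))]
        size_a = size_b = None
        if i < config.n_unequal:
            size_a, size_b = min(2 * n, config.size_range[1] - n), n
        rec = simulate_trial(design, index=i,
                             study_id=f"synthetic-study-{study_no:03d}",
                             outcome_label=f"outcome-{i + 1:03d}",
                             outcome_tier=tier,
                             size_a=size_a, size_b=size_b)
        records.append(rec)
    logger.info("generated %d comparisons (%d publications), seed %d",
                len(records), study_no if records else 0, config.seed)
    return records
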
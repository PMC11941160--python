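"""Statistical layer: distribution summaries, paralogue correlation,
deletion-strain tests, phase-resolved expression, bud enrichment and
compensation reports.

Per-cell transcript counts are zero-inflated and heavy-tailed, so the
summaries favour quantile ladders (letter values, the basis of boxenplots)
over moments, correlations are plain Pearson on counts (the field's
convention for co-expression), and two-group comparisons use the
Mann-Whitney U test.  Compensation between paralogues is scored as a drop
in the zero-count fraction together with a rise in mean expression of the
surviving gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from yeastfish.exceptions import UndefinedStatisticError
from yeastfish.phases import PHASES


# ---------------------------------------------------------------------------
# letter values (the quantile ladder behind boxenplots)

@dataclass(frozen=True)
class LetterValue:
    tag: str  # M, F, E, D, C, ...
    depth: float
    lower: float
    upper: float


_LETTER_TAGS = "MFEDCBAZYXWVUTSRQPON"


def letter_values(x: Sequence[float], min_tail: int = 8) -> list[LetterValue]:
    """Letter-value ladder of a sample.

    Depths follow the classic recursion d1 = (1 + n) / 2,
    d_(k+1) = (1 + floor(d_k)) / 2; the value at depth d is the average of
    the order statistics at floor(d) and ceil(d), taken from each end.
    The ladder stops once fewer than ``min_tail`` observations would lie at
    or outside the next depth (letter classes thinner than that are noise).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n == 0:
        raise ValueError("empty sample")

    def at_depth(d: float) -> tuple[float, float]:
        lo_i = (int(math.floor(d)) - 1, int(math.ceil(d)) - 1)
        lo = 0.5 * (xs[lo_i[0]] + xs[lo_i[1]])
        hi = 0.5 * (xs[n - 1 - lo_i[0]] + xs[n - 1 - lo_i[1]])
        return lo, hi

    out = []
    d = (1 + n) / 2.0
    for tag in _LETTER_TAGS:
        lo, hi = at_depth(d)
        out.append(LetterValue(tag, d, lo, hi))
        d_next = (1 + math.floor(d)) / 2.0
        if math.floor(d_next) < min_tail or d_next >= d:
            break
        d = d_next
    return out


@dataclass(frozen=True)
class SummaryStats:
    gene: str
    strain: str
    n_cells: int
    mean: float
    zero_fraction: float
    max_count: float
    letter_values: list[LetterValue] = field(default_factory=list)


def summarize(counts: Sequence[float], gene: str = "", strain: str = "") -> SummaryStats:
    """Mean, zero fraction, max and letter values of one gene/strain sample."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty sample")
    return SummaryStats(
        gene=gene,
        strain=strain,
        n_cells=int(c.size),
        mean=float(c.mean()),
        zero_fraction=float((c == 0).mean()),
        max_count=float(c.max()),
        letter_values=letter_values(c) if c.size >= 1 else [],
    )


# ---------------------------------------------------------------------------
# tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def pearson_pair(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation of two aligned count vectors (t-test p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), len(x), len(y), "pearson")


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements per U value (no ties), by recursion.

    c(n1, n2)[u] satisfies c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    if n1 == 0 or n2 == 0:
        return np.array([1.0])
    a = _u_counts(n1 - 1, n2)  # contributes at u - n2
    b = _u_counts(n1, n2 - 1)
    size = n1 * n2 + 1
    out = np.zeros(size)
    out[n2 : n2 + len(a)] += a
    out[: len(b)] += b
    return out


def mw_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> TestResult:
    """Mann-Whitney U test (midranks; exact for small untied samples).

    The statistic is U for the first sample.  With ``n1 + n2 <=
    exact_max_n`` and no ties the p-value comes from full enumeration of
    the U distribution; otherwise from the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < n1 + n2

    if not has_ties and n1 + n2 <= exact_max_n:
        counts = _u_counts(n1, n2)
        total = counts.sum()
        u = int(round(u1))
        p_le = counts[: u + 1].sum() / total
        p_ge = counts[u:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return TestResult(float(u1), float(p), n1, n2, "mann-whitney-exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(float(u1), 1.0, n1, n2, "mann-whitney-normal")
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u1 - mu) - 0.5) / sd
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "less":
        z = (u1 - mu + 0.5) / sd
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        z = (u1 - mu - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(u1), float(min(p, 1.0)), n1, n2, "mann-whitney-normal")


# ---------------------------------------------------------------------------
# table-level reports

def _whole_counts(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    sub = table[(table["gene_id"] == gene) & (table["compartment"] == "whole")]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from table")
    return sub


def phase_resolved(
    table: pd.DataFrame, gene: str, phases: Sequence[str] | None = None
) -> dict[str, tuple[SummaryStats | None, np.ndarray]]:
    """Per-phase summaries and raw count arrays for one gene.

    Phases with no cells are emitted with (None, empty array) so plots can
    show the full cycle.  Unknown phase labels in the table raise.
    """
    sub = _whole_counts(table, gene)
    seen = set(sub["phase"].unique())
    bad = seen - set(PHASES) - {"unassigned"}
    if bad:
        raise ValueError(f"unknown phase labels {sorted(bad)}")
    phases = list(phases) if phases is not None else [p for p in PHASES if p in seen]
    out: dict[str, tuple[SummaryStats | None, np.ndarray]] = {}
    strain = str(sub["strain_id"].iloc[0])
    for ph in phases:
        vals = sub.loc[sub["phase"] == ph, "count"].to_numpy(dtype=float)
        vals = np.sort(vals)
        if vals.size == 0:
            out[ph] = (None, vals)
        else:
            out[ph] = (summarize(vals, gene=gene, strain=strain), vals)
    return out


@dataclass(frozen=True)
class BudEnrichmentReport:
    gene: str
    n_pairs: int
    mean_bud_fraction: float
    p_value_vs_half: float
    per_pair: pd.DataFrame


def bud_enrichment(table: pd.DataFrame, gene: str) -> BudEnrichmentReport:
    """Bud fraction per budded cell and a population test against 0.5.

    ``bud_fraction = bud / (mother + bud)`` for pairs with at least one
    transcript; the Wilcoxon signed-rank test checks symmetry around 0.5.
    """
    sub = table[table["gene_id"] == gene]
    piv = sub[sub["compartment"].isin(["mother", "bud"])].pivot_table(
        index="cell_id", columns="compartment", values="count", aggfunc="first"
    )
    if piv.empty or "bud" not in piv or "mother" not in piv:
        return BudEnrichmentReport(gene, 0, float("nan"), float("nan"), pd.DataFrame())
    piv = piv.dropna()
    total = piv["mother"] + piv["bud"]
    piv = piv[total > 0]
    if piv.empty:
        return BudEnrichmentReport(gene, 0, float("nan"), float("nan"), pd.DataFrame())
    frac = (piv["bud"] / (piv["mother"] + piv["bud"])).rename("bud_fraction")
    diffs = frac - 0.5
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs[diffs != 0]).pvalue) if (diffs != 0).any() else 1.0
    return BudEnrichmentReport(
        gene=gene,
        n_pairs=int(len(frac)),
        mean_bud_fraction=float(frac.mean()),
        p_value_vs_half=p,
        per_pair=frac.reset_index(),
    )


@dataclass(frozen=True)
class CompensationReport:
    gene: str
    paralogue_deleted: str
    delta_zero_fraction: float
    mean_fold_change: float
    overall_test: TestResult
    per_phase_tests: dict[str, TestResult]
    verdict: bool
    thresholds: tuple[float, float]


def compensation_report(
    wt: pd.DataFrame,
    deletion: pd.DataFrame,
    gene: str,
    paralogue_deleted: str = "",
    d: float = 0.10,
    f: float = 1.5,
) -> CompensationReport:
    """Compensation of ``gene`` in a paralogue-deletion strain vs WT.

    delta_zero_fraction = zf(deletion) - zf(WT); mean_fold_change =
    mean(deletion) / mean(WT).  The verdict requires the zero fraction to
    drop by more than ``d`` AND the mean to rise by more than factor ``f``.
    """
    wt_counts = _whole_counts(wt, gene)["count"].to_numpy(dtype=float)
    del_sub = _whole_counts(deletion, gene)
    del_counts = del_sub["count"].to_numpy(dtype=float)
    zf_wt = float((wt_counts == 0).mean())
    zf_del = float((del_counts == 0).mean())
    mean_wt = float(wt_counts.mean())
    mean_del = float(del_counts.mean())
    fold = mean_del / mean_wt if mean_wt > 0 else float("inf") if mean_del > 0 else 1.0
    overall = mw_test(wt_counts, del_counts)
    per_phase = {}
    wt_sub = _whole_counts(wt, gene)
    for ph in PHASES:
        aw = wt_sub.loc[wt_sub["phase"] == ph, "count"].to_numpy(dtype=float)
        ad = del_sub.loc[del_sub["phase"] == ph, "count"].to_numpy(dtype=float)
        if len(aw) and len(ad):
            per_phase[ph] = mw_test(aw, ad)
    delta = zf_del - zf_wt
    return CompensationReport(
        gene=gene,
        paralogue_deleted=paralogue_deleted or str(del_sub["strain_id"].iloc[0]),
        delta_zero_fraction=delta,
        mean_fold_change=fold,
        overall_test=overall,
        per_phase_tests=per_phase,
        verdict=bool(delta < -d and fold > f),
        thresholds=(d, f),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; reports default to raw p-values)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * m / (rank_i + 1))
        adj[i] = running
    return adj
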
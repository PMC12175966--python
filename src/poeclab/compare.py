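"""Per-neuron nonparametric condition comparison and three-way classification.

Each neuron's fluorescence-rate multisets under two conditions are compared with
a two-sided Mann-Whitney U test at alpha = 0.05.  A significant neuron is
labelled ``increased`` or ``decreased`` according to the direction of the shift
(test condition relative to the ``on`` baseline); everything else is ``other``.
Neurons shifted in the same direction in both off-vs-on and fixed-vs-on are
consistent-trend neurons.

The U statistic uses midranks for ties.  The exact two-sided p-value is
obtained by full enumeration of rank assignments when both samples have at most
8 observations; larger samples use the normal approximation with tie correction
and continuity correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .events import RateSet

logger = logging.getLogger(__name__)

__all__ = [
    "MannWhitneyResult",
    "NeuronClassification",
    "TrendResult",
    "mann_whitney_u",
    "classify_neuron",
    "classify_cohort",
    "trend_analysis",
    "proportion_summary",
]

EXACT_MAX_N = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    u_a: float
    u_b: float
    p_value: float
    method: str  # "exact" or "normal_approx"


@dataclass(frozen=True)
class NeuronClassification:
    neuron_id: int
    comparison: str  # "off_vs_on" or "fixed_vs_on"
    label: str  # increased | decreased | other
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    reason: str = ""


@dataclass(frozen=True)
class TrendResult:
    neuron_id: int
    trend: str  # consistent_up | consistent_down | none
    median_on: float
    median_off: float
    median_fixed: float


def _u_from_ranks(pooled: np.ndarray, n_a: int) -> tuple[float, float, np.ndarray]:
    ranks = stats.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    n_b = pooled.size - n_a
    u_a = r_a - n_a * (n_a + 1) / 2.0
    return u_a, n_a * n_b - u_a, ranks


def mann_whitney_u(
    ra: np.ndarray,
    rb: np.ndarray,
    mode: str = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    ``mode`` is "exact" (full enumeration over rank assignments), or
    "normal_approx" (tie- and continuity-corrected), or "auto" (exact when both
    n <= 8).  U_a + U_b = n_a * n_b always holds.
    """
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    if ra.size == 0 or rb.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ConfigurationError(f"unknown mode: {mode!r}")
    n_a, n_b = ra.size, rb.size
    pooled = np.concatenate([ra, rb])
    u_a, u_b, ranks = _u_from_ranks(pooled, n_a)
    use_exact = mode == "exact" or (mode == "auto" and n_a <= EXACT_MAX_N and n_b <= EXACT_MAX_N)
    if use_exact:
        p = _exact_p(ranks, n_a, u_a)
        method = "exact"
    else:
        p = _normal_approx_p(ranks, n_a, n_b, u_a)
        method = "normal_approx"
    return MannWhitneyResult(u_a=u_a, u_b=u_b, p_value=p, method=method)


def _exact_p(ranks: np.ndarray, n_a: int, u_a: float) -> float:
    """Exact two-sided p by enumerating all C(N, n_a) rank assignments.

    The null distribution of U_a (with the observed midranks fixed) is
    symmetric about n_a*n_b/2, so the two-sided p is twice the smaller tail,
    capped at 1.  Half-integer U values from midranks are handled by working in
    doubled units.
    """
    n = ranks.size
    offset = n_a * (n_a + 1)  # doubled units
    u2_obs = int(round(2 * u_a))
    # enumerate doubled rank sums of every subset of size n_a
    ranks2 = np.round(2 * ranks).astype(int)
    u2_values = [sum(c) - offset for c in itertools.combinations(ranks2, n_a)]
    u2_values = np.asarray(u2_values)
    total = u2_values.size
    p_low = np.count_nonzero(u2_values <= u2_obs) / total
    p_high = np.count_nonzero(u2_values >= u2_obs) / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _normal_approx_p(ranks: np.ndarray, n_a: int, n_b: int, u_a: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations tied
    diff = u_a - mu
    # continuity correction shrinks |diff| by 0.5
    z = (abs(diff) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def classify_neuron(
    r_test: RateSet,
    r_on: RateSet,
    alpha: float = 0.05,
    min_events: int = 3,
    mode: str = "auto",
) -> NeuronClassification:
    """Three-way label for one neuron: test condition vs the ``on`` baseline.

    Significant (p < alpha) with the shift favouring the test condition ->
    ``increased``; favouring the baseline -> ``decreased``; otherwise ``other``.
    The direction statistic is U_a versus n_a*n_b/2 (equivalently the
    rank-biserial sign); an exact U tie falls back to the median difference.
    Neurons with fewer than ``min_events`` events in either set are labelled
    ``other`` with reason "insufficient".
    """
    if r_test.neuron_id != r_on.neuron_id:
        raise ConfigurationError("rate sets belong to different neurons")
    comparison = f"{r_test.condition}_vs_{r_on.condition}"
    base = dict(
        neuron_id=r_test.neuron_id,
        comparison=comparison,
        median_a=r_test.median,
        median_b=r_on.median,
        n_a=r_test.n_events,
        n_b=r_on.n_events,
    )
    if r_test.n_events < min_events or r_on.n_events < min_events:
        return NeuronClassification(label="other", p_value=float("nan"), reason="insufficient", **base)
    res = mann_whitney_u(r_test.rates, r_on.rates, mode=mode)
    label = "other"
    if res.p_value < alpha:
        mu = r_test.n_events * r_on.n_events / 2.0
        if res.u_a > mu:
            label = "increased"
        elif res.u_a < mu:
            label = "decreased"
        else:
            label = "increased" if r_test.median > r_on.median else "decreased"
    return NeuronClassification(label=label, p_value=res.p_value, **base)


def classify_cohort(
    rate_sets: list[RateSet],
    alpha: float = 0.05,
    min_events: int = 3,
    mode: str = "auto",
    adjust: str = "none",
) -> pd.DataFrame:
    """Classify every neuron for off-vs-on and fixed-vs-on.

    ``adjust="bh"`` applies Benjamini-Hochberg across neurons within each
    comparison before thresholding (off by default: per-neuron testing at alpha
    with no correction is the primary convention here).
    """
    by_key = {(rs.neuron_id, rs.condition): rs for rs in rate_sets}
    neurons = sorted({rs.neuron_id for rs in rate_sets})
    rows = []
    for comparison_cond in ("off", "fixed"):
        cls_list = []
        for nid in neurons:
            r_test = by_key.get((nid, comparison_cond))
            r_on = by_key.get((nid, "on"))
            if r_test is None or r_on is None:
                continue
            cls_list.append(classify_neuron(r_test, r_on, alpha=alpha, min_events=min_events, mode=mode))
        if adjust == "bh":
            tested = [c for c in cls_list if c.reason != "insufficient"]
            if tested:
                p_adj = stats.false_discovery_control([c.p_value for c in tested])
                relabelled = []
                for c, pa in zip(tested, p_adj):
                    label = c.label if pa < alpha else "other"
                    relabelled.append(
                        NeuronClassification(
                            neuron_id=c.neuron_id, comparison=c.comparison, label=label,
                            p_value=float(pa), median_a=c.median_a, median_b=c.median_b,
                            n_a=c.n_a, n_b=c.n_b, reason=c.reason,
                        )
                    )
                cls_list = relabelled + [c for c in cls_list if c.reason == "insufficient"]
        elif adjust != "none":
            raise ConfigurationError(f"unknown adjustment: {adjust!r}")
        rows.extend(vars(c) for c in cls_list)
    return pd.DataFrame(rows)


def trend_analysis(
    cls_off_vs_on: NeuronClassification,
    cls_fixed_vs_on: NeuronClassification,
    medians: dict[str, float],
    require_significance: bool = True,
) -> TrendResult:
    """Consistent-trend label for one neuron across both comparisons.

    With ``require_significance`` (primary), a neuron is consistent_up iff
    classified ``increased`` in both comparisons (consistent_down likewise).
    With ``require_significance=False`` only the median ordering matters
    (median_off > median_on and median_fixed > median_on, or both below).
    """
    if cls_off_vs_on.neuron_id != cls_fixed_vs_on.neuron_id:
        raise ConfigurationError("classifications belong to different neurons")
    if require_significance:
        labels = (cls_off_vs_on.label, cls_fixed_vs_on.label)
        if labels == ("increased", "increased"):
            trend = "consistent_up"
        elif labels == ("decreased", "decreased"):
            trend = "consistent_down"
        else:
            trend = "none"
    else:
        m_on = medians.get("on", float("nan"))
        m_off = medians.get("off", float("nan"))
        m_fix = medians.get("fixed", float("nan"))
        if m_off > m_on and m_fix > m_on:
            trend = "consistent_up"
        elif m_off < m_on and m_fix < m_on:
            trend = "consistent_down"
        else:
            trend = "none"
    return TrendResult(
        neuron_id=cls_off_vs_on.neuron_id,
        trend=trend,
        median_on=medians.get("on", float("nan")),
        median_off=medians.get("off", float("nan")),
        median_fixed=medians.get("fixed", float("nan")),
    )


def proportion_summary(classifications: pd.DataFrame) -> pd.DataFrame:
    """Stacked percentages of increased/decreased/other per comparison."""
    if classifications.empty:
        raise ConfigurationError("no classifications to summarise")
    rows = []
    for comparison, grp in classifications.groupby("comparison", sort=False):
        n = len(grp)
        counts = grp["label"].value_counts()
        row = {"comparison": comparison, "n_neurons": n}
        for label in ("increased", "decreased", "other"):
            row[f"pct_{label}"] = 100.0 * counts.get(label, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)
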
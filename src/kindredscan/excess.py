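"""Observed-vs-expected excess testing for pedigree case clusters.

For a cluster, the expected case count is the sum of cohort-specific case
rates over its death-certified descendants; the observed count is the
number of qualifying cases among the descendants (all cases, not only the
sampled ones that seeded the cluster).  Significance is the exact one-sided
Poisson upper tail P(X >= observed | lambda = expected); clusters with
p < alpha are flagged high-risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import poisson

from kindredscan.genealogy import CaseCluster, Genealogy
from kindredscan.phenotypes import RateTable, assign_cohort


@dataclass(frozen=True)
class ExcessResult:
    cluster_id: str
    n_descendants: int
    n_death_certified: int
    observed: int
    expected: float
    p_value: float
    high_risk: bool


def expected_cases(cluster: CaseCluster, g: Genealogy, rates: RateTable) -> float:
    """Sum of cohort rates over the cluster's death-certified descendants.

    Descendants are by blood; married-in spouses never contribute.  A
    descendant whose cohort is missing from the rate table contributes 0
    (with a logged warning from the rate lookup).
    """
    cohort_counts: dict = {}
    for ind_id in cluster.descendant_ids:
        ind = g.individual(ind_id)
        if not ind.has_death_certificate:
            continue
        key = assign_cohort(ind)
        cohort_counts[key] = cohort_counts.get(key, 0) + 1
    # grouped summation keeps the whole-population conservation identity
    # (expected == observed) at machine precision
    return math.fsum(n * rates.rate(key) for key, n in cohort_counts.items())


def poisson_upper_tail(observed: int, expected: float) -> float:
    """Exact one-sided upper tail P(X >= observed) for X ~ Poisson(expected).

    Returns 1.0 when observed == 0 (every count is >= 0), and 0.0 for
    observed > 0 with expected == 0 (the degenerate mass-at-zero law).
    """
    if observed < 0:
        raise ValueError(f"observed must be non-negative, got {observed}")
    if expected < 0:
        raise ValueError(f"expected must be non-negative, got {expected}")
    if observed == 0:
        return 1.0
    return float(poisson.sf(observed - 1, expected))


def test_cluster(
    cluster: CaseCluster,
    g: Genealogy,
    case_ids: Iterable[str],
    rates: RateTable,
    alpha: float = 0.05,
) -> ExcessResult:
    """Excess test for one cluster.

    ``case_ids`` is the full population case set; observed counts every
    case among the cluster's descendants, member or not.
    """
    case_set = {str(c) for c in case_ids}
    observed = len(case_set & cluster.descendant_ids)
    expected = expected_cases(cluster, g, rates)
    p = poisson_upper_tail(observed, expected)
    n_dc = sum(
        1 for i in cluster.descendant_ids if g.individual(i).has_death_certificate
    )
    return ExcessResult(
        cluster_id=cluster.cluster_id,
        n_descendants=len(cluster.descendant_ids),
        n_death_certified=n_dc,
        observed=observed,
        expected=expected,
        p_value=p,
        high_risk=p < alpha,
    )


def test_clusters(
    clusters: Iterable[CaseCluster],
    g: Genealogy,
    case_ids: Iterable[str],
    rates: RateTable,
    alpha: float = 0.05,
) -> list[ExcessResult]:
    case_set = {str(c) for c in case_ids}
    return [test_cluster(c, g, case_set, rates, alpha) for c in clusters]


def excess_report(results: Iterable[ExcessResult]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": r.cluster_id,
            "n_descendants": r.n_descendants,
            "n_death_certified": r.n_death_certified,
            "observed": r.observed,
            "expected": r.expected,
            "p_value": r.p_value,
            "high_risk": r.high_risk,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "n_descendants",
            "n_death_certified",
            "observed",
            "expected",
            "p_value",
            "high_risk",
        ],
    )
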
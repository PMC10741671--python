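"""Downstream evaluation of candidate variants.

Counts additional affected carriers from assay genotypes, infers obligate
(untyped but Mendelian-forced) carriers, checks whether additional carriers
are genealogically related to the index pair, tiers the segregation
evidence, and computes the 2x2 case-control odds ratio with a Fisher exact
p-value for external association look-ups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact

from kindredscan.errors import RecordError, UnknownIndividualError
from kindredscan.genealogy import CaseCluster, Genealogy

VariantKey = tuple[str, int, str, str]

CALL_CARRIER = "carrier"
CALL_NONCARRIER = "non-carrier"
CALL_FAILED = "failed"
CALL_INFERRED = "inferred"
_INPUT_CALLS = (CALL_CARRIER, CALL_NONCARRIER, CALL_FAILED)

TIERS = (
    "assay_failed",
    "no_additional",
    "one_additional",
    "multi_additional",
    "unrelated_carriers",
    "full_cosegregation",
)

#: phenotype tokens used in phenotype maps
PHENO_RECURRENT = "recurrent"
PHENO_BREAST = "breast"


@dataclass(frozen=True)
class AssayResult:
    """One genotyping-assay call.  ``inferred`` is never read from input;
    it is only produced by the obligate-carrier logic."""

    variant_key: VariantKey
    individual_id: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in _INPUT_CALLS:
            raise RecordError(
                f"assay call for {self.individual_id!r} must be one of "
                f"{_INPUT_CALLS}, got {self.call!r}"
            )


@dataclass(frozen=True)
class SegregationSummary:
    variant_key: VariantKey
    pedigree_id: str
    n_additional_recurrent_carriers: int
    n_additional_breastcancer_carriers: int
    inferred_carriers: frozenset[str]
    carriers_related_to_pair: bool
    tier: str


@dataclass(frozen=True)
class Assoc2x2:
    """Carrier counts in cases/controls with OR and two-sided Fisher p.

    ``odds_ratio`` is ``inf`` when a zero cell makes ad/bc undefined with a
    non-zero numerator, and ``nan`` for an empty-margin table.
    """

    a: int  # carrier cases
    b: int  # carrier controls
    c: int  # non-carrier cases
    d: int  # non-carrier controls
    odds_ratio: float
    p_value: float


def fisher_or(a: int, b: int, c: int, d: int, haldane: bool = False) -> Assoc2x2:
    """Odds ratio ad/bc and two-sided Fisher exact p for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed table
    (minimum-likelihood two-sided convention).  With ``haldane=True`` the
    odds ratio adds 0.5 to every cell (Haldane-Anscombe correction).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"cell {name} must be non-negative, got {v}")
    if haldane:
        oratio = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        oratio = math.inf if a * d > 0 else math.nan
    else:
        oratio = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return Assoc2x2(a=a, b=b, c=c, d=d, odds_ratio=oratio, p_value=float(p))


def infer_obligate_carriers(
    g: Genealogy,
    typed_carriers: Iterable[str],
    typed_noncarriers: Iterable[str] = (),
) -> set[str]:
    """Untyped individuals forced to carry by Mendelian transmission.

    Assumes a single origin of the variant within the pedigree.  An untyped
    individual is inferred iff, for every ancestor that could be the source
    (an ancestor of all typed carriers, not itself typed non-carrier), the
    individual lies on *every* transmission path from that source to at
    least one typed carrier.  Typed non-carriers can never transmit, so
    paths through them are excluded; consequently an untyped individual
    whose parents are both typed non-carriers is never inferred.
    """
    carriers = {str(c) for c in typed_carriers}
    noncarriers = {str(c) for c in typed_noncarriers}
    for ind_id in carriers | noncarriers:
        if ind_id not in g:
            raise UnknownIndividualError(f"typed individual {ind_id!r} not in genealogy")
    if len(carriers) < 2:
        return set()

    def reachable_down(start: str, blocked: frozenset[str]) -> set[str]:
        """Strict descendants of ``start`` reachable without passing through
        ``blocked`` (the start itself may be in ``blocked``)."""
        seen: set[str] = set()
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for child in g.children(node):
                if child in seen or child in blocked:
                    continue
                seen.add(child)
                frontier.append(child)
        return seen

    no_block = frozenset(noncarriers)
    sources = [
        s
        for s in g.ids
        if s not in noncarriers
        and carriers <= ({s} | reachable_down(s, no_block))
    ]
    if not sources:
        return set()

    untyped = g.ids - carriers - noncarriers
    inferred = set()
    for u in untyped:
        ok_for_all_sources = True
        for s in sources:
            if u == s:
                # the source itself is only forced if it is the unique source;
                # with several possible sources it is not obligate
                on_all_paths_to_some = len(sources) == 1
            else:
                blocked_u = frozenset(noncarriers | {u})
                reach_without_u = {s} | reachable_down(s, blocked_u)
                on_all_paths_to_some = any(
                    c not in reach_without_u for c in carriers
                )
            if not on_all_paths_to_some:
                ok_for_all_sources = False
                break
        if ok_for_all_sources:
            inferred.add(u)
    return inferred


def carrier_relatedness(
    g: Genealogy, carriers: Iterable[str], index_ids: Iterable[str]
) -> tuple[bool, list[set[str]]]:
    """Are additional carriers genealogically connected to the index pair?

    Returns ``(related, components)`` where ``related`` is True iff every
    carrier has kinship > 0 with at least one index member (vacuously True
    for an empty carrier set), and ``components`` partitions the carrier
    set into connected components under pairwise kinship > 0.
    """
    carrier_list = sorted({str(c) for c in carriers})
    index_list = sorted({str(i) for i in index_ids})
    related = all(
        any(g.kinship(c, i) > 0 for i in index_list if i != c) or c in index_list
        for c in carrier_list
    )
    components: list[set[str]] = []
    assigned: set[str] = set()
    for c in carrier_list:
        if c in assigned:
            continue
        comp = {c}
        frontier = [c]
        while frontier:
            x = frontier.pop()
            for y in carrier_list:
                if y not in comp and (x == y or g.kinship(x, y) > 0):
                    comp.add(y)
                    frontier.append(y)
        components.append(comp)
        assigned |= comp
    return related, components


def count_additional_carriers(
    variant_key: VariantKey,
    assay_results: Iterable[AssayResult],
    pedigree: CaseCluster,
    index_pair: tuple[str, str],
    phenotype_map: Mapping[str, str],
    g: Genealogy,
    sequenced_carriers: Iterable[str] = (),
    sequenced_ids: Iterable[str] = (),
    fully_segregates: bool | None = None,
) -> SegregationSummary:
    """Summarize segregation evidence for one candidate variant.

    ``phenotype_map`` maps individual id -> ``"recurrent"`` (recurrent
    breast cancer case) or ``"breast"`` (breast cancer case, recurrence
    status unknown or absent).  Additional *recurrent* carriers are carriers
    with the recurrent phenotype other than the index pair (the other
    sequenced cases count here); additional *breast cancer* carriers are
    carriers with the breast phenotype, including obligate carriers inferred
    from Mendelian transmission (flagged in ``inferred_carriers``).
    """
    pair = {str(i) for i in index_pair}
    seq_carriers = {str(s) for s in sequenced_carriers}
    seq_ids = {str(s) for s in sequenced_ids} | pair
    results = [r for r in assay_results if r.variant_key == variant_key]
    for r in results:
        if r.individual_id not in g:
            raise UnknownIndividualError(
                f"assay result references unknown individual {r.individual_id!r}"
            )
    assay_carriers = {r.individual_id for r in results if r.call == CALL_CARRIER}
    assay_noncarriers = {r.individual_id for r in results if r.call == CALL_NONCARRIER}
    all_failed = bool(results) and all(r.call == CALL_FAILED for r in results)

    if all_failed and not seq_carriers - pair:
        return SegregationSummary(
            variant_key=variant_key,
            pedigree_id=pedigree.cluster_id,
            n_additional_recurrent_carriers=0,
            n_additional_breastcancer_carriers=0,
            inferred_carriers=frozenset(),
            carriers_related_to_pair=True,
            tier="assay_failed",
        )

    typed_carriers = assay_carriers | seq_carriers | pair
    inferred = infer_obligate_carriers(g, typed_carriers, assay_noncarriers)
    carriers = typed_carriers | inferred

    additional_recurrent = {
        c
        for c in carriers - pair
        if phenotype_map.get(c) == PHENO_RECURRENT
    }
    additional_breast = {
        c
        for c in carriers - pair - seq_ids
        if phenotype_map.get(c) == PHENO_BREAST
    }
    additional = additional_recurrent | additional_breast
    related, _ = carrier_relatedness(g, additional, pair)

    if fully_segregates is None:
        fully_segregates = bool(seq_ids - pair) and seq_ids <= carriers

    n_total = len(additional)
    if fully_segregates and additional_recurrent:
        tier = "full_cosegregation"
    elif additional and not related:
        tier = "unrelated_carriers"
    elif n_total == 0:
        tier = "no_additional"
    elif n_total == 1:
        tier = "one_additional"
    else:
        tier = "multi_additional"

    return SegregationSummary(
        variant_key=variant_key,
        pedigree_id=pedigree.cluster_id,
        n_additional_recurrent_carriers=len(additional_recurrent),
        n_additional_breastcancer_carriers=len(additional_breast),
        inferred_carriers=frozenset(inferred),
        carriers_related_to_pair=related,
        tier=tier,
    )


def load_assay_table(path) -> list[AssayResult]:
    """Read a TSV of assay calls: chrom, pos, ref, alt, individual_id, call."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssayResult(
                variant_key=(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
                individual_id=str(row.individual_id),
                call=str(row.call),
            )
        )
    return out


def segregation_report(summaries: Iterable[SegregationSummary]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.variant_key[0],
            "pos": s.variant_key[1],
            "ref": s.variant_key[2],
            "alt": s.variant_key[3],
            "pedigree_id": s.pedigree_id,
            "n_additional_recurrent": s.n_additional_recurrent_carriers,
            "n_additional_breastcancer": s.n_additional_breastcancer_carriers,
            "n_inferred": len(s.inferred_carriers),
            "carriers_related_to_pair": s.carriers_related_to_pair,
            "tier": s.tier,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "pedigree_id",
            "n_additional_recurrent", "n_additional_breastcancer",
            "n_inferred", "carriers_related_to_pair", "tier",
        ],
    )
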
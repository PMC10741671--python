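"""Assay-based segregation evidence, obligate carriers and 2x2 association."""

import math
from fractions import Fraction

import numpy as np
import pytest

from kindredscan.errors import RecordError, UnknownIndividualError
from kindredscan.genealogy import CaseCluster, Genealogy
from kindredscan.segregation import (
    CALL_CARRIER,
    CALL_FAILED,
    CALL_NONCARRIER,
    AssayResult,
    carrier_relatedness,
    count_additional_carriers,
    fisher_or,
    infer_obligate_carriers,
)
from kindredscan.simulate import SimConfig, gene_drop, generate_genealogy

from conftest import build_cosegregation_pedigree, build_paironly_pedigree, ind

KEY = ("7", 76_000_000, "G", "A")


# -- Fisher exact / odds ratio ------------------------------------------------


def _fisher_two_sided_oracle(a, b, c, d) -> float:
    """Independent oracle: exact hypergeometric enumeration with Fractions."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def pmf(x):
        return Fraction(math.comb(c1, x) * math.comb(n - c1, r1 - x), math.comb(n, r1))
    obs = pmf(a)
    total = sum(
        pmf(x)
        for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
        if pmf(x) <= obs
    )
    return float(total)


def test_symmetric_table():
    res = fisher_or(5, 5, 100, 100)
    assert res.odds_ratio == 1.0
    assert res.p_value == pytest.approx(1.0)


def test_or_arithmetic():
    res = fisher_or(10, 5, 7633, 7638)
    assert res.odds_ratio == pytest.approx((10 * 7638) / (5 * 7633))


def test_zero_control_carriers_infinite_or():
    res = fisher_or(4, 0, 7639, 7643)
    assert math.isinf(res.odds_ratio)
    assert res.p_value == pytest.approx(_fisher_two_sided_oracle(4, 0, 7639, 7643), rel=1e-6)
    # balanced margins put this near the 1/8 two-tail mass
    assert res.p_value == pytest.approx(0.125, abs=0.002)


def test_haldane_correction():
    res = fisher_or(4, 0, 10, 10, haldane=True)
    assert res.odds_ratio == pytest.approx((4.5 * 10.5) / (0.5 * 10.5))


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        fisher_or(-1, 0, 1, 1)


def test_fisher_matches_enumeration_oracle_small_margins():
    rng = np.random.default_rng(4)
    tables = [tuple(int(x) for x in rng.integers(0, 50, size=4)) for _ in range(40)]
    tables += [(0, 0, 10, 10), (1, 0, 0, 1), (0, 5, 5, 0), (7, 7, 93, 93)]
    for a, b, c, d in tables:
        if a + b + c + d == 0:
            continue
        assert fisher_or(a, b, c, d).p_value == pytest.approx(
            _fisher_two_sided_oracle(a, b, c, d), rel=1e-6, abs=1e-12
        )


# -- obligate carriers --------------------------------------------------------


def obligate_fixture() -> Genealogy:
    """Grandparent couple as presumed source; untyped parent P with a typed
    carrier child and a typed carrier sibling."""
    return Genealogy(
        [
            ind("G1", sex="male", birth=1880),
            ind("G2", sex="female", birth=1882),
            ind("P", "G1", "G2", sex="female", birth=1905),
            ind("SIB", "G1", "G2", sex="male", birth=1907),
            ind("PH", sex="male", birth=1904),
            ind("CH", "PH", "P", sex="female", birth=1930),
        ]
    )


def test_untyped_parent_on_forced_path_is_inferred():
    g = obligate_fixture()
    inferred = infer_obligate_carriers(g, {"CH", "SIB"})
    assert "P" in inferred
    assert "PH" not in inferred  # married-in spouse is never forced


def test_single_typed_carrier_infers_nothing():
    g = obligate_fixture()
    assert infer_obligate_carriers(g, {"CH"}) == set()


def test_inference_never_contradicts_typed_noncarrier():
    g = obligate_fixture()
    inferred = infer_obligate_carriers(g, {"CH", "SIB"}, typed_noncarriers={"P"})
    assert "P" not in inferred


def test_child_of_two_typed_noncarriers_never_inferred():
    g = Genealogy(
        [
            ind("G1", sex="male"), ind("G2", sex="female"),
            ind("A", "G1", "G2", sex="female", birth=1905),
            ind("B", "G1", "G2", sex="male", birth=1907),
            ind("AH", sex="male"),
            ind("A1", "AH", "A", sex="female", birth=1930),
        ]
    )
    inferred = infer_obligate_carriers(g, {"B", "G1"}, typed_noncarriers={"A", "AH"})
    assert "A1" not in inferred


def test_unknown_typed_id_rejected(nuclear_family):
    with pytest.raises(UnknownIndividualError):
        infer_obligate_carriers(nuclear_family, {"C1", "nope"})


@pytest.mark.parametrize("seed", range(8))
def test_inferred_subset_of_true_carriers_under_gene_drop(seed):
    """Simulation oracle: whatever the obligate logic infers must be a true
    carrier in the drop that produced the typed genotypes."""
    rng = np.random.default_rng(seed)
    g, fathers = generate_genealogy(
        SimConfig(seed=seed, n_founder_couples=1, n_generations=4, mean_offspring=2.5),
        rng,
    )
    dosage = gene_drop(g, fathers[0], rng)
    true_carriers = {i for i, d in dosage.items() if d >= 1}
    if len(true_carriers) < 3:
        return
    typed = set(list(sorted(true_carriers))[::2])
    noncarriers = {i for i, d in dosage.items() if d == 0}
    typed_nc = set(sorted(noncarriers)[::3])
    inferred = infer_obligate_carriers(g, typed, typed_nc)
    assert inferred <= true_carriers - typed


# -- carrier relatedness ------------------------------------------------------


def test_descendant_carriers_are_related(three_generation):
    related, comps = carrier_relatedness(three_generation, {"N1", "N2"}, {"A1", "A2"})
    assert related and len(comps) == 1


def test_unrelated_carriers_three_components():
    g = Genealogy(
        [ind(f"X{i}", sex="female", birth=1900 + i) for i in range(3)]
        + [ind("I1", sex="female"), ind("I2", sex="female")]
    )
    related, comps = carrier_relatedness(g, {"X0", "X1", "X2"}, {"I1", "I2"})
    assert not related
    assert len(comps) == 3


def test_empty_carrier_set_vacuously_related(nuclear_family):
    related, comps = carrier_relatedness(nuclear_family, set(), {"C1"})
    assert related and comps == []


# -- additional-carrier counting ---------------------------------------------


def _cluster_for(g, roots, members):
    desc = frozenset().union(*(g.descendants_of(r) for r in roots))
    return CaseCluster(
        cluster_id="+".join(roots), root_couple=tuple(roots),
        member_cases=frozenset(members), descendant_ids=desc,
    )


def _assays(carriers=(), noncarriers=(), failed=(), key=KEY):
    calls = [AssayResult(key, i, CALL_CARRIER) for i in carriers]
    calls += [AssayResult(key, i, CALL_NONCARRIER) for i in noncarriers]
    calls += [AssayResult(key, i, CALL_FAILED) for i in failed]
    return calls


def test_extended_cosegregation_counts_two_and_seven():
    """Four sequenced recurrent carriers plus six assayed and one obligate
    breast-cancer carrier: 2 additional recurrent, 7 additional breast."""
    g, roles = build_cosegregation_pedigree()
    cluster = _cluster_for(g, ("F0", "M0"), roles["sequenced"])
    phenotypes = {i: "recurrent" for i in roles["recurrent"]}
    phenotypes.update({i: "breast" for i in roles["breast"]})
    summary = count_additional_carriers(
        KEY,
        _assays(carriers=roles["assayed_carriers"], noncarriers=["A'", "B'"]),
        cluster,
        roles["pair"],
        phenotypes,
        g,
        sequenced_carriers=roles["sequenced"],
        sequenced_ids=roles["sequenced"],
    )
    assert summary.n_additional_recurrent_carriers == 2
    assert summary.n_additional_breastcancer_carriers == 7
    assert roles["obligate_bc"] in summary.inferred_carriers
    assert summary.carriers_related_to_pair
    assert summary.tier == "full_cosegregation"


def test_paironly_pedigree_counts_zero_and_two():
    """Pair carries, three other sequenced recurrent cases do not; the two
    additional carriers are non-recurrent breast cancer cases."""
    g, roles = build_paironly_pedigree()
    cluster = _cluster_for(g, ("G", "H"), roles["sequenced"])
    phenotypes = {i: "recurrent" for i in roles["recurrent"]}
    phenotypes.update({i: "breast" for i in roles["breast"]})
    summary = count_additional_carriers(
        KEY,
        _assays(carriers=roles["assayed_carriers"], noncarriers=["U1", "U2", "U3"]),
        cluster,
        roles["pair"],
        phenotypes,
        g,
        sequenced_carriers=roles["pair"],
        sequenced_ids=roles["sequenced"],
        fully_segregates=False,
    )
    assert summary.n_additional_recurrent_carriers == 0
    assert summary.n_additional_breastcancer_carriers == 2
    assert summary.tier == "multi_additional"


def test_all_assays_failed_tier():
    g, roles = build_paironly_pedigree()
    cluster = _cluster_for(g, ("G", "H"), roles["sequenced"])
    summary = count_additional_carriers(
        KEY,
        _assays(failed=["S", "T", "U1"]),
        cluster,
        roles["pair"],
        {},
        g,
    )
    assert summary.tier == "assay_failed"
    assert summary.n_additional_recurrent_carriers == 0
    assert summary.n_additional_breastcancer_carriers == 0


def test_assay_for_unknown_individual_rejected(nuclear_family):
    cluster = _cluster_for(nuclear_family, ("F", "M"), ["C1"])
    with pytest.raises(UnknownIndividualError):
        count_additional_carriers(
            KEY, _assays(carriers=["ghost"]), cluster, ("C1", "C2"), {}, nuclear_family
        )


def test_invalid_assay_call_rejected():
    with pytest.raises(RecordError):
        AssayResult(KEY, "A", "inferred")  # never read from input


def test_tier_partition_of_assayed_variants():
    """A synthetic panel mirroring the reported partition of assayed
    variants: 7 failed / 6 none / 11 one / 1 two / 2 unrelated-multi /
    3 full co-segregation."""
    g, roles = build_cosegregation_pedigree()
    # unrelated singleton carriers live outside the pedigree
    g = Genealogy(
        list(g) + [ind(f"OUT{i}", sex="female", birth=1900 + i) for i in range(5)]
    )
    cluster = _cluster_for(g, ("F0", "M0"), roles["sequenced"])
    phenotypes = {i: "recurrent" for i in roles["recurrent"]}
    phenotypes.update({i: "breast" for i in roles["breast"]})
    phenotypes.update({f"OUT{i}": "breast" for i in range(5)})

    def key(i):
        return ("1", 1000 + i, "A", "T")

    tiers = []
    idx = 0
    specs = (
        [("failed", None)] * 7
        + [("none", None)] * 6
        + [("one", None)] * 11
        + [("two", None)]
        + [("unrelated", ["OUT0", "OUT1", "OUT2"]), ("unrelated", ["OUT3", "OUT4"])]
        + [("coseg", None)] * 3
    )
    for kind, extra in specs:
        k = key(idx)
        idx += 1
        if kind == "failed":
            calls = _assays(failed=["A2", "B2"], key=k)
            seq_carriers, seq_ids, fully = roles["pair"], roles["pair"], None
        elif kind == "none":
            calls = _assays(noncarriers=["A2", "B2"], key=k)
            seq_carriers, seq_ids, fully = roles["pair"], roles["sequenced"], False
        elif kind == "one":
            calls = _assays(carriers=["A2"], key=k)
            seq_carriers, seq_ids, fully = roles["pair"], roles["sequenced"], False
        elif kind == "two":
            calls = _assays(carriers=["A2", "B2"], key=k)
            seq_carriers, seq_ids, fully = roles["pair"], roles["sequenced"], False
        elif kind == "unrelated":
            calls = _assays(carriers=extra, key=k)
            seq_carriers, seq_ids, fully = roles["pair"], roles["sequenced"], False
        else:  # coseg
            calls = _assays(carriers=roles["assayed_carriers"], key=k)
            seq_carriers, seq_ids, fully = (
                roles["sequenced"], roles["sequenced"], None,
            )
        summary = count_additional_carriers(
            k, calls, cluster, roles["pair"], phenotypes, g,
            sequenced_carriers=seq_carriers, sequenced_ids=seq_ids,
            fully_segregates=fully,
        )
        tiers.append(summary.tier)
    from collections import Counter

    assert Counter(tiers) == {
        "assay_failed": 7,
        "no_additional": 6,
        "one_additional": 11,
        "multi_additional": 1,
        "unrelated_carriers": 2,
        "full_cosegregation": 3,
    }
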
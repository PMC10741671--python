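"""Genealogy graph: loading, traversal, kinship, relationships, clusters."""

import io

import numpy as np
import pandas as pd
import pytest

from kindredscan.errors import GenealogyError, UnknownIndividualError
from kindredscan.genealogy import Genealogy, Individual, load_genealogy
from kindredscan.simulate import SimConfig, generate_genealogy

from conftest import ind


# -- loading -----------------------------------------------------------------


def test_empty_table_gives_empty_genealogy():
    df = pd.DataFrame(columns=["id", "father", "mother", "sex", "birth_year"])
    assert len(load_genealogy(df)) == 0


def test_nuclear_family_loads_with_expected_structure():
    tsv = io.StringIO(
        "id\tfather\tmother\tsex\tbirth_year\tbirthplace\n"
        "F\t0\t0\tmale\t1900\t1\n"
        "M\t0\t0\tfemale\t1902\t1\n"
        "C1\tF\tM\tfemale\t1930\t1\n"
        "C2\tF\tM\tmale\t1932\t0\n"
    )
    g = load_genealogy(tsv)
    assert g.founders() == {"F", "M"}
    for child in ("C1", "C2"):
        assert g.ancestors_of(child) == {"F": 1, "M": 1}
    assert not g.individual("C2").birthplace_in_state


def test_ped_dialect_loads():
    ped = io.StringIO(
        "fam1 F 0 0 1 0\nfam1 M 0 0 2 0\nfam1 C1 F M 2 1\n"
    )
    g = load_genealogy(ped, fmt="ped")
    assert g.parents("C1") == ("F", "M")
    assert g.individual("M").sex == "female"


def test_duplicate_id_names_offender():
    with pytest.raises(GenealogyError, match="duplicate.*'X'"):
        Genealogy([ind("X"), ind("X")])


def test_self_parent_is_reported_as_cycle():
    df = pd.DataFrame(
        [{"id": "A", "father": "A", "mother": "0", "sex": "male", "birth_year": 1900}]
    )
    with pytest.raises(GenealogyError, match="cycle"):
        load_genealogy(df)


def test_two_node_cycle_detected():
    with pytest.raises(GenealogyError, match="cycle"):
        Genealogy(
            [
                ind("A", father="B", sex="male"),
                ind("B", father="A", sex="male"),
            ]
        )


def test_parent_sex_inconsistency_rejected():
    with pytest.raises(GenealogyError, match="not male"):
        Genealogy([ind("P", sex="female"), ind("C", father="P")])


def test_unknown_parent_rejected():
    with pytest.raises(GenealogyError, match="unknown father"):
        Genealogy([ind("C", father="ghost")])


def test_death_before_birth_rejected():
    with pytest.raises(GenealogyError, match="precedes"):
        ind("A", birth=1950, death_year=1940)


def test_death_certificate_requires_death_year():
    with pytest.raises(GenealogyError, match="certificate"):
        ind("A", has_death_certificate=True)


# -- traversal ---------------------------------------------------------------


def _brute_force_ancestors(g: Genealogy, start: str) -> dict[str, int]:
    """Independent oracle: exhaustive path enumeration over parent links."""
    best: dict[str, int] = {}

    def walk(node: str, depth: int):
        for parent in g.parents(node):
            if parent is None:
                continue
            if parent not in best or depth + 1 < best[parent]:
                best[parent] = depth + 1
            walk(parent, depth + 1)

    walk(start, 0)
    return best


def _brute_force_descendants(g: Genealogy, start: str) -> set[str]:
    out: set[str] = set()

    def walk(node: str):
        for other in g.ids:
            if start != other and node in g.parents(other) and other not in out:
                out.add(other)
                walk(other)

    walk(start)
    return out


@pytest.fixture(scope="module")
def random_pedigree() -> Genealogy:
    g, _ = generate_genealogy(
        SimConfig(n_founder_couples=2, n_generations=5, mean_offspring=2.0, seed=17),
        np.random.default_rng(17),
    )
    return g


def test_founder_has_no_ancestors_leaf_no_descendants(nuclear_family):
    assert nuclear_family.ancestors_of("F") == {}
    assert nuclear_family.descendants_of("C1") == set()
    assert nuclear_family.descendants_of("F") == {"C1", "C2"}


def test_traversal_matches_brute_force_oracle(random_pedigree):
    g = random_pedigree
    some = sorted(g.ids)[:: max(1, len(g) // 25)]
    for i in some:
        assert g.ancestors_of(i) == _brute_force_ancestors(g, i)
        assert g.descendants_of(i) == _brute_force_descendants(g, i)


def test_ancestor_descendant_duality(random_pedigree):
    g = random_pedigree
    rng = np.random.default_rng(3)
    ids = sorted(g.ids)
    for _ in range(200):
        a, b = rng.choice(ids, size=2, replace=False)
        assert (b in g.descendants_of(a)) == (a in g.ancestors_of(b))


def test_spouses_are_not_descendants(three_generation):
    assert "W1" not in three_generation.descendants_of("GF")
    assert "HN1" not in three_generation.descendants_of("GF")


def test_unknown_id_raises(nuclear_family):
    with pytest.raises(UnknownIndividualError):
        nuclear_family.ancestors_of("nope")
    with pytest.raises(UnknownIndividualError):
        nuclear_family.kinship("F", "nope")


# -- kinship -----------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("GF", "A1", 0.25),       # parent-offspring
        ("A1", "A2", 0.25),       # full siblings
        ("N1", "N2", 0.0625),     # first cousins
        ("A2", "N1", 0.125),      # aunt/niece
        ("GF", "N1", 0.125),      # grandparent
        ("GF", "W1", 0.0),        # no common ancestor
        ("GF", "GF", 0.5),        # self, outbred
    ],
)
def test_kinship_textbook_values(three_generation, a, b, expected):
    assert three_generation.kinship(a, b) == pytest.approx(expected)
    assert three_generation.kinship(b, a) == three_generation.kinship(a, b)


def _mc_gene_drop_kinship(g: Genealogy, a: str, b: str, n: int, seed: int) -> tuple[float, float]:
    """Independent Monte-Carlo oracle: drop uniquely labelled founder
    alleles, estimate P(random allele from each is identical by descent)."""
    rng = np.random.default_rng(seed)
    order = g.topological_order()
    label = 0
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in order:
        f, m = g.parents(i)
        got = []
        for parent in (f, m):
            if parent is None:
                got.append(np.full(n, label))
                label += 1
            else:
                pick = rng.integers(0, 2, size=n).astype(bool)
                pa, pm = alleles[parent]
                got.append(np.where(pick, pa, pm))
        alleles[i] = (got[0], got[1])
    matches = np.zeros(n)
    for x in alleles[a]:
        for y in alleles[b]:
            matches += x == y
    per = matches / 4
    return float(per.mean()), float(per.std(ddof=1) / np.sqrt(n))


def test_kinship_agrees_with_gene_drop_oracle(three_generation):
    for a, b in [("N1", "N2"), ("A2", "N1"), ("A1", "A2")]:
        est, se = _mc_gene_drop_kinship(three_generation, a, b, 100_000, seed=11)
        assert abs(est - three_generation.kinship(a, b)) <= 3 * se


def test_kinship_matches_oracle_on_random_pedigree(random_pedigree):
    g = random_pedigree
    rng = np.random.default_rng(9)
    ids = sorted(g.ids)
    pairs = [tuple(rng.choice(ids, size=2, replace=False)) for _ in range(5)]
    for a, b in pairs:
        est, se = _mc_gene_drop_kinship(g, a, b, 60_000, seed=13)
        assert abs(est - g.kinship(a, b)) <= max(3 * se, 1e-12)


# -- relationship labels -----------------------------------------------------


def test_relationship_labels(three_generation):
    g = three_generation
    assert g.classify_relationship("A1", "A2") == "sibling"
    assert g.classify_relationship("A2", "N1") == "avuncular"
    assert g.classify_relationship("N1", "N2") == "first-cousin"
    assert g.classify_relationship("GF", "A1") == "parent-offspring"
    assert g.classify_relationship("GF", "N1") == "other-related"  # grandparent
    assert g.classify_relationship("N2", "GG1") == "first-cousin-once-removed"
    assert g.classify_relationship("GF", "W1") == "unrelated"


def test_second_cousins_and_half_siblings():
    g = Genealogy(
        [
            ind("GGF", sex="male"), ind("GGM", sex="female"),
            ind("S1", "GGF", "GGM", sex="male", birth=1905),
            ind("S2", "GGF", "GGM", sex="female", birth=1907),
            ind("S1w", sex="female"), ind("S2h", sex="male"),
            ind("K1", "S1", "S1w", sex="male", birth=1930),
            ind("K2", "S2h", "S2", sex="female", birth=1931),
            ind("K1w", sex="female"), ind("K2h", sex="male"),
            ind("L1", "K1", "K1w", sex="female", birth=1955),
            ind("L2", "K2h", "K2", sex="female", birth=1956),
            # half-siblings: same father, different mothers
            ind("Hm1", sex="female"), ind("Hm2", sex="female"),
            ind("HS1", "GGF", "Hm1", sex="male", birth=1906),
        ]
    )
    assert g.classify_relationship("L1", "L2") == "second-cousin"
    assert g.classify_relationship("S1", "HS1") == "other-related"  # half-sibling


def test_self_classification_rejected(nuclear_family):
    with pytest.raises(ValueError):
        nuclear_family.classify_relationship("F", "F")


# -- case clusters -----------------------------------------------------------


def test_two_sibling_cases_cluster_at_parent_couple(nuclear_family):
    clusters = nuclear_family.find_case_clusters({"C1", "C2"})
    assert len(clusters) == 1
    (c,) = clusters
    assert c.root_couple == ("F", "M")
    assert c.member_cases == {"C1", "C2"}


def test_dedup_keeps_most_recent_couple(three_generation):
    # N1 and N2 cluster under GF+GM only (their parents root singleton sets)
    clusters = three_generation.find_case_clusters({"N1", "N2"})
    assert [c.root_couple for c in clusters] == [("GF", "GM")]


def test_disjoint_singletons_give_no_clusters(overlap_pedigree):
    assert overlap_pedigree.find_case_clusters({"Y", "Z"}) == []


def test_case_in_two_clusters_through_different_ancestors(overlap_pedigree):
    clusters = overlap_pedigree.find_case_clusters({"X", "Y", "Z"})
    member_sets = {c.member_cases for c in clusters}
    assert member_sets == {frozenset({"X", "Y"}), frozenset({"X", "Z"})}
    containing_x = [c for c in clusters if "X" in c.member_cases]
    assert len(containing_x) == 2


def test_min_cases_one_is_superset_of_two(overlap_pedigree):
    g = overlap_pedigree
    cases = {"X", "Y", "Z"}
    two = {c.member_cases for c in g.find_case_clusters(cases, min_cases=2)}
    one = {c.member_cases for c in g.find_case_clusters(cases, min_cases=1)}
    assert two <= one


def test_cluster_invariants_hold(overlap_pedigree):
    for c in overlap_pedigree.find_case_clusters({"X", "Y", "Z"}, min_cases=1):
        assert c.member_cases <= c.descendant_ids
        for root in c.root_couple:
            assert root not in c.descendant_ids


def test_unknown_case_ids_listed():
    g = Genealogy([ind("A")])
    with pytest.raises(UnknownIndividualError, match="B.*C|C.*B"):
        g.find_case_clusters({"A", "B", "C"}, min_cases=1)
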
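"""Shared pedigree fixtures.  All fixtures are synthetic constructions."""

import pytest

from kindredscan.genealogy import Genealogy, Individual


def ind(id, father=None, mother=None, sex="female", birth=1900, **kw):
    return Individual(
        id=id, father_id=father, mother_id=mother, sex=sex, birth_year=birth, **kw
    )


@pytest.fixture
def nuclear_family() -> Genealogy:
    """Two founders and two children."""
    return Genealogy(
        [
            ind("F", sex="male", birth=1900),
            ind("M", sex="female", birth=1902),
            ind("C1", "F", "M", sex="female", birth=1930),
            ind("C2", "F", "M", sex="male", birth=1932),
        ]
    )


@pytest.fixture
def three_generation() -> Genealogy:
    """Founder couple, two married children, grandchildren (first cousins),
    and one great-grandchild; includes an aunt/niece pair (A2, N1)."""
    return Genealogy(
        [
            ind("GF", sex="male", birth=1880),
            ind("GM", sex="female", birth=1882),
            ind("A1", "GF", "GM", sex="male", birth=1905),
            ind("A2", "GF", "GM", sex="female", birth=1907),
            ind("W1", sex="female", birth=1906),
            ind("H2", sex="male", birth=1905),
            ind("N1", "A1", "W1", sex="female", birth=1930),
            ind("N2", "H2", "A2", sex="female", birth=1931),
            ind("HN1", sex="male", birth=1929),
            ind("GG1", "HN1", "N1", sex="female", birth=1955),
        ]
    )


@pytest.fixture
def overlap_pedigree() -> Genealogy:
    """One individual descending from two unrelated founder couples, each
    shared with a different second case: X is in the A-line and the B-line."""
    return Genealogy(
        [
            ind("FA", sex="male", birth=1880),
            ind("MA", sex="female", birth=1882),
            ind("FB", sex="male", birth=1881),
            ind("MB", sex="female", birth=1883),
            ind("P1", "FA", "MA", sex="male", birth=1905),
            ind("P2", "FB", "MB", sex="female", birth=1907),
            ind("X", "P1", "P2", sex="female", birth=1932),
            ind("Y", "FA", "MA", sex="female", birth=1908),
            ind("Z", "FB", "MB", sex="female", birth=1909),
        ]
    )


def build_cosegregation_pedigree():
    """Synthetic extended pedigree mirroring the structure of a large
    founder-couple pedigree with four sequenced recurrent cases (a cousin
    pair plus two), six assayed breast-cancer carriers and one untyped
    breast-cancer case forced to carry by transmission (obligate).

    Returns (genealogy, roles) where roles maps semantic names to ids.
    """
    people = [
        ind("F0", sex="male", birth=1820),
        ind("M0", sex="female", birth=1822),
        # five children of the founder couple; E stays untyped
        ind("A", "F0", "M0", sex="female", birth=1848),
        ind("B", "F0", "M0", sex="male", birth=1850),
        ind("C", "F0", "M0", sex="female", birth=1852),
        ind("D", "F0", "M0", sex="male", birth=1854),
        ind("E", "F0", "M0", sex="female", birth=1856),
        # married-in spouses
        ind("A'", sex="male", birth=1847),
        ind("B'", sex="female", birth=1851),
        ind("C'", sex="male", birth=1851),
        ind("D'", sex="female", birth=1855),
        ind("E'", sex="male", birth=1855),
        # grandchildren
        ind("A1", "A'", "A", sex="female", birth=1875),   # sequenced, pair
        ind("A2", "A'", "A", sex="female", birth=1877),   # assayed bc carrier
        ind("B1", "B", "B'", sex="female", birth=1878),   # sequenced, pair
        ind("B2", "B", "B'", sex="female", birth=1880),   # assayed bc carrier
        ind("C1", "C'", "C", sex="female", birth=1879),   # sequenced carrier
        ind("C2", "C'", "C", sex="female", birth=1881),   # assayed bc carrier
        ind("D1", "D", "D'", sex="female", birth=1882),   # sequenced carrier
        ind("D2", "D", "D'", sex="male", birth=1884),     # assayed bc carrier (male bc)
        ind("E1", "E'", "E", sex="female", birth=1883),   # assayed bc carrier
        ind("E2", "E'", "E", sex="male", birth=1885),     # assayed bc carrier (male bc)
    ]
    g = Genealogy(people)
    roles = {
        "pair": ("A1", "B1"),
        "sequenced": ["A1", "B1", "C1", "D1"],
        "assayed_carriers": ["A2", "B2", "C2", "D2", "E1", "E2"],
        "obligate_bc": "E",
        "recurrent": {"A1", "B1", "C1", "D1"},
        "breast": {"A2", "B2", "C2", "D2", "E1", "E2", "E"},
    }
    return g, roles


def build_paironly_pedigree():
    """Synthetic pedigree mirroring a cousin pair whose variant is absent
    from the three other sequenced recurrent cases: the pair's parents are
    the two additional (non-recurrent) breast cancer carriers."""
    people = [
        ind("G", sex="male", birth=1850),
        ind("H", sex="female", birth=1852),
        ind("S", "G", "H", sex="male", birth=1875),     # bc case, assay carrier
        ind("T", "G", "H", sex="female", birth=1877),   # bc case, assay carrier
        ind("U", "G", "H", sex="female", birth=1879),
        ind("S'", sex="female", birth=1876),
        ind("T'", sex="male", birth=1876),
        ind("U'", sex="male", birth=1878),
        ind("P1", "S", "S'", sex="female", birth=1900),  # sequenced, pair
        ind("P2", "T'", "T", sex="female", birth=1902),  # sequenced, pair
        ind("U1", "U'", "U", sex="female", birth=1901),  # sequenced non-carrier
        ind("U2", "U'", "U", sex="female", birth=1903),  # sequenced non-carrier
        ind("U3", "U'", "U", sex="female", birth=1905),  # sequenced non-carrier
    ]
    g = Genealogy(people)
    roles = {
        "pair": ("P1", "P2"),
        "sequenced": ["P1", "P2", "U1", "U2", "U3"],
        "assayed_carriers": ["S", "T"],
        "recurrent": {"P1", "P2", "U1", "U2", "U3"},
        "breast": {"S", "T"},
    }
    return g, roles
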
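"""Population genealogy graph: ancestry, kinship, relationships, case clusters.

The genealogy is a directed acyclic graph with parent -> child edges built
from per-individual father/mother references (a trio table).  Individuals
with no recorded parents are treated as population founders.  All queries
(ancestor/descendant sets, the kinship coefficient, relationship labels,
case-cluster discovery) operate on this graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from kindredscan.errors import GenealogyError, UnknownIndividualError

FEMALE = "female"
MALE = "male"

_SEX_CODES = {
    "female": FEMALE, "f": FEMALE, "2": FEMALE,
    "male": MALE, "m": MALE, "1": MALE,
}

#: Relationship labels, ordered from closest to most remote; ties between
#: equally-close connections resolve toward the earlier label.
RELATIONSHIP_LABELS = (
    "parent-offspring",
    "sibling",
    "avuncular",
    "first-cousin",
    "first-cousin-once-removed",
    "second-cousin",
    "other-related",
    "unrelated",
)


@dataclass(frozen=True)
class Individual:
    """One genealogy member with vital-record attributes.

    ``father_id``/``mother_id`` are ``None`` for founders.  ``cause_codes``
    holds abstract cause-of-death tokens from the linked death certificate.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = FEMALE
    birth_year: int | None = None
    birthplace_in_state: bool = True
    death_year: int | None = None
    has_death_certificate: bool = False
    cause_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise GenealogyError(f"individual {self.id!r}: invalid sex {self.sex!r}")
        if (
            self.death_year is not None
            and self.birth_year is not None
            and self.death_year < self.birth_year
        ):
            raise GenealogyError(
                f"individual {self.id!r}: death year {self.death_year} precedes "
                f"birth year {self.birth_year}"
            )
        if self.has_death_certificate and self.death_year is None:
            raise GenealogyError(
                f"individual {self.id!r}: death certificate without a death year"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class CaseCluster:
    """A set of sampled cases descending from a common ancestor (couple).

    ``root_couple`` is a 1- or 2-tuple of ids; ``member_cases`` are the
    sampled case ids that define the cluster; ``descendant_ids`` is the
    union of strict descendants of the root individuals (married-in spouses
    are not descendants).  Clusters from different roots may overlap.
    """

    cluster_id: str
    root_couple: tuple[str, ...]
    member_cases: frozenset[str]
    descendant_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_cases <= self.descendant_ids:
            raise GenealogyError(
                f"cluster {self.cluster_id}: member cases outside descendant set"
            )


class Genealogy:
    """Validated, immutable view of a population pedigree."""

    def __init__(self, individuals: Iterable[Individual]):
        self._individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._individuals:
                raise GenealogyError(f"duplicate individual id {ind.id!r}")
            self._individuals[ind.id] = ind
        self._validate_parents()
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self._individuals)
        for ind in self._individuals.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    self._graph.add_edge(parent, ind.id)
        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise GenealogyError(f"genealogy contains a cycle: {path}")
        self._depth: dict[str, int] = {}
        for node in nx.topological_sort(self._graph):
            parents = list(self._graph.predecessors(node))
            self._depth[node] = 1 + max((self._depth[p] for p in parents), default=-1)
        self._kinship_memo: dict[tuple[str, str], float] = {}

    def _validate_parents(self) -> None:
        for ind in self._individuals.values():
            if ind.father_id is not None:
                father = self._individuals.get(ind.father_id)
                if father is None:
                    raise GenealogyError(
                        f"individual {ind.id!r}: unknown father {ind.father_id!r}"
                    )
                if father.sex != MALE:
                    raise GenealogyError(
                        f"individual {ind.id!r}: father {father.id!r} is not male"
                    )
            if ind.mother_id is not None:
                mother = self._individuals.get(ind.mother_id)
                if mother is None:
                    raise GenealogyError(
                        f"individual {ind.id!r}: unknown mother {ind.mother_id!r}"
                    )
                if mother.sex != FEMALE:
                    raise GenealogyError(
                        f"individual {ind.id!r}: mother {mother.id!r} is not female"
                    )

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._individuals

    def __iter__(self):
        return iter(self._individuals.values())

    @property
    def ids(self) -> set[str]:
        return set(self._individuals)

    def individual(self, ind_id: str) -> Individual:
        try:
            return self._individuals[ind_id]
        except KeyError:
            raise UnknownIndividualError(f"unknown individual id {ind_id!r}") from None

    def parents(self, ind_id: str) -> tuple[str | None, str | None]:
        ind = self.individual(ind_id)
        return ind.father_id, ind.mother_id

    def children(self, ind_id: str) -> set[str]:
        self.individual(ind_id)
        return set(self._graph.successors(ind_id))

    def founders(self) -> set[str]:
        return {i for i, ind in self._individuals.items() if ind.is_founder}

    def generation_depth(self, ind_id: str) -> int:
        """Longest parent-chain length from any founder down to ``ind_id``."""
        self.individual(ind_id)
        return self._depth[ind_id]

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-children."""
        return sorted(self._individuals, key=lambda i: (self._depth[i], i))

    def with_death_records(self, deaths: pd.DataFrame) -> "Genealogy":
        """Return a copy with death year / certificate / cause codes attached.

        ``deaths`` columns: individual_id, death_year, cause_codes
        (semicolon-separated tokens).
        """
        updated = dict(self._individuals)
        for row in deaths.itertuples(index=False):
            ind_id = str(row.individual_id)
            if ind_id not in updated:
                raise UnknownIndividualError(
                    f"death record for unknown individual {ind_id!r}"
                )
            causes = _parse_causes(getattr(row, "cause_codes", ""))
            updated[ind_id] = replace(
                updated[ind_id],
                death_year=int(row.death_year),
                has_death_certificate=True,
                cause_codes=causes,
            )
        return Genealogy(updated.values())

    # -- traversal ----------------------------------------------------------

    def ancestors_of(self, ind_id: str) -> dict[str, int]:
        """All strict ancestors mapped to their minimal meiosis depth."""
        self.individual(ind_id)
        depths: dict[str, int] = {}
        frontier = [(ind_id, 0)]
        while frontier:
            current, d = frontier.pop()
            for parent in self._graph.predecessors(current):
                if parent not in depths or depths[parent] > d + 1:
                    depths[parent] = d + 1
                    frontier.append((parent, d + 1))
        return depths

    def descendants_of(self, ind_id: str) -> set[str]:
        """All strict descendants (married-in spouses excluded)."""
        self.individual(ind_id)
        return set(nx.descendants(self._graph, ind_id))

    # -- kinship ------------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) in [0, 0.5].

        Probability that one allele drawn at random from each individual is
        identical by descent, under the standard recursion with founders
        assumed unrelated and non-inbred.  phi(parent, offspring) = 1/4 for
        an outbred pair; first cousins 1/16.
        """
        self.individual(a)
        self.individual(b)
        return self._phi(a, b)

    def _phi(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        memo = self._kinship_memo
        if key in memo:
            return memo[key]
        if a == b:
            fa, ma = self.parents(a)
            value = 0.5 + 0.5 * self._phi(fa, ma)
        else:
            # recurse on the individual farther from the founders so the
            # other can never be its descendant
            if self._depth[b] < self._depth[a]:
                a, b = b, a
            fb, mb = self.parents(b)
            value = 0.5 * (self._phi(a, fb) + self._phi(a, mb))
        memo[key] = value
        return value

    # -- relationship labels -------------------------------------------------

    def classify_relationship(self, a: str, b: str) -> str:
        """Label the closest genealogical connection between two individuals.

        The label derives from the minimal meiosis path(s) through the
        nearest common ancestor(s); collateral labels (sibling, avuncular,
        cousin) require a full relationship, i.e. a shared ancestral
        *couple*.  Half-relationships and anything more remote than second
        cousins are labelled ``other-related``.
        """
        self.individual(a)
        self.individual(b)
        if a == b:
            raise ValueError("cannot classify an individual against itself")
        anc_a = self.ancestors_of(a)
        anc_a[a] = 0
        anc_b = self.ancestors_of(b)
        anc_b[b] = 0
        common = set(anc_a) & set(anc_b)
        if not common:
            return "unrelated"
        best_total = min(anc_a[c] + anc_b[c] for c in common)
        nearest = [c for c in common if anc_a[c] + anc_b[c] == best_total]
        labels = set()
        for c in nearest:
            da, db = anc_a[c], anc_b[c]
            lo, hi = min(da, db), max(da, db)
            if lo == 0:
                labels.add("parent-offspring" if hi == 1 else "other-related")
                continue
            full = any(
                other != c
                and anc_a.get(other) == da
                and anc_b.get(other) == db
                and self._are_couple(c, other)
                for other in nearest
            )
            collateral = {
                (1, 1): "sibling",
                (1, 2): "avuncular",
                (2, 2): "first-cousin",
                (2, 3): "first-cousin-once-removed",
                (3, 3): "second-cousin",
            }.get((lo, hi))
            labels.add(collateral if full and collateral else "other-related")
        for label in RELATIONSHIP_LABELS:
            if label in labels:
                return label
        return "other-related"

    def _are_couple(self, a: str, b: str) -> bool:
        """True when two individuals have at least one child together."""
        for child in self._graph.successors(a):
            f, m = self.parents(child)
            if {f, m} == {a, b}:
                return True
        return False

    # -- case clusters -------------------------------------------------------

    def find_case_clusters(
        self, case_ids: Iterable[str], min_cases: int = 2
    ) -> list[CaseCluster]:
        """Discover all clusters of >= ``min_cases`` cases under a common ancestor.

        Every ancestor whose strict-descendant set contains at least
        ``min_cases`` of ``case_ids`` defines a candidate cluster; clusters
        with identical member-case sets are deduplicated by retaining the
        most recent common ancestor, paired with a co-parent spouse when one
        roots the same member set.  Overlapping clusters with distinct
        member sets are all returned.
        """
        case_set = {str(c) for c in case_ids}
        missing = sorted(c for c in case_set if c not in self._individuals)
        if missing:
            raise UnknownIndividualError(
                f"case ids absent from genealogy: {', '.join(missing)}"
            )
        if min_cases < 1:
            raise ValueError("min_cases must be >= 1")

        # case-descendant sets, computed children-last so each node reuses
        # its children's sets
        case_desc: dict[str, frozenset[str]] = {}
        for node in reversed(list(nx.topological_sort(self._graph))):
            acc: set[str] = set()
            for child in self._graph.successors(node):
                acc |= case_desc[child]
                if child in case_set:
                    acc.add(child)
            case_desc[node] = frozenset(acc)

        by_members: dict[frozenset[str], list[str]] = {}
        for node, members in case_desc.items():
            if len(members) >= min_cases:
                by_members.setdefault(members, []).append(node)

        clusters: list[CaseCluster] = []
        for members, roots in by_members.items():
            # most recent root = smallest descendant set (fewest generations
            # above the cases); deterministic tie-break on id
            sized = sorted(roots, key=lambda r: (len(self.descendants_of(r)), r))
            root = sized[0]
            partner = next(
                (
                    other
                    for other in sized[1:]
                    if len(self.descendants_of(other)) == len(self.descendants_of(root))
                    and self._are_couple(root, other)
                ),
                None,
            )
            couple = tuple(sorted((root, partner))) if partner else (root,)
            desc = frozenset().union(*(self.descendants_of(r) for r in couple))
            clusters.append(
                CaseCluster(
                    cluster_id="+".join(couple),
                    root_couple=couple,
                    member_cases=members,
                    descendant_ids=desc,
                )
            )
        clusters.sort(key=lambda c: c.cluster_id)
        return clusters


def population_cluster(g: Genealogy, case_ids: Iterable[str]) -> CaseCluster:
    """A pseudo-cluster spanning the whole population.

    Used for conservation checks: when the excess test is applied to the
    very population the rates were estimated from, expected equals observed.
    """
    return CaseCluster(
        cluster_id="__population__",
        root_couple=(),
        member_cases=frozenset(str(c) for c in case_ids),
        descendant_ids=frozenset(g.ids),
    )


# -- loading ----------------------------------------------------------------

_TRIO_REQUIRED = ("id", "father", "mother", "sex", "birth_year")


def _parse_causes(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(";") if tok.strip())


def _parse_parent(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text in ("", "0", "0.0", "nan", "NA", "."):
        return None
    return text


def _parse_sex(raw, ind_id: str) -> str:
    try:
        return _SEX_CODES[str(raw).strip().lower()]
    except KeyError:
        raise GenealogyError(f"individual {ind_id!r}: invalid sex {raw!r}") from None


def _coerce_bool(raw) -> bool:
    if isinstance(raw, bool):
        return raw
    text = str(raw).strip().lower()
    return text in ("1", "true", "t", "yes", "y", "1.0")


def load_genealogy(source, fmt: str = "auto") -> Genealogy:
    """Load a genealogy from a trio table or a PED-compatible file.

    ``source`` is a path, file-like object, or DataFrame.  The trio dialect
    is delimited text (TSV or CSV) with header columns ``id, father, mother,
    sex, birth_year, birthplace`` and optional ``death_year, death_cert,
    cause_codes``; 0/empty marks a missing parent.  The PED dialect is the
    headerless 6-column ``fam id father mother sex phenotype`` layout with
    sex coded 1=male / 2=female.
    """
    if fmt == "ped":
        return _from_ped(source)
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = _read_table(source, fmt)
    if fmt == "auto" and "id" not in df.columns:
        raise GenealogyError(
            "table lacks trio headers; pass fmt='ped' for headerless PED input"
        )
    missing = [c for c in _TRIO_REQUIRED if c not in df.columns]
    if missing:
        raise GenealogyError(f"trio table missing columns: {', '.join(missing)}")
    individuals = []
    for row in df.itertuples(index=False):
        ind_id = str(row.id).strip()
        father = _parse_parent(row.father)
        mother = _parse_parent(row.mother)
        if father == ind_id or mother == ind_id:
            raise GenealogyError(
                f"genealogy contains a cycle: {ind_id} is its own parent"
            )
        birth = getattr(row, "birth_year", None)
        death = getattr(row, "death_year", None)
        death = None if death is None or pd.isna(death) else int(death)
        individuals.append(
            Individual(
                id=ind_id,
                father_id=father,
                mother_id=mother,
                sex=_parse_sex(row.sex, ind_id),
                birth_year=None if birth is None or pd.isna(birth) else int(birth),
                birthplace_in_state=_coerce_bool(getattr(row, "birthplace", True)),
                death_year=death,
                has_death_certificate=_coerce_bool(getattr(row, "death_cert", False)),
                cause_codes=_parse_causes(getattr(row, "cause_codes", None)),
            )
        )
    return Genealogy(individuals)


def _read_table(source, fmt: str) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, sep=None, engine="python", dtype=str)
    return pd.read_csv(source, sep=None, engine="python", dtype=str)


def _from_ped(source) -> Genealogy:
    if isinstance(source, pd.DataFrame):
        df = source
        df.columns = ["fam", "id", "father", "mother", "sex", "phenotype"][
            : len(df.columns)
        ]
    else:
        df = pd.read_csv(
            source,
            sep=r"\s+",
            header=None,
            dtype=str,
            names=["fam", "id", "father", "mother", "sex", "phenotype"],
        )
    individuals = []
    for row in df.itertuples(index=False):
        ind_id = str(row.id).strip()
        father = _parse_parent(row.father)
        mother = _parse_parent(row.mother)
        if father == ind_id or mother == ind_id:
            raise GenealogyError(
                f"genealogy contains a cycle: {ind_id} is its own parent"
            )
        individuals.append(
            Individual(
                id=ind_id,
                father_id=father,
                mother_id=mother,
                sex=_parse_sex(row.sex, ind_id),
                birth_year=None,
            )
        )
    return Genealogy(individuals)


def genealogy_to_trio_frame(g: Genealogy) -> pd.DataFrame:
    """Serialize a genealogy back to the trio-table layout."""
    rows = []
    for ind_id in g.topological_order():
        ind = g.individual(ind_id)
        rows.append(
            {
                "id": ind.id,
                "father": ind.father_id or "0",
                "mother": ind.mother_id or "0",
                "sex": ind.sex,
                "birth_year": ind.birth_year,
                "birthplace": int(ind.birthplace_in_state),
                "death_year": ind.death_year if ind.death_year is not None else "",
                "death_cert": int(ind.has_death_certificate),
                "cause_codes": ";".join(sorted(ind.cause_codes)),
            }
        )
    return pd.DataFrame(rows)
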
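"""Recurrent-case classification, cohort assignment and cohort rate estimation.

A *recurrent breast cancer* case is operationally defined as a female with a
registry diagnosis of primary breast cancer whose linked death certificate
lists breast cancer as a cause of death at least ``min_lag_years`` (default
10) years after the earliest diagnosis.  Population cohorts are keyed by
sex, five-year birth bin and in-state birth; cohort rates are the fraction
of death-certified cohort members who are recurrent cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from kindredscan.errors import RecordError
from kindredscan.genealogy import FEMALE, Genealogy, Individual

logger = logging.getLogger(__name__)

BREAST_SITE = "breast"
#: abstract cause-of-death token standing in for the breast-cancer ICD codes
BREAST_CAUSE = "C50"


class CohortKey(NamedTuple):
    """Cohort identity: sex, start year of the 5-year birth bin, in-state birth."""

    sex: str
    birth_bin: int
    in_state: bool


def assign_cohort(ind: Individual) -> CohortKey:
    """Deterministic cohort key; birth bins are [5k, 5k+5) anchored at 0."""
    if ind.birth_year is None:
        raise RecordError(f"individual {ind.id!r} has no birth year")
    return CohortKey(ind.sex, 5 * (ind.birth_year // 5), ind.birthplace_in_state)


@dataclass(frozen=True)
class RateTable:
    """Cohort -> (case count, denominator count, rate) mapping.

    The denominator for each cohort is its number of death-certified
    individuals; the rate is cases / denominator (0 when the denominator is
    0).  Lookups for cohorts absent from the table return 0 with a logged
    warning, mirroring the convention that an unobserved cohort contributes
    no expectation.
    """

    counts: dict[CohortKey, tuple[int, int]]

    def __post_init__(self) -> None:
        for key, (cases, denom) in self.counts.items():
            if not 0 <= cases <= denom:
                raise RecordError(
                    f"cohort {key}: case count {cases} outside [0, {denom}]"
                )

    def rate(self, key: CohortKey) -> float:
        if key not in self.counts:
            logger.warning("cohort %s absent from rate table; using rate 0", (key,))
            return 0.0
        cases, denom = self.counts[key]
        return cases / denom if denom else 0.0

    def cases(self, key: CohortKey) -> int:
        return self.counts.get(key, (0, 0))[0]

    def denominator(self, key: CohortKey) -> int:
        return self.counts.get(key, (0, 0))[1]

    @property
    def total_cases(self) -> int:
        return sum(c for c, _ in self.counts.values())

    @property
    def total_denominator(self) -> int:
        return sum(d for _, d in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sex": k.sex,
                "birth_bin": k.birth_bin,
                "in_state": k.in_state,
                "cases": c,
                "denominator": d,
                "rate": c / d if d else 0.0,
            }
            for k, (c, d) in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["sex", "birth_bin", "in_state", "cases", "denominator", "rate"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        counts = {
            CohortKey(str(r.sex), int(r.birth_bin), bool(r.in_state)): (
                int(r.cases),
                int(r.denominator),
            )
            for r in df.itertuples(index=False)
        }
        return cls(counts)


def classify_recurrent_cases(
    g: Genealogy,
    registry: pd.DataFrame,
    min_lag_years: int = 10,
    site: str = BREAST_SITE,
    cause_code: str = BREAST_CAUSE,
) -> set[str]:
    """Ids of recurrent cases: female, primary diagnosis of ``site``, death
    certificate listing ``cause_code``, death at least ``min_lag_years``
    years after the earliest diagnosis.

    The lag is computed against the *earliest* primary diagnosis year.
    Registry records referencing unknown individuals, or diagnoses before
    birth, raise :class:`RecordError`.
    """
    if registry.empty:
        return set()
    cases: set[str] = set()
    earliest_dx: dict[str, int] = {}
    for row in registry.itertuples(index=False):
        ind_id = str(row.individual_id)
        if ind_id not in g:
            raise RecordError(f"registry record for unknown individual {ind_id!r}")
        ind = g.individual(ind_id)
        year = int(row.diagnosis_year)
        if ind.birth_year is not None and year < ind.birth_year:
            raise RecordError(
                f"individual {ind_id!r}: diagnosis year {year} precedes birth"
            )
        if str(row.site) != site:
            continue
        if ind_id not in earliest_dx or year < earliest_dx[ind_id]:
            earliest_dx[ind_id] = year
    for ind_id, dx_year in earliest_dx.items():
        ind = g.individual(ind_id)
        if ind.sex != FEMALE:
            continue
        if not ind.has_death_certificate or cause_code not in ind.cause_codes:
            continue
        assert ind.death_year is not None
        if ind.death_year - dx_year >= min_lag_years:
            cases.add(ind_id)
    return cases


def estimate_rates(g: Genealogy, case_ids: Iterable[str]) -> RateTable:
    """Cohort-specific case rates over the death-certified population.

    The denominator population is every individual with a linked death
    certificate; a case id without a death certificate is an error, because
    cases are defined through death certificates.
    """
    case_set = {str(c) for c in case_ids}
    counts: dict[CohortKey, list[int]] = {}
    for ind in g:
        if not ind.has_death_certificate:
            continue
        key = assign_cohort(ind)
        entry = counts.setdefault(key, [0, 0])
        entry[1] += 1
        if ind.id in case_set:
            entry[0] += 1
    covered = sum(c for c, _ in counts.values())
    if covered != len(case_set):
        bad = sorted(
            c
            for c in case_set
            if c not in g or not g.individual(c).has_death_certificate
        )
        raise RecordError(
            "case ids outside the death-certified denominator population: "
            + ", ".join(bad)
        )
    return RateTable({k: (c, d) for k, (c, d) in counts.items()})


def load_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "site", "diagnosis_year"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"registry table missing columns: {sorted(missing)}")
    return df


def load_death_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "cause_codes": str})
    required = {"individual_id", "death_year"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"death table missing columns: {sorted(missing)}")
    return df
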
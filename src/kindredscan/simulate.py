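"""Synthetic population generator emulating a statewide genealogy resource.

Generates a multi-generation founder population (large 19th-century-style
sibships, married-in spouses drawn as new founders), vital records with
partial death-certificate coverage, cohort-structured recurrent-cancer
phenotypes with an optional dominant founder risk allele (gene-drop
transmission), and an annotated multi-sample VCF of unlinked background
variants plus the planted risk variant.  A truth table records the true
carrier sets and case mechanisms so every downstream stage can be checked
against ground truth.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` in documented order: genealogy, gene drop,
phenotypes, background variants, sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from kindredscan.errors import ConfigError
from kindredscan.genealogy import FEMALE, MALE, Genealogy, Individual
from kindredscan.phenotypes import BREAST_CAUSE, BREAST_SITE, CohortKey, assign_cohort
from kindredscan.variants import Genotype, VariantRecord

_OTHER_CAUSES = ("I25", "J44", "E11", "C61", "I64", "C34")
_PRESENT_YEAR = 2020


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults emulate the resource the pipeline targets: founder couples
    born 1800-1850, large sibships (historical Utah-style families of ~4
    children reaching adulthood), a ~28-year generation gap, recurrent
    breast cancer striking ~0.8% of death-certified females, and a dominant
    founder risk allele with BRCA-like carrier penetrance (baseline x
    ``relative_risk``, capped at 1).
    """

    seed: int = 0
    n_founder_couples: int = 8
    n_generations: int = 4
    mean_offspring: float = 6.0
    founder_birth_year_range: tuple[int, int] = (1780, 1820)
    generation_gap_mean: float = 28.0
    generation_gap_sd: float = 5.0
    baseline_rate: float = 0.008
    baseline_rates: Mapping[CohortKey, float] | None = None
    relative_risk: float = 60.0
    risk_gene: str = "RISK1"
    risk_chrom: str = "7"
    risk_pos: int = 5_000_000
    risk_ref: str = "G"
    risk_alt: str = "A"
    n_background_variants: int = 300
    background_af_range: tuple[float, float] = (1e-4, 0.05)
    common_fraction: float = 0.15
    synonymous_fraction: float = 0.25
    sampling_fraction: float = 0.8
    death_cert_coverage: float = 0.85
    out_of_state_founder_fraction: float = 0.3
    sporadic_breast_rate: float = 0.03
    assay_failure_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_founder_couples < 1:
            raise ConfigError("n_founder_couples must be >= 1")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.mean_offspring < 0:
            raise ConfigError("mean_offspring must be >= 0")
        for name in (
            "sampling_fraction",
            "death_cert_coverage",
            "common_fraction",
            "synonymous_fraction",
            "out_of_state_founder_fraction",
            "sporadic_breast_rate",
            "assay_failure_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_rate * self.relative_risk > 1.0:
            raise ConfigError(
                "baseline_rate x relative_risk exceeds 1; not a probability"
            )

    def true_rate(self, key: CohortKey) -> float:
        """Configured baseline recurrent-case rate for a cohort (0 for males)."""
        if self.baseline_rates is not None and key in self.baseline_rates:
            return float(self.baseline_rates[key])
        return self.baseline_rate if key.sex == FEMALE else 0.0


@dataclass
class SimOutput:
    """Everything one simulation emits, cross-referenced by individual id."""

    config: SimConfig
    genealogy: Genealogy
    registry: pd.DataFrame
    deaths: pd.DataFrame
    vcf_records: list[VariantRecord]
    samples: list[str]
    risk_founder: str
    risk_carriers: frozenset[str]
    case_ids: frozenset[str]
    sporadic_breast_ids: frozenset[str]
    variant_carriers: dict[tuple[str, int, str, str], frozenset[str]]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.genealogy:
            rows.append(
                {
                    "id": ind.id,
                    "risk_carrier": int(ind.id in self.risk_carriers),
                    "recurrent_case": int(ind.id in self.case_ids),
                    "sporadic_breast": int(ind.id in self.sporadic_breast_ids),
                    "sampled": int(ind.id in set(self.samples)),
                }
            )
        return pd.DataFrame(rows)


# -- genealogy --------------------------------------------------------------


def generate_genealogy(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[Genealogy, list[str]]:
    """Build the pedigree graph; returns the genealogy and founder-father ids.

    Founder couples start generation 0; every non-terminal child pairs with
    a newly drawn founder spouse, so blood-descendant sets of distinct
    original founder couples never overlap.  Birth years increase down the
    generations; death years come from a clipped normal lifespan, and a
    configured fraction of the deceased receive a linked death certificate.
    """
    records: list[dict] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    def draw_in_state(founder: bool) -> bool:
        p = 1.0 - cfg.out_of_state_founder_fraction if founder else 0.95
        return bool(rng.random() < p)

    lo, hi = cfg.founder_birth_year_range
    couples: list[tuple[dict, dict]] = []
    founder_fathers: list[str] = []
    for _ in range(cfg.n_founder_couples):
        father = {
            "id": new_id(), "father": None, "mother": None, "sex": MALE,
            "birth_year": int(rng.integers(lo, hi + 1)),
            "in_state": draw_in_state(True),
        }
        mother = {
            "id": new_id(), "father": None, "mother": None, "sex": FEMALE,
            "birth_year": father["birth_year"] + int(rng.integers(-5, 6)),
            "in_state": draw_in_state(True),
        }
        records += [father, mother]
        couples.append((father, mother))
        founder_fathers.append(father["id"])

    for gen in range(1, cfg.n_generations):
        next_couples: list[tuple[dict, dict]] = []
        for father, mother in couples:
            n_kids = int(rng.poisson(cfg.mean_offspring))
            base_year = max(father["birth_year"], mother["birth_year"])
            for _ in range(n_kids):
                gap = float(
                    np.clip(
                        rng.normal(cfg.generation_gap_mean, cfg.generation_gap_sd),
                        16, 45,
                    )
                )
                child = {
                    "id": new_id(),
                    "father": father["id"],
                    "mother": mother["id"],
                    "sex": MALE if rng.random() < 0.5 else FEMALE,
                    "birth_year": base_year + int(round(gap)),
                    "in_state": draw_in_state(False),
                }
                records.append(child)
                if gen < cfg.n_generations - 1:
                    spouse = {
                        "id": new_id(), "father": None, "mother": None,
                        "sex": FEMALE if child["sex"] == MALE else MALE,
                        "birth_year": child["birth_year"] + int(rng.integers(-4, 5)),
                        "in_state": draw_in_state(True),
                    }
                    records.append(spouse)
                    pair = (child, spouse) if child["sex"] == MALE else (spouse, child)
                    next_couples.append(pair)
        couples = next_couples

    individuals = []
    for rec in records:
        lifespan = float(np.clip(rng.normal(72.0, 15.0), 20, 105))
        death_year = rec["birth_year"] + int(round(lifespan))
        if death_year > _PRESENT_YEAR:
            death_year = None
        has_cert = death_year is not None and rng.random() < cfg.death_cert_coverage
        individuals.append(
            Individual(
                id=rec["id"],
                father_id=rec["father"],
                mother_id=rec["mother"],
                sex=rec["sex"],
                birth_year=rec["birth_year"],
                birthplace_in_state=rec["in_state"],
                death_year=death_year,
                has_death_certificate=has_cert,
            )
        )
    return Genealogy(individuals), founder_fathers


# -- gene drop ---------------------------------------------------------------


def gene_drop(
    g: Genealogy, founder_id: str, rng: np.random.Generator
) -> dict[str, int]:
    """Mendelian drop of one allele from a heterozygous founder.

    Each meiosis transmits the alternate allele with probability 1/2,
    independently.  Returns alternate-allele dosage (0/1/2) for everyone;
    all other founders are homozygous reference.
    """
    founder = g.individual(founder_id)
    if not founder.is_founder:
        raise ConfigError(f"gene drop must start at a founder; {founder_id!r} has parents")
    dosage: dict[str, int] = {}
    for ind_id in g.topological_order():
        if ind_id == founder_id:
            dosage[ind_id] = 1
            continue
        father, mother = g.parents(ind_id)
        if father is None and mother is None:
            dosage[ind_id] = 0
            continue
        d = 0
        for parent in (father, mother):
            pd_ = dosage[parent] if parent is not None else 0
            if pd_ and rng.random() < pd_ / 2.0:
                d += 1
        dosage[ind_id] = d
    return dosage


def _topology_arrays(g: Genealogy) -> tuple[list[str], np.ndarray, np.ndarray, list[np.ndarray]]:
    """Topological id order, parent index arrays (-1 = founder), depth levels."""
    order = g.topological_order()
    index = {ind_id: i for i, ind_id in enumerate(order)}
    fidx = np.full(len(order), -1, dtype=np.int64)
    midx = np.full(len(order), -1, dtype=np.int64)
    depth = np.zeros(len(order), dtype=np.int64)
    for i, ind_id in enumerate(order):
        f, m = g.parents(ind_id)
        if f is not None:
            fidx[i] = index[f]
        if m is not None:
            midx[i] = index[m]
        depth[i] = g.generation_depth(ind_id)
    levels = [np.flatnonzero(depth == d) for d in range(int(depth.max()) + 1 if len(order) else 0)]
    return order, fidx, midx, levels


def gene_drop_matrix(
    g: Genealogy, founder_id: str, n_replicates: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Vectorized gene drop: (n_replicates x n_individuals) dosage matrix."""
    founder = g.individual(founder_id)
    if not founder.is_founder:
        raise ConfigError(f"gene drop must start at a founder; {founder_id!r} has parents")
    order, fidx, midx, levels = _topology_arrays(g)
    index = {ind_id: i for i, ind_id in enumerate(order)}
    dos = np.zeros((n_replicates, len(order)), dtype=np.int8)
    dos[:, index[founder_id]] = 1
    for level in levels[1:]:
        for pidx in (fidx, midx):
            parents = pidx[level]
            has_parent = parents >= 0
            cols = level[has_parent]
            pdos = dos[:, parents[has_parent]]
            dos[:, cols] += (
                rng.random(pdos.shape) < pdos / 2.0
            ).astype(np.int8)
    return order, dos


def drop_unlinked_variants(
    g: Genealogy, allele_freqs: np.ndarray, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Drop many unlinked variants through the pedigree at once.

    Founders draw dosage ~ Binomial(2, af_v); each child receives an allele
    from each parent with probability dosage/2.  Returns the id order and a
    (n_variants x n_individuals) dosage matrix.
    """
    order, fidx, midx, levels = _topology_arrays(g)
    n_var = len(allele_freqs)
    dos = np.zeros((n_var, len(order)), dtype=np.int8)
    founder_cols = np.flatnonzero((fidx < 0) & (midx < 0))
    dos[:, founder_cols] = rng.binomial(
        2, allele_freqs[:, None], size=(n_var, len(founder_cols))
    ).astype(np.int8)
    for level in levels:
        # married-in founders at deeper levels have no parents and already
        # carry their Binomial draw; only fill parented columns
        for pidx in (fidx, midx):
            parents = pidx[level]
            has_parent = parents >= 0
            if not has_parent.any():
                continue
            cols = level[has_parent]
            pdos = dos[:, parents[has_parent]]
            dos[:, cols] += (rng.random(pdos.shape) < pdos / 2.0).astype(np.int8)
    return order, dos


# -- phenotypes ---------------------------------------------------------------


def simulate_phenotypes(
    g: Genealogy,
    carrier_map: Mapping[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, frozenset[str], frozenset[str]]:
    """Draw recurrent-case and sporadic breast cancer phenotypes.

    Every death-certified female who lived past 40 is at risk of being a
    recurrent case with probability ``true_rate(cohort) * relative_risk``
    if she carries the risk allele (dominant), else the baseline rate.
    Cases receive a primary diagnosis 10-25 years before death and a death
    certificate listing the breast-cancer cause; non-case deaths receive
    other causes.  Sporadic (non-recurrent) breast cancers are added among
    the remaining females so assays have a breast-cancer phenotype pool.

    Returns (registry, deaths, case_ids, sporadic_ids).
    """
    registry_rows: list[dict] = []
    death_rows: list[dict] = []
    case_ids: set[str] = set()
    sporadic_ids: set[str] = set()
    for ind_id in g.topological_order():
        ind = g.individual(ind_id)
        is_case = False
        if (
            ind.sex == FEMALE
            and ind.has_death_certificate
            and ind.death_year is not None
            and ind.birth_year is not None
            and ind.death_year - ind.birth_year >= 40
        ):
            rate = cfg.true_rate(assign_cohort(ind))
            if carrier_map.get(ind_id, 0) >= 1:
                rate = min(1.0, rate * cfg.relative_risk)
            is_case = bool(rng.random() < rate)
        if is_case:
            case_ids.add(ind_id)
            lag = int(rng.integers(10, 26))
            dx_year = max(ind.death_year - lag, ind.birth_year + 20)
            registry_rows.append(
                {"individual_id": ind_id, "site": BREAST_SITE, "diagnosis_year": dx_year}
            )
            death_rows.append(
                {
                    "individual_id": ind_id,
                    "death_year": ind.death_year,
                    "cause_codes": BREAST_CAUSE,
                }
            )
            continue
        if ind.has_death_certificate:
            cause = _OTHER_CAUSES[int(rng.integers(0, len(_OTHER_CAUSES)))]
            death_rows.append(
                {
                    "individual_id": ind_id,
                    "death_year": ind.death_year,
                    "cause_codes": cause,
                }
            )
        # sporadic, non-recurrent breast cancer among other adult females
        if (
            ind.sex == FEMALE
            and ind.birth_year is not None
            and (ind.death_year is None or ind.death_year - ind.birth_year >= 35)
            and ind.birth_year + 35 <= _PRESENT_YEAR
            and rng.random() < cfg.sporadic_breast_rate
        ):
            sporadic_ids.add(ind_id)
            latest = min(
                ind.death_year if ind.death_year is not None else _PRESENT_YEAR,
                _PRESENT_YEAR,
            )
            dx_year = int(rng.integers(ind.birth_year + 30, max(latest, ind.birth_year + 31)))
            registry_rows.append(
                {"individual_id": ind_id, "site": BREAST_SITE, "diagnosis_year": dx_year}
            )
    registry = pd.DataFrame(
        registry_rows, columns=["individual_id", "site", "diagnosis_year"]
    )
    deaths = pd.DataFrame(
        death_rows, columns=["individual_id", "death_year", "cause_codes"]
    )
    return registry, deaths, frozenset(case_ids), frozenset(sporadic_ids)


# -- variants -----------------------------------------------------------------


_CSQ_POOL = ("nonsynonymous", "frameshift", "splicing", "stopgain", "other_exonic")


def simulate_background_variants(
    g: Genealogy,
    samples: list[str],
    cfg: SimConfig,
    rng: np.random.Generator,
    risk_dosage: Mapping[str, int] | None = None,
) -> tuple[list[VariantRecord], dict[tuple[str, int, str, str], frozenset[str]]]:
    """Unlinked annotated background variants plus the planted risk variant.

    Allele frequencies are log-uniform over ``background_af_range`` with a
    ``common_fraction`` drawn common (0.01-0.20); a ``synonymous_fraction``
    of records is synonymous.  The planted variant is written rare
    (AF 0.0005) and nonsynonymous with clean genotype quality so it always
    survives the default filter cascade.  Returns the VCF records
    (genotypes restricted to ``samples``) and the full truth map
    variant key -> carrier ids over the whole population.
    """
    n = cfg.n_background_variants
    lo, hi = cfg.background_af_range
    afs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    common = rng.random(n) < cfg.common_fraction
    afs[common] = rng.uniform(0.01, 0.20, size=int(common.sum()))
    order, dos = drop_unlinked_variants(g, afs, rng) if n else (g.topological_order(), np.zeros((0, len(g))))
    col = {ind_id: i for i, ind_id in enumerate(order)}

    records: list[VariantRecord] = []
    truth: dict[tuple[str, int, str, str], frozenset[str]] = {}
    bases = ("A", "C", "G", "T")
    pos_counter = {}
    for v in range(n):
        chrom = str(int(rng.integers(1, 23)))
        pos_counter[chrom] = pos_counter.get(chrom, 100_000) + int(rng.integers(1_000, 50_000))
        pos = pos_counter[chrom]
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        csq = (
            "synonymous"
            if rng.random() < cfg.synonymous_fraction
            else _CSQ_POOL[int(rng.integers(0, len(_CSQ_POOL)))]
        )
        gene = f"GENE{int(rng.integers(1, 120)):04d}"
        genotypes = {}
        for s in samples:
            d = int(dos[v, col[s]])
            gq = 99 if rng.random() < 0.96 else int(rng.integers(5, 20))
            dp = int(rng.poisson(30)) + 1 if rng.random() < 0.97 else int(rng.integers(3, 10))
            genotypes[s] = Genotype(n_alt=d, gq=gq, dp=dp)
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            consequence=csq, pop_af=float(afs[v]), genotypes=genotypes,
        )
        records.append(rec)
        truth[rec.key] = frozenset(
            order[i] for i in np.flatnonzero(dos[v] >= 1)
        )

    if risk_dosage is not None:
        genotypes = {
            s: Genotype(n_alt=int(risk_dosage.get(s, 0)), gq=99, dp=35)
            for s in samples
        }
        rec = VariantRecord(
            chrom=cfg.risk_chrom, pos=cfg.risk_pos, ref=cfg.risk_ref,
            alt=cfg.risk_alt, gene=cfg.risk_gene, consequence="nonsynonymous",
            pop_af=0.0005, genotypes=genotypes,
        )
        records.append(rec)
        truth[rec.key] = frozenset(i for i, d in risk_dosage.items() if d >= 1)
    records.sort(key=lambda r: (int(r.chrom) if r.chrom.isdigit() else 99, r.pos))
    return records, truth


def write_vcf(records: Iterable[VariantRecord], samples: list[str], path) -> None:
    """Emit records as uncompressed VCF 4.2 with GENE/CSQCLASS/AF INFO fields."""
    records = list(records)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [
        f"##contig=<ID={c}>"
        for c in sorted({r.chrom for r in records}, key=lambda x: (len(x), x))
    ]
    header_cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header_cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header_cols)
    for rec in records:
        info = f"GENE={rec.gene};CSQCLASS={rec.consequence}"
        if rec.pop_af is not None:
            info += f";AF={rec.pop_af:.6g}"
        cols = [
            rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", info,
        ]
        if samples:
            cols.append("GT:GQ:DP")
        for s in samples:
            gt = rec.genotypes[s]
            if gt.n_alt is None:
                gt_str = "./."
            else:
                gt_str = ["0/0", "0/1", "1/1"][gt.n_alt]
            gq = "." if gt.gq is None else str(gt.gq)
            dp = "." if gt.dp is None else str(gt.dp)
            cols.append(f"{gt_str}:{gq}:{dp}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# -- full dataset --------------------------------------------------------------


def simulate_dataset(cfg: SimConfig) -> SimOutput:
    """Run the full generator: genealogy, gene drop, phenotypes, variants.

    The risk allele enters through the father of the first founder couple.
    VCF samples are the recurrent cases holding a (simulated) stored DNA
    sample, drawn with probability ``sampling_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    g, founder_fathers = generate_genealogy(cfg, rng)
    risk_founder = founder_fathers[0]
    carrier_map = gene_drop(g, risk_founder, rng)
    registry, deaths, case_ids, sporadic_ids = simulate_phenotypes(
        g, carrier_map, cfg, rng
    )
    g = g.with_death_records(deaths) if not deaths.empty else g
    sampled = [i for i in sorted(case_ids) if rng.random() < cfg.sampling_fraction]
    vcf_records, truth = simulate_background_variants(
        g, sampled, cfg, rng, risk_dosage=carrier_map
    )
    return SimOutput(
        config=cfg,
        genealogy=g,
        registry=registry,
        deaths=deaths,
        vcf_records=vcf_records,
        samples=sampled,
        risk_founder=risk_founder,
        risk_carriers=frozenset(i for i, d in carrier_map.items() if d >= 1),
        case_ids=case_ids,
        sporadic_breast_ids=sporadic_ids,
        variant_carriers=truth,
    )


def write_dataset(sim: SimOutput, outdir) -> dict[str, Path]:
    """Write the trio/registry/death/VCF/truth files other stages consume."""
    from kindredscan.genealogy import genealogy_to_trio_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trio": outdir / "trio.tsv",
        "registry": outdir / "registry.tsv",
        "deaths": outdir / "deaths.tsv",
        "vcf": outdir / "variants.vcf",
        "samples": outdir / "samples.txt",
        "truth": outdir / "truth.tsv",
        "variant_truth": outdir / "variant_carriers.tsv",
    }
    genealogy_to_trio_frame(sim.genealogy).to_csv(paths["trio"], sep="\t", index=False)
    sim.registry.to_csv(paths["registry"], sep="\t", index=False)
    sim.deaths.to_csv(paths["deaths"], sep="\t", index=False)
    write_vcf(sim.vcf_records, sim.samples, paths["vcf"])
    paths["samples"].write_text("\n".join(sim.samples) + "\n" if sim.samples else "")
    sim.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    rows = [
        {
            "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
            "carriers": ";".join(sorted(v)),
        }
        for k, v in sim.variant_carriers.items()
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "carriers"]).to_csv(
        paths["variant_truth"], sep="\t", index=False
    )
    return paths
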
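"""Rare shared-variant discovery from an annotated multi-sample VCF.

The filter cascade keeps exonic variants that are rare in a reference
population (AF strictly below ``maf_max``), non-synonymous in the broad
sense (any consequence other than ``synonymous``), and confidently
genotyped in at least one carrier (genotype quality and depth thresholds;
genotypes failing quality are masked to missing).  Candidates are variants
where both members of a designated affected relative pair carry at least
one alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd
from cyvcf2 import VCF

from kindredscan.errors import VcfError

logger = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "frameshift",
    "splicing",
    "stopgain",
    "other_exonic",
)


@dataclass(frozen=True)
class Genotype:
    """Per-sample diploid call: alternate-allele dosage plus quality fields.

    ``n_alt`` is None for a missing call; ``gq``/``dp`` are None when the
    VCF omits the FORMAT field.
    """

    n_alt: int | None
    gq: int | None = None
    dp: int | None = None

    @property
    def is_carrier(self) -> bool:
        return self.n_alt is not None and self.n_alt >= 1


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: float | None
    genotypes: dict[str, Genotype]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> frozenset[str]:
        return frozenset(s for s, gt in self.genotypes.items() if gt.is_carrier)


@dataclass(frozen=True)
class CandidateVariant:
    """A filtered variant shared by both members of an affected relative pair."""

    variant: VariantRecord
    pedigree_id: str
    pair_ids: tuple[str, str]
    carriers_among_sequenced: frozenset[str]

    def __post_init__(self) -> None:
        if not set(self.pair_ids) <= self.carriers_among_sequenced:
            raise VcfError(
                f"candidate {self.variant.key}: pair members must both be carriers"
            )


def read_annotated_vcf(
    path, expected_samples: Sequence[str] | None = None
) -> Iterator[VariantRecord]:
    """Stream annotated variant records from a VCF.

    Expects single-allelic records (split multi-allelics upstream), INFO
    fields GENE / CSQCLASS / AF, and per-sample GT with optional GQ and DP.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if expected_samples is not None:
        missing = sorted(set(expected_samples) - set(samples))
        if missing:
            raise VcfError(f"samples absent from VCF: {', '.join(missing)}")
    for idx, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise VcfError(
                f"record {idx} ({var.CHROM}:{var.POS}) is multi-allelic; "
                "split multi-allelic sites upstream (e.g. `bcftools norm -m-`)"
            )
        gene = var.INFO.get("GENE")
        csq = var.INFO.get("CSQCLASS")
        af = var.INFO.get("AF")
        if isinstance(af, (tuple, list)):
            af = af[0]
        gq = var.format("GQ")
        dp = var.format("DP")
        genotypes: dict[str, Genotype] = {}
        for i, sample in enumerate(samples):
            alleles = var.genotypes[i][:-1]
            n_alt = None if any(a < 0 for a in alleles) else sum(1 for a in alleles if a > 0)
            genotypes[sample] = Genotype(
                n_alt=n_alt,
                gq=None if gq is None else int(gq[i][0]),
                dp=None if dp is None else int(dp[i][0]),
            )
        yield VariantRecord(
            chrom=str(var.CHROM),
            pos=int(var.POS),
            ref=str(var.REF),
            alt=str(var.ALT[0]),
            gene="" if gene is None else str(gene),
            consequence="" if csq is None else str(csq),
            pop_af=None if af is None else float(af),
            genotypes=genotypes,
        )


# -- filter cascade (the three stages commute) ------------------------------


def filter_by_af(
    records: Iterable[VariantRecord], maf_max: float = 0.005
) -> list[VariantRecord]:
    """Keep records with population AF strictly below ``maf_max``.

    Missing AF is treated as rare (an allele absent from the reference
    panel is rare by construction); the number of such records is logged.
    """
    kept, n_missing_af = [], 0
    for rec in records:
        if rec.pop_af is None:
            n_missing_af += 1
            kept.append(rec)
        elif rec.pop_af < maf_max:
            kept.append(rec)
    if n_missing_af:
        logger.info("retained %d records with missing population AF", n_missing_af)
    return kept


def filter_by_consequence(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop synonymous records."""
    return [r for r in records if r.consequence != "synonymous"]


def mask_low_quality(
    records: Iterable[VariantRecord], min_gq: int = 20, min_dp: int = 10
) -> list[VariantRecord]:
    """Set genotypes failing GQ/DP thresholds to missing.

    A missing GQ or DP field passes (thresholds only apply when the VCF
    reports the value).
    """
    out = []
    for rec in records:
        new = {}
        for sample, gt in rec.genotypes.items():
            fails = (gt.gq is not None and gt.gq < min_gq) or (
                gt.dp is not None and gt.dp < min_dp
            )
            new[sample] = replace(gt, n_alt=None) if fails and gt.n_alt is not None else gt
        out.append(replace(rec, genotypes=new))
    return out


def drop_carrierless(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop records with no confident carrier left after quality masking."""
    return [r for r in records if r.carriers()]


def apply_variant_filters(
    records: Iterable[VariantRecord],
    maf_max: float = 0.005,
    min_gq: int = 20,
    min_dp: int = 10,
) -> list[VariantRecord]:
    """Full cascade: rare AF, non-synonymous, quality-masked, >=1 carrier."""
    recs = filter_by_af(records, maf_max)
    recs = filter_by_consequence(recs)
    recs = mask_low_quality(recs, min_gq, min_dp)
    return drop_carrierless(recs)


def shared_in_pair(
    records: Iterable[VariantRecord],
    pair: tuple[str, str],
    pedigree_id: str = "",
) -> list[CandidateVariant]:
    """Variants where both pair members carry >= 1 confident alternate allele."""
    a, b = pair
    candidates = []
    records = list(records)
    if records:
        samples = set(records[0].genotypes)
        unknown = sorted({a, b} - samples)
        if unknown:
            raise VcfError(f"pair samples absent from VCF: {', '.join(unknown)}")
    for rec in records:
        if rec.genotypes[a].is_carrier and rec.genotypes[b].is_carrier:
            candidates.append(
                CandidateVariant(
                    variant=rec,
                    pedigree_id=pedigree_id,
                    pair_ids=(a, b),
                    carriers_among_sequenced=rec.carriers(),
                )
            )
    return candidates


def cross_pedigree_summary(
    candidates: Iterable[CandidateVariant],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recurrence tables across pairs/pedigrees.

    Returns (variant table, gene table): per variant, the number of distinct
    pairs sharing it; per gene, the number of distinct pedigrees that
    contributed a (possibly different) candidate variant in that gene.
    """
    var_rows: dict[tuple, dict] = {}
    gene_peds: dict[str, set[str]] = {}
    gene_vars: dict[str, set[tuple]] = {}
    for cand in candidates:
        key = cand.variant.key
        entry = var_rows.setdefault(
            key,
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "gene": cand.variant.gene,
                "pairs": set(),
            },
        )
        entry["pairs"].add(cand.pair_ids)
        gene_peds.setdefault(cand.variant.gene, set()).add(cand.pedigree_id)
        gene_vars.setdefault(cand.variant.gene, set()).add(key)
    variant_df = pd.DataFrame(
        [
            {**{k: v for k, v in row.items() if k != "pairs"}, "n_pairs": len(row["pairs"])}
            for row in var_rows.values()
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "n_pairs"],
    )
    gene_df = pd.DataFrame(
        [
            {
                "gene": gene,
                "n_pedigrees": len(peds),
                "n_distinct_variants": len(gene_vars[gene]),
            }
            for gene, peds in gene_peds.items()
        ],
        columns=["gene", "n_pedigrees", "n_distinct_variants"],
    )
    if not variant_df.empty:
        variant_df = variant_df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if not gene_df.empty:
        gene_df = gene_df.sort_values("gene").reset_index(drop=True)
    return variant_df, gene_df


def full_segregation_among_sequenced(
    candidate: CandidateVariant, sequenced_ids_in_pedigree: Iterable[str]
) -> bool:
    """True iff every sequenced case in the pedigree carries the variant."""
    sequenced = {str(s) for s in sequenced_ids_in_pedigree}
    unknown = sorted(sequenced - set(candidate.variant.genotypes))
    if unknown:
        raise VcfError(f"sequenced ids absent from VCF: {', '.join(unknown)}")
    return sequenced <= candidate.carriers_among_sequenced


def candidates_to_frame(candidates: Iterable[CandidateVariant]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "gene": c.variant.gene,
            "consequence": c.variant.consequence,
            "pop_af": c.variant.pop_af,
            "pedigree_id": c.pedigree_id,
            "pair_ids": ";".join(c.pair_ids),
            "carriers": ";".join(sorted(c.carriers_among_sequenced)),
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence",
            "pop_af", "pedigree_id", "pair_ids", "carriers",
        ],
    )
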
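"""End-to-end orchestration: staged execution over files in an output directory.

Stage order mirrors the study design funnel: classify recurrent cases ->
estimate cohort rates -> discover sampled-case clusters -> excess test ->
rare shared-variant filtering per high-risk pedigree -> segregation /
association evaluation -> summary report.  Each stage reads the files the
previous stages wrote, so running stages individually and running
:func:`run_pipeline` produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kindredscan import excess, phenotypes, segregation, simulate, variants
from kindredscan.errors import ConfigError, KindredScanError
from kindredscan.genealogy import CaseCluster, Genealogy, load_genealogy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    min_lag_years: int = 10
    maf_max: float = 0.005
    min_gq: int = 20
    min_dp: int = 10
    alpha: float = 0.05
    min_cases: int = 2
    max_sequenced_per_pedigree: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.maf_max <= 1:
            raise ConfigError(f"maf_max must be in [0,1], got {self.maf_max}")
        if self.min_cases < 1:
            raise ConfigError("min_cases must be >= 1")
        if self.max_sequenced_per_pedigree < 2:
            raise ConfigError("max_sequenced_per_pedigree must be >= 2")


@dataclass
class PipelineConfig:
    """Either a ``simulate`` block or explicit input paths must be present."""

    simulate: simulate.SimConfig | None = None
    trio: str | None = None
    registry: str | None = None
    deaths: str | None = None
    vcf: str | None = None
    samples: str | None = None
    assay: str | None = None
    assoc_counts: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and (self.trio is None or self.registry is None):
            raise ConfigError(
                "config needs either a simulate block or trio+registry input paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.get("simulate")
        sim_cfg = simulate.SimConfig(**sim) if isinstance(sim, dict) else None
        inputs = raw.get("inputs", {})
        params = PipelineParams(**raw.get("params", {}))
        return cls(
            simulate=sim_cfg,
            trio=inputs.get("trio"),
            registry=inputs.get("registry"),
            deaths=inputs.get("deaths"),
            vcf=inputs.get("vcf"),
            samples=inputs.get("samples"),
            assay=inputs.get("assay"),
            assoc_counts=inputs.get("assoc_counts"),
            params=params,
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "inputs": {
                k: getattr(self, k)
                for k in ("trio", "registry", "deaths", "vcf", "samples", "assay", "assoc_counts")
                if getattr(self, k)
            },
        }
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim.pop("baseline_rates", None)
            d["simulate"] = sim
        return d


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise KindredScanError(
            f"stage {stage!r}: missing input {path.name} "
            f"(run the {produced_by!r} stage first)"
        )
    return path


def _input_path(cfg: PipelineConfig, out: Path, attr: str, default_name: str) -> Path:
    explicit = getattr(cfg, attr)
    return Path(explicit) if explicit else out / default_name


def _load_genealogy(cfg: PipelineConfig, out: Path, stage: str) -> Genealogy:
    trio = _require(_input_path(cfg, out, "trio", "trio.tsv"), stage, "simulate")
    g = load_genealogy(trio)
    deaths_path = _input_path(cfg, out, "deaths", "deaths.tsv")
    if deaths_path.exists():
        g = g.with_death_records(phenotypes.load_death_table(deaths_path))
    return g


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [] if df.empty else [str(i) for i in df["id"]]


def _read_lines(path: Path) -> list[str]:
    text = Path(path).read_text().strip()
    return text.splitlines() if text else []


# -- stages -----------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    sim = simulate.simulate_dataset(sim_cfg)
    simulate.write_dataset(sim, out)
    return {"n_individuals": len(sim.genealogy), "n_true_cases": len(sim.case_ids)}


def stage_classify(cfg: PipelineConfig, out: Path) -> dict:
    g = _load_genealogy(cfg, out, "classify")
    registry = phenotypes.load_registry(
        _require(_input_path(cfg, out, "registry", "registry.tsv"), "classify", "simulate")
    )
    cases = phenotypes.classify_recurrent_cases(
        g, registry, min_lag_years=cfg.params.min_lag_years
    )
    pd.DataFrame({"id": sorted(cases)}).to_csv(out / "cases.tsv", sep="\t", index=False)
    return {"n_cases": len(cases)}


def stage_rates(cfg: PipelineConfig, out: Path) -> dict:
    g = _load_genealogy(cfg, out, "rates")
    cases = _read_id_column(_require(out / "cases.tsv", "rates", "classify"))
    table = phenotypes.estimate_rates(g, cases)
    table.to_frame().to_csv(out / "rates.tsv", sep="\t", index=False)
    return {"n_cohorts": len(table.counts), "denominator": table.total_denominator}


def stage_clusters(cfg: PipelineConfig, out: Path) -> dict:
    g = _load_genealogy(cfg, out, "clusters")
    cases = set(_read_id_column(_require(out / "cases.tsv", "clusters", "classify")))
    samples_path = _input_path(cfg, out, "samples", "samples.txt")
    sampled = set(_read_lines(samples_path)) & cases if samples_path.exists() else cases
    clusters = g.find_case_clusters(sampled, min_cases=cfg.params.min_cases)
    rows = [
        {
            "cluster_id": c.cluster_id,
            "root_couple": ";".join(c.root_couple),
            "member_cases": ";".join(sorted(c.member_cases)),
            "n_descendants": len(c.descendant_ids),
        }
        for c in clusters
    ]
    pd.DataFrame(
        rows, columns=["cluster_id", "root_couple", "member_cases", "n_descendants"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    return {"n_sampled": len(sampled), "n_clusters": len(clusters)}


def _read_clusters(g: Genealogy, path: Path) -> list[CaseCluster]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters = []
    for row in df.itertuples(index=False):
        roots = tuple(str(row.root_couple).split(";"))
        desc = frozenset().union(*(g.descendants_of(r) for r in roots))
        clusters.append(
            CaseCluster(
                cluster_id=str(row.cluster_id),
                root_couple=roots,
                member_cases=frozenset(str(row.member_cases).split(";")),
                descendant_ids=desc,
            )
        )
    return clusters


def stage_excess(cfg: PipelineConfig, out: Path) -> dict:
    g = _load_genealogy(cfg, out, "excess")
    cases = _read_id_column(_require(out / "cases.tsv", "excess", "classify"))
    rates = phenotypes.RateTable.from_frame(
        pd.read_csv(_require(out / "rates.tsv", "excess", "rates"), sep="\t")
    )
    clusters = _read_clusters(g, _require(out / "clusters.tsv", "excess", "clusters"))
    results = excess.test_clusters(clusters, g, cases, rates, alpha=cfg.params.alpha)
    excess.excess_report(results).to_csv(out / "excess.tsv", sep="\t", index=False)
    n_high = sum(r.high_risk for r in results)
    return {"n_tested": len(results), "n_high_risk": n_high}


def stage_share(cfg: PipelineConfig, out: Path) -> dict:
    g = _load_genealogy(cfg, out, "share")
    vcf_path = _require(_input_path(cfg, out, "vcf", "variants.vcf"), "share", "simulate")
    excess_df = pd.read_csv(_require(out / "excess.tsv", "share", "excess"), sep="\t")
    clusters = {
        c.cluster_id: c
        for c in _read_clusters(g, _require(out / "clusters.tsv", "share", "clusters"))
    }
    records = list(variants.read_annotated_vcf(vcf_path))
    vcf_samples = set(records[0].genotypes) if records else set()
    surviving = variants.apply_variant_filters(
        records,
        maf_max=cfg.params.maf_max,
        min_gq=cfg.params.min_gq,
        min_dp=cfg.params.min_dp,
    )
    high_risk_ids = [
        str(r.cluster_id) for r in excess_df.itertuples(index=False) if r.high_risk
    ]
    pair_rows = []
    all_candidates = []
    for cid in high_risk_ids:
        cluster = clusters[cid]
        pair, sequenced = select_index_pair(
            g, cluster, vcf_samples, cfg.params.max_sequenced_per_pedigree
        )
        if pair is None:
            continue
        cands = variants.shared_in_pair(surviving, pair, pedigree_id=cid)
        all_candidates.extend(cands)
        pair_rows.append(
            {
                "pedigree_id": cid,
                "pair_ids": ";".join(pair),
                "relationship": g.classify_relationship(*pair),
                "sequenced_ids": ";".join(sequenced),
                "n_candidates": len(cands),
            }
        )
    variants.candidates_to_frame(all_candidates).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        pair_rows,
        columns=["pedigree_id", "pair_ids", "relationship", "sequenced_ids", "n_candidates"],
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)
    var_df, gene_df = variants.cross_pedigree_summary(all_candidates)
    var_df.to_csv(out / "variant_recurrence.tsv", sep="\t", index=False)
    gene_df.to_csv(out / "gene_recurrence.tsv", sep="\t", index=False)
    stats = {
        "n_variants_input": len(records),
        "n_variants_pass_filters": len(surviving),
        "n_pedigrees_with_pair": len(pair_rows),
        "n_candidates": len(all_candidates),
    }
    (out / "share_summary.yaml").write_text(yaml.safe_dump(stats))
    return stats


def select_index_pair(
    g: Genealogy,
    cluster: CaseCluster,
    vcf_samples: set[str],
    max_sequenced: int,
) -> tuple[tuple[str, str] | None, list[str]]:
    """Choose the affected relative pair and the sequenced set for a pedigree.

    Among sampled member cases present in the VCF, the index pair is the
    related pair with the *smallest* kinship (the more remote the shared
    ancestry, the stronger the rare-sharing argument: first cousins share
    only 1/8 of their genome).  The sequenced set adds the remaining
    members closest to the pair, up to ``max_sequenced``.
    """
    members = sorted(cluster.member_cases & vcf_samples)
    if len(members) < 2:
        return None, []
    pairs = [
        (a, b)
        for i, a in enumerate(members)
        for b in members[i + 1 :]
        if g.kinship(a, b) > 0
    ]
    if not pairs:
        return None, []
    pair = min(pairs, key=lambda p: (g.kinship(*p), p))
    rest = [m for m in members if m not in pair]
    rest.sort(key=lambda m: (-max(g.kinship(m, pair[0]), g.kinship(m, pair[1])), m))
    sequenced = list(pair) + rest[: max_sequenced - 2]
    return pair, sequenced


def stage_segregate(cfg: PipelineConfig, out: Path) -> dict:
    g = _load_genealogy(cfg, out, "segregate")
    cand_df = pd.read_csv(
        _require(out / "candidates.tsv", "segregate", "share"), sep="\t", dtype={"chrom": str}
    )
    pairs_df = pd.read_csv(_require(out / "pairs.tsv", "segregate", "share"), sep="\t")
    clusters = {
        c.cluster_id: c
        for c in _read_clusters(g, _require(out / "clusters.tsv", "segregate", "clusters"))
    }
    cases = set(_read_id_column(_require(out / "cases.tsv", "segregate", "classify")))
    registry = phenotypes.load_registry(
        _require(_input_path(cfg, out, "registry", "registry.tsv"), "segregate", "simulate")
    )
    breast_ids = {
        str(r.individual_id)
        for r in registry.itertuples(index=False)
        if str(r.site) == phenotypes.BREAST_SITE
    }
    phenotype_map = {i: segregation.PHENO_RECURRENT for i in cases}
    phenotype_map.update(
        {i: segregation.PHENO_BREAST for i in breast_ids - cases}
    )

    if cfg.assay:
        assay_calls = segregation.load_assay_table(Path(cfg.assay))
    else:
        assay_calls = _simulate_assay(cfg, out, cand_df, pairs_df, phenotype_map)
        segregation_assay_frame(assay_calls).to_csv(
            out / "assay.tsv", sep="\t", index=False
        )

    pair_info = {
        str(r.pedigree_id): (
            tuple(str(r.pair_ids).split(";")),
            str(r.sequenced_ids).split(";"),
        )
        for r in pairs_df.itertuples(index=False)
    }
    summaries = []
    for row in cand_df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        pedigree_id = str(row.pedigree_id)
        pair, sequenced = pair_info[pedigree_id]
        carriers = set(str(row.carriers).split(";")) if str(row.carriers) else set()
        sequenced_carriers = carriers & set(sequenced)
        fully = set(sequenced) <= carriers
        summaries.append(
            segregation.count_additional_carriers(
                variant_key=key,
                assay_results=assay_calls,
                pedigree=clusters[pedigree_id],
                index_pair=(pair[0], pair[1]),
                phenotype_map=phenotype_map,
                g=g,
                sequenced_carriers=sequenced_carriers,
                sequenced_ids=sequenced,
                fully_segregates=fully,
            )
        )
    segregation.segregation_report(summaries).to_csv(
        out / "segregation.tsv", sep="\t", index=False
    )
    tiers = pd.Series([s.tier for s in summaries]).value_counts().to_dict()
    return {"n_summaries": len(summaries), "tiers": tiers}


def _simulate_assay(
    cfg: PipelineConfig,
    out: Path,
    cand_df: pd.DataFrame,
    pairs_df: pd.DataFrame,
    phenotype_map: dict,
) -> list[segregation.AssayResult]:
    """Synthesize assay calls for candidates from the simulation truth table.

    The assay panel is every breast-cancer-affected individual (recurrent or
    sporadic) who is not among the sequenced ids, subsampled at the
    simulated DNA-storage fraction; calls read the true carrier sets with a
    configured failure probability.
    """
    truth_path = out / "variant_carriers.tsv"
    if not truth_path.exists():
        raise KindredScanError(
            "stage 'segregate': no assay table configured and no simulation "
            "truth (variant_carriers.tsv) to synthesize one from"
        )
    truth_df = pd.read_csv(truth_path, sep="\t", dtype={"chrom": str})
    truth = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): (
            set(str(r.carriers).split(";")) if isinstance(r.carriers, str) and r.carriers else set()
        )
        for r in truth_df.itertuples(index=False)
    }
    sequenced: set[str] = set()
    for r in pairs_df.itertuples(index=False):
        sequenced |= set(str(r.sequenced_ids).split(";"))
    rng = np.random.default_rng([cfg.seed, 1])
    sampling = cfg.simulate.sampling_fraction if cfg.simulate else 1.0
    fail_rate = cfg.simulate.assay_failure_rate if cfg.simulate else 0.05
    panel = [
        i
        for i in sorted(phenotype_map)
        if i not in sequenced and rng.random() < sampling
    ]
    keys = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in cand_df.itertuples(index=False)
    }
    calls = []
    for key in sorted(keys):
        carriers = truth.get(key, set())
        for ind in panel:
            if rng.random() < fail_rate:
                call = segregation.CALL_FAILED
            else:
                call = (
                    segregation.CALL_CARRIER
                    if ind in carriers
                    else segregation.CALL_NONCARRIER
                )
            calls.append(
                segregation.AssayResult(variant_key=key, individual_id=ind, call=call)
            )
    return calls


def segregation_assay_frame(calls) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.variant_key[0],
            "pos": c.variant_key[1],
            "ref": c.variant_key[2],
            "alt": c.variant_key[3],
            "individual_id": c.individual_id,
            "call": c.call,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "individual_id", "call"]
    )


def stage_assoc(cfg: PipelineConfig, out: Path) -> dict:
    """2x2 association from pre-matched case/control carrier counts."""
    if not cfg.assoc_counts:
        pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "a", "b", "c", "d", "odds_ratio", "p_value"]
        ).to_csv(out / "assoc.tsv", sep="\t", index=False)
        return {"n_assoc": 0}
    df = pd.read_csv(Path(cfg.assoc_counts), sep="\t", dtype={"chrom": str})
    rows = []
    for r in df.itertuples(index=False):
        res = segregation.fisher_or(int(r.a), int(r.b), int(r.c), int(r.d))
        rows.append(
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "odds_ratio": res.odds_ratio, "p_value": res.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(out / "assoc.tsv", sep="\t", index=False)
    return {"n_assoc": len(rows)}


def stage_report(cfg: PipelineConfig, out: Path) -> dict:
    """Funnel summary over the stage outputs."""
    def rows_in(name: str) -> int | None:
        p = out / name
        if not p.exists():
            return None
        df = pd.read_csv(p, sep="\t")
        return len(df)

    excess_path = out / "excess.tsv"
    n_high = None
    if excess_path.exists():
        n_high = int(pd.read_csv(excess_path, sep="\t")["high_risk"].sum())
    seg_path = out / "segregation.tsv"
    tiers = {}
    if seg_path.exists():
        seg = pd.read_csv(seg_path, sep="\t")
        tiers = seg["tier"].value_counts().to_dict() if not seg.empty else {}
    summary = {
        "n_cases": rows_in("cases.tsv"),
        "n_clusters": rows_in("clusters.tsv"),
        "n_high_risk": n_high,
        "n_candidates": rows_in("candidates.tsv"),
        "n_assoc": rows_in("assoc.tsv"),
        "tiers": {str(k): int(v) for k, v in tiers.items()},
    }
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    return summary


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "rates": stage_rates,
    "clusters": stage_clusters,
    "excess": stage_excess,
    "share": stage_share,
    "segregate": stage_segregate,
    "assoc": stage_assoc,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages in order; aborts on the failing stage, keeping partial
    outputs, and writes the resolved config for provenance."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=False)
    )
    order = [s for s in STAGES if s != "simulate" or cfg.simulate is not None]
    results = {}
    for name in order:
        t0 = time.perf_counter()
        try:
            results[name] = STAGES[name](cfg, out)
        except KindredScanError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
            raise KindredScanError(f"stage {name!r} failed: {exc}") from exc
        logger.info(
            "stage %-9s %6.2fs %s", name, time.perf_counter() - t0, results[name]
        )
    return results


def run_demo(sim_cfg: simulate.SimConfig) -> dict:
    """Simulate-then-analyze in a temporary directory; report planted-variant
    recovery (used by the end-to-end experiments)."""
    cfg = PipelineConfig(simulate=sim_cfg, seed=sim_cfg.seed)
    with tempfile.TemporaryDirectory() as tmp:
        results = run_pipeline(cfg, tmp)
        out = Path(tmp)
        seg = pd.read_csv(out / "segregation.tsv", sep="\t", dtype={"chrom": str})
        key = (
            sim_cfg.risk_chrom,
            sim_cfg.risk_pos,
            sim_cfg.risk_ref,
            sim_cfg.risk_alt,
        )
        hit = seg[
            (seg["chrom"] == key[0])
            & (seg["pos"] == key[1])
            & (seg["ref"] == key[2])
            & (seg["alt"] == key[3])
        ]
        recovered = not hit.empty
        full_coseg = recovered and (hit["tier"] == "full_cosegregation").any()
        return {
            "stage_results": results,
            "planted_candidate": recovered,
            "recovered_full_cosegregation": bool(full_coseg),
        }
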
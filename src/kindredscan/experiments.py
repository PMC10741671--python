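"""Reusable simulation experiments: IBD sharing, calibration, power, recovery.

These wrap the synthetic-data generator and the excess test into the
Monte-Carlo experiments that validate the method: identity-by-descent
sharing between first cousins, type-I calibration of the exact Poisson
excess test on null populations, power against a planted dominant founder
allele, and end-to-end recovery of the planted variant by the full
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import poisson

from kindredscan.genealogy import FEMALE, Genealogy, Individual
from kindredscan.phenotypes import assign_cohort
from kindredscan.simulate import SimConfig, gene_drop_matrix, generate_genealogy

# Study conditions for calibration: statewide-resource-scale founder lines
# (~10^4 descendants each, like the resource's large pioneer pedigrees),
# tested at a common-cancer-site baseline rate (3% of death-certified
# females) so per-cluster expected counts land in the 40-110 range of the
# anchor pedigree's per-site excess tests.  There the exact test's
# analytically computed attained size averages ~0.043; at small expected
# counts the discrete Poisson tail is conservative by construction (see
# docs/methods.md).  Only generations deceased by the present day
# contribute death-certified descendants, hence the early founder years
# and the large sibships characteristic of 19th-century founder families.
CALIBRATION_CONFIG = SimConfig(
    n_founder_couples=12,
    n_generations=6,
    mean_offspring=6.0,
    founder_birth_year_range=(1780, 1810),
    baseline_rate=0.03,
    relative_risk=1.0,
    n_background_variants=0,
)

# Study conditions for power: one large founder line with a dominant allele
# at the reference effect size (relative risk 20 over the baseline).
POWER_CONFIG = SimConfig(
    n_founder_couples=1,
    n_generations=6,
    mean_offspring=6.0,
    founder_birth_year_range=(1780, 1810),
    relative_risk=20.0,
    n_background_variants=0,
)


def first_cousin_pedigree() -> tuple[Genealogy, tuple[str, str]]:
    """Minimal outbred pedigree containing one first-cousin pair (C1, C2)."""
    inds = [
        Individual("GF", sex="male", birth_year=1900),
        Individual("GM", sex="female", birth_year=1902),
        Individual("S1", "GF", "GM", sex="male", birth_year=1928),
        Individual("S2", "GF", "GM", sex="male", birth_year=1930),
        Individual("W1", sex="female", birth_year=1929),
        Individual("W2", sex="female", birth_year=1931),
        Individual("C1", "S1", "W1", sex="female", birth_year=1955),
        Individual("C2", "S2", "W2", sex="female", birth_year=1957),
    ]
    return Genealogy(inds), ("C1", "C2")


def drop_founder_alleles(
    g: Genealogy, n_loci: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Drop uniquely labelled founder alleles at many unlinked loci.

    Every founder receives two globally unique allele labels; each child
    inherits one allele from each parent, chosen uniformly and
    independently per locus.  Returns (id order, paternal-label matrix,
    maternal-label matrix), each (n_loci x n_individuals).
    """
    order = g.topological_order()
    index = {i: k for k, i in enumerate(order)}
    pat = np.zeros((n_loci, len(order)), dtype=np.int32)
    mat = np.zeros((n_loci, len(order)), dtype=np.int32)
    label = 1
    for ind_id in order:
        k = index[ind_id]
        f, m = g.parents(ind_id)
        if f is None and m is None:
            pat[:, k] = label
            mat[:, k] = label + 1
            label += 2
            continue
        for parent, out in ((f, pat), (m, mat)):
            if parent is None:
                out[:, k] = label
                label += 1
                continue
            j = index[parent]
            pick = rng.random(n_loci) < 0.5
            out[:, k] = np.where(pick, pat[:, j], mat[:, j])
    return order, pat, mat


def ibd_sharing_fraction(
    g: Genealogy, a: str, b: str, n_loci: int, rng: np.random.Generator
) -> float:
    """Mean genome fraction shared identical-by-descent between a and b.

    Per locus the shared fraction is (number of IBD-matched alleles)/2;
    first cousins expect 1/8 (kinship 1/16, relatedness 2*phi).
    """
    order, pat, mat = drop_founder_alleles(g, n_loci, rng)
    ka, kb = order.index(a), order.index(b)
    a_alleles = np.stack([pat[:, ka], mat[:, ka]])
    b_alleles = np.stack([pat[:, kb], mat[:, kb]])
    # count of a's alleles matched IBD in b (each allele can match once)
    shared = np.zeros(n_loci, dtype=np.int32)
    used_b0 = np.zeros(n_loci, dtype=bool)
    for i in range(2):
        m0 = (a_alleles[i] == b_alleles[0]) & ~used_b0
        used_b0 |= m0
        m1 = (a_alleles[i] == b_alleles[1]) & ~m0
        shared += m0.astype(np.int32) + m1.astype(np.int32)
    return float(np.mean(shared / 2.0))


def mc_kinship(
    g: Genealogy, a: str, b: str, n_loci: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo kinship estimate and its standard error.

    phi = P(one random allele from each individual is IBD); per locus the
    estimator averages the 4 cross-allele comparisons.
    """
    order, pat, mat = drop_founder_alleles(g, n_loci, rng)
    ka, kb = order.index(a), order.index(b)
    matches = np.zeros(n_loci, dtype=np.float64)
    for x in (pat[:, ka], mat[:, ka]):
        for y in (pat[:, kb], mat[:, kb]):
            matches += (x == y).astype(np.float64)
    per_locus = matches / 4.0
    return float(per_locus.mean()), float(per_locus.std(ddof=1) / np.sqrt(n_loci))


@dataclass(frozen=True)
class CalibrationResult:
    n_tests: int
    n_flagged: int
    fraction_flagged: float
    expected_counts: tuple[float, ...]


def null_calibration(
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    cfg: SimConfig = CALIBRATION_CONFIG,
) -> CalibrationResult:
    """Type-I error of the excess test on null founder-line clusters.

    One population is generated; every founder line forms a cluster, and
    each replicate redraws the recurrent-case phenotype for all
    death-certified females at the configured true cohort rates (relative
    risk 1).  Per-individual Bernoulli draws are grouped into per-cohort
    binomial counts, which is distributionally identical and fast; the
    expected count uses the same true rates.  Returns the fraction of
    cluster tests with p < alpha over >= ``n_replicates`` tests.
    """
    rng = np.random.default_rng(seed)
    g, founder_fathers = generate_genealogy(cfg, rng)
    clusters = []
    for father in founder_fathers:
        desc = g.descendants_of(father)
        cohort_counts: dict = {}
        for ind_id in desc:
            ind = g.individual(ind_id)
            if ind.sex != FEMALE or not ind.has_death_certificate:
                continue
            if ind.death_year is None or ind.death_year - ind.birth_year < 40:
                continue
            key = assign_cohort(ind)
            cohort_counts[key] = cohort_counts.get(key, 0) + 1
        ns = np.array(list(cohort_counts.values()), dtype=np.int64)
        ps = np.array([cfg.true_rate(k) for k in cohort_counts], dtype=np.float64)
        clusters.append((ns, ps))
    n_draws = int(np.ceil(n_replicates / len(clusters)))
    flagged = 0
    total = 0
    lambdas = []
    for ns, ps in clusters:
        lam = float(np.dot(ns, ps))
        lambdas.append(lam)
        obs = rng.binomial(ns[None, :], ps[None, :], size=(n_draws, len(ns))).sum(axis=1)
        pvals = poisson.sf(obs - 1, lam)
        pvals[obs == 0] = 1.0
        flagged += int((pvals < alpha).sum())
        total += n_draws
    return CalibrationResult(
        n_tests=total,
        n_flagged=flagged,
        fraction_flagged=flagged / total,
        expected_counts=tuple(lambdas),
    )


@dataclass(frozen=True)
class PowerResult:
    n_replicates: int
    n_flagged: int
    fraction_flagged: float
    expected_count: float
    mean_observed: float


def planted_power(
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    cfg: SimConfig = POWER_CONFIG,
    n_genealogies: int = 10,
) -> PowerResult:
    """Power of the excess test against a planted dominant founder allele.

    Replicates are spread over ``n_genealogies`` independently generated
    founder-line populations (a single line's size is a high-variance
    branching process, so power is averaged over the genealogy draw as well
    as the gene drop).  Each replicate redraws the gene drop from the risk
    founder and the phenotypes (baseline rate for non-carriers, baseline x
    relative risk for carriers); the expected count under the null uses the
    true baseline rates, as in calibration.
    """
    rng = np.random.default_rng(seed)
    per = int(np.ceil(n_replicates / n_genealogies))
    flagged = total = 0
    lams, obs_means = [], []
    for _ in range(n_genealogies):
        g, founder_fathers = generate_genealogy(cfg, rng)
        risk_founder = founder_fathers[0]
        desc = g.descendants_of(risk_founder)
        order, dos = gene_drop_matrix(g, risk_founder, per, rng)
        col = {ind_id: i for i, ind_id in enumerate(order)}
        eligible = [
            i
            for i in desc
            if (ind := g.individual(i)).sex == FEMALE
            and ind.has_death_certificate
            and ind.death_year is not None
            and ind.death_year - ind.birth_year >= 40
        ]
        cols = np.array([col[i] for i in eligible], dtype=np.int64)
        base = np.array(
            [cfg.true_rate(assign_cohort(g.individual(i))) for i in eligible]
        )
        lam = float(base.sum())
        carrier = dos[:, cols] >= 1
        probs = np.where(carrier, np.minimum(1.0, base * cfg.relative_risk), base)
        obs = (rng.random(probs.shape) < probs).sum(axis=1)
        pvals = poisson.sf(obs - 1, lam)
        pvals[obs == 0] = 1.0
        flagged += int((pvals < alpha).sum())
        total += per
        lams.append(lam)
        obs_means.append(float(obs.mean()))
    return PowerResult(
        n_replicates=total,
        n_flagged=flagged,
        fraction_flagged=flagged / total,
        expected_count=float(np.mean(lams)),
        mean_observed=float(np.mean(obs_means)),
    )


def end_to_end_recovery(seeds, cfg: SimConfig | None = None) -> dict:
    """Run the full pipeline on demo simulations across seeds.

    Success for a seed means: the planted variant survives the filter
    cascade, is shared by the chosen affected relative pair of a high-risk
    cluster containing the risk founder line, and is tiered
    ``full_cosegregation``.  Returns per-seed outcomes and the success
    fraction.
    """
    from kindredscan.pipeline import run_demo

    outcomes = []
    for seed in seeds:
        demo_cfg = replace(cfg or SimConfig(), seed=int(seed))
        result = run_demo(demo_cfg)
        outcomes.append(result)
    n_ok = sum(1 for r in outcomes if r["recovered_full_cosegregation"])
    return {
        "seeds": list(seeds),
        "outcomes": outcomes,
        "n_success": n_ok,
        "fraction_success": n_ok / len(outcomes),
    }
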
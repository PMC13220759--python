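"""Synthetic cohorts and two-locus epistasis experiments.

The generator emulates the structure of a case-control rare-variant study:
a panel of background genes whose rare-variant content scales with coding
length, independent Hardy-Weinberg genotypes with a rare-skewed allele
frequency spectrum, benign-skewed pathogenicity scores, and a candidate-pair list
with high interaction-prediction scores. Disease signal is planted through
three classical two-locus odds models (threshold, multiplicative, classic
epistasis), whose baseline odds alpha and effect size theta are solved from
a prescribed prevalence, causal MAF, and genotype odds ratio.

Type-I-error and power experiments run the full testing pipeline on many
replicate cohorts and summarize calibration (MLFC, tail rates) and the
detection rate of the planted pair with exact binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as gio, pipeline, tnb

__all__ = [
    "TwoLocusModel",
    "SyntheticCohort",
    "ExperimentResult",
    "odds_multiplier",
    "solve_alpha_theta",
    "simulate_background",
    "insert_causal_pair",
    "write_cohort",
    "type1_experiment",
    "power_experiment",
    "clopper_pearson",
    "DESK_B_GRID",
    "DESK_T_GRID",
]

MODEL_KINDS = ("threshold", "multiplicative", "classic")

#: desk-scale grid used by the replicate experiments (subset of the full
#: 20 x 3 grid; keeps a replicate affordable while still exercising the
#: bin-length / truncation selection)
DESK_B_GRID = (0.05, 0.1, 0.2)
DESK_T_GRID = (0, 1)

#: score assigned to planted causal variants: disease-causing variants are
#: modeled as confidently deleterious on the [0, 1] pathogenicity scale
CAUSAL_SCORE = 0.9

_CONSEQUENCES = sorted(gio.NONSYNONYMOUS)


@dataclass
class TwoLocusModel:
    """Two-locus disease odds model: odds(g) = alpha * multiplier(g)."""

    kind: str
    alpha: float
    theta_eff: float
    maf: float
    or_target: float
    prevalence: float

    def penetrance(self, gA, gB) -> np.ndarray:
        odds = self.alpha * odds_multiplier(self.kind, gA, gB, self.theta_eff)
        return odds / (1.0 + odds)


@dataclass
class SyntheticCohort:
    gm: gio.GenotypeMatrix
    sites: pd.DataFrame
    features: pd.DataFrame
    pairs: pd.DataFrame
    causal_pair: tuple[str, str] | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    """Replicate-level outcomes of a simulation experiment."""

    replicate_pvalues: np.ndarray | None = None
    background_pvalues: list = field(default_factory=list)
    power: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    type1_rates: dict = field(default_factory=dict)
    mlfc_values: np.ndarray | None = None
    mlfc_mean: float | None = None
    mlfc_sd: float | None = None
    n_replicates: int = 0
    settings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# two-locus odds models


def odds_multiplier(kind: str, gA, gB, theta_eff: float):
    """Odds multiplier m(gA, gB) relative to the baseline genotype.

    gA/gB count risk-allele copies at the two loci (0, 1, 2); vectorized.

    threshold: (1 + theta) once both loci carry a risk allele, flat beyond;
    multiplicative: (1 + theta)^(gA * gB), each extra copy compounds;
    classic: (1 + 4 theta) for the two opposite-homozygote cells
    ((2,0) and (0,2)), (1 + 2 theta) for the double heterozygote, 1
    elsewhere (one allele masks the other's effect).
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    if np.any((gA < 0) | (gA > 2) | (gB < 0) | (gB > 2)):
        raise ValueError("genotypes must be 0, 1, or 2")
    if kind == "threshold":
        m = np.where((gA >= 1) & (gB >= 1), 1.0 + theta_eff, 1.0)
    elif kind == "multiplicative":
        m = (1.0 + theta_eff) ** (gA * gB)
    elif kind == "classic":
        m = np.ones(np.broadcast(gA, gB).shape)
        m = np.where(((gA == 2) & (gB == 0)) | ((gA == 0) & (gB == 2)), 1.0 + 4.0 * theta_eff, m)
        m = np.where((gA == 1) & (gB == 1), 1.0 + 2.0 * theta_eff, m)
    else:
        raise ValueError(f"unknown two-locus model kind: {kind!r}")
    if m.ndim == 0:
        return float(m)
    return m


def _hwe_probs(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def solve_alpha_theta(
    kind: str, prevalence: float, maf: float, or_target: float
) -> TwoLocusModel:
    """Solve baseline odds alpha and effect size theta from design quantities.

    theta is fixed so the maximal-risk genotype cell has odds ratio
    ``or_target`` versus the double-baseline cell: 1 + theta (threshold),
    (1 + theta)^4 (multiplicative), 1 + 4 theta (classic). alpha is then the
    root of  sum_g P_HWE(g) alpha m(g) / (1 + alpha m(g)) = prevalence.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    if not (0.0 < maf < 0.5):
        raise ValueError("causal MAF must lie in (0, 0.5)")
    if or_target < 1.0:
        raise ValueError("genotype OR must be >= 1")
    if kind == "threshold":
        theta = or_target - 1.0
    elif kind == "multiplicative":
        theta = or_target ** 0.25 - 1.0
    elif kind == "classic":
        theta = (or_target - 1.0) / 4.0
    else:
        raise ValueError(f"unknown two-locus model kind: {kind!r}")

    pg = _hwe_probs(maf)
    gA, gB = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    pcell = np.outer(pg, pg)
    m = odds_multiplier(kind, gA, gB, theta)

    def f(log_alpha):
        a = np.exp(log_alpha)
        return float(np.sum(pcell * a * m / (1.0 + a * m))) - prevalence

    lo, hi = np.log(1e-12), np.log(1e8)
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(
            f"alpha root not bracketed for {kind}, Pr(D)={prevalence}, "
            f"maf={maf}, OR={or_target}"
        )
    log_alpha = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    return TwoLocusModel(
        kind=kind,
        alpha=float(np.exp(log_alpha)),
        theta_eff=float(theta),
        maf=maf,
        or_target=or_target,
        prevalence=prevalence,
    )


def implied_prevalence(model: TwoLocusModel) -> float:
    """Population prevalence implied by a fitted model (self-consistency check)."""
    pg = _hwe_probs(model.maf)
    gA, gB = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    pcell = np.outer(pg, pg)
    return float(np.sum(pcell * model.penetrance(gA, gB)))


# ---------------------------------------------------------------------------
# background cohort generator
#
# Defaults define the study conditions used throughout the experiments:
# 500 background genes with a broad coding-length spread (lognormal, median
# 1.3 kb, sigma 0.75) whose rare-variant count scales with CDS length
# (~1 variant per 750 bp of CDS), reference MAFs log-uniform on
# (0.0008, 0.009) (all qualifying under the 1% rare cutoff), benign-skewed
# Beta(1, 3) pathogenicity scores, and 40000 candidate pairs with prediction scores
# above 0.8. This puts the per-gene cumulative rare-variant carrier
# frequency near 2% — the regime of real exomes, where most candidate pairs
# are co-mutated in no case or very few cases (hence the truncation point)
# and roughly 6000-7000 pairs carry enough burden to enter the background fit at
# n = 1000. Coding length and accumulated MAF genuinely drive the expected
# burden, giving the baseline regression real signal to fit.


def simulate_background(
    n_samples: int,
    n_genes: int = 500,
    n_pairs: int = 40000,
    seed=0,
    case_fraction: float = 0.5,
    maf_range: tuple[float, float] = (8e-4, 9e-3),
    variants_per_bp: float = 1.0 / 750.0,
    cds_sigma: float = 0.75,
    score_beta: tuple[float, float] = (1.0, 3.0),
    stratification: bool = False,
    fst: float = 0.1,
    reserve_genes: tuple[str, ...] = (),
) -> SyntheticCohort:
    """Null case-control cohort: genotypes independent of phenotype labels.

    ``stratification`` draws the allele frequencies of half the controls from
    a Balding-Nichols divergence of the case pool (mimicking ancestrally
    mixed controls). ``reserve_genes`` names genes to create with features
    but zero variants (targets for later causal insertion).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]

    cds = np.clip(
        rng.lognormal(mean=np.log(1300.0), sigma=cds_sigma, size=n_genes), 150, 30000
    ).astype(int)
    n_var = 1 + rng.poisson(cds * variants_per_bp)

    reserved = list(reserve_genes)
    all_gene_ids = gene_ids + reserved
    all_cds = np.concatenate(
        [
            cds,
            np.clip(
                rng.lognormal(np.log(1300.0), cds_sigma, size=len(reserved)),
                150,
                30000,
            ).astype(int),
        ]
    )

    # per-variant attributes; pathogenicity scores are skewed benign
    # (Beta(1,3), mean 0.25) as real deleteriousness spectra are — most rare
    # non-synonymous variants score low, so a confidently deleterious variant
    # carries a genuinely larger functional weight than the background bulk
    lo, hi = maf_range
    total_var = int(n_var.sum())
    maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=total_var))
    score = rng.beta(score_beta[0], score_beta[1], size=total_var)
    gene_of = np.repeat(np.arange(n_genes), n_var)
    consequence = rng.choice(_CONSEQUENCES, size=total_var)

    n_cases = int(round(n_samples * case_fraction))
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[:n_cases] = True

    if stratification:
        # half the controls come from a diverged population
        ctrl_idx = np.flatnonzero(~is_case)
        diverged = np.zeros(n_samples, dtype=bool)
        diverged[ctrl_idx[: len(ctrl_idx) // 2]] = True
        a = maf * (1 - fst) / fst
        bpar = (1 - maf) * (1 - fst) / fst
        maf2 = np.clip(rng.beta(a, bpar), 1e-6, 0.999999)
        genotypes = np.empty((total_var, n_samples), dtype=np.int8)
        genotypes[:, ~diverged] = rng.binomial(
            2, maf[:, None], size=(total_var, int((~diverged).sum()))
        )
        genotypes[:, diverged] = rng.binomial(
            2, maf2[:, None], size=(total_var, int(diverged.sum()))
        )
    else:
        genotypes = rng.binomial(2, maf[:, None], size=(total_var, n_samples)).astype(
            np.int8
        )

    variant_ids = [
        f"{all_gene_ids[g]}:v{k}"
        for g, k in zip(gene_of, _within_gene_counter(gene_of))
    ]
    sample_ids = [
        f"case_{i:05d}" if c else f"ctrl_{i:05d}" for i, c in enumerate(is_case)
    ]

    sites = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gene_id": [all_gene_ids[g] for g in gene_of],
            "score": score,
            "reference_MAF": maf,
            "consequence": consequence,
            "n_alleles": 2,
        }
    )
    gm = gio.GenotypeMatrix(
        genotypes=genotypes.astype(np.int8),
        variant_ids=variant_ids,
        sample_ids=sample_ids,
        is_case=is_case,
    )

    acc = np.zeros(len(all_gene_ids))
    np.add.at(acc, gene_of, maf)
    features = pd.DataFrame(
        {
            "gene_id": all_gene_ids,
            "cds_length": all_cds,
            "acc_maf": acc,
            "cds_times_maf": all_cds * acc,
            "oe_mis": rng.uniform(0.3, 1.2, size=len(all_gene_ids)),
            "oe_lof": rng.uniform(0.2, 1.5, size=len(all_gene_ids)),
            "gc_content": rng.uniform(0.35, 0.60, size=len(all_gene_ids)),
        }
    ).set_index("gene_id")

    pairs = _sample_pairs(rng, gene_ids, n_pairs)
    return SyntheticCohort(
        gm=gm,
        sites=sites,
        features=features,
        pairs=pairs,
        meta={"seed": seed, "stratification": stratification, "fst": fst},
    )


def _within_gene_counter(gene_of: np.ndarray) -> np.ndarray:
    counter = np.zeros_like(gene_of)
    counts: dict[int, int] = {}
    for i, g in enumerate(gene_of):
        counts[g] = counts.get(g, 0) + 1
        counter[i] = counts[g]
    return counter


def _sample_pairs(rng, gene_ids, n_pairs: int) -> pd.DataFrame:
    n = len(gene_ids)
    max_pairs = n * (n - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"cannot draw {n_pairs} distinct pairs from {n} genes")
    seen = set()
    while len(seen) < n_pairs:
        a = rng.integers(0, n, size=2 * (n_pairs - len(seen)) + 16)
        b = rng.integers(0, n, size=a.size)
        for x, y in zip(a, b):
            if x == y:
                continue
            key = (min(x, y), max(x, y))
            if key not in seen:
                seen.add(key)
                if len(seen) == n_pairs:
                    break
    idx = sorted(seen)
    return pd.DataFrame(
        {
            "gene_i": [gene_ids[i] for i, _ in idx],
            "gene_j": [gene_ids[j] for _, j in idx],
            "pair_score": rng.uniform(0.801, 1.0, size=len(idx)),
        }
    )


# ---------------------------------------------------------------------------
# causal insertion


def insert_causal_pair(
    cohort: SyntheticCohort,
    model: TwoLocusModel,
    target_pair: tuple[str, str] = ("TARGET_A", "TARGET_B"),
    causal_score: float = CAUSAL_SCORE,
    causal_ref_maf: float | None = None,
    seed=0,
    max_draws: int = 10_000_000,
) -> SyntheticCohort:
    """Plant one causal variant pair driving disease status.

    Two-locus genotypes are drawn under HWE at the model's MAF and disease
    status assigned with probability alpha m(g) / (1 + alpha m(g)),
    rejection-sampling until the cohort's case and control quotas are met.
    The two causal variants become the *only* variants of the target genes
    (pre-cleared of background signal), and the target pair is appended to
    the candidate list.

    ``causal_ref_maf`` is the reference-panel MAF recorded for the causal
    variants; semi-simulation inserts signal on vehicle variants that stay
    rare in the reference panel even when the simulated population frequency
    is higher, so it defaults to min(model.maf, 0.009) to keep the planted
    variants inside the rare-variant filter.
    """
    rng = np.random.default_rng(seed)
    gm = cohort.gm
    n_cases = gm.n_cases
    n_controls = gm.n_controls

    case_g, ctrl_g = _rejection_sample(model, n_cases, n_controls, rng, max_draws)

    gA = np.empty(len(gm.sample_ids), dtype=np.int8)
    gB = np.empty_like(gA)
    gA[gm.is_case], gB[gm.is_case] = case_g
    gA[~gm.is_case], gB[~gm.is_case] = ctrl_g

    name_a, name_b = target_pair
    for name in target_pair:
        if name not in cohort.features.index:
            raise ValueError(
                f"target gene {name} missing from the feature table; "
                "reserve it when simulating the background"
            )
    # drop any pre-existing variants of the target genes
    keep = ~cohort.sites["gene_id"].isin(target_pair).to_numpy()
    sites = cohort.sites.loc[keep].reset_index(drop=True)
    genotypes = gm.genotypes[keep]

    if causal_ref_maf is None:
        causal_ref_maf = min(model.maf, 0.009)
    causal_sites = pd.DataFrame(
        {
            "variant_id": [f"{name_a}:causal", f"{name_b}:causal"],
            "gene_id": [name_a, name_b],
            "score": causal_score,
            "reference_MAF": causal_ref_maf,
            "consequence": "missense",
            "n_alleles": 2,
        }
    )
    sites = pd.concat([sites, causal_sites], ignore_index=True)
    genotypes = np.vstack([genotypes, gA[None, :], gB[None, :]])

    features = cohort.features.copy()
    for name in target_pair:
        features.loc[name, "acc_maf"] = causal_ref_maf
        features.loc[name, "cds_times_maf"] = (
            features.loc[name, "cds_length"] * causal_ref_maf
        )

    pairs = pd.concat(
        [
            cohort.pairs,
            pd.DataFrame(
                {"gene_i": [name_a], "gene_j": [name_b], "pair_score": [0.95]}
            ),
        ],
        ignore_index=True,
    )

    new_gm = gio.GenotypeMatrix(
        genotypes=genotypes.astype(np.int8),
        variant_ids=list(sites["variant_id"]),
        sample_ids=gm.sample_ids,
        is_case=gm.is_case,
    )
    return SyntheticCohort(
        gm=new_gm,
        sites=sites,
        features=features,
        pairs=pairs,
        causal_pair=(min(target_pair), max(target_pair)),
        meta={**cohort.meta, "model": model},
    )


def _rejection_sample(model, n_cases, n_controls, rng, max_draws, chunk=65536):
    """Draw two-locus genotypes for the required case/control quotas."""
    pg = _hwe_probs(model.maf)
    got_case: list[np.ndarray] = []
    got_ctrl: list[np.ndarray] = []
    nc = nk = 0
    drawn = 0
    while (nc < n_cases or nk < n_controls) and drawn < max_draws:
        gA = rng.choice(3, size=chunk, p=pg)
        gB = rng.choice(3, size=chunk, p=pg)
        disease = rng.random(chunk) < model.penetrance(gA, gB)
        drawn += chunk
        if nc < n_cases:
            sel = np.flatnonzero(disease)[: n_cases - nc]
            got_case.append(np.stack([gA[sel], gB[sel]]))
            nc += len(sel)
        if nk < n_controls:
            sel = np.flatnonzero(~disease)[: n_controls - nk]
            got_ctrl.append(np.stack([gA[sel], gB[sel]]))
            nk += len(sel)
    if nc < n_cases or nk < n_controls:
        raise RuntimeError(
            f"rejection sampling exhausted {max_draws} draws "
            f"(got {nc}/{n_cases} cases, {nk}/{n_controls} controls); "
            "prevalence too low for the requested sample size"
        )
    return np.hstack(got_case), np.hstack(got_ctrl)


# ---------------------------------------------------------------------------
# cohort serialization (VCF + TSV sidecars)


def write_cohort(cohort: SyntheticCohort, prefix: str) -> dict:
    """Write the cohort as an uncompressed VCF plus the three TSV sidecars."""
    gm = cohort.gm
    vcf_path = f"{prefix}.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", gio.MISSING: "./."}
        for pos, (vid, row) in enumerate(zip(gm.variant_ids, gm.genotypes), start=1):
            calls = "\t".join(gt_str[int(g)] for g in row)
            fh.write(f"1\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")
    anno_path = f"{prefix}.anno.tsv"
    cohort.sites[
        ["variant_id", "gene_id", "score", "reference_MAF", "consequence"]
    ].to_csv(anno_path, sep="\t", index=False)
    feat_path = f"{prefix}.features.tsv"
    cohort.features.reset_index().to_csv(feat_path, sep="\t", index=False)
    pairs_path = f"{prefix}.pairs.tsv"
    cohort.pairs.to_csv(pairs_path, sep="\t", index=False)
    cases_path = f"{prefix}.cases.txt"
    with open(cases_path, "w") as fh:
        for s, c in zip(gm.sample_ids, gm.is_case):
            if c:
                fh.write(s + "\n")
    return {
        "vcf": vcf_path,
        "anno": anno_path,
        "features": feat_path,
        "pairs": pairs_path,
        "cases": cases_path,
    }


# ---------------------------------------------------------------------------
# experiments


def _desk_config(b_grid, t_grid, min_background) -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(
        b_grid=tuple(b_grid),
        t_grid=tuple(t_grid),
        min_background=min_background,
        apply_qc=True,
    )


def type1_experiment(
    n_samples: int = 1000,
    n_pairs: int = 40000,
    n_reps: int = 50,
    alphas=(1e-3, 1e-4, 1e-5),
    seed=0,
    b_grid=DESK_B_GRID,
    t_grid=DESK_T_GRID,
    min_background: int = tnb.MIN_BACKGROUND,
    progress=None,
) -> ExperimentResult:
    """Null-cohort calibration study.

    Per replicate, runs the full pipeline on a cohort with no planted signal,
    records the chosen cell's background MLFC, and pools the background
    p-values; type-I error at level a is the pooled fraction below a.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    cfg = _desk_config(b_grid, t_grid, min_background)
    mlfcs = np.empty(n_reps)
    pooled: list[np.ndarray] = []
    for r in range(n_reps):
        cohort = simulate_background(
            n_samples=n_samples, n_pairs=n_pairs, seed=children[r]
        )
        res = pipeline.run_arrays(
            cohort.gm, cohort.sites, cohort.features, cohort.pairs, cfg
        )
        mlfcs[r] = res.chosen.mlfc
        pooled.append(
            res.records.loc[res.records["in_background"], "p_value"].to_numpy()
        )
        if progress:
            progress(r + 1, n_reps)
    allp = np.concatenate(pooled)
    rates = {a: float(np.mean(allp < a)) for a in alphas}
    return ExperimentResult(
        background_pvalues=pooled,
        type1_rates=rates,
        mlfc_values=mlfcs,
        mlfc_mean=float(mlfcs.mean()),
        mlfc_sd=float(mlfcs.std(ddof=1)),
        n_replicates=n_reps,
        settings={
            "n_samples": n_samples,
            "n_pairs": n_pairs,
            "alphas": tuple(alphas),
            "b_grid": tuple(b_grid),
            "t_grid": tuple(t_grid),
            "seed": seed,
        },
    )


def power_experiment(
    kind: str,
    or_target: float,
    maf: float,
    n_cases: int,
    n_controls: int,
    n_reps: int = 50,
    sig_level: float = 0.05,
    prevalence: float = 0.01,
    n_pairs: int = 40000,
    seed=0,
    b_grid=DESK_B_GRID,
    t_grid=DESK_T_GRID,
    min_background: int = tnb.MIN_BACKGROUND,
    progress=None,
) -> ExperimentResult:
    """Detection rate of a planted causal pair across replicate cohorts.

    Power is the fraction of replicates whose target-pair p-value falls
    below ``sig_level``; a Clopper-Pearson 95% interval is attached.
    """
    model = solve_alpha_theta(kind, prevalence, maf, or_target)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    cfg = _desk_config(b_grid, t_grid, min_background)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        bg_seed, causal_seed = children[r].spawn(2)
        cohort = simulate_background(
            n_samples=n_cases + n_controls,
            n_pairs=n_pairs,
            seed=bg_seed,
            case_fraction=n_cases / (n_cases + n_controls),
            reserve_genes=("TARGET_A", "TARGET_B"),
        )
        cohort = insert_causal_pair(cohort, model, seed=causal_seed)
        res = pipeline.run_arrays(
            cohort.gm, cohort.sites, cohort.features, cohort.pairs, cfg
        )
        rec = res.records
        hit = rec.loc[
            (rec["gene_i"] == cohort.causal_pair[0])
            & (rec["gene_j"] == cohort.causal_pair[1])
        ]
        pvals[r] = float(hit["p_value"].iloc[0]) if len(hit) else 1.0
        if progress:
            progress(r + 1, n_reps)
    k = int((pvals < sig_level).sum())
    lo, hi = clopper_pearson(k, n_reps)
    return ExperimentResult(
        replicate_pvalues=pvals,
        power=k / n_reps,
        ci_low=lo,
        ci_high=hi,
        n_replicates=n_reps,
        settings={
            "kind": kind,
            "or": or_target,
            "maf": maf,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "sig_level": sig_level,
            "prevalence": prevalence,
            "seed": seed,
            "b_grid": tuple(b_grid),
            "t_grid": tuple(t_grid),
        },
    )


def clopper_pearson(successes: int, trials: int, level: float = 0.95):
    """Exact binomial confidence interval from beta quantiles."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    a = 1.0 - level
    lo = (
        0.0
        if successes == 0
        else float(stats.beta.ppf(a / 2, successes, trials - successes + 1))
    )
    hi = (
        1.0
        if successes == trials
        else float(stats.beta.ppf(1 - a / 2, successes + 1, trials - successes))
    )
    return lo, hi
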
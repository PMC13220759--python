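"""Input handling: genotypes, annotations, gene features, candidate pairs, QC.

Genotypes come from a VCF (v4.x, diploid, GT plus optional per-genotype DP
and GQ). Three TSV sidecars carry what the test needs beyond genotypes:

* variant annotations — ``variant_id, gene_id, score, reference_MAF,
  consequence`` (functional score in [0, 1] and reference-panel MAF);
* gene features — ``gene_id, cds_length, acc_maf, cds_times_maf, oe_mis,
  oe_lof, gc_content``;
* candidate pairs — ``gene_i, gene_j, pair_score`` (interaction-prediction
  scores in [0, 1], header optional).

QC follows the usual sequencing-study recipe: genotypes with low depth or
quality are set to no-calls, sites out of Hardy-Weinberg equilibrium in
controls or with too many alleles or too many missing genotypes are dropped,
and only rare non-synonymous variants enter the burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "NONSYNONYMOUS",
    "DEFAULT_EXCLUDED_GENES",
    "load_vcf",
    "load_features",
    "load_pairs",
    "qc_filter",
    "hwe_exact_p",
    "filter_rare",
    "select_pairs",
    "accumulated_maf",
    "pair_predictors",
    "FEATURE_COLUMNS",
]

#: non-synonymous consequence categories admitted to the burden by default
NONSYNONYMOUS = frozenset(
    {
        "missense",
        "start-loss",
        "stop-loss",
        "stop-gain",
        "splicing",
        "frameshift",
        "non-frameshift",
    }
)

#: genes with extreme CDS length whose burden swamps the baseline model
DEFAULT_EXCLUDED_GENES = (
    "TTN",
    "MUC16",
    "OBSCN",
    "NEB",
    "MUC19",
    "MUC4",
    "DST",
    "DNAH14",
)

FEATURE_COLUMNS = [
    "cds_length",
    "acc_maf",
    "cds_times_maf",
    "oe_mis",
    "oe_lof",
    "gc_content",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Minor-allele copy numbers (variants x samples), -1 for no-calls."""

    genotypes: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str]
    is_case: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    warnings_: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def case_columns(self) -> np.ndarray:
        return self.genotypes[:, self.is_case]

    def control_columns(self) -> np.ndarray:
        return self.genotypes[:, ~self.is_case]


def _sample_maf(genotypes: np.ndarray) -> np.ndarray:
    g = genotypes.astype(float)
    ok = g >= 0
    with np.errstate(invalid="ignore"):
        af = np.where(ok, g, 0.0).sum(axis=1) / np.maximum(
            2.0 * ok.sum(axis=1), 1.0
        )
    return af


def load_vcf(path, annotations, case_ids=None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF plus its annotation sidecar into a genotype matrix and
    per-variant site table.

    Multi-allelic records are split into one site per ALT allele (copy
    numbers count that allele only); sites lacking an annotation row are
    dropped with a warning count; genotypes are oriented so that copy
    numbers count the reference panel's minor allele.

    ``case_ids``: iterable of sample ids labeled as cases; defaults to
    samples whose id starts with ``"case"``.
    """
    from cyvcf2 import VCF

    anno = pd.read_csv(annotations, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "gene_id", "score", "reference_MAF", "consequence"}
    missing_cols = required - set(anno.columns)
    if missing_cols:
        raise ValueError(f"annotation file lacks columns: {sorted(missing_cols)}")
    anno = anno.set_index("variant_id")

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    counters = {"no_annotation": 0, "flipped_orientation": 0, "no_dp": 0, "no_gq": 0}

    rows, dps, gqs, meta = [], [], [], []
    n_alleles_list = []
    for rec in vcf:
        alts = rec.ALT or []
        n_alleles = 1 + len(alts)
        alleles = np.array([[gt[0], gt[1]] for gt in rec.genotypes], dtype=float)
        try:
            dp_arr = rec.format("DP")
        except KeyError:
            dp_arr = None
        try:
            gq_arr = rec.format("GQ")
        except KeyError:
            gq_arr = None
        if dp_arr is None:
            counters["no_dp"] += 1
        if gq_arr is None:
            counters["no_gq"] += 1
        for ai, alt in enumerate(alts, start=1):
            vid = rec.ID if rec.ID not in (None, ".") and len(alts) == 1 else (
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            )
            if vid not in anno.index:
                counters["no_annotation"] += 1
                continue
            g = np.where(
                np.isnan(alleles).any(axis=1) | (alleles < 0).any(axis=1),
                MISSING,
                (alleles == ai).sum(axis=1),
            ).astype(np.int8)
            rows.append(g)
            dps.append(
                dp_arr.reshape(n).astype(np.int32) if dp_arr is not None else None
            )
            gqs.append(
                gq_arr.reshape(n).astype(np.int32) if gq_arr is not None else None
            )
            meta.append(vid)
            n_alleles_list.append(n_alleles)
    vcf.close()

    if counters["no_annotation"]:
        warnings.warn(
            f"{counters['no_annotation']} variant(s) without annotation dropped"
        )
    for field_name, key in (("DP", "no_dp"), ("GQ", "no_gq")):
        if counters[key]:
            warnings.warn(
                f"{field_name} absent for {counters[key]} record(s); "
                f"{field_name}-based genotype masking will be skipped there"
            )

    genotypes = (
        np.vstack(rows) if rows else np.empty((0, n), dtype=np.int8)
    )
    sites = anno.loc[meta].reset_index()
    sites["n_alleles"] = n_alleles_list

    # orient to the reference panel's minor allele
    flip = sites["reference_MAF"].to_numpy() > 0.5
    if flip.any():
        counters["flipped_orientation"] = int(flip.sum())
        gflip = genotypes[flip]
        gflip = np.where(gflip == MISSING, MISSING, 2 - gflip).astype(np.int8)
        genotypes[flip] = gflip
        sites.loc[flip, "reference_MAF"] = 1.0 - sites.loc[flip, "reference_MAF"]

    if case_ids is None:
        is_case = np.array([s.startswith("case") for s in samples])
    else:
        case_set = set(case_ids)
        is_case = np.array([s in case_set for s in samples])

    def _stack(arrs):
        if not arrs or any(a is None for a in arrs):
            return None
        return np.vstack(arrs)

    gm = GenotypeMatrix(
        genotypes=genotypes,
        variant_ids=meta,
        sample_ids=samples,
        is_case=is_case,
        dp=_stack(dps),
        gq=_stack(gqs),
        warnings_=counters,
    )
    sites["sample_MAF"] = _sample_maf(genotypes)
    return gm, sites


def load_features(path) -> pd.DataFrame:
    """Gene feature table keyed on gene_id; validates X3 = X1 * X2."""
    feats = pd.read_csv(path, sep="\t")
    need = {"gene_id", *FEATURE_COLUMNS}
    if not need <= set(feats.columns):
        raise ValueError(f"feature file lacks columns: {sorted(need - set(feats.columns))}")
    bad = ~np.isclose(
        feats["cds_times_maf"],
        feats["cds_length"] * feats["acc_maf"],
        rtol=1e-9,
        atol=1e-12,
    )
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} gene(s) violate cds_times_maf = cds_length * acc_maf"
        )
    if (feats["cds_length"] <= 0).any():
        raise ValueError("cds_length must be positive")
    return feats.set_index("gene_id")


def load_pairs(path) -> pd.DataFrame:
    """Three-column candidate pair TSV (gene, gene, score); header optional."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = not _is_number(first.iloc[0, 2])
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    df.columns = ["gene_i", "gene_j", "pair_score"]
    return df


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# QC


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value (Wigginton et al. 2005).

    Two-sided: sum of probabilities of heterozygote counts no more likely
    than the observed one, conditional on the allele counts.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    if rare == 0:
        return 1.0
    # log-probabilities over all het counts with the parity of `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    out = np.ones(genotypes.shape[0])
    for i, g in enumerate(genotypes):
        g = g[g >= 0]
        n_het = int((g == 1).sum())
        n_hom_alt = int((g == 2).sum())
        n_hom_ref = int((g == 0).sum())
        out[i] = hwe_exact_p(n_het, min(n_hom_alt, n_hom_ref), max(n_hom_alt, n_hom_ref))
    return out


def qc_filter(
    gm: GenotypeMatrix,
    sites: pd.DataFrame,
    hwe_threshold: float = 1e-5,
    dp_min: int = 8,
    gq_min: int = 20,
    missing_max: float = 0.20,
    max_alleles: int = 4,
    hwe_on: str = "controls",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Site- and genotype-level QC.

    Genotypes with DP < dp_min or GQ < gq_min become no-calls (skipped per
    field when the VCF lacks it); sites with HWE exact p <= hwe_threshold
    (computed on control samples, where association cannot distort the
    test), with more than ``max_alleles`` alleles, or with a post-masking
    missing rate above ``missing_max`` are removed. Idempotent: the surviving
    matrix passes unchanged through a second application.
    """
    g = gm.genotypes.copy()
    if gm.dp is not None:
        g[gm.dp < dp_min] = MISSING
    if gm.gq is not None:
        g[gm.gq < gq_min] = MISSING

    hwe_src = g[:, ~gm.is_case] if hwe_on == "controls" else g
    if hwe_src.shape[1] == 0:
        hwe_src = g
    hwe_p = _hwe_pvalues(hwe_src)

    n_alleles = (
        sites["n_alleles"].to_numpy()
        if "n_alleles" in sites.columns
        else np.full(len(sites), 2)
    )
    keep = (hwe_p > hwe_threshold) & (n_alleles <= max_alleles)

    missing_rate = (g == MISSING).mean(axis=1)
    keep &= missing_rate <= missing_max

    sites = sites.loc[keep].copy()
    sites["hwe_p"] = hwe_p[keep]
    sites["missing_rate"] = missing_rate[keep]
    sites["sample_MAF"] = _sample_maf(g[keep])
    new_gm = GenotypeMatrix(
        genotypes=g[keep],
        variant_ids=[v for v, k in zip(gm.variant_ids, keep) if k],
        sample_ids=gm.sample_ids,
        is_case=gm.is_case,
        dp=gm.dp[keep] if gm.dp is not None else None,
        gq=gm.gq[keep] if gm.gq is not None else None,
        warnings_=dict(gm.warnings_),
    )
    return new_gm, sites.reset_index(drop=True)


# ---------------------------------------------------------------------------
# variant and pair selection


def filter_rare(
    sites: pd.DataFrame,
    maf_cutoff: float = 0.01,
    use_reference: bool = True,
    consequences=NONSYNONYMOUS,
) -> pd.DataFrame:
    """Keep non-synonymous sites with MAF strictly below the cutoff.

    The MAF source is the reference panel by default (in-sample otherwise).
    """
    if not (0.0 < maf_cutoff <= 0.5):
        raise ValueError(f"maf_cutoff must lie in (0, 0.5], got {maf_cutoff}")
    maf = sites["reference_MAF"] if use_reference else sites["sample_MAF"]
    keep = (maf < maf_cutoff) & sites["consequence"].isin(consequences)
    return sites.loc[keep].copy()


def select_pairs(
    pairs: pd.DataFrame,
    score_threshold: float = 0.8,
    exclude_genes=DEFAULT_EXCLUDED_GENES,
    features: pd.DataFrame | None = None,
    genes_with_variants=None,
) -> pd.DataFrame:
    """Candidate pairs with prediction score strictly above the threshold.

    Unordered pairs are canonicalized (lexicographic) and deduplicated;
    a pair listed twice with conflicting scores is an error. Pairs touching
    ``exclude_genes``, genes absent from the feature table, or genes without
    retained rare variants are removed.
    """
    df = pairs.copy()
    if (df["gene_i"] == df["gene_j"]).any():
        raise ValueError("self-pairs (gene_i == gene_j) are not allowed")
    lo = df[["gene_i", "gene_j"]].min(axis=1)
    hi = df[["gene_i", "gene_j"]].max(axis=1)
    df["gene_i"], df["gene_j"] = lo, hi
    grouped = df.groupby(["gene_i", "gene_j"])["pair_score"]
    conflict = grouped.nunique() > 1
    if conflict.any():
        offenders = conflict[conflict].index.tolist()
        raise ValueError(f"conflicting scores for duplicated pairs: {offenders}")
    df = df.drop_duplicates(subset=["gene_i", "gene_j"])
    keep = df["pair_score"] > score_threshold
    excl = set(exclude_genes or ())
    if excl:
        keep &= ~df["gene_i"].isin(excl) & ~df["gene_j"].isin(excl)
    if features is not None:
        have = set(features.index)
        keep &= df["gene_i"].isin(have) & df["gene_j"].isin(have)
    if genes_with_variants is not None:
        have = set(genes_with_variants)
        keep &= df["gene_i"].isin(have) & df["gene_j"].isin(have)
    return df.loc[keep].reset_index(drop=True)


def accumulated_maf(gene_sites: pd.DataFrame, use_reference: bool = True) -> float:
    """Accumulated MAF (X2) of one gene: the sum of reference-panel MAFs over
    its qualifying rare variants (0 for a gene with none)."""
    if len(gene_sites) == 0:
        return 0.0
    col = "reference_MAF" if use_reference else "sample_MAF"
    return float(gene_sites[col].sum())


def pair_predictors(fi, fj, x7=None, include_x7: bool = True) -> np.ndarray:
    """Predictor vector of a gene pair: elementwise products of the six gene
    features, plus the control burden X7 when requested.

    ``fi``/``fj`` are feature rows (mapping or Series with FEATURE_COLUMNS).
    """
    if fi is fj or (
        hasattr(fi, "name") and hasattr(fj, "name") and fi.name == fj.name
    ):
        raise ValueError("a gene cannot be paired with itself")
    prods = np.array([float(fi[c]) * float(fj[c]) for c in FEATURE_COLUMNS])
    if prods[0] <= 0:
        raise ValueError("nonpositive CDS-length product: degenerate gene")
    if include_x7:
        if x7 is None:
            raise ValueError("include_x7 requested but x7 is None")
        return np.append(prods, float(x7))
    return prods
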
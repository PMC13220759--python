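"""Rare-variant interaction burden (RVIB) for gene pairs.

For a pair of genes (i, j) and K case subjects, the basic burden is

    y_ij = sum_k max{ g_{i,p,k} * g_{j,q,k} : p in V_i, q in V_j }

where g in {0, 1, 2} is the minor-allele copy number. Only subjects carrying
at least one minor allele in *both* genes contribute (the product is zero
otherwise). The functionally weighted burden replaces each copy number by
w_v * g_v, where w_v = ceil(s_v / b) converts a pathogenicity score
s_v in [0, 1] into an integer weight at bin length b.

Because all terms are nonnegative, the maximum over cross-gene variant pairs
factorizes:

    max_{p,q} (w_p g_p)(w_q g_q) = (max_p w_p g_p) * (max_q w_q g_q)

so per-sample, per-gene maxima are computed once and burdens for all pairs
reduce to elementwise products. The exhaustive double loop is kept in the
test suite as an independent oracle.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "integer_weight",
    "rvib_basic",
    "rvib_weighted",
    "control_rvib",
    "gene_sample_max",
    "pair_burdens",
]


def integer_weight(s, b: float):
    """Integer functional weight ceil(s / b) for score(s) in [0, 1].

    ``s`` may be a scalar or array. A score of exactly 0 yields weight 0:
    the variant carries no pathogenic evidence and drops out of the
    weighted burden.
    """
    if not (0.0 < b <= 1.0):
        raise ValueError(f"bin length b must be in (0, 1], got {b}")
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("functional scores must lie in [0, 1]")
    w = np.ceil(s / b).astype(np.int64)
    if w.ndim == 0:
        return int(w)
    return w


def _clean(g) -> np.ndarray:
    """Genotypes as float array with missing (<0 or NaN) set to 0 copies."""
    g = np.asarray(g, dtype=float)
    g = np.where(np.isfinite(g), g, 0.0)
    return np.where(g < 0, 0.0, g)


def gene_sample_max(genotypes, weights=None) -> np.ndarray:
    """Per-sample maximum of (weight * copy number) over one gene's variants.

    genotypes: (n_variants, n_samples); weights: (n_variants,) or None for
    the unweighted burden. Returns a (n_samples,) vector; zero variants give
    the empty max, defined as 0.
    """
    g = _clean(genotypes)
    if g.ndim != 2:
        g = np.atleast_2d(g)
    if g.shape[0] == 0:
        return np.zeros(g.shape[1] if g.ndim == 2 else 0)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != g.shape[0]:
            raise ValueError(
                f"weight vector length {w.shape[0]} != variant count {g.shape[0]}"
            )
        g = g * w[:, None]
    return g.max(axis=0)


def rvib_basic(g_i, g_j) -> int:
    """Basic RVIB y_ij over cases: sum_k max_{p,q} g_i[p,k] * g_j[q,k].

    ``g_i``/``g_j`` are (variants, cases) copy-number matrices for the two
    genes, columns aligned on the same case subjects. Missing genotypes
    count as 0 copies. Zero variants in either gene give 0.
    """
    mi = gene_sample_max(g_i)
    mj = gene_sample_max(g_j)
    if mi.shape != mj.shape:
        raise ValueError("case columns of the two genes do not align")
    return int(round(float(np.sum(mi * mj))))


def rvib_weighted(g_i, g_j, w_i, w_j) -> int:
    """Weighted RVIB Y_ij: as :func:`rvib_basic` with copy numbers scaled by
    the integer functional weights of their variants."""
    mi = gene_sample_max(g_i, w_i)
    mj = gene_sample_max(g_j, w_j)
    if mi.shape != mj.shape:
        raise ValueError("case columns of the two genes do not align")
    return int(round(float(np.sum(mi * mj))))


def control_rvib(g_i, g_j, w_i, w_j):
    """Weighted interaction burden of the pair observed in controls (X7).

    Returns None when there are zero control samples; the caller must then
    drop the control-burden predictor from the regression.
    """
    g_i = np.atleast_2d(np.asarray(g_i))
    if g_i.shape[1] == 0:
        return None
    return rvib_weighted(g_i, g_j, w_i, w_j)


def pair_burdens(M: np.ndarray, gi_idx, gj_idx, chunk: int = 4096) -> np.ndarray:
    """Burdens for many pairs at once from a per-gene max matrix.

    ``M`` is (n_genes, n_samples) holding the per-sample maxima returned by
    :func:`gene_sample_max` for every gene (weighted or not); ``gi_idx`` /
    ``gj_idx`` index the genes of each pair. Returns integer burdens summed
    over the samples in ``M``. Pairs are processed in chunks to bound the
    temporary (pairs x samples) product matrix.
    """
    gi_idx = np.asarray(gi_idx)
    gj_idx = np.asarray(gj_idx)
    out = np.empty(len(gi_idx), dtype=np.int64)
    Mf = np.ascontiguousarray(M, dtype=np.float32)
    for lo in range(0, len(gi_idx), chunk):
        sl = slice(lo, lo + chunk)
        prod = Mf[gi_idx[sl]] * Mf[gj_idx[sl]]
        out[sl] = np.rint(prod.sum(axis=1, dtype=np.float64)).astype(np.int64)
    return out


def max_weight(b: float) -> int:
    """Largest attainable weight at bin length b (score 1.0)."""
    return int(math.ceil(1.0 / b))
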
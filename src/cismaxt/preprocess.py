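"""Preprocessing transforms: M-values, column standardization, perfect-LD filter."""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import Layer, OmicsMatrix

logger = logging.getLogger(__name__)

#: beta-values are clipped into [BETA_CLIP, 1 - BETA_CLIP] before the logit2
#: transform; values of exactly 0 or 1 otherwise map to +/- infinity.
BETA_CLIP = 1e-6

#: squared correlations at least 1 - LD_TOL count as perfect LD.
LD_TOL = 1e-12


def beta_to_m(beta, clip: float = BETA_CLIP):
    """Methylation beta-values to M-values, ``M = log2(beta / (1 - beta))``.

    M-values are preferred for linear modelling because their variance is
    approximately constant across the methylation range, unlike the
    proportion-scale beta-values.  Boundary values are clipped into
    ``[clip, 1 - clip]`` (count logged); values outside [0, 1] raise.
    """
    arr = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("beta-values contain missing/non-finite entries")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("beta-values must lie in [0, 1]")
    n_clip = int(np.sum((arr < clip) | (arr > 1 - clip)))
    if n_clip:
        logger.info("beta_to_m: clipped %d boundary beta-value(s) to [%g, %g]",
                    n_clip, clip, 1 - clip)
        arr = np.clip(arr, clip, 1 - clip)
    out = np.log2(arr / (1.0 - arr))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2**M / (1 + 2**M)``."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


def transform_cpg_matrix(cpg: OmicsMatrix, clip: float = BETA_CLIP) -> OmicsMatrix:
    """Return a copy of a beta-value CpG matrix on the M-value scale."""
    if cpg.layer is not Layer.CPG:
        raise ValueError("transform_cpg_matrix expects a CPG-layer matrix")
    return OmicsMatrix(
        values=beta_to_m(cpg.values, clip=clip),
        sample_ids=cpg.sample_ids,
        annotations=cpg.annotations,
        layer=Layer.CPG,
    )


def standardize_columns(design: np.ndarray):
    """Center and scale the columns of a samples x features design.

    Scaling uses the population standard deviation (divide by n), the
    normalization under which the coordinate-descent penalty grids below are
    expressed.  Constant columns carry no signal and are dropped (logged).

    Returns
    -------
    standardized : ndarray, shape (n_samples, n_kept)
    means, scales : per-kept-column center and scale
    kept : integer indices of retained columns in the input
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D (samples x features)")
    if X.shape[1] == 0:
        return X.copy(), np.empty(0), np.empty(0), np.empty(0, dtype=int)
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # population convention (ddof=0)
    kept = np.flatnonzero(scales > 0)
    n_drop = X.shape[1] - kept.size
    if n_drop:
        logger.info("standardize_columns: dropped %d constant column(s)", n_drop)
    Xs = (X[:, kept] - means[kept]) / scales[kept]
    return Xs, means[kept], scales[kept], kept


def filter_perfect_ld(snps: OmicsMatrix, tol: float = LD_TOL) -> OmicsMatrix:
    """Drop SNPs in perfect LD (r^2 = 1) with an earlier SNP.

    Two dosage vectors are in perfect LD when their squared Pearson
    correlation is 1; that includes perfectly anti-correlated pairs (allele
    coding flips).  Within each perfect-LD group only the first feature in
    annotation (genomic) order is kept; output row order is preserved.
    Constant rows have no defined correlation and are always retained.

    Detection is exact up to ``tol`` on r^2 but runs in O(features x samples):
    a row attains r^2 = 1 with another iff their z-scored vectors agree up to
    sign, so rows are grouped by a rounded sign-canonical z-score key and
    candidate groups verified by direct correlation.
    """
    if snps.layer is not Layer.SNP:
        raise ValueError("filter_perfect_ld expects a SNP-layer matrix")
    X = snps.values
    m = X.shape[0]
    if m == 0:
        return snps
    sd = X.std(axis=1)
    keep = np.ones(m, dtype=bool)
    variable = np.flatnonzero(sd > 0)
    if variable.size:
        Z = (X[variable] - X[variable].mean(axis=1, keepdims=True)) / sd[variable, None]
        # canonical sign: first nonzero entry positive
        first_nz = np.argmax(np.abs(Z) > 1e-9, axis=1)
        signs = np.sign(Z[np.arange(Z.shape[0]), first_nz])
        signs[signs == 0] = 1.0
        Zc = Z * signs[:, None]
        # r^2 >= 1 - tol  <=>  min over sign of ||z1 -/+ z2||^2 <= n * (1 - sqrt(1-tol)) * 2
        decimals = 6
        rounded = np.round(Zc, decimals)
        rounded[rounded == 0] = 0.0  # normalize -0.0 so keys hash equally
        groups: dict[bytes, list[int]] = {}
        for pos, row in zip(variable, rounded):
            groups.setdefault(row.tobytes(), []).append(pos)
        r2_cut = 1.0 - tol
        for members in groups.values():
            if len(members) < 2:
                continue
            head = members[0]
            zh = Z[np.searchsorted(variable, head)]
            n = zh.size
            for other in members[1:]:
                zo = Z[np.searchsorted(variable, other)]
                r = float(zh @ zo) / n
                if r * r >= r2_cut:
                    keep[other] = False
    n_drop = int(m - keep.sum())
    if n_drop:
        logger.info("filter_perfect_ld: removed %d SNP(s) in perfect LD", n_drop)
    rows = np.flatnonzero(keep)
    return OmicsMatrix(
        values=X[rows],
        sample_ids=snps.sample_ids,
        annotations=[snps.annotations[i] for i in rows],
        layer=Layer.SNP,
    )
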
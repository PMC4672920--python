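"""Synthetic three-layer datasets: null expression, HWE genotypes, methylation.

The null generator draws expression probes i.i.d. Normal(mu = 8.4,
sigma^2 = 0.4) — log2-microarray-like intensities — for n = 27 samples by
default, independent of every predictor, so any association a screen finds
on such data is a false positive.  Genotype and methylation generators are
deliberately minimal but preserve the two statistical features the
penalized screen must confront: multicollinearity (LD blocks of SNPs, CpG
islands with exchangeable correlation) and p >> n.  The signal generator
plants known cis effects for power and recovery studies.

Probes are laid out at regular spacing wide enough that +/-1Mb windows of
distinct probes never share features; their SNPs and CpGs are placed
uniformly inside each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import FeatureAnnotation, Layer, OmicsMatrix
from .preprocess import m_to_beta

GENE_LENGTH = 10_000
PROBE_SPACING = 2_200_000  # keeps +/-1Mb windows of same-chrom neighbours disjoint
N_CHROMS = 22


@dataclass
class SimSpec:
    """Parameters of one synthetic dataset.

    Defaults reproduce the null-simulation conditions (27 samples,
    expression ~ Normal(8.4, 0.4)); ``m_probes`` scales the probe count.
    """

    m_probes: int = 200
    n_samples: int = 27
    mu: float = 8.4
    sigma2: float = 0.4
    snps_per_window: int = 50
    cpgs_per_window: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_flip_prob: float = 0.1
    cpg_corr: float = 0.5
    cpg_island_size: int = 5
    effects: tuple[tuple[str, str, float], ...] = ()  # (probe, feature, beta)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.cpg_corr < 1):
            raise ValueError("cpg_corr must lie in [0, 1)")
        if self.ld_block_size < 1 or self.cpg_island_size < 1:
            raise ValueError("block/island sizes must be >= 1")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def probe_location(self, i: int) -> tuple[str, int, int]:
        chrom = f"chr{i % N_CHROMS + 1}"
        start = 1_500_000 + (i // N_CHROMS) * PROBE_SPACING
        return chrom, start, start + GENE_LENGTH

    def _seeds(self):
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("expression", "snp", "cpg", "signal"), children))


def _probe_annotations(spec: SimSpec) -> list[FeatureAnnotation]:
    out = []
    for i in range(spec.m_probes):
        chrom, start, end = spec.probe_location(i)
        out.append(FeatureAnnotation(
            feature_id=f"probe{i:05d}", chrom=chrom, start=start, end=end,
            layer=Layer.EXPRESSION,
        ))
    return out


def simulate_null_expression(spec: SimSpec) -> OmicsMatrix:
    """i.i.d. Normal(mu, sigma2) expression, independent of all predictors."""
    rng = np.random.default_rng(spec._seeds()["expression"])
    values = rng.normal(spec.mu, np.sqrt(spec.sigma2),
                        size=(spec.m_probes, spec.n_samples))
    return OmicsMatrix(values=values, sample_ids=spec.sample_ids(),
                       annotations=_probe_annotations(spec),
                       layer=Layer.EXPRESSION)


def _window_positions(spec: SimSpec, i: int, count: int,
                      rng: np.random.Generator) -> np.ndarray:
    chrom, start, end = spec.probe_location(i)
    lo = max(0, start - 1_000_000)
    hi = end + 1_000_000
    # distinct uniform positions; the window dwarfs count, so top-ups are rare
    pos = np.unique(rng.integers(lo, hi, size=2 * count))
    while pos.size < count:
        pos = np.unique(np.concatenate([pos, rng.integers(lo, hi, size=count)]))
    return np.sort(rng.choice(pos, size=count, replace=False))


def simulate_genotypes(spec: SimSpec) -> OmicsMatrix:
    """Hardy-Weinberg dosages 0/1/2 with LD blocks, one window per probe.

    Within each block of ``ld_block_size`` SNPs, genotypes copy a block
    founder; each sample's copy is independently redrawn from the founder's
    HWE distribution with probability ``ld_flip_prob``, so flip probability 0
    yields perfect LD inside the block and block size 1 independent SNPs.
    """
    rng = np.random.default_rng(spec._seeds()["snp"])
    values, annotations = [], []
    for i in range(spec.m_probes):
        chrom, _, _ = spec.probe_location(i)
        positions = _window_positions(spec, i, spec.snps_per_window, rng)
        j = 0
        while j < spec.snps_per_window:
            block = min(spec.ld_block_size, spec.snps_per_window - j)
            maf = rng.uniform(*spec.maf_range)
            founder = rng.binomial(2, maf, size=spec.n_samples)
            for _ in range(block):
                geno = founder.copy()
                flip = rng.random(spec.n_samples) < spec.ld_flip_prob
                if flip.any():
                    geno[flip] = rng.binomial(2, maf, size=int(flip.sum()))
                values.append(geno)
                annotations.append(FeatureAnnotation(
                    feature_id=f"snp{i:05d}_{j:04d}", chrom=chrom,
                    start=int(positions[j]), end=int(positions[j]) + 1,
                    layer=Layer.SNP,
                ))
                j += 1
    return OmicsMatrix(values=np.array(values, dtype=float),
                       sample_ids=spec.sample_ids(),
                       annotations=annotations, layer=Layer.SNP)


def simulate_methylation(spec: SimSpec) -> OmicsMatrix:
    """Beta-value methylation with exchangeable latent correlation in islands.

    A latent M-value for CpG j of island s is ``mean_j + sqrt(rho) * f_s +
    sqrt(1 - rho) * e_j`` with standard-normal island factor and noise; the
    logistic inverse of the M-transform maps it into (0, 1), so transforming
    the returned beta-values back recovers the latent Gaussian exactly.
    """
    rng = np.random.default_rng(spec._seeds()["cpg"])
    rho = spec.cpg_corr
    values, annotations = [], []
    for i in range(spec.m_probes):
        chrom, _, _ = spec.probe_location(i)
        positions = _window_positions(spec, i, spec.cpgs_per_window, rng)
        j = 0
        while j < spec.cpgs_per_window:
            island = min(spec.cpg_island_size, spec.cpgs_per_window - j)
            factor = rng.standard_normal(spec.n_samples)
            for _ in range(island):
                mean_j = rng.uniform(-3, 3)
                latent = mean_j + np.sqrt(rho) * factor + \
                    np.sqrt(1 - rho) * rng.standard_normal(spec.n_samples)
                values.append(m_to_beta(latent))
                annotations.append(FeatureAnnotation(
                    feature_id=f"cpg{i:05d}_{j:04d}", chrom=chrom,
                    start=int(positions[j]), end=int(positions[j]) + 1,
                    layer=Layer.CPG,
                ))
                j += 1
    return OmicsMatrix(values=np.array(values, dtype=float),
                       sample_ids=spec.sample_ids(),
                       annotations=annotations, layer=Layer.CPG)


@dataclass
class SimulatedDataset:
    expression: OmicsMatrix
    snps: OmicsMatrix
    cpgs: OmicsMatrix
    spec: SimSpec


def simulate_with_signal(spec: SimSpec) -> SimulatedDataset:
    """Linked three-layer dataset with planted cis effects.

    Probes named in ``spec.effects`` get ``mu + sum(beta *
    standardized(feature)) + Normal(0, noise_sd^2)``; every other probe (and
    every feature not referenced) stays at the null Normal(mu, sigma2),
    independent of the predictors.  An empty effects list therefore reduces
    to :func:`simulate_null_expression` plus independent predictor layers.
    """
    expression = simulate_null_expression(spec)
    snps = simulate_genotypes(spec)
    cpgs = simulate_methylation(spec)
    if spec.effects:
        rng = np.random.default_rng(spec._seeds()["signal"])
        probe_rows = expression.row_index()
        feature_rows = {Layer.SNP: snps.row_index(), Layer.CPG: cpgs.row_index()}
        by_probe: dict[str, list[tuple[str, float]]] = {}
        for probe_id, feature_id, beta in spec.effects:
            if probe_id not in probe_rows:
                raise ValueError(f"effect references unknown probe {probe_id!r}")
            by_probe.setdefault(probe_id, []).append((feature_id, float(beta)))
        values = expression.values.copy()
        for probe_id, feats in by_probe.items():
            y = np.full(spec.n_samples, spec.mu)
            for feature_id, beta in feats:
                if feature_id in feature_rows[Layer.SNP]:
                    x = snps.values[feature_rows[Layer.SNP][feature_id]]
                elif feature_id in feature_rows[Layer.CPG]:
                    x = cpgs.values[feature_rows[Layer.CPG][feature_id]]
                else:
                    raise ValueError(
                        f"effect references unknown feature {feature_id!r}")
                sd = x.std()
                if sd == 0:
                    raise ValueError(
                        f"effect feature {feature_id!r} is constant in this draw")
                y = y + beta * (x - x.mean()) / sd
            values[probe_rows[probe_id]] = y + rng.normal(
                0.0, spec.noise_sd, size=spec.n_samples)
        expression = OmicsMatrix(values=values, sample_ids=expression.sample_ids,
                                 annotations=expression.annotations,
                                 layer=Layer.EXPRESSION)
    return SimulatedDataset(expression=expression, snps=snps, cpgs=cpgs,
                            spec=spec)
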
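"""Core containers for sample-aligned omics matrices and their genomic annotations.

Three feature layers are handled: expression probes (continuous intensities),
SNP dosages (0/1/2 or real dosages in [0, 2]) and CpG methylation (beta-values
in (0, 1), or M-values after the logit2 transform).  All layers share one set
of samples; rows are features carrying a genomic interval annotation in BED
convention (0-based, half-open).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class Layer(str, enum.Enum):
    """Which omics layer a feature or matrix belongs to."""

    EXPRESSION = "expression"
    SNP = "snp"
    CPG = "cpg"


class ModelKind(str, enum.Enum):
    """Predictor set of the per-gene multivariable model.

    SNP uses cis-window SNP dosages only, CPG uses cis-window CpG columns
    only, and GLOBAL concatenates both layers into one design.
    """

    SNP = "snp"
    CPG = "cpg"
    GLOBAL = "global"


class MethodKind(str, enum.Enum):
    """Penalty family: pure L1 (LASSO) or L1+L2 mixture (elastic net)."""

    LASSO = "lasso"
    ENET = "enet"


@dataclass(frozen=True, slots=True)
class FeatureAnnotation:
    """Genomic location of one probe, SNP or CpG.

    Coordinates follow the BED convention: ``start`` is 0-based inclusive,
    ``end`` exclusive.  Point features (SNPs, CpGs) use ``end = start + 1``.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    layer: Layer

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"feature {self.feature_id!r}: start must be >= 0, got {self.start}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id!r}: end ({self.end}) must be > start ({self.start})"
            )


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix bound to row annotations.

    Invariants enforced at construction: no missing values, one annotation
    per row, unique feature ids and sample ids, and SNP dosages within
    [0, 2].  CpG values may be beta-values or M-values; range checks for
    beta-values happen in :func:`cismaxt.preprocess.beta_to_m`.
    """

    values: np.ndarray
    sample_ids: list[str]
    annotations: list[FeatureAnnotation]
    layer: Layer

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.annotations = list(self.annotations)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        n_feat, n_samp = self.values.shape
        if len(self.annotations) != n_feat:
            raise ValueError(
                f"{n_feat} rows but {len(self.annotations)} annotations"
            )
        if len(self.sample_ids) != n_samp:
            raise ValueError(
                f"{n_samp} columns but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("sample ids are not unique")
        ids = [a.feature_id for a in self.annotations]
        if len(set(ids)) != n_feat:
            raise ValueError(f"duplicated feature ids within layer {self.layer.value}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "missing/non-finite value at feature "
                f"{ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.layer is Layer.SNP and n_feat:
            if self.values.min() < 0 or self.values.max() > 2:
                raise ValueError("SNP dosages must lie in [0, 2]")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return [a.feature_id for a in self.annotations]

    def row_index(self) -> dict[str, int]:
        return {a.feature_id: i for i, a in enumerate(self.annotations)}

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        """Row-subset by feature id, preserving the requested order."""
        idx = self.row_index()
        rows = [idx[f] for f in feature_ids]
        return OmicsMatrix(
            values=self.values[rows],
            sample_ids=self.sample_ids,
            annotations=[self.annotations[r] for r in rows],
            layer=self.layer,
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Column-reorder to the given sample id order (must be a permutation)."""
        if set(sample_ids) != set(self.sample_ids) or len(sample_ids) != self.n_samples:
            raise ValueError(
                f"sample ids for layer {self.layer.value} do not match the requested order"
            )
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return OmicsMatrix(
            values=self.values[:, cols],
            sample_ids=list(sample_ids),
            annotations=self.annotations,
            layer=self.layer,
        )


def _default_enet_grid() -> tuple[float, ...]:
    # 0.01 .. 0.99 in steps of 0.01 on the L1-fraction scale
    return tuple(np.round(np.arange(1, 100) / 100.0, 2))


@dataclass
class AnalysisConfig:
    """Knobs of one screening run.

    Parameters
    ----------
    window_bp : cis-window half-width in base pairs around the gene interval.
    k_folds : folds of the cross-validation selecting the penalty.
    n_permutations : B, number of maxT permutation replicates.
    alpha_threshold : adjusted-p significance cut-off (strict ``<``).
    l1_fraction_grid : elastic-net candidate L1 fractions in (0, 1];
        ignored for LASSO (fixed at 1.0).  ``None`` means 0.01..0.99 by 0.01.
    lambda_path_size, lambda_min_ratio : geometric penalty path
        from lambda_max down to ``lambda_max * lambda_min_ratio``.
    seed : master seed; permutation plan and fold shuffling derive from it.
    model, method : which design and penalty family to run.
    shared_permutations : if True (default) one sample reordering per
        replicate is applied to every probe, preserving inter-gene
        dependence in the permutation null; if False each probe draws its
        own reorderings.
    """

    window_bp: int = 1_000_000
    k_folds: int = 5
    n_permutations: int = 100
    alpha_threshold: float = 0.1
    l1_fraction_grid: tuple[float, ...] | None = None
    lambda_path_size: int = 20
    lambda_min_ratio: float = 0.01
    seed: int = 0
    model: ModelKind = ModelKind.SNP
    method: MethodKind = MethodKind.LASSO
    shared_permutations: bool = True

    def __post_init__(self) -> None:
        self.model = ModelKind(self.model)
        self.method = MethodKind(self.method)
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations (B) must be >= 1")
        if not (0 < self.alpha_threshold <= 1):
            raise ValueError("alpha_threshold must lie in (0, 1]")
        if self.lambda_path_size < 2:
            raise ValueError("lambda_path_size must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.l1_fraction_grid is not None:
            grid = tuple(float(g) for g in self.l1_fraction_grid)
            if not grid:
                raise ValueError("l1_fraction_grid must be nonempty")
            if any(not (0 < g <= 1) for g in grid):
                raise ValueError("l1_fraction_grid values must lie in (0, 1]")
            self.l1_fraction_grid = grid

    def effective_grid(self) -> tuple[float, ...]:
        """The L1-fraction grid actually searched for the configured method."""
        if self.method is MethodKind.LASSO:
            return (1.0,)
        if self.l1_fraction_grid is None:
            return _default_enet_grid()
        return self.l1_fraction_grid

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = self.model.value
        d["method"] = self.method.value
        if self.l1_fraction_grid is not None:
            d["l1_fraction_grid"] = list(self.l1_fraction_grid)
        return d
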
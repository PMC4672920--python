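"""Cis-window construction: candidate SNPs/CpGs within +/- window_bp of each gene.

The window of a probe annotated on ``[gene_start, gene_end)`` spans
``[max(0, gene_start - window_bp), gene_end + window_bp)`` on the same
chromosome, symmetric in both directions and strand-agnostic.  Point features
(SNPs, CpGs) belong to the window when their start lies inside it; interval
features when they overlap it.  Probes with no candidate features keep empty
lists — they remain hypotheses with deviance 0 downstream, so the tested
family is always the full probe universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import FeatureAnnotation


@dataclass
class GeneWindow:
    """Candidate cis features for one expression probe."""

    probe_id: str
    chrom: str
    window_start: int
    window_end: int
    snp_ids: list[str] = field(default_factory=list)
    cpg_ids: list[str] = field(default_factory=list)
    gene_symbol: str | None = None


def _layer_arrays(annotations: Iterable[FeatureAnnotation]):
    """Group annotations by chromosome into position-sorted arrays."""
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a)
    out = {}
    for chrom, anns in by_chrom.items():
        anns.sort(key=lambda a: (a.start, a.end, a.feature_id))
        out[chrom] = (
            np.array([a.start for a in anns]),
            np.array([a.end for a in anns]),
            [a.feature_id for a in anns],
        )
    return out


def build_windows(
    expression_annotations: Iterable[FeatureAnnotation],
    snp_annotations: Iterable[FeatureAnnotation] = (),
    cpg_annotations: Iterable[FeatureAnnotation] = (),
    window_bp: int = 1_000_000,
) -> dict[str, GeneWindow]:
    """Build one :class:`GeneWindow` per expression probe.

    A probe on a chromosome absent from a feature layer simply gets an empty
    candidate list for that layer.  Candidate lists come out ordered by
    genomic position.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    snp_idx = _layer_arrays(snp_annotations)
    cpg_idx = _layer_arrays(cpg_annotations)

    def members(idx, chrom, ws, we):
        entry = idx.get(chrom)
        if entry is None:
            return []
        starts, ends, ids = entry
        mask = (starts < we) & (ends > ws)
        return [ids[i] for i in np.flatnonzero(mask)]

    windows: dict[str, GeneWindow] = {}
    for probe in expression_annotations:
        ws = max(0, probe.start - window_bp)
        we = probe.end + window_bp
        windows[probe.feature_id] = GeneWindow(
            probe_id=probe.feature_id,
            chrom=probe.chrom,
            window_start=ws,
            window_end=we,
            snp_ids=members(snp_idx, probe.chrom, ws, we),
            cpg_ids=members(cpg_idx, probe.chrom, ws, we),
        )
    return windows


def window_census(windows: Mapping[str, GeneWindow]) -> pd.DataFrame:
    """Per-probe candidate counts (probe_id, chrom, window bounds, n_snps, n_cpgs)."""
    rows = [
        {
            "probe_id": w.probe_id,
            "chrom": w.chrom,
            "window_start": w.window_start,
            "window_end": w.window_end,
            "n_snps": len(w.snp_ids),
            "n_cpgs": len(w.cpg_ids),
        }
        for w in windows.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "window_start", "window_end", "n_snps", "n_cpgs"],
    )
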
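"""Readers and writers for matrix TSVs, BED-like annotations, configs and results.

File conventions
----------------
* Matrix: TSV, first column ``feature_id``, remaining columns one per sample,
  header row carries the sample ids.
* Annotations: 4-column BED-like TSV ``chrom  start  end  feature_id``
  (0-based, half-open), no header.
* Results: TSV written by :func:`write_results`; numeric columns round-trip
  bit-identically through :func:`read_results`.
* Config: flat ``key=value`` text mirroring :class:`~cismaxt.datamodel.AnalysisConfig`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, FeatureAnnotation, Layer, OmicsMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "probe_id", "gene", "chrom", "model", "method", "deviance", "p_adj",
    "p_display", "rank", "n_snps_selected", "n_cpgs_selected",
    "selected_feature_ids", "coefficients",
]


def read_annotations(path, layer: Layer) -> list[FeatureAnnotation]:
    """Read a 4-column BED-like TSV (chrom, start, end, feature_id)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected >= 4 BED columns, got {df.shape[1]}")
    anns = [
        FeatureAnnotation(
            feature_id=str(fid), chrom=str(chrom), start=int(start), end=int(end),
            layer=layer,
        )
        for chrom, start, end, fid in df.iloc[:, :4].itertuples(index=False)
    ]
    ids = [a.feature_id for a in anns]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated feature_id {dup!r}")
    return anns


def write_annotations(annotations, path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.feature_id}\n")


def read_matrix(path, annotation_path, layer: Layer) -> OmicsMatrix:
    """Read a feature x sample TSV plus its annotation BED into an OmicsMatrix.

    Rows are matched to annotations by feature id; matrix rows lacking an
    annotation are dropped (count logged).  Annotation order (genomic order
    of the BED file) defines the output row order.  Missing values and
    duplicated feature ids are hard errors.
    """
    layer = Layer(layer)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature_id {dup!r}")
    values = df.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    annotations = read_annotations(annotation_path, layer)
    have = set(df.index)
    matched = [a for a in annotations if a.feature_id in have]
    n_unannotated = len(df.index) - len({a.feature_id for a in matched})
    if n_unannotated:
        logger.info("read_matrix(%s): dropped %d row(s) without annotation",
                    path, n_unannotated)
    order = [a.feature_id for a in matched]
    return OmicsMatrix(
        values=df.loc[order].to_numpy(dtype=float),
        sample_ids=[str(c) for c in df.columns],
        annotations=matched,
        layer=layer,
    )


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Inverse of :func:`read_matrix` (matrix part); uses repr-precision floats."""
    df = pd.DataFrame(matrix.values, index=matrix.feature_ids,
                      columns=matrix.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_results(results: pd.DataFrame, path, n_permutations: int | None = None) -> None:
    """Write a screening results table as TSV.

    Adds a ``p_display`` column where an adjusted p-value of exactly 0 is
    shown as ``<1/B`` (e.g. ``<0.01`` at B = 100): the permutation estimate
    can reach 0 but the underlying p-value is merely below the resolution.
    """
    df = results.copy()
    if n_permutations:
        def _disp(p):
            if p == 0:
                return f"<{1.0 / n_permutations:g}"
            return f"{p:g}"
        df["p_display"] = df["p_adj"].map(_disp)
    elif "p_display" not in df.columns:
        df["p_display"] = df["p_adj"].map("{:g}".format)
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str},
                     float_precision="round_trip")
    return df


# -- config files --------------------------------------------------------------

_CONFIG_INT = {"window_bp", "k_folds", "n_permutations", "lambda_path_size", "seed"}
_CONFIG_FLOAT = {"alpha_threshold", "lambda_min_ratio"}
_CONFIG_BOOL = {"shared_permutations"}


def write_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in config.to_dict().items():
            if key == "l1_fraction_grid":
                val = "" if val is None else ",".join(f"{v:g}" for v in val)
            fh.write(f"{key}={val}\n")


def read_config(path) -> AnalysisConfig:
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key in _CONFIG_INT:
            kwargs[key] = int(raw)
        elif key in _CONFIG_FLOAT:
            kwargs[key] = float(raw)
        elif key in _CONFIG_BOOL:
            kwargs[key] = raw.lower() in ("1", "true", "yes")
        elif key == "l1_fraction_grid":
            kwargs[key] = tuple(float(v) for v in raw.split(",")) if raw else None
        elif key in ("model", "method"):
            kwargs[key] = raw
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return AnalysisConfig(**kwargs)
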
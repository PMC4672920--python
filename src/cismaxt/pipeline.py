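"""Screen orchestration: windows -> per-probe fits -> permutation maxT -> results.

``run_model`` executes one method x model combination over all expression
probes.  Matrices are first put into a canonical sample order (sorted sample
ids); fold assignment and the permutation plan are defined on that order, so
relabeling the input samples identically in every layer leaves every
adjusted p-value unchanged.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datamodel import AnalysisConfig, Layer, MethodKind, ModelKind, OmicsMatrix
from .maxt import PermutationPlan, _probe_grid, make_plan, maxt_adjust
from .penalized import CVEngine, _fit_to_result, assemble_design, make_folds
from .windows import GeneWindow, build_windows

logger = logging.getLogger(__name__)

RESULT_SORT = ["rank", "probe_id"]


def _canonical_order(expression: OmicsMatrix, others: list[OmicsMatrix]):
    order = sorted(expression.sample_ids)
    out = [expression.reorder_samples(order)]
    for om in others:
        if om is not None:
            if set(om.sample_ids) != set(order):
                raise ValueError(
                    f"sample ids of layer {om.layer.value} do not match expression"
                )
            out.append(om.reorder_samples(order))
        else:
            out.append(None)
    return out


def run_model(expression: OmicsMatrix, snps: OmicsMatrix | None = None,
              cpgs: OmicsMatrix | None = None,
              config: AnalysisConfig | None = None,
              plan: PermutationPlan | None = None,
              windows: dict[str, GeneWindow] | None = None,
              gene_symbols: dict[str, str] | None = None,
              n_jobs: int = 1) -> pd.DataFrame:
    """Run one full screen (one method, one model) and return the results table.

    Parameters
    ----------
    expression : probe x sample matrix (the outcomes).
    snps, cpgs : predictor matrices; the one(s) required by ``config.model``
        must be present.  CpG values are used as given (transform beta-values
        to M-values beforehand with
        :func:`cismaxt.preprocess.transform_cpg_matrix`).
    plan : optional shared permutation plan; passing the same plan to several
        method/model runs removes permutation noise from their comparison.
    windows : optional prebuilt cis windows (rebuilt from annotations if None).
    gene_symbols : optional probe_id -> gene symbol map for reporting.

    Returns
    -------
    DataFrame in rank order: probe_id, gene, chrom, model, method, deviance,
    p_adj, rank, significant, chosen penalties, selection counts and the
    selected features with their standardized-scale coefficients.
    """
    config = config or AnalysisConfig()
    model = ModelKind(config.model)
    method = MethodKind(config.method)
    if model in (ModelKind.SNP, ModelKind.GLOBAL) and snps is None:
        raise ValueError(f"model {model.value} requires a SNP matrix")
    if model in (ModelKind.CPG, ModelKind.GLOBAL) and cpgs is None:
        raise ValueError(f"model {model.value} requires a CpG matrix")

    expression, snps, cpgs = _canonical_order(expression, [snps, cpgs])
    n = expression.n_samples
    if config.k_folds > n:
        raise ValueError("k_folds exceeds the number of samples")

    if windows is None:
        windows = build_windows(
            expression.annotations,
            snps.annotations if snps is not None else (),
            cpgs.annotations if cpgs is not None else (),
            window_bp=config.window_bp,
        )
    matrices = {}
    if snps is not None:
        matrices[Layer.SNP] = snps
    if cpgs is not None:
        matrices[Layer.CPG] = cpgs

    if plan is None:
        plan = make_plan(n, config.n_permutations, config.seed)
    elif plan.permutations.shape[1] != n:
        raise ValueError("permutation plan was built for a different sample count")
    folds = make_folds(n, config.k_folds, config.seed)
    grid = _probe_grid(method, config)

    probe_ids = expression.feature_ids
    t0 = time.perf_counter()

    def one(i: int, probe_id: str):
        window = windows[probe_id]
        try:
            X, ids, layers = assemble_design(window, matrices, model)
            engine = CVEngine(X, fold_assignment=folds)
            y = expression.values[i]
            res = engine.fit(y, l1_fraction_grid=grid,
                             path_size=config.lambda_path_size,
                             min_ratio=config.lambda_min_ratio)
            fit = _fit_to_result(probe_id, model, method, res, ids, layers,
                                 engine.kept)
            from .maxt import _plan_for_probe

            perms = _plan_for_probe(plan, probe_id, config)
            dev_b = np.empty(plan.B)
            for b, perm in enumerate(perms):
                dev_b[b] = engine.fit(y[perm], l1_fraction_grid=grid,
                                      path_size=config.lambda_path_size,
                                      min_ratio=config.lambda_min_ratio)["deviance"]
            return fit, dev_b
        except Exception as exc:  # pragma: no cover - context for aborts
            raise RuntimeError(f"fit failed for probe {probe_id!r}") from exc

    if n_jobs == 1:
        fitted = [one(i, pid) for i, pid in enumerate(probe_ids)]
    else:
        fitted = Parallel(n_jobs=n_jobs)(
            delayed(one)(i, pid) for i, pid in enumerate(probe_ids)
        )
    fits = {f.probe_id: f for f, _ in fitted}
    observed = np.array([fits[pid].deviance for pid in probe_ids])
    permuted = (np.vstack([d for _, d in fitted])
                if fitted else np.empty((0, plan.B)))
    logger.info("run_model(%s/%s): fitted %d probes x %d replicates in %.1fs",
                method.value, model.value, len(probe_ids), plan.B,
                time.perf_counter() - t0)

    adj = maxt_adjust(observed, permuted, probe_ids=probe_ids,
                      alpha_threshold=config.alpha_threshold)
    chrom = {a.feature_id: a.chrom for a in expression.annotations}
    gene_symbols = gene_symbols or {}
    rows = []
    for rec in adj.itertuples(index=False):
        f = fits[rec.probe_id]
        feats = sorted(f.coefficients)
        rows.append({
            "probe_id": rec.probe_id,
            "gene": gene_symbols.get(rec.probe_id, ""),
            "chrom": chrom.get(rec.probe_id, ""),
            "model": f.model.value,
            "method": f.method.value,
            "deviance": rec.observed_D,
            "p_adj": rec.p_adj,
            "rank": rec.rank,
            "significant": bool(rec.significant),
            "chosen_lambda": f.chosen_lambda,
            "chosen_l1_fraction": f.chosen_l1_fraction,
            "n_snps_selected": f.n_snps_selected,
            "n_cpgs_selected": f.n_cpgs_selected,
            "selected_feature_ids": ",".join(feats),
            "coefficients": ",".join(f"{f.coefficients[k]:.17g}" for k in feats),
        })
    return pd.DataFrame(rows)


def summarize_overlaps(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Venn-style overlap counts of significant probe sets across runs.

    For every nonempty subset of the given runs, reports the plain
    intersection size (``n_intersection``) and the exclusive Venn-cell size
    (``n_exclusive``: probes significant in exactly that subset).  Exclusive
    cells partition the union, so their counts sum to the union size.
    """
    if len(results) < 2:
        raise ValueError("need at least two result tables to compare")
    names = list(results)
    sig = {
        name: set(df.loc[df["significant"].astype(bool), "probe_id"])
        for name, df in results.items()
    }
    universe = set().union(*sig.values())
    rows = []
    for mask in range(1, 2 ** len(names)):
        members = [names[k] for k in range(len(names)) if mask >> k & 1]
        inter = set(universe)
        for m in members:
            inter &= sig[m]
        excl = set(inter)
        for m in names:
            if m not in members:
                excl -= sig[m]
        rows.append({
            "members": "&".join(members),
            "n_members": len(members),
            "n_intersection": len(inter),
            "n_exclusive": len(excl),
        })
    return pd.DataFrame(rows).sort_values(
        ["n_members", "members"]).reset_index(drop=True)


@dataclass
class RunManifest:
    """Reproducibility record of one screening run."""

    config: dict
    inputs: dict
    seed: int
    m_probes: int
    n_samples: int
    software_version: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


class MaxTScreen:
    """Estimator-style front end to :func:`run_model`.

    Parameters mirror :class:`~cismaxt.datamodel.AnalysisConfig`; ``fit``
    takes the three omics matrices and populates ``results_``,
    ``n_significant_`` and ``windows_``.
    """

    def __init__(self, window_bp: int = 1_000_000, k_folds: int = 5,
                 n_permutations: int = 100, alpha_threshold: float = 0.1,
                 l1_fraction_grid=None, lambda_path_size: int = 20,
                 lambda_min_ratio: float = 0.01, seed: int = 0,
                 model: str = "snp", method: str = "lasso",
                 shared_permutations: bool = True, n_jobs: int = 1):
        self.window_bp = window_bp
        self.k_folds = k_folds
        self.n_permutations = n_permutations
        self.alpha_threshold = alpha_threshold
        self.l1_fraction_grid = l1_fraction_grid
        self.lambda_path_size = lambda_path_size
        self.lambda_min_ratio = lambda_min_ratio
        self.seed = seed
        self.model = model
        self.method = method
        self.shared_permutations = shared_permutations
        self.n_jobs = n_jobs

    _PARAMS = ("window_bp", "k_folds", "n_permutations", "alpha_threshold",
               "l1_fraction_grid", "lambda_path_size", "lambda_min_ratio",
               "seed", "model", "method", "shared_permutations", "n_jobs")

    def get_params(self, deep: bool = True) -> dict:
        return {p: getattr(self, p) for p in self._PARAMS}

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self._PARAMS:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def _config(self) -> AnalysisConfig:
        kwargs = {p: getattr(self, p) for p in self._PARAMS if p != "n_jobs"}
        return AnalysisConfig(**kwargs)

    def fit(self, expression: OmicsMatrix, snps: OmicsMatrix | None = None,
            cpgs: OmicsMatrix | None = None,
            plan: PermutationPlan | None = None,
            gene_symbols: dict[str, str] | None = None):
        config = self._config()
        self.config_ = config
        self.windows_ = build_windows(
            expression.annotations,
            snps.annotations if snps is not None else (),
            cpgs.annotations if cpgs is not None else (),
            window_bp=config.window_bp,
        )
        self.results_ = run_model(expression, snps, cpgs, config=config,
                                  plan=plan, windows=self.windows_,
                                  gene_symbols=gene_symbols,
                                  n_jobs=self.n_jobs)
        self.n_significant_ = int(self.results_["significant"].sum())
        return self
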
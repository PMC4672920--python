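"""Step-down maxT permutation procedure for family-wise error control.

Penalized fits carry no usable standard errors, so significance of each
per-gene model is assessed by permutation: sample labels of the expression
vectors are shuffled B times, every fit — including its CV penalty
selection — is redone on the shuffled outcome, and the observed deviances
are referred to the successive maxima of the permuted ones (Westfall-Young
step-down maxT).  One permutation pass serves both the p-value estimation
and the multiplicity correction.

With hypotheses ordered by decreasing observed |D| (|D_(1)| >= ... >= |D_(m)|)
and D_(i),b the permuted statistic of the i-th ordered hypothesis in
replicate b, the successive maxima are

    U_(m),b = |D_(m),b|,   U_(i),b = max(U_(i+1),b, |D_(i),b|),

the raw adjusted p-values  p_(i) = #{b : U_(i),b >= |D_(i)|} / B,  and
monotonicity is enforced downward:  p~_(i) = max(p~_(i-1), p_(i)).  Each
probe's adjusted p then dominates its own marginal permutation p-value.

By default one sample reordering per replicate is shared by all probes,
which preserves the dependence structure between genes under the null;
per-probe independent reorderings are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datamodel import AnalysisConfig, Layer, MethodKind, ModelKind, OmicsMatrix
from .penalized import CVEngine, assemble_design
from .windows import GeneWindow


@dataclass
class PermutationPlan:
    """B seeded reorderings of the n sample indices."""

    B: int
    seed: int
    permutations: np.ndarray  # shape (B, n), each row a permutation of 0..n-1

    def __post_init__(self) -> None:
        self.permutations = np.asarray(self.permutations, dtype=int)
        if self.permutations.shape[0] != self.B:
            raise ValueError("plan has wrong number of replicates")


def make_plan(n_samples: int, B: int, seed: int) -> PermutationPlan:
    """Draw B uniform permutations of n sample indices, reproducibly.

    The identity permutation is not forcibly included; at realistic n the
    chance of drawing it is negligible and excluding it would bias the null.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to permute")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_samples) for _ in range(B)])
    return PermutationPlan(B=B, seed=seed, permutations=perms)


def _probe_grid(method: MethodKind, config: AnalysisConfig):
    if MethodKind(method) is MethodKind.LASSO:
        return (1.0,)
    return config.effective_grid() if hasattr(config, "effective_grid") else (0.5,)


def _probe_deviances(engine: CVEngine, y, grid, config: AnalysisConfig,
                     perms: np.ndarray) -> tuple[float, np.ndarray]:
    """Observed deviance plus one deviance per permutation replicate."""
    obs = engine.fit(y, l1_fraction_grid=grid,
                     path_size=config.lambda_path_size,
                     min_ratio=config.lambda_min_ratio)["deviance"]
    out = np.empty(perms.shape[0])
    for b, perm in enumerate(perms):
        out[b] = engine.fit(y[perm], l1_fraction_grid=grid,
                            path_size=config.lambda_path_size,
                            min_ratio=config.lambda_min_ratio)["deviance"]
    return obs, out


def permuted_deviances(windows, matrices: dict[Layer, OmicsMatrix],
                       expression: OmicsMatrix, model: ModelKind,
                       method: MethodKind, config: AnalysisConfig,
                       plan: PermutationPlan, n_jobs: int = 1) -> np.ndarray:
    """Deviance matrix (m probes x B replicates) under full refits.

    For each replicate the probe's expression vector is reordered (predictors
    fixed) and the entire fit — CV penalty selection included — is redone.
    With ``config.shared_permutations`` (default) every probe uses the plan's
    shared reorderings; otherwise probe-specific plans are derived from the
    plan seed.
    """
    probe_ids = expression.feature_ids
    expr_rows = {pid: expression.values[i] for i, pid in enumerate(probe_ids)}

    def one(probe_id: str) -> np.ndarray:
        window = windows[probe_id]
        X, _, _ = assemble_design(window, matrices, model)
        engine = CVEngine(X, k_folds=config.k_folds, fold_seed=config.seed)
        perms = _plan_for_probe(plan, probe_id, config)
        _, dev = _probe_deviances(engine, expr_rows[probe_id],
                                  _probe_grid(method, config), config, perms)
        return dev

    if n_jobs == 1:
        rows = [one(pid) for pid in probe_ids]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(one)(pid) for pid in probe_ids)
    return np.vstack(rows) if rows else np.empty((0, plan.B))


def _plan_for_probe(plan: PermutationPlan, probe_id: str,
                    config: AnalysisConfig) -> np.ndarray:
    if getattr(config, "shared_permutations", True):
        return plan.permutations
    # derive a probe-specific stream from the plan seed and a stable id hash
    import zlib

    child = np.random.default_rng(
        np.random.SeedSequence([plan.seed, zlib.crc32(probe_id.encode())])
    )
    n = plan.permutations.shape[1]
    return np.stack([child.permutation(n) for _ in range(plan.B)])


def maxt_adjust(observed, permuted, probe_ids=None,
                alpha_threshold: float = 0.1) -> pd.DataFrame:
    """Step-down maxT adjusted p-values from observed and permuted statistics.

    Parameters
    ----------
    observed : (m,) observed deviances.
    permuted : (m, B) permuted deviances, rows aligned with ``observed``.
    probe_ids : optional ids; default x0..x{m-1}.  Ties in |D| break by
        ascending probe id (stable).
    alpha_threshold : strict cut-off for the ``significant`` flag.

    Returns
    -------
    DataFrame with columns probe_id, observed_D, rank, p_adj, significant,
    in rank order (rank 1 = largest observed deviance).
    """
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    m = observed.size
    if m == 0:
        return pd.DataFrame(
            columns=["probe_id", "observed_D", "rank", "p_adj", "significant"]
        )
    if permuted.shape[0] != m:
        raise ValueError("observed and permuted row counts differ")
    if probe_ids is None:
        probe_ids = [f"x{i}" for i in range(m)]
    probe_ids = list(probe_ids)
    B = permuted.shape[1]

    abs_obs = np.abs(observed)
    order = sorted(range(m), key=lambda i: (-abs_obs[i], probe_ids[i]))
    P = np.abs(permuted)[order]                       # (m, B), rank order
    U = np.maximum.accumulate(P[::-1], axis=0)[::-1]  # successive maxima
    p_raw = (U >= abs_obs[order][:, None]).sum(axis=1) / B
    p_adj = np.maximum.accumulate(p_raw)

    df = pd.DataFrame({
        "probe_id": [probe_ids[i] for i in order],
        "observed_D": observed[order],
        "rank": np.arange(1, m + 1),
        "p_adj": p_adj,
        "significant": p_adj < alpha_threshold,
    })
    return df
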
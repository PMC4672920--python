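"""Per-gene penalized regression with k-fold CV penalty selection and deviance.

The per-gene model regresses one expression vector y (n samples) on the
standardized cis-window predictor columns X, minimizing

    (1 / 2n) * ||y - b0 - X b||^2
        + lambda * ( f * ||b||_1  +  (1 - f) / 2 * ||b||_2^2 )

where ``f`` is the L1 fraction of the penalty: f = 1 is the LASSO, f in
(0, 1) the elastic net.  The solver is scikit-learn's cyclical coordinate
descent (:func:`sklearn.linear_model.enet_path`), run along a geometric
lambda path from lambda_max (the smallest penalty with an all-zero solution,
``max_j |x_j'(y - ybar)| / (n f)``) down to ``lambda_min_ratio *
lambda_max``.  lambda — and for the elastic net jointly the L1 fraction —
is chosen to minimize the k-fold cross-validated squared prediction error.

Goodness of fit is summarized by the Gaussian deviance against the
intercept-only null,

    D = 2 [loglik(full) - loglik(null)] = n * ln(RSS_null / RSS_full),

with the maximum-likelihood variance profiled out per model.  D >= 0 for any
penalized fit, since b = 0 is feasible.

Note on mixing conventions: some authors parameterize the elastic net by the
*ridge* fraction (their alpha = 1 leaves pure ridge); this module always uses
the L1 fraction ``f`` (f = 1 is the LASSO), and reporting helpers expose
``ridge_fraction = 1 - f`` alongside to avoid silent convention bugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import config_context
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.utils.validation import check_is_fitted

from .datamodel import Layer, MethodKind, ModelKind, OmicsMatrix
from .preprocess import standardize_columns
from .windows import GeneWindow

#: relative floor on RSS_full to keep the deviance finite on interpolating fits
RSS_FLOOR_RATIO = 1e-12

#: CV error ties within this absolute tolerance resolve to the sparsest model
CV_TIE_TOL = 1e-12

_CV_TOL = 1e-3      # coordinate-descent tolerance inside CV folds (selection only)
_FINAL_TOL = 1e-7   # tolerance of the refit at the chosen penalty
_MAX_ITER = 5000


def gaussian_deviance(y, y_hat_full, rss_floor_ratio: float = RSS_FLOOR_RATIO) -> float:
    """Deviance of a fitted mean vector against the intercept-only null.

    ``D = n * ln(RSS_null / RSS_full)`` with RSS_full floored at
    ``rss_floor_ratio * RSS_null``.  A constant y (RSS_null = 0) returns 0.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat_full, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    n = y.size
    rss_null = float(np.sum((y - y.mean()) ** 2))
    if rss_null <= 0.0:
        return 0.0
    rss_full = float(np.sum((y - y_hat) ** 2))
    rss_full = max(rss_full, rss_floor_ratio * rss_null)
    return n * float(np.log(rss_null / rss_full))


def lambda_path(design, y, l1_fraction: float = 1.0,
                path_size: int = 20, min_ratio: float = 0.01) -> np.ndarray:
    """Descending geometric penalty path for a standardized design.

    Starts at ``lambda_max = max_j |x_j'(y - ybar)| / (n * l1_fraction)``,
    the smallest penalty at which the KKT conditions hold at b = 0, and ends
    at ``lambda_max * min_ratio``.  Empty design or signal-free y give an
    empty path.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        return np.empty(0)
    if not (0 < l1_fraction <= 1):
        raise ValueError("l1_fraction must lie in (0, 1]")
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ yc))) / (X.shape[0] * l1_fraction)
    if not np.isfinite(lam_max) or lam_max <= 0:
        return np.empty(0)
    return np.geomspace(lam_max, lam_max * min_ratio, path_size)


def _solve_path(X, yc, l1_fraction, alphas, gram=None, tol=_FINAL_TOL):
    """enet_path wrapper: returns coefficients (p x n_alphas), warnings muted.

    The smallest-lambda end of the path rarely reaches the duality-gap target
    when n << p; the CV selection is insensitive to that residual gap.
    """
    with warnings.catch_warnings(), config_context(skip_parameter_validation=True):
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            X, yc, l1_ratio=l1_fraction, alphas=alphas,
            precompute=gram if gram is not None else "auto",
            Xy=None if gram is None else X.T @ yc,
            check_input=False, tol=tol, max_iter=_MAX_ITER,
        )
    return coefs


def solve_at_penalty(design, y, lam: float, l1_fraction: float = 1.0,
                     tol: float = 1e-10):
    """Exact-ish solution (coef, intercept) at one fixed (lambda, L1 fraction).

    Centers y internally; the design is used as given (callers standardize).
    """
    X = np.asfortranarray(np.asarray(design, dtype=float))
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            X, yc, l1_ratio=l1_fraction, alphas=np.array([lam]),
            tol=tol, max_iter=1_000_000,
        )
    coef = coefs[:, -1]
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return coef, intercept


def make_folds(n_samples: int, k_folds: int, fold_seed: int) -> np.ndarray:
    """Deterministic fold labels: contiguous blocks after a seeded shuffle.

    With n = 27 and k = 5 this yields fold sizes {6, 6, 5, 5, 5}.
    """
    if k_folds > n_samples:
        raise ValueError(f"k_folds ({k_folds}) exceeds n_samples ({n_samples})")
    rng = np.random.default_rng(fold_seed)
    order = rng.permutation(n_samples)
    labels = np.empty(n_samples, dtype=int)
    for k, block in enumerate(np.array_split(order, k_folds)):
        labels[block] = k
    return labels


class CVEngine:
    """Reusable CV machinery for one fixed design and fold assignment.

    Standardizes the design once, precomputes per-fold centered training
    blocks and their Gram matrices, then fits any number of outcome vectors
    cheaply — the workhorse of the permutation refits, where the design is
    fixed and only y is reordered.
    """

    def __init__(self, design, k_folds: int = 5, fold_seed: int = 0,
                 fold_assignment=None):
        X_raw = np.asarray(design, dtype=float)
        if X_raw.ndim != 2:
            raise ValueError("design must be 2-D (samples x features)")
        self.n_samples = X_raw.shape[0]
        self.n_features_in = X_raw.shape[1]
        Xs, self.means, self.scales, self.kept = standardize_columns(X_raw)
        self.X = np.asfortranarray(Xs)
        self.p = self.X.shape[1]
        if self.p:
            self.gram = np.ascontiguousarray(self.X.T @ self.X)
        else:
            self.gram = None
        if fold_assignment is None:
            fold_assignment = make_folds(self.n_samples, k_folds, fold_seed)
        self.fold_assignment = np.asarray(fold_assignment, dtype=int)
        if self.fold_assignment.shape != (self.n_samples,):
            raise ValueError("fold_assignment must have one label per sample")
        self._folds = []
        if self.p:
            for k in np.unique(self.fold_assignment):
                va = np.flatnonzero(self.fold_assignment == k)
                tr = np.flatnonzero(self.fold_assignment != k)
                Xtr = self.X[tr]
                mu = Xtr.mean(axis=0)
                Xtr = np.asfortranarray(Xtr - mu)
                self._folds.append((
                    tr, va, Xtr, np.ascontiguousarray(Xtr.T @ Xtr), self.X[va] - mu,
                ))

    def _null_result(self, y):
        return {
            "coef": np.zeros(self.p), "intercept": float(np.mean(y)),
            "chosen_lambda": float("nan"), "chosen_l1_fraction": float("nan"),
            "rss_null": float(np.sum((y - np.mean(y)) ** 2)),
            "rss_full": float(np.sum((y - np.mean(y)) ** 2)),
            "deviance": 0.0, "n_selected": 0,
        }

    def fit(self, y, l1_fraction_grid=(1.0,), path_size: int = 20,
            min_ratio: float = 0.01):
        """Full CV fit of one outcome vector; returns a result dict.

        Selection minimizes the pooled k-fold squared prediction error over
        the joint (L1 fraction, lambda) grid; ties within ``CV_TIE_TOL``
        resolve to the largest lambda, then the largest L1 fraction — the
        sparsest of the equally good models.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_samples,):
            raise ValueError("y has wrong length for this design")
        ybar = float(y.mean())
        yc = y - ybar
        rss_null = float(yc @ yc)
        if self.p == 0 or rss_null <= 0.0:
            return self._null_result(y)

        best = (np.inf, -np.inf, -np.inf)  # (cv_err, lambda, f) under tie rules
        chosen = None
        cov_max = float(np.max(np.abs(self.X.T @ yc)))
        if cov_max <= 0.0:
            return self._null_result(y)
        for f in l1_fraction_grid:
            lam_max = cov_max / (self.n_samples * f)
            alphas = np.geomspace(lam_max, lam_max * min_ratio, path_size)
            sse = np.zeros(path_size)
            for tr, va, Xtr, Gtr, Xva in self._folds:
                ytr = y[tr]
                mtr = ytr.mean()
                coefs = _solve_path(Xtr, ytr - mtr, f, alphas, gram=Gtr, tol=_CV_TOL)
                resid = (y[va] - mtr)[:, None] - Xva @ coefs
                sse += np.einsum("ij,ij->j", resid, resid)
            cv_err = sse / self.n_samples
            for j in range(path_size):
                cand = (cv_err[j], alphas[j], f)
                if (cand[0] < best[0] - CV_TIE_TOL) or (
                    abs(cand[0] - best[0]) <= CV_TIE_TOL
                    and (cand[1], cand[2]) > (best[1], best[2])
                ):
                    best = cand
                    chosen = (f, alphas, j)

        f_star, alphas, j_star = chosen
        coefs = _solve_path(self.X, yc, f_star, alphas[: j_star + 1],
                            gram=self.gram, tol=_FINAL_TOL)
        coef = coefs[:, -1]
        resid = yc - self.X @ coef
        rss_full = float(resid @ resid)
        return {
            "coef": coef, "intercept": ybar,
            "chosen_lambda": float(alphas[j_star]),
            "chosen_l1_fraction": float(f_star),
            "rss_null": rss_null,
            "rss_full": max(rss_full, RSS_FLOOR_RATIO * rss_null),
            "deviance": gaussian_deviance(y, ybar + self.X @ coef),
            "n_selected": int(np.count_nonzero(coef)),
        }


class PenalizedGeneModel(RegressorMixin, BaseEstimator):
    """Penalized linear model with CV penalty selection and deviance score.

    scikit-learn-style estimator around :class:`CVEngine`.  The design is
    standardized internally (population SD; constant columns dropped);
    ``coef_`` is reported on the original predictor scale so that
    ``predict`` consumes raw inputs, while ``coef_std_`` keeps the
    standardized-scale coefficients that the deviance and selection are
    defined on.

    Parameters
    ----------
    method : "lasso" or "enet".
    l1_fraction_grid : elastic-net L1 fractions searched (default
        0.01..0.99 by 0.01); forced to (1.0,) for LASSO.
    lambda_path_size, lambda_min_ratio : geometric penalty path geometry.
    k_folds : CV folds (must not exceed n_samples).
    fold_seed : seed of the deterministic fold shuffle.

    Attributes
    ----------
    coef_, intercept_ : fit on the original predictor scale.
    coef_std_ : coefficients on the standardized scale (zeros for dropped
        constant columns).
    deviance_ : Gaussian deviance vs. the intercept-only null.
    chosen_lambda_, chosen_l1_fraction_ : CV winners.
    rss_null_, rss_full_, n_selected_ : fit summaries.
    """

    def __init__(self, method: str = "lasso", l1_fraction_grid=None,
                 lambda_path_size: int = 20, lambda_min_ratio: float = 0.01,
                 k_folds: int = 5, fold_seed: int = 0):
        self.method = method
        self.l1_fraction_grid = l1_fraction_grid
        self.lambda_path_size = lambda_path_size
        self.lambda_min_ratio = lambda_min_ratio
        self.k_folds = k_folds
        self.fold_seed = fold_seed

    def _grid(self):
        method = MethodKind(self.method)
        if method is MethodKind.LASSO:
            return (1.0,)
        if self.l1_fraction_grid is None:
            return tuple(np.round(np.arange(1, 100) / 100.0, 2))
        grid = tuple(float(g) for g in self.l1_fraction_grid)
        if not grid or any(not (0 < g <= 1) for g in grid):
            raise ValueError("l1_fraction_grid values must lie in (0, 1]")
        return grid

    def fit(self, X, y, fold_assignment=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be 1-D with one value per row of X")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite (no missing values)")
        engine = CVEngine(X, k_folds=min(self.k_folds, max(2, X.shape[0])),
                          fold_seed=self.fold_seed, fold_assignment=fold_assignment)
        if self.k_folds > X.shape[0]:
            raise ValueError("k_folds exceeds the number of samples")
        res = engine.fit(y, l1_fraction_grid=self._grid(),
                         path_size=self.lambda_path_size,
                         min_ratio=self.lambda_min_ratio)
        self.n_features_in_ = X.shape[1]
        self.coef_std_ = np.zeros(X.shape[1])
        self.coef_std_[engine.kept] = res["coef"]
        self.coef_ = np.zeros(X.shape[1])
        if engine.kept.size:
            self.coef_[engine.kept] = res["coef"] / engine.scales
        self.intercept_ = res["intercept"] - float(
            engine.means @ self.coef_[engine.kept]
        ) if engine.kept.size else res["intercept"]
        self.deviance_ = res["deviance"]
        self.chosen_lambda_ = res["chosen_lambda"]
        self.chosen_l1_fraction_ = res["chosen_l1_fraction"]
        self.rss_null_ = res["rss_null"]
        self.rss_full_ = res["rss_full"]
        self.n_selected_ = res["n_selected"]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    @property
    def ridge_fraction_(self) -> float:
        """1 - chosen L1 fraction (the ridge share of the penalty)."""
        check_is_fitted(self, "coef_")
        return 1.0 - self.chosen_l1_fraction_


@dataclass
class FitResult:
    """One per-probe penalized fit, keyed by feature id."""

    probe_id: str
    model: ModelKind
    method: MethodKind
    intercept: float
    coefficients: dict[str, float]          # standardized scale, nonzero only
    chosen_lambda: float
    chosen_l1_fraction: float
    rss_full: float
    rss_null: float
    deviance: float
    n_selected: int
    n_snps_selected: int = 0
    n_cpgs_selected: int = 0


def design_feature_ids(window: GeneWindow, model: ModelKind) -> list[str]:
    """Predictor ids of a window under the given model, SNPs before CpGs."""
    model = ModelKind(model)
    if model is ModelKind.SNP:
        return list(window.snp_ids)
    if model is ModelKind.CPG:
        return list(window.cpg_ids)
    return list(window.snp_ids) + list(window.cpg_ids)


def assemble_design(window: GeneWindow, matrices: dict[Layer, OmicsMatrix],
                    model: ModelKind):
    """Raw (unstandardized) samples x features design + feature ids + layer tags."""
    model = ModelKind(model)
    ids: list[str] = []
    blocks: list[np.ndarray] = []
    layers: list[Layer] = []
    wanted = []
    if model in (ModelKind.SNP, ModelKind.GLOBAL):
        wanted.append((Layer.SNP, window.snp_ids))
    if model in (ModelKind.CPG, ModelKind.GLOBAL):
        wanted.append((Layer.CPG, window.cpg_ids))
    n_samples = None
    for layer, feat_ids in wanted:
        om = matrices.get(layer)
        if om is None:
            if feat_ids:
                raise ValueError(f"window lists {layer.value} features but no "
                                 f"{layer.value} matrix was provided")
            continue
        n_samples = om.n_samples
        if feat_ids:
            sub = om.subset_features(feat_ids)
            blocks.append(sub.values.T)
            ids.extend(feat_ids)
            layers.extend([layer] * len(feat_ids))
    if n_samples is None:
        for om in matrices.values():
            n_samples = om.n_samples
            break
    if n_samples is None:
        raise ValueError("no predictor matrices provided")
    X = np.hstack(blocks) if blocks else np.empty((n_samples, 0))
    return X, ids, layers


def _fit_to_result(probe_id, model, method, res, ids, layers, kept) -> FitResult:
    coef = res["coef"]
    nz = np.flatnonzero(coef)
    kept_ids = [ids[k] for k in kept]
    kept_layers = [layers[k] for k in kept]
    coefficients = {kept_ids[i]: float(coef[i]) for i in nz}
    n_snp = sum(1 for i in nz if kept_layers[i] is Layer.SNP)
    n_cpg = sum(1 for i in nz if kept_layers[i] is Layer.CPG)
    return FitResult(
        probe_id=probe_id, model=ModelKind(model), method=MethodKind(method),
        intercept=res["intercept"], coefficients=coefficients,
        chosen_lambda=res["chosen_lambda"],
        chosen_l1_fraction=res["chosen_l1_fraction"],
        rss_full=res["rss_full"], rss_null=res["rss_null"],
        deviance=res["deviance"], n_selected=res["n_selected"],
        n_snps_selected=n_snp, n_cpgs_selected=n_cpg,
    )


def fit_gene_model(window: GeneWindow, matrices: dict[Layer, OmicsMatrix],
                   y, model: ModelKind, method: MethodKind,
                   config=None, fold_assignment=None) -> FitResult:
    """Fit one probe's cis model and score it by deviance.

    ``matrices`` maps predictor layers to sample-aligned OmicsMatrix objects;
    ``y`` is the probe's expression vector in the same sample order.
    """
    from .datamodel import AnalysisConfig

    config = config or AnalysisConfig()
    X, ids, layers = assemble_design(window, matrices, model)
    engine = CVEngine(X, k_folds=config.k_folds, fold_seed=config.seed,
                      fold_assignment=fold_assignment)
    grid = ((1.0,) if MethodKind(method) is MethodKind.LASSO
            else (config.l1_fraction_grid or tuple(np.round(np.arange(1, 100) / 100.0, 2))))
    res = engine.fit(np.asarray(y, dtype=float), l1_fraction_grid=grid,
                     path_size=config.lambda_path_size,
                     min_ratio=config.lambda_min_ratio)
    return _fit_to_result(window.probe_id, model, method, res, ids, layers,
                          engine.kept)


def fit_lasso_cv(design, y, config=None, probe_id: str = "") -> FitResult:
    """LASSO CV fit of a bare design (no window bookkeeping)."""
    return _fit_bare(design, y, MethodKind.LASSO, config, probe_id)


def fit_enet_cv(design, y, config=None, probe_id: str = "") -> FitResult:
    """Elastic-net CV fit of a bare design, joint (L1 fraction, lambda) search."""
    return _fit_bare(design, y, MethodKind.ENET, config, probe_id)


def _fit_bare(design, y, method, config, probe_id):
    from .datamodel import AnalysisConfig

    config = config or AnalysisConfig()
    X = np.asarray(design, dtype=float)
    engine = CVEngine(X, k_folds=config.k_folds, fold_seed=config.seed)
    grid = ((1.0,) if method is MethodKind.LASSO
            else (config.l1_fraction_grid or tuple(np.round(np.arange(1, 100) / 100.0, 2))))
    res = engine.fit(np.asarray(y, dtype=float), l1_fraction_grid=grid,
                     path_size=config.lambda_path_size,
                     min_ratio=config.lambda_min_ratio)
    ids = [f"x{j}" for j in range(X.shape[1])]
    layers = [Layer.SNP] * X.shape[1]
    return _fit_to_result(probe_id, ModelKind.SNP, method, res, ids, layers,
                          engine.kept)
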
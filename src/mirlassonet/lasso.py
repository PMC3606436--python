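"""L1-penalized regression of disease signatures on miRNA influence profiles.

The model regresses a disease's gene-signature vector y (one entry per gene
of the intersected universe) on the binary influence profiles of all miRNAs:

    y_i = beta_0 + sum_j NetmiR_ij * beta_j + eps_i,

fitted by minimizing  (1/2n) ||y - beta_0 - X beta||^2  +  lambda * P(beta),
with the penalty  P(beta) = sum_j (1/2) |beta_j|.  The 1/2 in the penalty is
absorbed into an effective penalty level lambda_eff = lambda / 2, so the
solver is a standard Lasso while reported lambda values keep the model's own
parameterization.  beta_j measures how strongly miRNA j explains the disease
signature; the penalty zeroes most coefficients, and only positive
coefficients are interpreted as functional associations by default.

The solver is cyclic coordinate descent with soft-threshold updates over the
Gram matrix, warm-started along a decreasing log-spaced lambda path;
lambda is selected by k-fold cross-validation on the genes (minimum mean
held-out squared error, ties resolved toward the sparser, larger lambda).

Usage follows the model/results convention::

    model = MirnaLassoModel.from_networks(netmir, disease_matrix, "D01", config)
    res = model.fit()
    res.summary()
    res.associations()
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Config
from .netmir import NetMiRMatrix
from .signatures import DiseaseSignatureMatrix

__all__ = [
    "soft_threshold",
    "fit_lasso",
    "fit_lasso_path",
    "lambda_max",
    "lambda_path",
    "cross_validate",
    "CVResult",
    "MirnaLassoModel",
    "MirnaLassoResults",
    "fit_disease",
    "fit_gene_list",
    "extract_associations",
    "AssociationNetwork",
    "objective_value",
    "kkt_max_violation",
]


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0); elementwise on arrays."""
    if np.any(np.asarray(gamma) < 0):
        raise ValueError("gamma must be >= 0")
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


# ---------------------------------------------------------------------------
# Solver internals
# ---------------------------------------------------------------------------

class _Design:
    """Centered (optionally standardized) design with cached Gram matrix."""

    def __init__(self, X: np.ndarray, y: np.ndarray, standardize: bool):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if y.shape != (X.shape[0],):
            raise ValueError("y must match the rows of X")
        n, p = X.shape
        self.n, self.p = n, p
        self.standardize = standardize
        self.x_mean = X.mean(axis=0)
        Xc = X - self.x_mean
        if standardize:
            scale = Xc.std(axis=0)
        else:
            scale = np.ones(p)
        self.dead = scale == 0.0
        if not standardize:
            # a constant column has zero centered norm: pin its coefficient
            self.dead = (Xc ** 2).sum(axis=0) == 0.0
        if np.any(self.dead):
            warnings.warn(
                f"{int(self.dead.sum())} constant predictor column(s); "
                "their coefficients are pinned to 0",
                stacklevel=3,
            )
        safe_scale = np.where(scale == 0.0, 1.0, scale)
        self.scale = safe_scale
        Xs = Xc / safe_scale if standardize else Xc
        self.y_mean = y.mean()
        yc = y - self.y_mean
        self.G = Xs.T @ Xs / n
        self.c = Xs.T @ yc / n
        self.c[self.dead] = 0.0
        self.yty_n = float(yc @ yc) / n
        self.Xs = Xs

    def lambda_eff_max(self) -> float:
        return float(np.max(np.abs(self.c))) if self.p else 0.0

    def to_original(self, beta_std: np.ndarray) -> tuple[float, np.ndarray]:
        beta = beta_std / self.scale if self.standardize else beta_std
        intercept = float(self.y_mean - self.x_mean @ beta)
        return intercept, beta

    def from_original(self, beta: np.ndarray) -> np.ndarray:
        return beta * self.scale if self.standardize else np.asarray(beta, float).copy()

    def objective(self, beta_std: np.ndarray, lam_eff: float) -> float:
        quad = 0.5 * self.yty_n - self.c @ beta_std + 0.5 * beta_std @ (self.G @ beta_std)
        return float(quad + lam_eff * np.abs(beta_std).sum())


def _sweep(
    coords: Sequence[int],
    beta: np.ndarray,
    Gb: np.ndarray,
    Gcols: list[np.ndarray],
    gdiag: np.ndarray,
    c: np.ndarray,
    lam_eff: float,
) -> float:
    """One pass of soft-threshold updates over ``coords``; returns the
    largest coefficient change."""
    delta_max = 0.0
    for j in coords:
        gjj = gdiag[j]
        bj = beta[j]
        z = c[j] - Gb[j] + gjj * bj
        # inline soft_threshold(z, lam_eff) / gjj
        if z > lam_eff:
            b_new = (z - lam_eff) / gjj
        elif z < -lam_eff:
            b_new = (z + lam_eff) / gjj
        else:
            b_new = 0.0
        d = b_new - bj
        if d != 0.0:
            Gb += Gcols[j] * d
            beta[j] = b_new
            ad = abs(d)
            if ad > delta_max:
                delta_max = ad
    return delta_max


def _coordinate_descent(
    design: _Design,
    lam_eff: float,
    beta0: np.ndarray,
    tol: float,
    max_iter: int,
    objective_trace: list[float] | None = None,
) -> np.ndarray:
    """Cyclic coordinate descent on the internal (standardized) scale.

    Full sweeps alternate with iteration restricted to the active (nonzero)
    set; convergence requires a full sweep whose largest coefficient change
    is below ``tol``.  When ``objective_trace`` is supplied, the objective is
    recorded after every full sweep (and active-set shortcuts are skipped so
    the trace covers each sweep).
    """
    G, c, dead = design.G, design.c, design.dead
    p = design.p
    beta = beta0.copy()
    Gb = G @ beta
    gdiag = np.diag(G).copy()
    Gcols = [np.ascontiguousarray(G[:, j]) for j in range(p)]
    live = [j for j in range(p) if not dead[j]]

    sweeps = 0
    delta_max = np.inf
    while sweeps < max_iter:
        delta_max = _sweep(live, beta, Gb, Gcols, gdiag, c, lam_eff)
        sweeps += 1
        if objective_trace is not None:
            objective_trace.append(design.objective(beta, lam_eff))
        if delta_max < tol:
            return beta
        if objective_trace is None:
            active = [j for j in live if beta[j] != 0.0]
            while sweeps < max_iter:
                d_act = _sweep(active, beta, Gb, Gcols, gdiag, c, lam_eff)
                sweeps += 1
                if d_act < tol:
                    break
    raise RuntimeError(
        f"coordinate descent did not converge in {max_iter} sweeps "
        f"(last max coefficient change {delta_max:.3e} >= tol {tol:.3e})"
    )


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    standardize: bool = True,
    beta0: np.ndarray | None = None,
    objective_trace: list[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Solve the penalized least-squares problem at one penalty level.

    Returns ``(intercept, beta)`` on the original predictor scale.  ``lam`` is
    on the model's own scale (effective L1 penalty is ``lam / 2``).  ``beta0``
    optionally warm-starts the solver (original scale).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    design = _Design(X, y, standardize)
    start = design.from_original(np.asarray(beta0, float)) if beta0 is not None \
        else np.zeros(design.p)
    beta_std = _coordinate_descent(design, lam / 2.0, start, tol, max_iter,
                                   objective_trace)
    return design.to_original(beta_std)


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lams: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit every penalty level of ``lams`` with warm starts (in given order).

    Returns ``(intercepts, betas)`` with ``betas`` of shape
    ``(len(lams), n_predictors)`` on the original scale.
    """
    design = _Design(X, y, standardize)
    betas = np.zeros((len(lams), design.p))
    intercepts = np.zeros(len(lams))
    beta_std = np.zeros(design.p)
    for i, lam in enumerate(lams):
        if lam < 0:
            raise ValueError("lam must be >= 0")
        beta_std = _coordinate_descent(design, lam / 2.0, beta_std, tol, max_iter)
        intercepts[i], betas[i] = design.to_original(beta_std)
    return intercepts, betas


def lambda_max(X: np.ndarray, y: np.ndarray, standardize: bool = True) -> float:
    """Smallest penalty at which all coefficients are exactly zero:
    ``2/n * max_j |x_j' (y - ybar)|`` on the (optionally standardized) design."""
    design = _Design(X, y, standardize)
    lmax = 2.0 * design.lambda_eff_max()
    if lmax == 0.0:
        raise ValueError(
            "lambda_max is undefined: response is constant or uncorrelated "
            "with every non-constant predictor"
        )
    return lmax


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    standardize: bool = True,
) -> np.ndarray:
    """Decreasing log-spaced penalty grid from lambda_max down to
    ``lambda_max * lambda_min_ratio``."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not (0.0 < lambda_min_ratio < 1.0):
        raise ValueError("lambda_min_ratio must be in (0, 1)")
    lmax = lambda_max(X, y, standardize)
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


@dataclass
class CVResult:
    """Cross-validation error curve over a penalty path."""

    lambda_path: np.ndarray
    fold_mse: np.ndarray  # (n_folds, n_lambda)
    mean_mse: np.ndarray  # (n_lambda,)
    lambda_selected: float
    index_selected: int
    seed: int


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    path: Sequence[float],
    n_folds: int = 10,
    seed: int = 17,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    standardize: bool = True,
) -> CVResult:
    """k-fold CV over the penalty path; folds are contiguous blocks of a
    seeded shuffle of the rows (genes are exchangeable units here).

    The selected penalty minimizes the mean held-out squared error; ties go
    to the largest (sparsest) penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    path = np.asarray(path, dtype=float)
    n = X.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} rows, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)

    fold_mse = np.zeros((n_folds, len(path)))
    for f, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        intercepts, betas = fit_lasso_path(
            X[mask], y[mask], path, tol=tol, max_iter=max_iter,
            standardize=standardize,
        )
        pred = X[test_idx] @ betas.T + intercepts  # (n_test, n_lambda)
        fold_mse[f] = ((pred - y[test_idx][:, None]) ** 2).mean(axis=0)
    mean_mse = fold_mse.mean(axis=0)
    idx = int(np.argmin(mean_mse))  # path is decreasing: first min = largest lambda
    return CVResult(
        lambda_path=path,
        fold_mse=fold_mse,
        mean_mse=mean_mse,
        lambda_selected=float(path[idx]),
        index_selected=idx,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def objective_value(
    X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray,
    lam: float, standardize: bool = True,
) -> float:
    """Penalized objective at a candidate solution, on the scale the solver
    optimizes (standardized coefficients when ``standardize``)."""
    design = _Design(X, y, standardize)
    return design.objective(design.from_original(np.asarray(beta, float)), lam / 2.0)


def kkt_max_violation(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float,
    standardize: bool = True,
) -> float:
    """Maximum violation of the stationarity conditions at a solution.

    For active coefficients ``|grad_j + lam_eff * sign(beta_j)|`` must vanish;
    for zero coefficients ``|grad_j| <= lam_eff``.  Returns the largest excess
    over these bounds (0 for an exact solution).
    """
    design = _Design(X, y, standardize)
    beta_std = design.from_original(np.asarray(beta, float))
    lam_eff = lam / 2.0
    grad = design.G @ beta_std - design.c  # d/dbeta of the smooth part
    viol = 0.0
    for j in range(design.p):
        if design.dead[j]:
            continue
        if beta_std[j] != 0.0:
            viol = max(viol, abs(grad[j] + lam_eff * np.sign(beta_std[j])))
        else:
            viol = max(viol, abs(grad[j]) - lam_eff)
    return float(viol)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class AssociationNetwork:
    """Scored disease-miRNA edges (score = Lasso coefficient at the selected
    penalty; only nonzero scores are kept)."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if any(s == 0.0 for _, _, s in self.edges):
            raise ValueError("association scores must be nonzero")

    def __len__(self) -> int:
        return len(self.edges)

    def scores(self) -> dict[tuple[str, str], float]:
        return {(d, m): s for d, m, s in self.edges}

    def for_disease(self, disease_id: str) -> dict[str, float]:
        return {m: s for d, m, s in self.edges if d == disease_id}


class MirnaLassoModel:
    """Penalized regression of one disease signature on miRNA influence
    profiles.

    Parameters
    ----------
    X : (n_genes, n_mirnas) array
        miRNA influence profiles (typically the binary NetMiR matrix).
    y : (n_genes,) array
        The disease signature encoding over the same genes.
    mirna_ids, disease_id : labels for reporting.
    config : Config, optional
        Path, CV and standardization settings (defaults used when omitted).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        mirna_ids: Sequence[str] | None = None,
        disease_id: str = "",
        config: Config | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one entry per row of X")
        self.mirna_ids = (
            list(mirna_ids)
            if mirna_ids is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        if len(self.mirna_ids) != self.X.shape[1]:
            raise ValueError("one mirna_id required per column of X")
        self.disease_id = disease_id
        self.config = config or Config()

    @classmethod
    def from_networks(
        cls,
        netmir: NetMiRMatrix,
        disease_matrix: DiseaseSignatureMatrix,
        disease_id: str,
        config: Config | None = None,
    ) -> "MirnaLassoModel":
        if netmir.gene_ids != disease_matrix.gene_ids:
            raise ValueError(
                "NetMiR and disease matrices must share an identical gene row "
                "order; run intersect_universe first"
            )
        y = disease_matrix.column(disease_id)
        if np.all(y == y[0]):
            raise ValueError(
                f"disease {disease_id!r} has a zero-variance signature column"
            )
        return cls(netmir.values, y, mirna_ids=netmir.mirna_ids,
                   disease_id=disease_id, config=config)

    def fit(self, tol: float = 1e-8, max_iter: int = 10_000) -> "MirnaLassoResults":
        cfg = self.config
        path = lambda_path(
            self.X, self.y,
            n_lambda=cfg.lambda_grid_size,
            lambda_min_ratio=cfg.lambda_min_ratio,
            standardize=cfg.standardize,
        )
        cv = cross_validate(
            self.X, self.y, path,
            n_folds=cfg.n_folds, seed=cfg.seed,
            tol=tol, max_iter=max_iter, standardize=cfg.standardize,
        )
        intercepts, betas = fit_lasso_path(
            self.X, self.y, path, tol=tol, max_iter=max_iter,
            standardize=cfg.standardize,
        )
        return MirnaLassoResults(
            model=self,
            disease_id=self.disease_id,
            mirna_ids=list(self.mirna_ids),
            beta=betas[cv.index_selected].copy(),
            intercept=float(intercepts[cv.index_selected]),
            lambda_path=path,
            cv=cv,
            path_betas=betas,
            path_intercepts=intercepts,
        )


@dataclass
class MirnaLassoResults:
    """Fit results: coefficients at the CV-selected penalty plus the full
    path and CV diagnostics."""

    model: MirnaLassoModel
    disease_id: str
    mirna_ids: list[str]
    beta: np.ndarray
    intercept: float
    lambda_path: np.ndarray
    cv: CVResult
    path_betas: np.ndarray
    path_intercepts: np.ndarray

    @property
    def lambda_selected(self) -> float:
        return self.cv.lambda_selected

    @property
    def cv_mse(self) -> np.ndarray:
        return self.cv.mean_mse

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model.X if X is None else np.asarray(X, dtype=float)
        return self.intercept + X @ self.beta

    def nonzero(self) -> dict[str, float]:
        return {m: float(b) for m, b in zip(self.mirna_ids, self.beta) if b != 0.0}

    def kkt_max_violation(self) -> float:
        return kkt_max_violation(
            self.model.X, self.model.y, self.beta, self.lambda_selected,
            standardize=self.model.config.standardize,
        )

    def associations(self, keep_sign: str | None = None) -> list[tuple[str, str, float]]:
        keep = keep_sign or self.model.config.keep_sign
        if keep not in ("positive", "both"):
            raise ValueError("keep_sign must be 'positive' or 'both'")
        out = []
        for m, b in zip(self.mirna_ids, self.beta):
            if b > 0.0 or (keep == "both" and b != 0.0):
                out.append((self.disease_id, m, float(b)))
        return out

    def summary(self) -> str:
        lines = [
            f"Lasso regression of disease signature {self.disease_id or '(unnamed)'}",
            f"  genes (rows):        {self.model.X.shape[0]}",
            f"  miRNAs (predictors): {self.model.X.shape[1]}",
            f"  lambda selected:     {self.lambda_selected:.6g} "
            f"(grid of {len(self.lambda_path)}, {self.model.config.n_folds}-fold CV)",
            f"  CV MSE at selection: {self.cv.mean_mse[self.cv.index_selected]:.6g}",
            f"  nonzero coefficients: {int(np.count_nonzero(self.beta))}",
            f"  intercept:           {self.intercept:.6g}",
            "",
            f"  {'miRNA':<20s} {'coef':>12s}",
        ]
        nz = sorted(self.nonzero().items(), key=lambda kv: -abs(kv[1]))
        for m, b in nz:
            lines.append(f"  {m:<20s} {b:>12.6f}")
        return "\n".join(lines)


def fit_disease(
    netmir: NetMiRMatrix,
    disease_matrix: DiseaseSignatureMatrix,
    disease_id: str,
    config: Config | None = None,
) -> MirnaLassoResults:
    """Fit the per-disease model: response = the disease's signature column,
    predictors = the miRNA influence profiles."""
    model = MirnaLassoModel.from_networks(netmir, disease_matrix, disease_id, config)
    return model.fit()


def fit_gene_list(
    netmir: NetMiRMatrix,
    gene_list: set[str],
    config: Config | None = None,
    list_id: str = "gene_list",
) -> MirnaLassoResults:
    """Enrichment by regression: the response is the membership indicator of
    an arbitrary gene list over the NetMiR gene universe, and miRNAs are
    ranked by their coefficients."""
    y = np.array([1.0 if g in gene_list else 0.0 for g in netmir.gene_ids])
    if np.all(y == y[0]):
        raise ValueError("gene list is empty or covers the whole universe")
    model = MirnaLassoModel(netmir.values, y, mirna_ids=netmir.mirna_ids,
                            disease_id=list_id, config=config)
    return model.fit()


def extract_associations(
    fits: Sequence[MirnaLassoResults], keep_sign: str = "positive"
) -> AssociationNetwork:
    """Collect scored disease-miRNA edges across per-disease fits.

    Negative coefficients carry no biological interpretation here and are
    dropped under the default policy."""
    if not fits:
        raise ValueError("fits must be non-empty")
    edges: list[tuple[str, str, float]] = []
    for fit in fits:
        edges.extend(fit.associations(keep_sign))
    return AssociationNetwork(edges=edges)
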
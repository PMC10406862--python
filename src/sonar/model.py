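"""Geographically weighted Poisson-Gamma regression for spot deconvolution.

The observation model for spot ``i`` and gene ``g`` is

.. math::

    y_{ig} \\mid V_{ig} \\sim \\mathrm{Poisson}(\\Phi_i \\lambda_{ig} V_{ig}),
    \\qquad V_{ig} \\sim \\mathrm{Gamma}(\\alpha_i, \\alpha_i),

with expected rate :math:`\\lambda_{ig} = \\beta_{i0} + \\sum_t \\beta_{it}
s_{tg}` a non-negative linear mixture of the reference cell-type signatures
:math:`s_{tg}`.  Marginalising the Gamma multiplier gives the standard
negative-binomial pmf with mean :math:`\\mu = \\Phi_i \\lambda_{ig}` and
variance :math:`\\mu + \\mu^2/\\alpha_i`; the model reduces to Poisson as
:math:`\\alpha_i \\to \\infty`.

Each spot's parameters :math:`(\\boldsymbol{\\beta}_i, \\alpha_i)` maximise a
geographically weighted local log-likelihood: the sum of the spot
log-likelihoods of its neighbours, evaluated at the focal spot's parameters
and weighted by spatially decaying (and similarity-adjusted) weights built
in :mod:`sonar.weights`.

The module-level functions implement the individual likelihood pieces and
per-spot fits; :class:`SONARModel` / :class:`DeconvolutionResult` wrap them
in a model/results interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from scipy.special import digamma, gammaln

from .data import SpatialDataset

__all__ = [
    "FitConfig",
    "SpotFit",
    "DeconvolutionResult",
    "SONARModel",
    "expected_rate",
    "nb_logpmf",
    "poisson_logpmf",
    "spot_loglik",
    "local_weighted_loglik",
    "fit_spot",
    "fit_all",
    "SONARResults",
]

# Finite stand-in for log 0 so optimizer line searches stay finite.
NEG_SENTINEL = -1e10
# Rate floor used inside the smooth optimization objective only.
_RATE_FLOOR = 1e-12


class FitError(RuntimeError):
    """Raised when a spot's likelihood cannot be maximised."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the per-spot maximum-likelihood fit.

    ``tol`` is the relative log-likelihood improvement below which the
    quasi-Newton iteration stops; ``alpha_init`` starts the dispersion at a
    moderately overdispersed value and ``alpha_min`` keeps it strictly
    positive.  ``overdispersion=False`` fixes the Gamma multiplier at 1,
    i.e. a plain Poisson regression with no dispersion parameter.
    """

    tol: float = 1e-6
    max_iter: int = 500
    alpha_init: float = 10.0
    alpha_min: float = 1e-4
    overdispersion: bool = True


@dataclass
class SpotFit:
    """Per-spot estimate: beta (intercept + T loadings), dispersion, fit info."""

    beta: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    n_iter: int
    failed: bool = False
    message: str = ""


def expected_rate(beta: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Expected expression rate lambda_g = beta_0 + sum_t beta_t * s_{t,g}.

    Parameters
    ----------
    beta : array of length T+1
        Non-negative intercept followed by T cell-type loadings.
    S : array of shape (T, G)
        Non-negative signature matrix.
    """
    beta = np.asarray(beta, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if beta.ndim != 1 or S.ndim != 2 or beta.shape[0] != S.shape[0] + 1:
        raise ValueError(
            f"beta must have length T+1={S.shape[0] + 1}, got {beta.shape}"
        )
    return beta[0] + beta[1:] @ S


def nb_logpmf(y, mu, alpha) -> np.ndarray:
    """Log-pmf of the Gamma-Poisson (negative binomial) marginal.

    With ``V ~ Gamma(alpha, alpha)`` and ``y | V ~ Poisson(mu V)`` the
    marginal is NB with mean ``mu`` and variance ``mu + mu**2/alpha``:

    ``log P(y) = lgamma(y+a) - lgamma(a) - lgamma(y+1)
    + a*log(a/(a+mu)) + y*log(mu/(a+mu))``.

    ``mu = 0`` is handled as a point mass at zero: returns 0 for ``y = 0``
    and a large negative sentinel (not ``-inf``) for ``y > 0``.
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha must be > 0")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0")
    y, mu = np.broadcast_arrays(y, mu)
    out = np.empty(y.shape, dtype=np.float64)
    zero = mu == 0
    if np.any(zero):
        out[zero] = np.where(y[zero] == 0, 0.0, NEG_SENTINEL)
    pos = ~zero
    if np.any(pos):
        yp, mp = y[pos], mu[pos]
        out[pos] = (
            gammaln(yp + alpha)
            - gammaln(alpha)
            - gammaln(yp + 1)
            + alpha * np.log(alpha / (alpha + mp))
            + yp * np.log(mp / (alpha + mp))
        )
    return out if out.ndim else float(out)


def poisson_logpmf(y, mu) -> np.ndarray:
    """Poisson log-pmf with the same mu=0 conventions as :func:`nb_logpmf`."""
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    y, mu = np.broadcast_arrays(y, mu)
    out = np.empty(y.shape, dtype=np.float64)
    zero = mu == 0
    out[zero] = np.where(y[zero] == 0, 0.0, NEG_SENTINEL)
    pos = ~zero
    if np.any(pos):
        yp, mp = y[pos], mu[pos]
        out[pos] = yp * np.log(mp) - mp - gammaln(yp + 1)
    return out if out.ndim else float(out)


def spot_loglik(beta, alpha, counts_row, depth, S, overdispersion=True) -> float:
    """Log-likelihood of one spot's full expression profile.

    Sums the per-gene NB (or Poisson) log-pmf at mean ``depth * lambda_g``.
    """
    lam = expected_rate(beta, S)
    mu = depth * lam
    if overdispersion:
        terms = nb_logpmf(counts_row, mu, alpha)
    else:
        terms = poisson_logpmf(counts_row, mu)
    return float(np.sum(terms))


def local_weighted_loglik(
    beta, alpha, focal_spot: int, dataset: SpatialDataset, S, weights,
    overdispersion=True,
) -> float:
    """Geographically weighted local log-likelihood of a focal spot.

    ``weights`` maps neighbour index -> final weight; the focal spot must be
    a key.  Parameters are shared across neighbours: every neighbour's spot
    log-likelihood is evaluated at the focal spot's ``(beta, alpha)``.
    """
    if focal_spot not in weights:
        raise ValueError(f"focal spot {focal_spot} missing from its weight map")
    total = 0.0
    for n, w in weights.items():
        if not 0 <= n < dataset.n_spots:
            raise ValueError(f"weight given for spot {n} outside the dataset")
        total += w * spot_loglik(
            beta, alpha, dataset.counts[n], dataset.depth[n], S, overdispersion
        )
    return total


def _pack_neighbors(dataset, S, neighbor_idx, neighbor_w):
    """Stack neighbour rows/depths/weights for the vectorised objective."""
    idx = np.asarray(neighbor_idx, dtype=int)
    w = np.asarray(neighbor_w, dtype=np.float64)
    keep = w > 0
    idx, w = idx[keep], w[keep]
    Y = dataset.counts[idx]
    phi = dataset.depth[idx]
    return Y, phi, w


def _neg_local_loglik_and_grad(theta, Y, phi, w, S, overdispersion):
    """Negative weighted local log-likelihood and its gradient.

    theta = (beta_0..beta_T[, alpha]).  The rate is floored at a tiny
    positive value so the objective stays smooth where some lambda_g = 0;
    the floor is far below any data-supported rate.
    """
    T = S.shape[0]
    beta = theta[: T + 1]
    lam = np.maximum(beta[0] + beta[1:] @ S, _RATE_FLOOR)
    # floored so zero-depth neighbours stay finite (their y is all zero)
    mu = np.maximum(phi[:, None] * lam[None, :], _RATE_FLOOR)
    if overdispersion:
        a = theta[T + 1]
        ll_terms = (
            gammaln(Y + a)
            - gammaln(a)
            - gammaln(Y + 1)
            + a * np.log(a / (a + mu))
            + Y * np.log(mu / (a + mu))
        )
        dmu = Y / mu - (Y + a) / (a + mu)
        da_terms = (
            digamma(Y + a) - digamma(a) + np.log(a / (a + mu)) + (mu - Y) / (a + mu)
        )
        grad_alpha = np.sum(w[:, None] * da_terms)
    else:
        ll_terms = Y * np.log(mu) - mu - gammaln(Y + 1)
        dmu = Y / mu - 1.0
    ll = np.sum(w[:, None] * ll_terms)
    dlam = np.sum((w * phi)[:, None] * dmu, axis=0)  # genes
    grad_beta = np.empty(T + 1)
    grad_beta[0] = dlam.sum()
    grad_beta[1:] = S @ dlam
    if overdispersion:
        grad = np.concatenate([grad_beta, [grad_alpha]])
    else:
        grad = grad_beta
    return -ll, -grad


def _init_beta(counts_row, depth, S):
    """Non-negative least squares of the depth-normalised profile on S."""
    target = counts_row / max(depth, 1.0)
    coef, _ = nnls(S.T, target)
    beta = np.zeros(S.shape[0] + 1)
    beta[1:] = coef
    return beta


def fit_spot(
    focal_spot: int,
    dataset: SpatialDataset,
    S: np.ndarray,
    weights: dict,
    config: FitConfig = FitConfig(),
) -> SpotFit:
    """Maximise the weighted local likelihood for one spot.

    beta is initialised by NNLS of the focal spot's depth-normalised counts
    on the signatures (intercept 0), alpha at ``config.alpha_init``; both
    are then refined by bound-constrained quasi-Newton (L-BFGS-B) with
    lower bounds 0 for beta and ``config.alpha_min`` for alpha.  The
    returned likelihood never falls below its value at initialisation.
    """
    S = np.asarray(S, dtype=np.float64)
    T = S.shape[0]
    if focal_spot not in weights:
        raise FitError(f"spot {focal_spot}: focal spot missing from weight map")
    Y, phi, w = _pack_neighbors(dataset, S, list(weights), list(weights.values()))
    if len(w) == 0:
        raise FitError(f"spot {focal_spot}: all neighbour weights are zero")

    beta0 = _init_beta(dataset.counts[focal_spot], dataset.depth[focal_spot], S)
    if config.overdispersion:
        theta0 = np.concatenate([beta0, [config.alpha_init]])
        bounds = [(0.0, None)] * (T + 1) + [(config.alpha_min, None)]
    else:
        theta0 = beta0
        bounds = [(0.0, None)] * (T + 1)

    f0, _ = _neg_local_loglik_and_grad(theta0, Y, phi, w, S, config.overdispersion)
    if not np.isfinite(f0):
        raise FitError(f"spot {focal_spot}: non-finite likelihood at initialisation")

    res = minimize(
        _neg_local_loglik_and_grad,
        theta0,
        args=(Y, phi, w, S, config.overdispersion),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.max_iter, "ftol": config.tol},
    )
    if not np.isfinite(res.fun) or res.fun > f0:
        # Keep the initialisation if the optimizer failed to improve.
        theta, fval, converged = theta0, f0, False
    else:
        theta, fval, converged = res.x, res.fun, bool(res.success)
    beta = np.maximum(theta[: T + 1], 0.0)
    alpha = float(theta[T + 1]) if config.overdispersion else np.inf
    return SpotFit(
        beta=beta,
        alpha=alpha,
        loglik=-float(fval),
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def fit_all(
    dataset: SpatialDataset,
    S: np.ndarray,
    scheme,
    config: FitConfig = FitConfig(),
    cell_type_ids=None,
) -> "DeconvolutionResult":
    """Fit every spot independently under its local weight map.

    Spot fits are independent maximisations, so the result does not depend
    on spot order.  A failing spot is recorded, flagged, and given uniform
    proportions; more than 10% failures aborts the run.
    """
    S = np.asarray(S, dtype=np.float64)
    T = S.shape[0]
    n = dataset.n_spots
    beta_matrix = np.zeros((n, T + 1))
    alpha_vector = np.full(n, np.nan)
    loglik = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    failed = np.zeros(n, dtype=bool)
    for i in range(n):
        wmap = scheme.weight_map(i) if hasattr(scheme, "weight_map") else scheme[i]
        try:
            fit = fit_spot(i, dataset, S, wmap, config)
        except FitError as err:
            warnings.warn(f"fit failed for spot {dataset.spot_ids[i]}: {err}",
                          stacklevel=2)
            failed[i] = True
            continue
        beta_matrix[i] = fit.beta
        alpha_vector[i] = fit.alpha
        loglik[i] = fit.loglik
        converged[i] = fit.converged
    n_failed = int(failed.sum())
    if n_failed > 0.10 * n:
        raise RuntimeError(
            f"{n_failed}/{n} spot fits failed (>10%); aborting run"
        )
    if cell_type_ids is None:
        cell_type_ids = [f"type_{t}" for t in range(T)]
    return DeconvolutionResult(
        beta_matrix=beta_matrix,
        alpha_vector=alpha_vector,
        loglik=loglik,
        converged=converged,
        failed=failed,
        cell_type_ids=list(cell_type_ids),
        spot_ids=list(dataset.spot_ids),
    )


@dataclass
class DeconvolutionResult:
    """Per-spot parameter estimates and derived cell-type proportions.

    Proportions normalise the type loadings beta_{i,1..T} to the simplex;
    the intercept beta_{i,0} is a spot-specific nuisance effect and is
    excluded.  Spots whose loadings are all zero (or whose fit failed) get
    uniform proportions and are flagged degenerate.
    """

    beta_matrix: np.ndarray  # spots x (T+1)
    alpha_vector: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    failed: np.ndarray
    cell_type_ids: list[str]
    spot_ids: list[str]
    model: "SONARModel" = field(default=None, repr=False)

    @property
    def n_types(self) -> int:
        return len(self.cell_type_ids)

    @property
    def degenerate(self) -> np.ndarray:
        """Spots with no usable loadings: failed fits or an all-zero beta row."""
        return self.failed | (self.beta_matrix[:, 1:].sum(axis=1) == 0)

    @property
    def proportions(self) -> np.ndarray:
        loadings = self.beta_matrix[:, 1:]
        totals = loadings.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = loadings / totals
        p[self.degenerate] = 1.0 / self.n_types
        return p

    @property
    def proportions_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.spot_ids, columns=self.cell_type_ids
        )

    def params_df(self) -> pd.DataFrame:
        cols = {"alpha": self.alpha_vector, "beta_0": self.beta_matrix[:, 0]}
        for t, name in enumerate(self.cell_type_ids):
            cols[f"beta_{name}"] = self.beta_matrix[:, t + 1]
        cols["loglik"] = self.loglik
        cols["converged"] = self.converged
        cols["degenerate"] = self.degenerate
        return pd.DataFrame(cols, index=self.spot_ids)

    def summary(self) -> str:
        n = len(self.spot_ids)
        mean_p = self.proportions.mean(axis=0)
        lines = [
            "SONAR deconvolution results",
            "=" * 44,
            f"spots: {n}    cell types: {self.n_types}",
            f"converged: {int(self.converged.sum())}/{n}"
            f"    degenerate: {int(self.degenerate.sum())}"
            f"    failed: {int(self.failed.sum())}",
            f"total local log-likelihood: {np.nansum(self.loglik):.2f}",
            f"median dispersion alpha: {np.nanmedian(self.alpha_vector):.3g}",
            "-" * 44,
            f"{'cell type':<24}{'mean prop.':>12}",
        ]
        for name, p in zip(self.cell_type_ids, mean_p):
            lines.append(f"{name:<24}{p:>12.4f}")
        return "\n".join(lines)

    def plot_spatial(self, cell_type: str, ax=None, **scatter_kw):
        """Scatter one cell type's proportion over the spot coordinates."""
        if self.model is None:
            raise ValueError("result has no attached model (no coordinates)")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.cell_type_ids.index(cell_type)
        coords = self.model.dataset.coords
        sc = ax.scatter(
            coords[:, 0], coords[:, 1], c=self.proportions[:, t],
            s=scatter_kw.pop("s", 20), **scatter_kw,
        )
        ax.set_aspect("equal")
        ax.set_title(cell_type)
        plt.colorbar(sc, ax=ax, label="proportion")
        return ax


class SONARModel:
    """Spatially weighted Poisson-Gamma deconvolution model.

    Parameters
    ----------
    dataset : SpatialDataset
        Spot counts (on the deconvolution gene panel), coordinates, and
        full-panel depths.
    signature : ndarray (T, G) or ReferenceSignature
        Cell-type signature matrix aligned to ``dataset.gene_ids``; a
        :class:`~sonar.reference.ReferenceSignature` contributes its
        platform-corrected matrix.
    bandwidth : float, optional
        Kernel radius; defaults to 1.2x the median nearest-neighbour
        distance so only first-order neighbours get positive weight.
    rho : float or "auto"
        Elastic weighting strength; "auto" scales it to the typical
        neighbour similarity deficit (see :func:`sonar.weights.resolve_rho`).
    precluster, elastic : bool
        Toggle the cluster mask and the similarity adjustment.  Both off
        is the pure-kernel ablation (SONAR-0).
    """

    def __init__(
        self,
        dataset: SpatialDataset,
        signature,
        *,
        bandwidth: float | None = None,
        rho: float | str = "auto",
        precluster: bool = True,
        elastic: bool = True,
        precluster_method: str = "leiden",
        precluster_resolution: float = 0.5,
        seed: int = 0,
        config: FitConfig = FitConfig(),
    ):
        from .reference import ReferenceSignature

        self.dataset = dataset
        if isinstance(signature, ReferenceSignature):
            self.cell_type_ids = list(signature.cell_type_ids)
            self.S = signature.S_corrected
            if list(signature.gene_ids) != list(dataset.gene_ids):
                raise ValueError(
                    "signature gene_ids must match dataset gene_ids; "
                    "align with dataset.subset_genes first"
                )
        else:
            self.S = np.asarray(signature, dtype=np.float64)
            self.cell_type_ids = [f"type_{t}" for t in range(self.S.shape[0])]
        if self.S.shape[1] != dataset.n_genes:
            raise ValueError(
                f"signature has {self.S.shape[1]} genes, dataset {dataset.n_genes}"
            )
        self.bandwidth = bandwidth
        self.rho = rho
        self.precluster = precluster
        self.elastic = elastic
        self.precluster_method = precluster_method
        self.precluster_resolution = precluster_resolution
        self.seed = seed
        self.config = config
        self.weight_scheme_ = None

    @classmethod
    def from_dataframes(
        cls, counts: pd.DataFrame, coords: pd.DataFrame, signature: pd.DataFrame,
        **kwargs,
    ) -> "SONARModel":
        """Build from spot x gene counts, (spot_id, x, y) coords, and a
        type x gene signature table; genes are intersected and aligned."""
        genes = [g for g in counts.columns if g in set(signature.columns)]
        if not genes:
            raise ValueError("counts and signature share no genes")
        coords = coords.set_index(coords.columns[0]) if coords.index.name is None \
            and coords.shape[1] == 3 else coords
        xy = coords.loc[counts.index, coords.columns[-2:]].to_numpy(float)
        ds = SpatialDataset(
            counts=counts.to_numpy(),
            coords=xy,
            spot_ids=list(counts.index),
            gene_ids=list(counts.columns),
        ).subset_genes(genes)
        model = cls(ds, signature[genes].to_numpy(float), **kwargs)
        model.cell_type_ids = list(signature.index)
        return model

    def build_weights(self):
        """Construct (and cache) the per-spot neighbour weight scheme."""
        from . import weights as W

        if self.weight_scheme_ is None:
            b = self.bandwidth
            if b is None:
                b = W.default_bandwidth(self.dataset.coords)
            if self.precluster:
                labels = W.precluster(
                    self.dataset,
                    method=self.precluster_method,
                    resolution=self.precluster_resolution,
                    seed=self.seed,
                )
            else:
                labels = np.zeros(self.dataset.n_spots, dtype=int)
            self.weight_scheme_ = W.build_weight_scheme(
                self.dataset, b, self.rho, labels, elastic=self.elastic
            )
        return self.weight_scheme_

    def fit(self) -> DeconvolutionResult:
        scheme = self.build_weights()
        result = fit_all(
            self.dataset, self.S, scheme, self.config,
            cell_type_ids=self.cell_type_ids,
        )
        result.model = self
        return result


# statsmodels-style alias: model.fit() returns the results object.
SONARResults = DeconvolutionResult
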
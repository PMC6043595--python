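"""Bayesian monotone penalized B-spline Bernoulli model of retreat probability.

The binary response ``y_i`` (1 = positive sea-level tendency, i.e. marsh
retreat) is modelled as Bernoulli(p_i) with

    logit(p) = sum_k b_k(x) * alpha_k,

where ``b_k`` are cubic B-spline basis functions of the RSLR rate ``x``
(mm/yr).  First-order differences of the coefficients are shrunk,
``alpha_k − alpha_{k−1} ~ N(0, sigma_a^2)``, which penalizes roughness;
with the monotonicity constraint the differences are additionally
required to be non-negative, so every posterior draw of the probability
curve is non-decreasing in the rate.

Parameterization and sampler
----------------------------
We sample ``(alpha_1, delta_2..delta_K, log sigma_a)`` where
``delta_k = alpha_k − alpha_{k−1}``.  Under the monotone model each
``delta_k`` carries a half-normal(sigma_a) prior (the N(0, sigma_a^2)
difference penalty truncated at zero); without the constraint the prior
is the untruncated normal.  ``alpha_1 ~ N(0, 10^2)`` and
``sigma_a ~ half-Cauchy(1)`` by default.  Posterior draws come from an
adaptive random-walk Metropolis-within-Gibbs sampler whose chain kernel
is JIT-compiled; because the basis forms a partition of unity, the
linear predictor is ``alpha_1 + sum_j delta_j * C_j(x)`` with
``C_j = sum_{k>=j} b_k``, making each component update O(n).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from numba import njit
from scipy.interpolate import BSpline
from scipy.special import expit, logit


# --------------------------------------------------------------------------
# basis


@dataclass
class SplineBasis:
    """Cubic (by default) B-spline basis on equally spaced knots.

    ``knots`` is the full knot vector with the boundary knots repeated
    ``degree + 1`` times; the basis spans ``support = [x_min, x_max]`` of
    the data it was built from and forms a partition of unity there.
    """

    degree: int
    K: int
    knots: np.ndarray
    support: tuple[float, float]

    def design_matrix(self, x: Sequence[float], *, clip: bool = True) -> np.ndarray:
        """Dense (len(x), K) basis matrix.

        With ``clip=True`` (default) evaluation points outside the support
        are clamped to the boundary, which realizes flat extrapolation of
        any curve expressed in this basis.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if clip:
            x = np.clip(x, self.support[0], self.support[1])
        elif np.any((x < self.support[0]) | (x > self.support[1])):
            raise ValueError("evaluation point outside basis support")
        dm = BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False)
        return np.asarray(dm.todense())


def build_basis(x: Sequence[float], K: int = 12, degree: int = 3) -> SplineBasis:
    """Equally spaced B-spline basis spanning the data range of ``x``."""
    x = np.asarray(x, dtype=float)
    if K < degree + 1:
        raise ValueError(f"K={K} too small for degree {degree}; need K >= degree + 1")
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if not xmin < xmax:
        raise ValueError("x needs at least 2 distinct values")
    # K basis functions of degree d need K + d + 1 knots: K - d - 1 interior
    breaks = np.linspace(xmin, xmax, K - degree + 1)
    knots = np.concatenate([np.full(degree, xmin), breaks, np.full(degree, xmax)])
    return SplineBasis(degree=degree, K=K, knots=knots, support=(xmin, xmax))


# --------------------------------------------------------------------------
# configuration / posterior containers


@dataclass
class ModelConfig:
    """Model and MCMC settings.

    sigma_prior_scale is the half-Cauchy scale on the smoothing scale
    sigma_a; smaller values favour smoother curves.
    """

    K: int = 12
    degree: int = 3
    monotone: bool = True
    alpha1_prior_sd: float = 10.0
    sigma_prior_scale: float = 1.0
    chains: int = 4
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelPosterior:
    """MCMC draws of the spline coefficients and smoothing scale."""

    alpha: np.ndarray  # (chains, draws, K)
    sigma: np.ndarray  # (chains, draws)
    basis: SplineBasis
    config: ModelConfig
    diagnostics: dict = field(default_factory=dict)
    boundary_degenerate: bool = False

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def alpha_flat(self) -> np.ndarray:
        return self.alpha.reshape(-1, self.alpha.shape[-1])

    def p_draws(self, x: Sequence[float]) -> np.ndarray:
        """Per-draw retreat probabilities at ``x``: (n_draws, len(x))."""
        B = self.basis.design_matrix(x)
        return expit(self.alpha_flat() @ B.T)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("max_rhat", np.inf) <= 1.05)


@dataclass
class ProbabilityCurve:
    """Posterior retreat-probability curve on a rate grid with 95% band."""

    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray  # 2.5th percentile
    hi: np.ndarray  # 97.5th percentile

    def evaluate(self, rates: Sequence[float]) -> np.ndarray:
        """Mean curve, linearly interpolated, flat beyond the grid."""
        return np.interp(np.asarray(rates, dtype=float), self.grid, self.mean)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"rate_mm_yr": self.grid, "mean": self.mean, "lo": self.lo, "hi": self.hi}
        )


@dataclass(frozen=True)
class NotReached:
    """Sentinel: the target probability is not attained by the curve.

    ``direction`` is "above_max" when the target exceeds the curve's
    maximum and "below_min" when it lies under its minimum.
    """

    direction: str


def retreat_odds(p: float) -> float:
    """Odds of retreat vs non-retreat implied by a probability: p/(1−p)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly inside (0, 1)")
    return p / (1.0 - p)


# --------------------------------------------------------------------------
# sampler kernels


@njit(cache=True)
def _bernoulli_loglik(eta, y):
    ll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i]
        if e > 0.0:
            ll += y[i] * e - e - np.log1p(np.exp(-e))
        else:
            ll += y[i] * e - np.log1p(np.exp(e))
    return ll


@njit(cache=True)
def _run_chain(
    B,  # (n, K) basis matrix
    C,  # (n, K) cumulative basis: C[:,0] = 1, C[:,j] = sum_{k>=j} b_k
    y,  # (n,) float 0/1
    monotone,
    like_on,
    alpha1_sd,
    sigma_scale,
    n_iter,
    burn_in,
    thin,
    seed,
):
    np.random.seed(seed)
    n, K = C.shape
    P = K + 1  # alpha1, delta_2..delta_K, log sigma

    theta = np.zeros(P)
    ybar = 0.5
    if like_on and n > 0:
        s = 0.0
        for i in range(n):
            s += y[i]
        ybar = s / n
        if ybar < 0.01:
            ybar = 0.01
        if ybar > 0.99:
            ybar = 0.99
    theta[0] = np.log(ybar / (1.0 - ybar)) + 0.5 * np.random.normal()
    for j in range(1, K):
        if monotone:
            theta[j] = 0.05 + 0.05 * abs(np.random.normal())
        else:
            theta[j] = 0.1 * np.random.normal()
    theta[P - 1] = 0.2 * np.random.normal()

    eta = np.empty(n)
    for i in range(n):
        e = theta[0]
        for j in range(1, K):
            e += theta[j] * C[i, j]
        eta[i] = e
    ll = _bernoulli_loglik(eta, y) if like_on else 0.0

    # two move families, each with its own adapted step sizes:
    # P component moves on (alpha1, delta_j, log sigma) plus K-1
    # compensated pair moves that change a single coefficient alpha_j
    # (alpha_j += e with delta_{j+1} -= e), breaking the level/difference
    # ridge at the weakly identified boundary.
    M = P + (K - 1)
    log_step = np.full(M, np.log(0.5))
    acc = np.zeros(M)
    tries = np.zeros(M)
    batch_acc = np.zeros(M)
    batch_n = np.zeros(M)

    n_keep = (n_iter - burn_in + thin - 1) // thin
    draws = np.empty((n_keep, P))
    keep = 0
    eta_new = np.empty(n)

    for it in range(n_iter):
        sigma = np.exp(theta[P - 1])
        inv2s2 = 1.0 / (2.0 * sigma * sigma)

        # --- alpha_1 (shifts the whole linear predictor)
        old = theta[0]
        prop = old + np.exp(log_step[0]) * np.random.normal()
        d = prop - old
        if like_on:
            for i in range(n):
                eta_new[i] = eta[i] + d
            ll_new = _bernoulli_loglik(eta_new, y)
        else:
            ll_new = 0.0
        logr = (ll_new - ll) + (old * old - prop * prop) / (2.0 * alpha1_sd * alpha1_sd)
        tries[0] += 1.0
        batch_n[0] += 1.0
        if np.log(np.random.random()) < logr:
            theta[0] = prop
            ll = ll_new
            if like_on:
                for i in range(n):
                    eta[i] = eta_new[i]
            acc[0] += 1.0
            batch_acc[0] += 1.0

        # --- differences delta_j
        for j in range(1, K):
            old = theta[j]
            prop = old + np.exp(log_step[j]) * np.random.normal()
            tries[j] += 1.0
            batch_n[j] += 1.0
            if monotone and prop < 0.0:
                continue  # zero prior mass: certain rejection
            d = prop - old
            if like_on:
                for i in range(n):
                    eta_new[i] = eta[i] + d * C[i, j]
                ll_new = _bernoulli_loglik(eta_new, y)
            else:
                ll_new = 0.0
            logr = (ll_new - ll) + (old * old - prop * prop) * inv2s2
            if np.log(np.random.random()) < logr:
                theta[j] = prop
                ll = ll_new
                if like_on:
                    for i in range(n):
                        eta[i] = eta_new[i]
                acc[j] += 1.0
                batch_acc[j] += 1.0

        # --- log sigma (touches only the difference priors + hyperprior)
        old_ls = theta[P - 1]
        prop_ls = old_ls + np.exp(log_step[P - 1]) * np.random.normal()
        ssq = 0.0
        for j in range(1, K):
            ssq += theta[j] * theta[j]
        s_old = np.exp(old_ls)
        s_new = np.exp(prop_ls)
        logr = (
            -ssq / 2.0 * (1.0 / (s_new * s_new) - 1.0 / (s_old * s_old))
            - (K - 1) * (prop_ls - old_ls)
            + (prop_ls - np.log1p((s_new / sigma_scale) ** 2))
            - (old_ls - np.log1p((s_old / sigma_scale) ** 2))
        )
        tries[P - 1] += 1.0
        batch_n[P - 1] += 1.0
        if np.log(np.random.random()) < logr:
            theta[P - 1] = prop_ls
            acc[P - 1] += 1.0
            batch_acc[P - 1] += 1.0

        # --- compensated pair moves: change alpha_j alone (j = 1..K-1)
        sigma = np.exp(theta[P - 1])
        inv2s2 = 1.0 / (2.0 * sigma * sigma)
        for j in range(1, K):
            m = P + j - 1
            e = np.exp(log_step[m]) * np.random.normal()
            tries[m] += 1.0
            batch_n[m] += 1.0
            if j == 1:
                old_a, old_d = theta[0], theta[1]
                new_a, new_d = old_a + e, old_d - e
                if monotone and new_d < 0.0:
                    continue
                dprior = (old_a * old_a - new_a * new_a) / (
                    2.0 * alpha1_sd * alpha1_sd
                ) + (old_d * old_d - new_d * new_d) * inv2s2
            else:
                old_a, old_d = theta[j - 1], theta[j]
                new_a, new_d = old_a + e, old_d - e
                if monotone and (new_a < 0.0 or new_d < 0.0):
                    continue
                dprior = (
                    old_a * old_a - new_a * new_a + old_d * old_d - new_d * new_d
                ) * inv2s2
            if like_on:
                for i in range(n):
                    eta_new[i] = eta[i] + e * B[i, j - 1]
                ll_new = _bernoulli_loglik(eta_new, y)
            else:
                ll_new = 0.0
            if np.log(np.random.random()) < (ll_new - ll) + dprior:
                theta[j - 1] = new_a
                theta[j] = new_d
                ll = ll_new
                if like_on:
                    for i in range(n):
                        eta[i] = eta_new[i]
                acc[m] += 1.0
                batch_acc[m] += 1.0

        # --- step-size adaptation (burn-in only, batches of 50)
        if it < burn_in and (it + 1) % 50 == 0:
            gain = 1.0 / np.sqrt((it + 1) / 50.0)
            if gain > 0.1:
                gain = 0.1
            for j in range(M):
                if batch_n[j] > 0.0:
                    rate = batch_acc[j] / batch_n[j]
                    if rate > 0.44:
                        log_step[j] += gain
                    else:
                        log_step[j] -= gain
                batch_acc[j] = 0.0
                batch_n[j] = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(P):
                draws[keep, j] = theta[j]
            keep += 1

    return draws, acc / np.maximum(tries, 1.0)


# --------------------------------------------------------------------------
# fitting


def _cumulative_basis(B: np.ndarray) -> np.ndarray:
    """C[:, j] = sum_{k >= j} B[:, k]; C[:, 0] == 1 by partition of unity."""
    return np.cumsum(B[:, ::-1], axis=1)[:, ::-1]


def fit_tendency_model(data, config: ModelConfig | None = None, *, prior_only: bool = False) -> ModelPosterior:
    """Fit the monotone P-spline Bernoulli model by MCMC.

    Parameters
    ----------
    data
        A :class:`~marshrisk.database_io.TendencyDataset` (or any object
        with finite ``x`` rates, 0/1 ``y`` and ``n``).
    config
        Model and sampler settings; defaults to :class:`ModelConfig()`.
    prior_only
        Switch the likelihood off to draw from the prior predictive
        (the data only fix the basis support).

    Convergence is assessed by split R-hat on every coefficient; failure
    (R-hat > 1.05) is recorded in ``diagnostics`` and on ``converged``,
    never hidden.
    """
    config = config or ModelConfig()
    x = np.asarray(data.x, dtype=float)
    y = np.asarray(data.y, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite rate in x")
    classes = np.unique(y)
    if data.n < 20 or classes.size < 2:
        warnings.warn(
            f"weakly informative data (n={data.n}, classes={classes.size}); "
            "posterior will be prior-dominated",
            UserWarning,
            stacklevel=2,
        )
    boundary_degenerate = classes.size < 2 and not prior_only

    basis = build_basis(x, K=config.K, degree=config.degree)
    B = basis.design_matrix(x)
    C = np.ascontiguousarray(_cumulative_basis(B))

    seed_rng = np.random.default_rng(config.seed)
    chain_seeds = seed_rng.integers(0, 2**31 - 1, size=config.chains)

    all_draws = []
    accept = []
    for cs in chain_seeds:
        draws, acc = _run_chain(
            np.ascontiguousarray(B),
            C,
            y,
            config.monotone,
            not prior_only,
            config.alpha1_prior_sd,
            config.sigma_prior_scale,
            config.iterations,
            config.burn_in,
            config.thin,
            int(cs),
        )
        all_draws.append(draws)
        accept.append(acc)
    theta = np.stack(all_draws)  # (chains, keep, K+1)

    K = config.K
    alpha = np.empty((theta.shape[0], theta.shape[1], K))
    alpha[:, :, 0] = theta[:, :, 0]
    alpha[:, :, 1:] = theta[:, :, 0:1] + np.cumsum(theta[:, :, 1:K], axis=2)
    sigma = np.exp(theta[:, :, K])

    diagnostics = _diagnostics(alpha, sigma)
    diagnostics["acceptance"] = np.mean(accept, axis=0).tolist()
    diagnostics["seed"] = config.seed

    return ModelPosterior(
        alpha=alpha,
        sigma=sigma,
        basis=basis,
        config=config,
        diagnostics=diagnostics,
        boundary_degenerate=boundary_degenerate,
    )


def _diagnostics(alpha: np.ndarray, sigma: np.ndarray) -> dict:
    import arviz as az  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.from_dict(posterior={"alpha": alpha, "sigma": sigma})
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    rhat_alpha = np.asarray(rhat["alpha"])
    ess_alpha = np.asarray(ess["alpha"])
    max_rhat = float(np.nanmax([np.nanmax(rhat_alpha), float(rhat["sigma"])]))
    return {
        "rhat_alpha": rhat_alpha.tolist(),
        "rhat_sigma": float(rhat["sigma"]),
        "ess_alpha": ess_alpha.tolist(),
        "ess_sigma": float(ess["sigma"]),
        "max_rhat": max_rhat,
        "converged": bool(max_rhat <= 1.05),
    }


# --------------------------------------------------------------------------
# posterior summaries


def probability_curve(post: ModelPosterior, grid: Sequence[float]) -> ProbabilityCurve:
    """Posterior mean and 2.5/97.5 percentiles of p on a rate grid.

    Grid points outside the fitted support use flat extrapolation (the
    boundary value of each draw's curve).
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if post.n_draws == 0:
        raise ValueError("posterior contains no draws")
    p = post.p_draws(grid)  # (draws, len(grid))
    mean = p.mean(axis=0)
    lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
    return ProbabilityCurve(grid=grid, mean=mean, lo=lo, hi=hi)


def rate_at_probability(curve: ProbabilityCurve, p_target: float) -> float | NotReached:
    """Smallest rate at which the posterior-mean probability reaches ``p_target``.

    The crossing is located on the grid and refined by linear
    interpolation between the bracketing grid points.  If the target lies
    above the curve's maximum (or below its minimum) a :class:`NotReached`
    sentinel records the direction.
    """
    mean = curve.mean
    if p_target > float(np.max(mean)):
        return NotReached("above_max")
    if p_target < float(np.min(mean)):
        return NotReached("below_min")
    idx = int(np.argmax(mean >= p_target))
    if idx == 0:
        return float(curve.grid[0])
    x0, x1 = curve.grid[idx - 1], curve.grid[idx]
    p0, p1 = mean[idx - 1], mean[idx]
    if p1 == p0:
        return float(x1)
    return float(x0 + (p_target - p0) / (p1 - p0) * (x1 - x0))


# --------------------------------------------------------------------------
# serialization

SCHEMA_VERSION = 1


def save_posterior(post: ModelPosterior, path) -> None:
    """Write the posterior (config, knots, draws, diagnostics) as JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(post.config),
        "basis": {
            "degree": post.basis.degree,
            "K": post.basis.K,
            "knots": post.basis.knots.tolist(),
            "support": list(post.basis.support),
        },
        "shape": list(post.alpha.shape),
        "alpha": post.alpha.ravel().tolist(),
        "sigma": post.sigma.ravel().tolist(),
        "diagnostics": post.diagnostics,
        "boundary_degenerate": post.boundary_degenerate,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_posterior(path) -> ModelPosterior:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported posterior schema: {payload.get('schema_version')}")
    shape = tuple(payload["shape"])
    basis = SplineBasis(
        degree=payload["basis"]["degree"],
        K=payload["basis"]["K"],
        knots=np.asarray(payload["basis"]["knots"]),
        support=tuple(payload["basis"]["support"]),
    )
    return ModelPosterior(
        alpha=np.asarray(payload["alpha"]).reshape(shape),
        sigma=np.asarray(payload["sigma"]).reshape(shape[:2]),
        basis=basis,
        config=ModelConfig(**payload["config"]),
        diagnostics=payload["diagnostics"],
        boundary_degenerate=payload["boundary_degenerate"],
    )


def implied_linear_coefficients(post: ModelPosterior) -> dict[str, float]:
    """Posterior mean/SD of the intercept and slope in the linear limit.

    Only meaningful when the basis is degree-1 with K = 2 (two hat
    functions), where logit p is the straight line through
    (x_min, alpha_1) and (x_max, alpha_2).
    """
    if post.basis.degree != 1 or post.basis.K != 2:
        raise ValueError("linear-limit summary requires degree=1, K=2")
    a = post.alpha_flat()
    xmin, xmax = post.basis.support
    slope = (a[:, 1] - a[:, 0]) / (xmax - xmin)
    intercept = a[:, 0] - slope * xmin
    return {
        "intercept_mean": float(intercept.mean()),
        "intercept_sd": float(intercept.std(ddof=1)),
        "slope_mean": float(slope.mean()),
        "slope_sd": float(slope.std(ddof=1)),
    }
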
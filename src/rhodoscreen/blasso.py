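"""Bayesian LASSO regression of λmax on pocket features, by Gibbs sampling.

The model is the standard hierarchical (scale-mixture) representation of
linear regression with a conditional Laplace prior on the coefficients:

    λmax^(k) ~ N(μ + βᵀ x^(k), σ²)
    β_j | σ², τ_j² ~ N(0, σ² τ_j²)            (j = 1..p)
    τ_j² ~ Exp(γ² / 2)                         (marginally: Laplace prior on β_j
                                                with rate γ / √σ²)
    σ² ~ InvGamma(a, b),   γ² ~ Gamma(r, δ),   μ ~ flat

whose full conditionals are all standard: multivariate normal for β, normal
for μ, inverse-gamma for σ², inverse-Gaussian for 1/τ_j², gamma for γ².  The
posterior mode of β at fixed (σ, γ) coincides with the LASSO estimator at
penalty 2γσ, which :func:`posterior_mode_check` verifies against an
independent coordinate-descent LASSO fit.

Draw order per sweep is fixed (β, μ, σ², τ², γ²) and a single seeded
generator drives the chain, so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .encoding import EncodedSample, Standardizer

_TAU2_MIN = 1e-12
_INVGAUSS_MEAN_MAX = 1e12


@dataclass(frozen=True)
class BlassoConfig:
    """Sampler settings.

    ``n_samples`` retained draws are returned after ``burn_in`` discarded
    sweeps, keeping every ``thinning``-th draw.  ``hyper_r``/``hyper_delta``
    are the gamma shape/rate on the squared shrinkage γ²; ``sigma2_a``/
    ``sigma2_b`` the inverse-gamma shape/rate on the noise variance.
    Defaults are weakly informative.
    """

    n_samples: int = 10_000
    burn_in: int = 1_000
    thinning: int = 1
    hyper_r: float = 1.0
    hyper_delta: float = 0.1
    sigma2_a: float = 0.01
    sigma2_b: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.burn_in < 0 or self.thinning < 1:
            raise ValueError("invalid chain-length settings")
        if min(self.hyper_r, self.hyper_delta, self.sigma2_a, self.sigma2_b) <= 0:
            raise ValueError("hyper-parameters must be strictly positive")


@dataclass(frozen=True)
class PosteriorSamples:
    """T retained Gibbs draws of (μ, β, σ², γ²)."""

    mu: np.ndarray          # (T,)
    beta: np.ndarray        # (T, p)
    sigma2: np.ndarray      # (T,)
    gamma2: np.ndarray      # (T,)
    config: BlassoConfig
    standardizer: Standardizer | None = None

    def __post_init__(self) -> None:
        T = len(self.mu)
        if self.beta.shape[0] != T or len(self.sigma2) != T or len(self.gamma2) != T:
            raise ValueError("inconsistent draw dimensions")
        for arr in (self.mu, self.beta, self.sigma2, self.gamma2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite posterior draws")
        if np.any(self.sigma2 <= 0) or np.any(self.gamma2 <= 0):
            raise ValueError("variance draws must be strictly positive")

    @property
    def n_draws(self) -> int:
        return len(self.mu)

    @property
    def n_features(self) -> int:
        return self.beta.shape[1]

    @property
    def standardizer_hash(self) -> str | None:
        return None if self.standardizer is None else self.standardizer.hash


def _design(train: Sequence[EncodedSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.x for s in train])
    missing = [s.id for s in train if s.lambda_max is None]
    if missing:
        raise ValueError(f"training samples lack lambda_max: {missing[:5]}")
    y = np.array([s.lambda_max for s in train], dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training features or responses")
    return X, y


def lasso_objective(
    mu: float,
    beta: np.ndarray,
    samples: Sequence[EncodedSample],
    gamma: float,
) -> float:
    """Σ_k (λmax^(k) − μ − βᵀx^(k))² + γ Σ_j |β_j| — the penalised
    least-squares objective whose minimiser the BLASSO posterior mode matches."""
    X, y = _design(samples)
    beta = np.asarray(beta, dtype=float)
    resid = y - mu - X @ beta
    return float(resid @ resid + gamma * np.abs(beta).sum())


def fit_blasso(
    train: Sequence[EncodedSample],
    config: BlassoConfig | None = None,
    standardizer: Standardizer | None = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return the retained draws.

    Training features are expected already standardized (the chain itself is
    agnostic; a :class:`Standardizer` may be attached so downstream
    prediction can verify candidates were transformed identically).  The
    sampler stays well-posed when features outnumber samples: the Laplace
    prior keeps the β conditional covariance positive definite.
    """
    config = config or BlassoConfig()
    if len(train) < 2:
        raise ValueError("need at least 2 training samples")
    X, y = _design(train)
    K, p = X.shape

    rng = np.random.default_rng(config.seed)
    XtX = X.T @ X
    Xty = X.T @ y
    colsum = X.sum(axis=0)

    # init
    mu = float(y.mean())
    sigma2 = float(y.var()) if y.var() > 0 else 1.0
    tau2 = np.ones(p)
    gamma2 = config.hyper_r / config.hyper_delta
    beta = np.zeros(p)

    T = config.n_samples
    n_sweeps = config.burn_in + T * config.thinning
    mu_out = np.empty(T)
    beta_out = np.empty((T, p))
    sigma2_out = np.empty(T)
    gamma2_out = np.empty(T)

    kept = 0
    for sweep in range(n_sweeps):
        # β | rest ~ N(A⁻¹ Xᵀ(y−μ), σ² A⁻¹),  A = XᵀX + diag(1/τ²)
        A = XtX.copy()
        A[np.diag_indices_from(A)] += 1.0 / tau2
        L = _chol(A)
        rhs = Xty - mu * colsum
        mean = linalg.cho_solve((L, True), rhs, check_finite=False)
        z = rng.standard_normal(p)
        beta = mean + np.sqrt(sigma2) * linalg.solve_triangular(
            L, z, trans="T", lower=True, check_finite=False
        )

        # μ | rest ~ N(mean(y − Xβ), σ²/K)   (flat prior)
        resid0 = y - X @ beta
        mu = float(resid0.mean() + np.sqrt(sigma2 / K) * rng.standard_normal())

        # σ² | rest ~ InvGamma(a + (K+p)/2, b + RSS/2 + βᵀD⁻¹β/2)
        resid = resid0 - mu
        shape = config.sigma2_a + 0.5 * (K + p)
        rate = config.sigma2_b + 0.5 * float(resid @ resid) + 0.5 * float(
            (beta * beta / tau2).sum()
        )
        sigma2 = float(rate / rng.gamma(shape))

        # 1/τ_j² | rest ~ InvGaussian(√(γ²σ²/β_j²), γ²)
        absb = np.maximum(np.abs(beta), 1e-300)
        ig_mean = np.minimum(np.sqrt(gamma2 * sigma2) / absb, _INVGAUSS_MEAN_MAX)
        inv_tau2 = rng.wald(ig_mean, gamma2)
        tau2 = np.maximum(1.0 / inv_tau2, _TAU2_MIN)

        # γ² | rest ~ Gamma(r + p, δ + Στ²/2)
        g_shape = config.hyper_r + p
        g_rate = config.hyper_delta + 0.5 * float(tau2.sum())
        gamma2 = float(rng.gamma(g_shape) / g_rate)

        post = sweep - config.burn_in
        if post >= 0 and post % config.thinning == 0 and kept < T:
            mu_out[kept] = mu
            beta_out[kept] = beta
            sigma2_out[kept] = sigma2
            gamma2_out[kept] = gamma2
            kept += 1

    return PosteriorSamples(
        mu=mu_out,
        beta=beta_out,
        sigma2=sigma2_out,
        gamma2=gamma2_out,
        config=config,
        standardizer=standardizer,
    )


def _chol(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter."""
    jitter = 0.0
    base = float(np.mean(np.diag(A)))
    for attempt in range(4):
        try:
            return linalg.cholesky(
                A if jitter == 0 else A + jitter * np.eye(A.shape[0]),
                lower=True,
                check_finite=False,
            )
        except linalg.LinAlgError:
            jitter = base * 10.0 ** (attempt - 8)
    raise linalg.LinAlgError(
        "β full-conditional covariance not positive definite; standardize "
        "features or increase prior shrinkage"
    )


# ---------------------------------------------------------------------------
# posterior-mode / LASSO equivalence


@dataclass(frozen=True)
class ModeCheckReport:
    """Comparison of the best-conditional-density draw against LASSO."""

    mode_mu: float
    mode_beta: np.ndarray
    lasso_mu: float
    lasso_beta: np.ndarray
    max_abs_deviation: float
    penalty: float


def conditional_log_density(
    mu: float,
    beta: np.ndarray,
    samples: Sequence[EncodedSample],
    gamma: float,
    sigma: float,
) -> float:
    """Log conditional density of (μ, β) given the data, σ and γ, up to an
    additive constant: −[RSS + 2γσ·Σ|β|] / (2σ²)."""
    X, y = _design(samples)
    resid = y - mu - X @ beta
    return float(-(resid @ resid + 2.0 * gamma * sigma * np.abs(beta).sum())
                 / (2.0 * sigma**2))


def posterior_mode_check(
    posterior: PosteriorSamples,
    train: Sequence[EncodedSample],
    gamma_hat: float | None = None,
    sigma_hat: float | None = None,
) -> ModeCheckReport:
    """Verify the LASSO/posterior-mode equivalence on a fitted chain.

    Scans the retained draws for the one maximising the conditional posterior
    density of (μ, β) at plugged-in point estimates (posterior means of √γ²
    and √σ² by default), solves the matching LASSO problem independently via
    coordinate descent, and reports the coordinate-wise maximum absolute
    deviation.  The penalty match: the conditional mode minimises
    RSS + 2γσ·Σ|β|, i.e. scikit-learn's Lasso with α = γσ/K.
    """
    from sklearn.linear_model import Lasso

    X, y = _design(train)
    K = len(y)
    if gamma_hat is None:
        gamma_hat = float(np.mean(np.sqrt(posterior.gamma2)))
    if sigma_hat is None:
        sigma_hat = float(np.mean(np.sqrt(posterior.sigma2)))

    penalty = 2.0 * gamma_hat * sigma_hat  # on the Σ|β| term of RSS + c·Σ|β|

    # score each draw by the conditional log-density (vectorised)
    pred = posterior.beta @ X.T  # (T, K)
    r = y[None, :] - posterior.mu[:, None] - pred
    score = -(np.einsum("tk,tk->t", r, r)
              + penalty * np.abs(posterior.beta).sum(axis=1))
    best = int(np.argmax(score))

    lasso = Lasso(alpha=penalty / (2.0 * K), fit_intercept=True, max_iter=100_000,
                  tol=1e-10)
    lasso.fit(X, y)

    dev = float(
        max(
            np.max(np.abs(posterior.beta[best] - lasso.coef_)),
            abs(posterior.mu[best] - lasso.intercept_),
        )
    )
    return ModeCheckReport(
        mode_mu=float(posterior.mu[best]),
        mode_beta=posterior.beta[best].copy(),
        lasso_mu=float(lasso.intercept_),
        lasso_beta=lasso.coef_.copy(),
        max_abs_deviation=dev,
        penalty=penalty,
    )


# ---------------------------------------------------------------------------
# persistence


def save_posterior(posterior: PosteriorSamples, outdir: str | Path) -> None:
    """Write draws as a TSV (t, mu, sigma2, gamma2, beta_0001..) plus a JSON
    sidecar echoing config and standardizer."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = posterior.n_features
    cols = {"t": np.arange(posterior.n_draws), "mu": posterior.mu,
            "sigma2": posterior.sigma2, "gamma2": posterior.gamma2}
    df = pd.DataFrame(cols)
    beta_df = pd.DataFrame(
        posterior.beta, columns=[f"beta_{j + 1:04d}" for j in range(p)]
    )
    pd.concat([df, beta_df], axis=1).to_csv(
        outdir / "posterior.tsv", sep="\t", index=False
    )
    side = {"config": asdict(posterior.config)}
    if posterior.standardizer is not None:
        side["standardizer"] = {
            "center": posterior.standardizer.center.tolist(),
            "scale": posterior.standardizer.scale.tolist(),
        }
    (outdir / "posterior_meta.json").write_text(json.dumps(side))


def load_posterior(outdir: str | Path) -> PosteriorSamples:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "posterior.tsv", sep="\t")
    meta = json.loads((outdir / "posterior_meta.json").read_text())
    beta_cols = [c for c in df.columns if c.startswith("beta_")]
    std = None
    if "standardizer" in meta:
        std = Standardizer(
            center=np.asarray(meta["standardizer"]["center"], dtype=float),
            scale=np.asarray(meta["standardizer"]["scale"], dtype=float),
        )
    return PosteriorSamples(
        mu=df["mu"].to_numpy(),
        beta=df[beta_cols].to_numpy(),
        sigma2=df["sigma2"].to_numpy(),
        gamma2=df["gamma2"].to_numpy(),
        config=BlassoConfig(**meta["config"]),
        standardizer=std,
    )
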
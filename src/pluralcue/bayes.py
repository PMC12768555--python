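"""Bayesian Beta regression of normalized gender conditioning, and the
Bayes-factor machinery built on it.

The response for participant i is the normalized mutual information
y_i = MI(C;G)/H(C) of their plural productions, modeled as

    y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)
    mu_i = logit^-1(beta0 + beta1 * H_i)

i.e. a mean-precision parameterized Beta likelihood with a logit link and the
participant's overall class entropy H_i as the single covariate.  Under a
gender-ignoring regime the plug-in MI is pure small-sample noise, which grows
with the variation available to "explain", so beta1 > 0; under genuine gender
conditioning the structured signal is diluted as variation grows, so
beta1 < 0.  One model is fitted per generative regime on a large simulated
calibration cohort; a real (or synthetic) participant is then scored by the
log posterior-predictive density of their (H, y) under each fitted model, and
differences of those log densities are the per-participant log Bayes factors.

Priors are weakly informative and calibrated so the prior predictive stays
off the 0/1 boundaries: beta0 ~ Normal(-0.5, 0.5), beta1 ~ Normal(0, 0.1),
phi ~ Gamma(shape 5, rate 1).

Sampling uses the affine-invariant ensemble sampler (emcee) on
(beta0, beta1, log phi); walkers are treated as chains for split-Rhat and
effective-sample-size diagnostics via ArviZ.  The Beta density is undefined
at y in {0, 1}, which simulated gender-ignoring participants can produce
exactly; responses are squeezed toward the interior before fitting with the
standard y' = (y (n-1) + 1/2)/n transform, and clamped to
[eps, 1-eps] (eps = 1e-4) when scoring single participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logsumexp

from .simulate import ParticipantSummary

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "BetaRegressionPosterior",
    "ClassificationResult",
    "squeeze_ratio",
    "fit_beta_regression",
    "posterior_summary",
    "log_pointwise_likelihood",
    "classify_participant",
    "aggregate_bayes_factor",
]

PARAM_NAMES = ("beta0", "beta1", "phi")
BOUNDARY_EPS = 1e-4
RHAT_LIMIT = 1.01
ESS_LIMIT = 400.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors for intercept, entropy slope, and precision."""

    beta0_mean: float = -0.5
    beta0_sd: float = 0.5
    beta1_mean: float = 0.0
    beta1_sd: float = 0.1
    phi_shape: float = 5.0
    phi_rate: float = 1.0

    def __post_init__(self):
        if min(self.beta0_sd, self.beta1_sd, self.phi_shape, self.phi_rate) <= 0:
            raise ValueError("prior scales and shape/rate must be positive")

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Log prior density at theta = (beta0, beta1, log phi), with the
        Jacobian of the log-phi transform included."""
        b0, b1, t = theta[..., 0], theta[..., 1], theta[..., 2]
        phi = np.exp(t)
        lp = -0.5 * ((b0 - self.beta0_mean) / self.beta0_sd) ** 2
        lp += -0.5 * ((b1 - self.beta1_mean) / self.beta1_sd) ** 2
        # Gamma(shape, rate) on phi plus log-Jacobian d phi / d t = phi
        lp += self.phi_shape * t - self.phi_rate * phi
        return lp


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings.

    Defaults give 32 walkers x 2,000 retained steps after 1,000 warmup
    steps, using differential-evolution proposals, which mix an order of
    magnitude faster than the default stretch move on this posterior's
    correlated (intercept, slope) ridge.
    """

    n_walkers: int = 32
    n_steps: int = 2000
    n_warmup: int = 1000
    seed: int = 0
    thin: int = 4  # thinning applied to stored draws for scoring speed


@dataclass
class BetaRegressionPosterior:
    """Posterior draws and summaries for one fitted hypothesis model."""

    hypothesis: str
    draws: dict                    # name -> (n_chains, n_draws) array
    summary: pd.DataFrame          # Estimate / Est.Error / l-95% / u-95%
    diagnostics: pd.DataFrame      # rhat / ess per parameter
    converged: bool
    priors: PriorSpec = field(default_factory=PriorSpec)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def posterior_means(self) -> dict:
        return {k: float(v.mean()) for k, v in self.draws.items()}


@dataclass(frozen=True)
class ClassificationResult:
    """Per-participant log predictive densities and the winning hypothesis."""

    participant_id: int
    log_lik: dict               # hypothesis -> log predictive density
    log_bf10: float             # log_lik[h1] - log_lik[h0]
    best_fit: str


def squeeze_ratio(y, n: int):
    """Smithson-Verkuilen boundary squeeze y' = (y (n-1) + 1/2) / n."""
    y = np.asarray(y, dtype=float)
    return (y * (n - 1) + 0.5) / n


def _grouped_data(h: np.ndarray, y: np.ndarray):
    """Collapse identical (H, y) rows, keeping multiplicities as weights.

    Simulated cohorts contain many duplicated summaries (count tables
    coincide), so the likelihood is evaluated on unique rows only.
    """
    pairs = np.column_stack([h, y])
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return uniq[:, 0], uniq[:, 1], counts.astype(float)


def _beta_loglik(theta, h, y, w):
    """Summed Beta log likelihood for parameter rows theta (K, 3)."""
    b0, b1, t = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
    phi = np.exp(t)
    mu = expit(b0 + b1 * h[None, :])
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (a - 1.0) * np.log(y)[None, :] + (b - 1.0) * np.log1p(-y)[None, :]
    ll -= betaln(a, b)
    return ll @ w


def fit_beta_regression(
    cohort: list[ParticipantSummary] | pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    hypothesis: str = "model",
) -> BetaRegressionPosterior:
    """Fit the Beta regression to a cohort of participant summaries by MCMC.

    The cohort may be a list of :class:`ParticipantSummary` or a DataFrame
    with ``h_bits`` and ``ratio`` columns.  Responses on the 0/1 boundary are
    squeezed (see module docstring).  An unconverged fit is returned flagged,
    with a warning, never silently.
    """
    import emcee

    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()

    if isinstance(cohort, pd.DataFrame):
        h = cohort["h_bits"].to_numpy(dtype=float)
        y = cohort["ratio"].to_numpy(dtype=float)
    else:
        h = np.array([s.h_bits for s in cohort], dtype=float)
        y = np.array([s.ratio for s in cohort], dtype=float)
    if h.size == 0:
        raise ValueError("empty cohort")
    if np.any(~np.isfinite(h)) or np.any((y < 0) | (y > 1)):
        raise ValueError("cohort has non-finite H or ratio outside [0, 1]")

    y = squeeze_ratio(y, n=y.size)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("all-boundary cohort cannot be squeezed into (0, 1)")
    hu, yu, wu = _grouped_data(h, y)

    # Sample with the covariate centered: the (intercept, slope) posterior is
    # nearly uncorrelated in that basis, which the ensemble sampler mixes
    # through far faster.  theta = (c0, beta1, log phi), beta0 = c0 - beta1*hbar.
    hbar = float(np.average(hu, weights=wu))
    hc = hu - hbar

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        uncentered = theta.copy()
        uncentered[:, 0] = theta[:, 0] - theta[:, 1] * hbar
        lp = priors.log_prior(uncentered)
        ok = np.abs(theta[:, 2]) < 20  # keep phi = exp(t) in floating range
        out = np.full(theta.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + _beta_loglik(theta[ok], hc, yu, wu)
        return out

    rng = np.random.default_rng(mcmc.seed)
    ybar = float(np.average(yu, weights=wu))
    c0_loc = float(np.log(ybar / (1.0 - ybar)))
    init = np.column_stack(
        [
            rng.normal(c0_loc, 0.2, mcmc.n_walkers),
            rng.normal(priors.beta1_mean, 0.05, mcmc.n_walkers),
            rng.normal(np.log(10.0), 0.3, mcmc.n_walkers),
        ]
    )
    sampler = emcee.EnsembleSampler(
        mcmc.n_walkers,
        3,
        log_prob,
        vectorize=True,
        moves=[
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ],
    )
    state = sampler.run_mcmc(init, mcmc.n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.n_steps, progress=False)

    chain = sampler.get_chain()  # (n_steps, n_walkers, 3)
    draws = {
        "beta0": (chain[:, :, 0] - chain[:, :, 1] * hbar).T,
        "beta1": chain[:, :, 1].T,
        "phi": np.exp(chain[:, :, 2]).T,
    }

    diagnostics = _diagnostics(draws)
    converged = bool(
        (diagnostics["rhat"] <= RHAT_LIMIT).all()
        and (diagnostics["ess"] >= ESS_LIMIT).all()
    )
    if not converged:
        warnings.warn(
            f"fit for {hypothesis!r} failed convergence gates "
            f"(max rhat {diagnostics['rhat'].max():.3f}, "
            f"min ess {diagnostics['ess'].min():.0f})",
            stacklevel=2,
        )

    if mcmc.thin > 1:
        draws = {k: v[:, :: mcmc.thin] for k, v in draws.items()}

    return BetaRegressionPosterior(
        hypothesis=hypothesis,
        draws=draws,
        summary=_summary_frame(draws),
        diagnostics=diagnostics,
        converged=converged,
        priors=priors,
    )


def _diagnostics(draws: dict) -> pd.DataFrame:
    import arviz as az

    rows = {}
    for name, arr in draws.items():
        ds = az.convert_to_dataset(arr)
        rows[name] = {
            "rhat": float(az.rhat(ds)["x"].values),
            "ess": float(az.ess(ds)["x"].values),
        }
    return pd.DataFrame(rows).T


def _summary_frame(draws: dict) -> pd.DataFrame:
    rows = {}
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows[name] = {
            "Estimate": flat.mean(),
            "Est.Error": flat.std(ddof=1),
            "l-95% CI": lo,
            "u-95% CI": hi,
        }
    return pd.DataFrame(rows).T


def posterior_summary(post: BetaRegressionPosterior, decimals: int | None = 2) -> pd.DataFrame:
    """Estimate / Est.Error / 95% interval per parameter, 2-decimal by default."""
    out = post.summary.copy()
    if decimals is not None:
        out = out.round(decimals)
    return out


def log_pointwise_likelihood(
    post: BetaRegressionPosterior,
    s: ParticipantSummary,
    mode: str = "posterior_predictive",
) -> float:
    """Log predictive density of one participant's (H, y) under a fit.

    ``posterior_predictive`` (default) averages the Beta likelihood over the
    posterior draws; ``plugin`` evaluates it at the posterior means.  The
    ratio is clamped to [eps, 1-eps] so the density stays finite at the
    boundaries.
    """
    y = float(np.clip(s.ratio, BOUNDARY_EPS, 1.0 - BOUNDARY_EPS))
    h = float(s.h_bits)
    if mode == "plugin":
        m = post.posterior_means()
        b0 = np.array([m["beta0"]])
        b1 = np.array([m["beta1"]])
        phi = np.array([m["phi"]])
    elif mode == "posterior_predictive":
        b0 = post.flat("beta0")
        b1 = post.flat("beta1")
        phi = post.flat("phi")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mu = expit(b0 + b1 * h)
    a, b = mu * phi, (1.0 - mu) * phi
    logpdf = (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)
    return float(logsumexp(logpdf) - np.log(logpdf.size))


def classify_participant(
    s: ParticipantSummary,
    posteriors: dict[str, BetaRegressionPosterior],
    mode: str = "posterior_predictive",
) -> ClassificationResult:
    """Score one participant under each fitted hypothesis model.

    ``best_fit`` is the hypothesis with the highest log predictive density;
    exact ties break toward ``h0`` (parsimony) and otherwise toward the
    earlier key.  ``log_bf10`` is reported when both ``h0`` and ``h1`` models
    are present, else NaN.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least two hypothesis models to classify")
    log_lik = {
        name: log_pointwise_likelihood(post, s, mode=mode)
        for name, post in posteriors.items()
    }
    order = sorted(log_lik, key=lambda k: (k != "h0", list(log_lik).index(k)))
    best = max(order, key=lambda k: log_lik[k])
    if "h0" in log_lik and "h1" in log_lik:
        log_bf10 = log_lik["h1"] - log_lik["h0"]
    else:
        log_bf10 = float("nan")
    return ClassificationResult(s.participant_id, log_lik, log_bf10, best)


def aggregate_bayes_factor(results: list[ClassificationResult]) -> dict:
    """Cohort-level evidence: summed per-participant log BF10 and its exp.

    A strongly negative sum underflows exp() to 0.0, matching the convention
    of reporting such Bayes factors as 0; the log value remains exact.
    """
    if not results:
        raise ValueError("no classification results")
    total = float(np.sum([r.log_bf10 for r in results]))
    with np.errstate(over="ignore"):
        bf = float(np.exp(total))
    return {"log_bf10": total, "bf10": bf, "n": len(results)}


def classification_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    """Flatten classification results to the on-disk CSV layout."""
    hyps = sorted({h for r in results for h in r.log_lik})
    data = {"participant_id": [r.participant_id for r in results]}
    for h in hyps:
        data[f"loglik_{h}"] = [r.log_lik.get(h, np.nan) for r in results]
    data["log_bf10"] = [r.log_bf10 for r in results]
    data["best_fit"] = [r.best_fit for r in results]
    return pd.DataFrame(data)
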
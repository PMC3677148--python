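"""Heteroscedastic bivariate-normal repeated-measures model, fit by Gibbs.

Per-subject (addition, subtraction) bias score pairs y_ik from group k
(1 = adults, 2 = children) follow

    y_ik ~ N(mu_k, Sigma_k),

with an unrestricted 2x2 covariance per group, so variances may differ
between operations and groups and the two operations may correlate.
Priors: mu_jk ~ N(0, tau2) independently per component (tau2 = 100000, an
effectively flat prior on standardized data) and Sigma_k ~
inverse-Wishart(I, 2).  The inverse-Wishart convention used throughout is
density proportional to |Sigma|^-((df+p+1)/2) * exp(-tr(scale @ inv(Sigma))/2)
with p = 2, so df = 2 is the smallest proper choice; the full conditional
is then inverse-Wishart(scale + scatter, df + n_k).

The sampler alternates the two conjugate full conditionals per group:

    mu_k    | Sigma_k, y ~ N(m, P^-1),  P = n_k inv(Sigma_k) + I/tau2,
                           m = P^-1 (n_k inv(Sigma_k) ybar_k)
    Sigma_k | mu_k,  y ~ IW(scale + sum_i (y_ik-mu_k)(y_ik-mu_k)', df + n_k)

Groups are conditionally independent, so each runs as its own chain.  The
2x2 linear algebra is written out in closed form and all randomness is
pre-drawn, which keeps a 600,000-iteration run in the tens of seconds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("adult", "child")
MEASUREMENTS = ("addition", "subtraction")

#: Summary rows, in the layout of the published-style posterior table:
#: four group means, six (co)variance entries, three derived effects.
SUMMARY_ROWS = (
    "mu_adult_addition", "mu_adult_subtraction",
    "mu_child_addition", "mu_child_subtraction",
    "var_adult_addition", "cov_adult", "var_adult_subtraction",
    "var_child_addition", "cov_child", "var_child_subtraction",
    "effect_adult", "effect_child", "interaction",
)


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters; defaults are the model's reference choice."""

    mean_prior_variance: float = 100000.0
    wishart_scale: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    wishart_df: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_prior_variance <= 0:
            raise ValueError("mean prior variance must be positive")
        if self.wishart_df <= 1:
            raise ValueError("wishart_df must exceed p - 1 = 1 for a proper prior")
        s = np.asarray(self.wishart_scale, dtype=float)
        if s.shape != (2, 2) or np.linalg.det(s) <= 0 or s[0, 0] <= 0:
            raise ValueError("wishart scale must be a 2x2 positive-definite matrix")


@dataclass(frozen=True)
class ModelData:
    """Standardized score pairs per group plus the transform record."""

    scores: dict[str, np.ndarray]  # group -> (n_k, 2) array
    grand_mean: float
    grand_sd: float

    def unstandardize(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) * self.grand_sd + self.grand_mean


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws; mu[t, k, j], sigma[t, k] = (s11, s12, s22)."""

    mu: np.ndarray
    sigma: np.ndarray
    groups: tuple[str, ...]
    n_iter: int
    burn_in: int
    seed: int
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def series(self) -> dict[str, np.ndarray]:
        """All scalar draw series keyed by summary-row name."""
        out: dict[str, np.ndarray] = {}
        for k, g in enumerate(self.groups):
            for j, m in enumerate(MEASUREMENTS):
                out[f"mu_{g}_{m}"] = self.mu[:, k, j]
            out[f"var_{g}_addition"] = self.sigma[:, k, 0]
            out[f"cov_{g}"] = self.sigma[:, k, 1]
            out[f"var_{g}_subtraction"] = self.sigma[:, k, 2]
        out.update(self.effects)
        return out

    def to_frame(self, thin: int = 1) -> pd.DataFrame:
        series = self.series()
        idx = np.arange(self.n_draws)[::thin]
        frame = pd.DataFrame({name: s[idx] for name, s in series.items()})
        frame.insert(0, "iteration", idx + self.burn_in)
        return frame


def standardize_scores(
    adult_scores: np.ndarray, child_scores: np.ndarray
) -> ModelData:
    """Pool all 2*(n1+n2) scores, subtract the grand mean, divide by the
    grand SD (sample SD, ddof=1), and record the transform."""
    adult = np.asarray(adult_scores, dtype=float)
    child = np.asarray(child_scores, dtype=float)
    for arr, name in ((adult, "adult"), (child, "child")):
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError(f"{name} scores must be an (n >= 2) x 2 array")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} scores contain non-finite values")
    pooled = np.concatenate([adult.ravel(), child.ravel()])
    grand_mean = float(pooled.mean())
    grand_sd = float(pooled.std(ddof=1))
    if grand_sd == 0:
        raise ValueError("grand SD is zero; scores cannot be standardized")
    return ModelData(
        scores={
            "adult": (adult - grand_mean) / grand_sd,
            "child": (child - grand_mean) / grand_sd,
        },
        grand_mean=grand_mean,
        grand_sd=grand_sd,
    )


def model_data_from_bias(bias: pd.DataFrame) -> ModelData:
    """Standardized model input from an om_bias table (subject rows)."""
    groups = {}
    for g in GROUPS:
        rows = bias[bias["group"] == g]
        groups[g] = rows[["bias_addition", "bias_subtraction"]].to_numpy(float)
    return standardize_scores(groups["adult"], groups["child"])


def _chol2(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Lower Cholesky of [[a, b], [b, c]] as (l11, l21, l22)."""
    l11 = math.sqrt(a)
    l21 = b / l11
    l22 = math.sqrt(c - l21 * l21)
    return l11, l21, l22


def _sample_group(
    y: np.ndarray,
    priors: Priors,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    *,
    fixed_sigma: np.ndarray | None = None,
    jitter: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs chain for one group; returns (mu_draws, sigma_draws)."""
    n = y.shape[0] if y.size else 0
    if n:
        yb1, yb2 = float(y[:, 0].mean()), float(y[:, 1].mean())
        syy11 = float(y[:, 0] @ y[:, 0])
        syy12 = float(y[:, 0] @ y[:, 1])
        syy22 = float(y[:, 1] @ y[:, 1])
    else:
        yb1 = yb2 = syy11 = syy12 = syy22 = 0.0
    q = 1.0 / priors.mean_prior_variance
    s0 = np.asarray(priors.wishart_scale, dtype=float)
    nu = priors.wishart_df + n

    kept = n_iter - burn_in
    mu_out = np.empty((kept, 2))
    sig_out = np.empty((kept, 3))

    # Pre-drawn randomness: 2 normals for mu, and for the Bartlett
    # decomposition of the Wishart draw one normal plus chi-square draws
    # with the fixed degrees of freedom nu and nu - 1.
    z = rng.standard_normal((n_iter, 3))
    c1 = rng.chisquare(nu, n_iter)
    c2 = rng.chisquare(nu - 1.0, n_iter)

    if fixed_sigma is not None:
        fs = np.asarray(fixed_sigma, dtype=float)
        s11, s12, s22 = float(fs[0, 0]), float(fs[0, 1]), float(fs[1, 1])
    else:
        s11, s12, s22 = 1.0, 0.0, 1.0  # initial covariance: identity
    n_jittered = 0

    for t in range(n_iter):
        # --- mu | Sigma: bivariate normal full conditional ---
        det = s11 * s22 - s12 * s12
        i11, i12, i22 = s22 / det, -s12 / det, s11 / det
        p11, p12, p22 = n * i11 + q, n * i12, n * i22 + q
        pdet = p11 * p22 - p12 * p12
        c11, c12, c22 = p22 / pdet, -p12 / pdet, p11 / pdet  # P^-1
        b1 = n * (i11 * yb1 + i12 * yb2)
        b2 = n * (i12 * yb1 + i22 * yb2)
        m1 = c11 * b1 + c12 * b2
        m2 = c12 * b1 + c22 * b2
        l11, l21, l22 = _chol2(c11, c12, c22)
        mu1 = m1 + l11 * z[t, 0]
        mu2 = m2 + l21 * z[t, 0] + l22 * z[t, 1]

        if fixed_sigma is None:
            # --- Sigma | mu: inverse-Wishart full conditional ---
            sc11 = syy11 - 2.0 * n * yb1 * mu1 + n * mu1 * mu1
            sc12 = syy12 - n * (yb1 * mu2 + yb2 * mu1) + n * mu1 * mu2
            sc22 = syy22 - 2.0 * n * yb2 * mu2 + n * mu2 * mu2
            psi11 = s0[0, 0] + sc11
            psi12 = s0[0, 1] + sc12
            psi22 = s0[1, 1] + sc22
            pdet2 = psi11 * psi22 - psi12 * psi12
            if pdet2 <= 0 or psi11 <= 0:
                # numerical degeneracy: nudge the diagonal and recompute
                n_jittered += 1
                psi11 += jitter
                psi22 += jitter
                pdet2 = psi11 * psi22 - psi12 * psi12
            v11, v12, v22 = psi22 / pdet2, -psi12 / pdet2, psi11 / pdet2  # Psi^-1
            l11, l21, l22 = _chol2(v11, v12, v22)
            a11 = math.sqrt(c1[t])
            a22 = math.sqrt(c2[t])
            a21 = z[t, 2]
            # B = chol(Psi^-1) @ A; W = B B' ~ Wishart(nu, Psi^-1)
            b11 = l11 * a11
            b21 = l21 * a11 + l22 * a21
            b22 = l22 * a22
            w11 = b11 * b11
            w12 = b11 * b21
            w22 = b21 * b21 + b22 * b22
            wdet = w11 * w22 - w12 * w12
            s11, s12, s22 = w22 / wdet, -w12 / wdet, w11 / wdet  # Sigma = W^-1

        if t >= burn_in:
            mu_out[t - burn_in, 0] = mu1
            mu_out[t - burn_in, 1] = mu2
            sig_out[t - burn_in, 0] = s11
            sig_out[t - burn_in, 1] = s12
            sig_out[t - burn_in, 2] = s22
    if n_jittered:
        warnings.warn(
            f"scale matrix jittered in {n_jittered} iterations to restore "
            "positive-definiteness",
            RuntimeWarning,
        )
    return mu_out, sig_out


def gibbs_sample(
    data: ModelData,
    priors: Priors = Priors(),
    n_iter: int = 600_000,
    burn_in: int = 100_000,
    seed: int | None = None,
    *,
    fixed_sigma: dict[str, np.ndarray] | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler for every group and collect retained draws.

    ``fixed_sigma`` freezes the covariance step at a given matrix per
    group, reducing the sampler to its normal full conditional — used to
    validate the mu step against the closed-form conjugate posterior.
    """
    if seed is None:
        raise ValueError("a seed is required for a reproducible chain")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    groups = tuple(data.scores.keys())
    kept = n_iter - burn_in
    mu = np.empty((kept, len(groups), 2))
    sigma = np.empty((kept, len(groups), 3))
    root = np.random.SeedSequence(seed)
    for k, g in enumerate(groups):
        rng = np.random.default_rng(root.spawn(1)[0])
        fs = None if fixed_sigma is None else fixed_sigma.get(g)
        mu[:, k, :], sigma[:, k, :] = _sample_group(
            data.scores[g], priors, n_iter, burn_in, rng, fixed_sigma=fs
        )
    draws = PosteriorDraws(
        mu=mu, sigma=sigma, groups=groups,
        n_iter=n_iter, burn_in=burn_in, seed=seed,
    )
    return derived_effects(draws)


def derived_effects(draws: PosteriorDraws) -> PosteriorDraws:
    """Append the operation effects and their interaction, iteration-wise.

    effect_adult = mu_adult_addition - mu_adult_subtraction; likewise for
    children; interaction = effect_adult - effect_child.  Runs lacking
    either group (e.g. single-group validation fits) are returned as-is.
    """
    if not {"adult", "child"} <= set(draws.groups):
        return draws
    ka = draws.groups.index("adult")
    kc = draws.groups.index("child")
    adult = draws.mu[:, ka, 0] - draws.mu[:, ka, 1]
    child = draws.mu[:, kc, 0] - draws.mu[:, kc, 1]
    draws.effects = {
        "effect_adult": adult,
        "effect_child": child,
        "interaction": adult - child,
    }
    return draws


def hdi(draw_series: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Sliding a window of ceil(mass * N) over the sorted draws and taking
    the minimum-width placement; exact for unimodal posteriors.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie strictly between 0 and 1")
    s = np.sort(np.asarray(draw_series, dtype=float))
    n = len(s)
    if n < 100:
        raise ValueError("need at least 100 draws for a stable HDI")
    k = int(math.ceil(mass * n))
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def sign_probability(draw_series: np.ndarray) -> float:
    """Posterior probability that the quantity is positive: the fraction
    of draws strictly greater than zero."""
    s = np.asarray(draw_series, dtype=float)
    if s.size == 0:
        raise ValueError("empty draw series")
    return float(np.mean(s > 0))


def convergence_diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-chain potential scale reduction and effective sample size.

    Each retained series is split in half to form two pseudo-chains for
    rank-normalized R-hat; warns when R-hat > 1.01 or ESS < 400.
    """
    import arviz as az

    rows = []
    for name, s in draws.series().items():
        half = len(s) // 2
        chains = np.stack([s[:half], s[half: 2 * half]])
        rhat = float(az.rhat(chains))
        ess = float(az.ess(chains))
        rows.append({"quantity": name, "rhat": rhat, "ess": ess})
    diag = pd.DataFrame(rows)
    bad = diag[(diag["rhat"] > 1.01) | (diag["ess"] < 400)]
    if len(bad):
        warnings.warn(
            "convergence diagnostics flag: "
            + ", ".join(f"{r.quantity} (rhat={r.rhat:.3f}, ess={r.ess:.0f})"
                        for r in bad.itertuples()),
            RuntimeWarning,
        )
    return diag


def summarize_posterior(draws: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, HDI, and sign probability for every model parameter
    and derived effect, one row each in the standard table layout."""
    series = draws.series()
    rows = []
    for name in SUMMARY_ROWS:
        s = series[name]
        lo, hi = hdi(s, mass)
        rows.append({
            "quantity": name,
            "mean": float(np.mean(s)),
            "hdi_low": lo,
            "hdi_high": hi,
            "hdi_mass": mass,
            "p_positive": sign_probability(s),
        })
    return pd.DataFrame(rows)


def summary_to_json(summary: pd.DataFrame) -> str:
    return json.dumps(
        {r["quantity"]: {k: r[k] for k in ("mean", "hdi_low", "hdi_high",
                                           "hdi_mass", "p_positive")}
         for _, r in summary.iterrows()},
        indent=2,
    )


def conjugate_mu_posterior(
    y: np.ndarray, sigma: np.ndarray, prior_variance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form normal posterior of mu for a known covariance.

    Independent oracle for the frozen-covariance sampler: with y_i ~
    N(mu, Sigma) and mu_j ~ N(0, tau2), the posterior is
    N(P^-1 n inv(Sigma) ybar, P^-1) with P = n inv(Sigma) + I/tau2.
    Returns (posterior mean, posterior covariance).
    """
    y = np.asarray(y, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = y.shape[0]
    isig = np.linalg.inv(sigma)
    prec = n * isig + np.eye(2) / prior_variance
    cov = np.linalg.inv(prec)
    mean = cov @ (n * isig @ y.mean(axis=0))
    return mean, cov
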
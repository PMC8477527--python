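"""Model fitting, convergence diagnostics, and posterior summarization.

``fit`` runs the NUTS kernel on the unconstrained hurdle-gamma posterior
(one chain per seed fanned out from the master seed) and returns draws of
the reported parameters on their natural scales: fixed effects on the
logit / log-kcal link scales, random-effect SDs, correlations, and the gamma
shape.  Convergence is assessed by the split-chain potential scale reduction
factor (Rhat), which should be close to 1 for every parameter, backed by
trace and density exports for visual inspection.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .data import EmaDataset
from .model import HurdleGammaPosterior, ModelSpec
from .sampling import SamplerConfig, nuts_sample

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit",
    "compute_rhat",
    "compute_ess",
    "summarize_posterior",
    "diagnostics_export",
]

CONVERGENCE_ADVICE = (
    "chains did not mix (split-Rhat above threshold); re-run with more "
    "iterations (e.g. double n_iter) and inspect trace/density plots"
)


@dataclass
class PosteriorDraws:
    """Posterior sample array indexed (chain, post-warmup iteration, parameter)."""

    values: np.ndarray
    parameter_names: list[str]
    config: SamplerConfig
    n_divergent: int = 0
    mean_accept: float = float("nan")

    def __post_init__(self) -> None:
        c, n, p = self.values.shape
        if c != self.config.n_chains or p != len(self.parameter_names):
            raise ValueError("draw array inconsistent with config/names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite posterior draws")

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, iterations)."""
        return self.values[:, :, self.parameter_names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        c, n, p = self.values.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), n * p),
            "iteration": np.tile(np.repeat(np.arange(n), p), c),
            "parameter": np.tile(self.parameter_names, c * n),
            "value": self.values.ravel(),
        })

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, SD, equal-tailed 95% CI and Rhat."""

    table: pd.DataFrame = field(repr=False)

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.table["rhat"].to_numpy()))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="parameter")


def fit(
    data: EmaDataset,
    spec: ModelSpec,
    config: SamplerConfig | None = None,
    keep_random_effects: bool = False,
) -> PosteriorDraws:
    """Fit the multilevel hurdle-gamma model by NUTS.

    Runs ``config.n_chains`` independent chains with per-chain seeds derived
    deterministically from the master seed, discards warmup, and maps the
    retained unconstrained draws to the reported parameter scales.  Emits a
    convergence report (max split-Rhat, divergences, acceptance) to the log.
    Identical seeds and data yield identical draws.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    config = config or SamplerConfig()
    post = HurdleGammaPosterior(data, spec)
    rngs = config.chain_seeds()

    t0 = time.time()
    chains = []
    n_div = 0
    accepts = []
    for c, rng in enumerate(rngs):
        theta0 = post.initial_point(rng)
        try:
            res = nuts_sample(
                post.logp_grad, theta0, config.n_warmup, config.n_keep, rng,
                target_accept=config.target_accept,
                max_treedepth=config.max_treedepth,
            )
        except (ValueError, FloatingPointError) as err:
            raise RuntimeError(
                f"chain {c} failed ({err}); {CONVERGENCE_ADVICE}"
            ) from err
        chains.append(res.samples)
        n_div += int(res.divergent.sum())
        accepts.append(res.accept_prob.mean())
        logger.info("chain %d done: step_size=%.3g, mean accept=%.2f, "
                    "divergent=%d", c, res.step_size, accepts[-1],
                    int(res.divergent.sum()))

    raw = np.stack(chains)  # (chains, n_keep, n_free)
    if not np.all(np.isfinite(raw)):
        raise RuntimeError(f"non-finite draws; {CONVERGENCE_ADVICE}")
    values = post.constrain(raw)
    names = list(post.parameter_names)
    if keep_random_effects:
        re_names = post.spec.random_effect_names()
        u = np.stack([
            np.stack([post.random_effects(draw) for draw in chain])
            for chain in raw
        ])  # (chains, n_keep, J, q)
        flat_u = u.reshape(u.shape[0], u.shape[1], -1)
        values = np.concatenate([values, flat_u], axis=-1)
        names += [f"r_{lab}[{re}]" for lab in post.labels for re in re_names]

    draws = PosteriorDraws(values=values, parameter_names=names, config=config,
                           n_divergent=n_div, mean_accept=float(np.mean(accepts)))
    rhats = np.array([compute_rhat(draws.get(n)) for n in post.parameter_names])
    max_rhat = np.nanmax(rhats)
    logger.info("fit finished in %.1fs: max split-Rhat %.3f, %d divergent "
                "transitions", time.time() - t0, max_rhat, n_div)
    if max_rhat > 1.05:
        warnings.warn(CONVERGENCE_ADVICE, stacklevel=2)
    return draws


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def compute_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    Each chain is halved, the between- to within-chain variance ratio is
    formed over the split halves, and sqrt((n-1)/n + B/(n W)) is returned.
    Values near 1 indicate that the chains have mixed; zero within-chain
    variance is flagged as undefined (NaN) rather than silently 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws shaped (n_chains >= 2, n_draws)")
    n = x.shape[1] // 2
    if n < 2:
        raise ValueError("need at least 4 draws per chain")
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    if within <= 0 or not np.isfinite(within):
        warnings.warn("zero within-chain variance; Rhat undefined", stacklevel=2)
        return float("nan")
    between = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def compute_ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial monotone positive sequence."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if x.var() <= 0:
        return float("nan")
    # mean autocorrelation across chains (FFT)
    acov = np.zeros(n)
    for row in x:
        d = row - row.mean()
        f = np.fft.rfft(np.concatenate([d, np.zeros(n)]))
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= m
    rho = acov / acov[0]
    # pair sums; truncate at first negative pair, enforce monotonicity
    t, s, prev = 1, 0.0, np.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        s += pair
        prev = pair
        t += 2
    tau = 1.0 + 2.0 * s  # integrated autocorrelation time
    return float(m * n / max(tau, 1.0))


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> PosteriorSummary:
    """Posterior mean, SD, equal-tailed CI (2.5/97.5 percentiles) and Rhat.

    Row order mirrors the reporting convention: fixed effects, random-effect
    SDs, correlations, shape (then any retained person effects).
    """
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    rows = []
    for name in draws.parameter_names:
        x = draws.get(name)
        flat = x.ravel()
        try:
            rhat = compute_rhat(x)
        except ValueError:
            rhat = float("nan")
        rows.append({
            "mean": flat.mean(),
            "sd": flat.std(ddof=1),
            "ci_low": np.percentile(flat, lo_q),
            "ci_high": np.percentile(flat, hi_q),
            "rhat": rhat,
            "ess": compute_ess(x),
        })
    table = pd.DataFrame(rows, index=pd.Index(draws.parameter_names, name="parameter"))
    return PosteriorSummary(table=table)


def diagnostics_export(draws: PosteriorDraws, n_density_points: int = 200) -> dict:
    """Machine-readable trace series and kernel density per parameter.

    Returns ``{parameter: {"trace": DataFrame(chain, iteration, value),
    "density": DataFrame(value, density), "degenerate": bool}}`` suitable for
    plotting trace plots (draws should hover around a single value) and
    density plots (should be clearly unimodal).  Constant chains are flagged
    degenerate and get no density estimate.
    """
    out = {}
    c, n, _ = draws.values.shape
    for name in draws.parameter_names:
        x = draws.get(name)
        trace = pd.DataFrame({
            "chain": np.repeat(np.arange(c), n),
            "iteration": np.tile(np.arange(n), c),
            "value": x.ravel(),
        })
        flat = x.ravel()
        degenerate = flat.std() == 0
        if degenerate:
            density = pd.DataFrame({"value": [flat[0]], "density": [np.inf]})
        else:
            kde = gaussian_kde(flat)
            grid = np.linspace(flat.min(), flat.max(), n_density_points)
            density = pd.DataFrame({"value": grid, "density": kde(grid)})
        out[name] = {"trace": trace, "density": density, "degenerate": bool(degenerate)}
    return out
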
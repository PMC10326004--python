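"""Posterior sampling and convergence diagnostics.

The sampler is an adaptive random-walk Metropolis with block updates:

* *joint* blocks propose a correlated step on all their coordinates at once
  and accept or reject them together;
* *independent* blocks exploit conditional independence (e.g. per-bird
  frailty terms, which enter the posterior only through that bird's own
  records): all coordinates are proposed at once and accepted coordinate-wise
  from per-component log-posterior contributions;
* optional Gibbs sweeps update latent categorical states (missing BACIPS
  group assignments) from their exact full conditionals.

Proposal scales adapt toward a target acceptance rate only during an initial
adaptation phase (by default the burn-in) and are frozen afterwards, so the
retained draws come from a fixed, detailed-balance-preserving kernel. A
single integer seed deterministically derives independent per-chain
substreams; identical seed + config + data give bit-identical output.

Also provided: the classic Gelman-Rubin potential scale reduction factor
(R-hat) and a trapezoid-quadrature oracle for validating posteriors of
models with one or two free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SamplerConfig",
    "Block",
    "ChainSet",
    "run_mcmc",
    "gelman_rubin",
    "quadrature_oracle",
    "GridPosterior",
]

_TARGET_ACCEPT_JOINT = 0.30
_TARGET_ACCEPT_SCALAR = 0.40


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    ``n_iterations`` counts all iterations per chain including burn-in;
    draws are retained every ``thin`` iterations after ``burn_in``.
    ``adapt_until`` bounds the adaptation phase (default: the burn-in).
    """

    n_chains: int = 3
    n_iterations: int = 6000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    adapt_window: int = 50
    adapt_until: int | None = None

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_saved(self) -> int:
        return int(np.ceil((self.n_iterations - self.burn_in) / self.thin))

    @classmethod
    def nest_fullscale(cls, seed: int = 0) -> "SamplerConfig":
        """Full-scale settings used for the nest model: 3 chains of 10,000
        retained-phase iterations thinned by 10 after 50,000 burn-in."""
        return cls(n_chains=3, n_iterations=60_000, burn_in=50_000, thin=10, seed=seed)

    @classmethod
    def adult_fullscale(cls, seed: int = 0) -> "SamplerConfig":
        """Full-scale settings used for the adult model: 3 chains of 100,000
        iterations thinned by 5 after 50,000 burn-in."""
        return cls(n_chains=3, n_iterations=150_000, burn_in=50_000, thin=5, seed=seed)


@dataclass
class Block:
    """A parameter block for the random-walk sampler.

    ``independent=True`` declares that the coordinates in ``idx`` are
    conditionally independent given the rest of the state, with per-component
    posterior contributions supplied via ``component_log_posterior``.
    """

    name: str
    idx: np.ndarray
    independent: bool = False
    scale: float = 0.5

    def __post_init__(self) -> None:
        self.idx = np.asarray(self.idx, dtype=int)


@dataclass
class ChainSet:
    """Multi-chain posterior draws: array (chains, saved iterations, params)."""

    draws: np.ndarray
    param_names: list[str]
    config: SamplerConfig
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, params)")
        if len(self.param_names) != self.draws.shape[2]:
            raise ValueError("param_names length mismatch")
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError("parameter names must be unique")

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, saved)."""
        return self.draws[:, :, self.param_names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter across chains."""
        return self.get(name).ravel()

    def rhat(self, name: str) -> float:
        return gelman_rubin(self, name)

    def rhat_table(self, names: Sequence[str] | None = None) -> dict[str, float]:
        return {n: self.rhat(n) for n in (names or self.param_names)}

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        c, s, p = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), s * p),
                "iteration": np.tile(np.repeat(np.arange(s), p), c),
                "parameter": np.tile(self.param_names, c * s),
                "value": self.draws.ravel(),
            }
        )


def _default_blocks(n_params: int, names: Sequence[str]) -> list[Block]:
    return [Block(name=names[j], idx=np.array([j])) for j in range(n_params)]


def run_mcmc(
    log_posterior: Callable,
    init,
    config: SamplerConfig,
    *,
    blocks: Sequence[Block] | None = None,
    component_log_posterior: Callable | None = None,
    gibbs: Callable | None = None,
    latent_init=None,
    param_names: Sequence[str] | None = None,
) -> ChainSet:
    """Sample a posterior with adaptive random-walk Metropolis (+ optional Gibbs).

    Parameters
    ----------
    log_posterior
        ``f(theta)`` or, when ``gibbs`` is given, ``f(theta, latent)``
        returning the (unnormalized) log posterior density; must be finite at
        the initial state of every chain.
    init
        Initial parameter vector, or callable ``init(chain, rng) -> vector``.
    blocks
        Update blocks; default is one scalar block per coordinate.
    component_log_posterior
        ``f(theta, latent, block) -> array`` of per-component contributions,
        required by blocks with ``independent=True``.
    gibbs
        ``f(theta, latent, rng) -> latent`` exact-conditional update of
        latent states, run once per iteration.
    """
    has_latent = gibbs is not None
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    all_draws = []
    accept_totals: dict[str, list[float]] = {}
    names = None

    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain])
        theta = np.array(
            init(chain, rng) if callable(init) else init, dtype=float
        ).copy()
        latent = (
            latent_init(chain, rng)
            if callable(latent_init)
            else (None if latent_init is None else np.array(latent_init).copy())
        )
        if names is None:
            names = list(param_names) if param_names is not None else [
                f"theta[{j}]" for j in range(theta.size)
            ]
            chain_blocks_template = (
                list(blocks) if blocks is not None else _default_blocks(theta.size, names)
            )

        def logp(th, lat=None):
            return log_posterior(th, lat) if has_latent else log_posterior(th)

        current_lp = logp(theta, latent)
        if not np.isfinite(current_lp):
            raise ValueError(
                f"log-posterior not finite at init of chain {chain}: theta={theta!r}"
            )

        # per-chain adaptive state
        blks = [replace(b) for b in chain_blocks_template]
        scales = [
            np.full(b.idx.size, float(b.scale)) if b.independent else float(b.scale)
            for b in blks
        ]
        acc_win = [np.zeros(b.idx.size) if b.independent else 0.0 for b in blks]
        acc_post = [np.zeros(b.idx.size) if b.independent else 0.0 for b in blks]
        n_post = 0
        adapt_until = config.adapt_until if config.adapt_until is not None else config.burn_in

        comp_cache: list[np.ndarray | None] = [None] * len(blks)
        saved = np.empty((config.n_saved, theta.size))
        k = 0
        for it in range(config.n_iterations):
            adapting = it < adapt_until
            for bi, block in enumerate(blks):
                if block.independent:
                    if component_log_posterior is None:
                        raise ValueError(
                            f"block {block.name!r} is independent but no "
                            "component_log_posterior was provided"
                        )
                    old = comp_cache[bi]
                    if old is None:
                        old = component_log_posterior(theta, latent, block)
                    step = rng.standard_normal(block.idx.size) * scales[bi]
                    prop = theta.copy()
                    prop[block.idx] += step
                    new = component_log_posterior(prop, latent, block)
                    logu = np.log(rng.random(block.idx.size))
                    acc = logu < (new - old)
                    theta[block.idx[acc]] = prop[block.idx[acc]]
                    merged = np.where(acc, new, old)
                    comp_cache = [None] * len(blks)
                    comp_cache[bi] = merged
                    current_lp = None  # stale; recomputed lazily for joint blocks
                    if adapting:
                        acc_win[bi] = acc_win[bi] + acc
                    else:
                        acc_post[bi] = acc_post[bi] + acc
                else:
                    if current_lp is None:
                        current_lp = logp(theta, latent)
                    prop = theta.copy()
                    prop[block.idx] += rng.standard_normal(block.idx.size) * scales[bi]
                    new_lp = logp(prop, latent)
                    if np.log(rng.random()) < new_lp - current_lp:
                        theta = prop
                        current_lp = new_lp
                        comp_cache = [None] * len(blks)
                        if adapting:
                            acc_win[bi] += 1.0
                        else:
                            acc_post[bi] += 1.0
            if has_latent:
                latent = gibbs(theta, latent, rng)
                current_lp = None
                comp_cache = [None] * len(blks)
            if not (it < adapt_until):
                n_post += 1
            if adapting and (it + 1) % config.adapt_window == 0:
                for bi, block in enumerate(blks):
                    target = (
                        _TARGET_ACCEPT_SCALAR
                        if block.independent or block.idx.size == 1
                        else _TARGET_ACCEPT_JOINT
                    )
                    rate = acc_win[bi] / config.adapt_window
                    scales[bi] = np.clip(
                        scales[bi] * np.exp(1.2 * (rate - target)), 1e-4, 50.0
                    )
                    acc_win[bi] = np.zeros(block.idx.size) if block.independent else 0.0
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                saved[k] = theta
                k += 1
        all_draws.append(saved[:k])

        for bi, block in enumerate(blks):
            rate = float(np.mean(acc_post[bi])) / max(n_post, 1)
            accept_totals.setdefault(block.name, []).append(rate)

    draws = np.stack(all_draws)
    acceptance = {k: float(np.mean(v)) for k, v in accept_totals.items()}
    return ChainSet(draws=draws, param_names=names, config=config, acceptance=acceptance)


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains, parameter: str | None = None) -> float:
    """Potential scale reduction factor R-hat.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-chain
    variance and ``B = n * var(chain means)``, sample variances with one
    degree of freedom removed. Returns NaN (with a warning) when the
    within-chain variance is zero, rather than silently reporting 1.
    """
    if isinstance(chains, ChainSet):
        if parameter is None:
            raise ValueError("parameter name required with a ChainSet")
        arr = chains.get(parameter)
    else:
        arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    m, n = arr.shape
    within = arr.var(axis=1, ddof=1).mean()
    between = n * arr.mean(axis=1).var(ddof=1)
    if within == 0:
        warnings.warn("zero within-chain variance: R-hat undefined", RuntimeWarning)
        return float("nan")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


# ---------------------------------------------------------------------------
# quadrature oracle


@dataclass
class GridPosterior:
    """Normalized posterior on a grid; summaries of arbitrary transforms."""

    points: np.ndarray  # (N, d)
    weights: np.ndarray  # (N,) summing to 1

    def _values(self, fn: Callable | None, dim: int) -> np.ndarray:
        if fn is None:
            return self.points[:, dim]
        return np.asarray([fn(p) for p in self.points], dtype=float)

    def mean(self, fn: Callable | None = None, dim: int = 0) -> float:
        return float(np.sum(self._values(fn, dim) * self.weights))

    def quantile(self, q, fn: Callable | None = None, dim: int = 0):
        vals = self._values(fn, dim)
        order = np.argsort(vals)
        w = self.weights[order]
        cdf = np.cumsum(w) - 0.5 * w  # midpoint convention, O(h^2) accurate
        return np.interp(q, cdf, vals[order])

    def median(self, fn: Callable | None = None, dim: int = 0) -> float:
        return float(self.quantile(0.5, fn, dim))

    def cri(self, fn: Callable | None = None, dim: int = 0) -> tuple[float, float]:
        lo, hi = self.quantile([0.025, 0.975], fn, dim)
        return float(lo), float(hi)


def quadrature_oracle(
    log_posterior: Callable, grid_spec: Sequence[tuple[float, float, int]]
) -> GridPosterior:
    """Trapezoid-quadrature posterior for models with <= 2 free parameters.

    ``grid_spec`` is a list of ``(lo, hi, n)`` per dimension. The log density
    is evaluated on the tensor grid, exponentiated stably and normalized with
    trapezoid weights. Serves as the independent reference that MCMC output
    is validated against.
    """
    if not 1 <= len(grid_spec) <= 2:
        raise ValueError("quadrature oracle supports 1 or 2 free parameters")
    axes = [np.linspace(lo, hi, int(n)) for lo, hi, n in grid_spec]
    traps = []
    for ax in axes:
        w = np.full(ax.size, ax[1] - ax[0])
        w[0] *= 0.5
        w[-1] *= 0.5
        traps.append(w)
    if len(axes) == 1:
        pts = axes[0][:, None]
        w = traps[0]
        logd = np.array([log_posterior(p) for p in axes[0]], dtype=float)
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.column_stack([g0.ravel(), g1.ravel()])
        w = np.outer(traps[0], traps[1]).ravel()
        logd = np.array([log_posterior(p[0], p[1]) for p in pts], dtype=float)
    finite = np.isfinite(logd)
    if not finite.any():
        raise ValueError("posterior is zero everywhere on the grid")
    dens = np.zeros_like(logd)
    dens[finite] = np.exp(logd[finite] - logd[finite].max())
    mass = np.sum(dens * w)
    if not np.isfinite(mass) or mass <= 0:
        raise ValueError("posterior not normalizable on the grid")
    return GridPosterior(points=pts, weights=dens * w / mass)
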
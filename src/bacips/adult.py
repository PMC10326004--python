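"""Monthly shared-frailty survival model for adult females.

Survival is treated as a continuous-time process observed at discrete
monthly intervals. The monthly unit hazard for bird b in study month t is

    UH = exp(eta_g + month_fx[m] + beta_c + gamma_b)

where the BACIPS group log-hazard is factorized as

    eta_g = mu + tau * I(impact) + rho * I(after) + delta * I(impact & after)

(``delta`` is the treatment x period interaction — the wildfire effect net
of pre-existing spatial differences and shared temporal trends), month_fx is
a 12-vector of calendar-month offsets constrained to sum to zero for
identifiability against ``mu``, ``beta_c`` is the yearling log-hazard ratio
(yearlings graduate to the adult reference class on 1 March), and
``gamma_b ~ Normal(0, sigma_gamma)`` is a per-bird frailty.

A bird alive through month t contributes ``exp(-UH)`` to the likelihood, a
death in month t contributes ``1 - exp(-UH)``, and months after the last
contact of a lost (censored) bird contribute nothing. Entry is staggered at
the first-relocation month.

Months with no relocation have an unknown BACIPS group, treated as a latent
categorical parameter with prior row ``pi[t]`` of the month-by-group
probability-weight matrix; its exact full conditional (prior times that
month's likelihood contribution) is available in closed form and is sampled
by Gibbs inside the MCMC.

Priors mirror the nest model: mu, tau, rho, delta, beta ~ Normal(0, sd 30);
month effects ~ Normal(0, sd 30) on the free coordinates; gamma hierarchy
with sigma_gamma ~ Uniform(0, 20). Annual survival for group g is derived
per posterior draw as ``exp(-sum_m exp(eta_g + month_fx[m]))`` over the 12
calendar months at the adult reference class and median frailty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grouping import AdultMonthlyHistory, BacipsGroup, PiMatrix, StudyMonths
from .mcmc import Block, ChainSet, SamplerConfig, run_mcmc

__all__ = [
    "AdultParams",
    "AdultData",
    "adult_unit_hazard",
    "adult_log_likelihood",
    "latent_group_conditional",
    "fit_adult_model",
    "derive_annual_survival",
    "ADULT_STRUCTURAL",
]

_SIGMA_HI = 20.0
_FIXED_SD = 30.0

_IMPACT = np.array([0.0, 1.0, 0.0, 1.0])  # indexed by group - 1 (BC,BI,AC,AI)
_AFTER = np.array([0.0, 0.0, 1.0, 1.0])


@dataclass
class AdultParams:
    """Parameter state of the adult hazard model."""

    mu: float
    tau: float  # impact-treatment offset
    rho: float  # after-period offset
    delta: float  # treatment x period interaction
    month_fx: np.ndarray  # 12 calendar-month offsets, sum to zero
    beta_yearling: float
    gamma: Mapping[str, float]
    sigma_gamma: float

    def __post_init__(self) -> None:
        self.month_fx = np.asarray(self.month_fx, dtype=float)
        if self.month_fx.shape != (12,):
            raise ValueError("month_fx must hold 12 offsets")
        if abs(self.month_fx.sum()) > 1e-10:
            raise ValueError("month_fx must sum to zero")

    def eta(self, group: BacipsGroup) -> float:
        g = int(group) - 1
        return self.mu + self.tau * _IMPACT[g] + self.rho * _AFTER[g] + self.delta * (
            _IMPACT[g] * _AFTER[g]
        )


def group_log_hazards(mu: float, tau: float, rho: float, delta: float) -> np.ndarray:
    """The four group log-hazards (BC, BI, AC, AI) under the factorization."""
    return mu + tau * _IMPACT + rho * _AFTER + delta * _IMPACT * _AFTER


def factorize_group_log_hazards(eta: np.ndarray) -> tuple[float, float, float, float]:
    """Invert group_log_hazards: any 4 group log-hazards map to (mu,tau,rho,delta)."""
    eta = np.asarray(eta, dtype=float)
    mu = eta[0]
    tau = eta[1] - eta[0]
    rho = eta[2] - eta[0]
    delta = eta[3] - eta[1] - eta[2] + eta[0]
    return float(mu), float(tau), float(rho), float(delta)


def adult_unit_hazard(
    params: AdultParams,
    group: BacipsGroup,
    calendar_month: int,
    age_class: str,
    bird_id: str,
) -> float:
    """Monthly unit hazard exp(eta_g + month_fx[m] + beta*I(yearling) + gamma_b)."""
    if not 1 <= calendar_month <= 12:
        raise ValueError("calendar_month must be in 1..12")
    if age_class not in ("yearling", "adult"):
        raise ValueError(f"unknown age class {age_class!r}")
    if bird_id not in params.gamma:
        raise ValueError(f"unknown bird {bird_id!r}")
    beta = params.beta_yearling if age_class == "yearling" else 0.0
    return float(
        np.exp(
            params.eta(BacipsGroup(group))
            + params.month_fx[calendar_month - 1]
            + beta
            + params.gamma[bird_id]
        )
    )


# ---------------------------------------------------------------------------
# vectorized data view


@dataclass
class AdultData:
    """Flat bird-month arrays extracted from encounter histories."""

    bird_idx: np.ndarray
    study_month: np.ndarray
    cal_month_idx: np.ndarray  # 0..11
    yearling: np.ndarray
    dead: np.ndarray
    obs_group_idx: np.ndarray  # 0..3 observed, -1 missing
    missing_slot: np.ndarray  # latent index for missing entries, -1 otherwise
    bird_ids: list[str]
    n_missing: int

    @classmethod
    def from_histories(
        cls, histories: Sequence[AdultMonthlyHistory], study_months: StudyMonths
    ) -> "AdultData":
        if not histories:
            raise ValueError("no adult histories")
        bird_ids = sorted(h.bird_id for h in histories)
        if len(set(bird_ids)) != len(bird_ids):
            raise ValueError("duplicate bird ids across histories")
        pos = {b: i for i, b in enumerate(bird_ids)}
        rows = []
        slot = 0
        for h in histories:
            for off, ms in enumerate(h.months):
                m = h.entry_month + off
                g = int(ms.group) - 1 if ms.group is not None else -1
                s = slot if g == -1 else -1
                if g == -1:
                    slot += 1
                rows.append(
                    (
                        pos[h.bird_id],
                        m,
                        study_months.calendar_month(m) - 1,
                        ms.age_class == "yearling",
                        ms.state == "dead",
                        g,
                        s,
                    )
                )
        return cls(
            bird_idx=np.array([r[0] for r in rows], int),
            study_month=np.array([r[1] for r in rows], int),
            cal_month_idx=np.array([r[2] for r in rows], int),
            yearling=np.array([r[3] for r in rows], bool),
            dead=np.array([r[4] for r in rows], bool),
            obs_group_idx=np.array([r[5] for r in rows], int),
            missing_slot=np.array([r[6] for r in rows], int),
            bird_ids=bird_ids,
            n_missing=slot,
        )

    @property
    def n_birds(self) -> int:
        return len(self.bird_ids)

    def group_vector(self, latent: np.ndarray | None) -> np.ndarray:
        g = self.obs_group_idx.copy()
        if self.n_missing:
            if latent is None or len(latent) != self.n_missing:
                raise ValueError("latent groups required for every missing month")
            miss = self.missing_slot >= 0
            g[miss] = latent[self.missing_slot[miss]]
        return g

    def per_month_loglik(
        self,
        eta: np.ndarray,
        month_fx: np.ndarray,
        beta: float,
        gamma: np.ndarray,
        latent: np.ndarray | None,
    ) -> np.ndarray:
        g = self.group_vector(latent)
        uh = np.exp(
            eta[g] + month_fx[self.cal_month_idx] + beta * self.yearling + gamma[self.bird_idx]
        )
        ll = -uh
        if self.dead.any():
            d = self.dead
            with np.errstate(divide="ignore"):  # zero hazard: death has -inf loglik
                ll[d] = np.log1p(-np.exp(-uh[d]))
        return ll


def adult_log_likelihood(
    histories: Sequence[AdultMonthlyHistory],
    params: AdultParams,
    latent: Mapping[tuple[str, int], BacipsGroup] | None = None,
    study_months: StudyMonths | None = None,
) -> float:
    """Summed monthly log-likelihood over all birds.

    ``latent`` supplies a BACIPS group for every (bird_id, study_month) whose
    group is missing; censored months after last contact contribute nothing
    (they are simply absent from the histories).
    """
    study_months = study_months or StudyMonths()
    data = AdultData.from_histories(histories, study_months)
    lat = None
    if data.n_missing:
        if latent is None:
            raise ValueError("latent groups required for every missing month")
        lat = np.empty(data.n_missing, int)
        miss = data.missing_slot >= 0
        for bird, month, slot in zip(
            data.bird_idx[miss], data.study_month[miss], data.missing_slot[miss]
        ):
            key = (data.bird_ids[bird], int(month))
            if key not in latent:
                raise ValueError(f"missing latent group for bird-month {key}")
            lat[slot] = int(latent[key]) - 1
    eta = group_log_hazards(params.mu, params.tau, params.rho, params.delta)
    gamma = np.array([params.gamma[b] for b in data.bird_ids])
    return float(
        data.per_month_loglik(
            eta, params.month_fx, params.beta_yearling, gamma, lat
        ).sum()
    )


def latent_group_conditional(
    history: AdultMonthlyHistory,
    month: int,
    params: AdultParams,
    pi: PiMatrix,
    study_months: StudyMonths | None = None,
) -> np.ndarray:
    """Posterior weights over the 4 groups for one missing bird-month.

    weight_g  ∝  pi[month, g] x (that month's likelihood under group g),
    normalized to sum to one.
    """
    study_months = study_months or StudyMonths()
    off = month - history.entry_month
    if not 0 <= off < len(history.months):
        raise ValueError(f"month {month} outside bird {history.bird_id}'s history")
    ms = history.months[off]
    if ms.group is not None:
        raise ValueError(f"month {month} of bird {history.bird_id} is not missing")
    beta = params.beta_yearling if ms.age_class == "yearling" else 0.0
    uh = np.exp(
        group_log_hazards(params.mu, params.tau, params.rho, params.delta)
        + params.month_fx[study_months.calendar_month(month) - 1]
        + beta
        + params.gamma[history.bird_id]
    )
    lik = 1.0 - np.exp(-uh) if ms.state == "dead" else np.exp(-uh)
    w = pi.row(month) * lik
    total = w.sum()
    if total <= 0:
        raise ValueError("all latent-group weights are zero (degenerate pi row)")
    return w / total


# ---------------------------------------------------------------------------
# fitting

ADULT_STRUCTURAL = (
    ["mu", "tau", "rho", "delta", "beta_yearling"]
    + [f"month_fx[{m}]" for m in range(1, 12)]
    + ["sigma_gamma"]
)
#: theta layout: [mu, tau, rho, delta, beta, fx_1..fx_11 (free), sigma, gamma...]
_N_FIXED = 5
_N_FX_FREE = 11
_SIGMA_POS = _N_FIXED + _N_FX_FREE  # 16


def _month_fx_full(free: np.ndarray) -> np.ndarray:
    return np.concatenate([free, [-free.sum()]])


def _theta_logpost(data: AdultData, pi_rows: np.ndarray):
    """Closures over the packed parameter vector; pi_rows is (n_missing, 4)."""
    B = data.n_birds
    miss = data.missing_slot >= 0
    order = np.argsort(data.missing_slot[miss])
    m_cal = data.cal_month_idx[miss][order]
    m_yr = data.yearling[miss][order]
    m_bird = data.bird_idx[miss][order]
    m_dead = data.dead[miss][order]

    def unpack(theta):
        """-> (fixed, month_fx, sigma, gamma) with gamma = sigma * z."""
        fixed = theta[:_N_FIXED]
        fx = _month_fx_full(theta[_N_FIXED:_SIGMA_POS])
        sig = theta[_SIGMA_POS]
        gamma = sig * theta[_SIGMA_POS + 1 : _SIGMA_POS + 1 + B]
        return fixed, fx, sig, gamma

    def log_prior(theta):
        fixed, fx, sig, _ = unpack(theta)
        if not 0.0 < sig < _SIGMA_HI:
            return -np.inf
        z = theta[_SIGMA_POS + 1 : _SIGMA_POS + 1 + B]
        lp = -np.log(_SIGMA_HI)
        free = theta[_N_FIXED:_SIGMA_POS]
        vals = np.concatenate([fixed, free])
        lp += np.sum(
            -0.5 * np.log(2 * np.pi * _FIXED_SD**2) - vals**2 / (2 * _FIXED_SD**2)
        )
        lp += -B * 0.5 * np.log(2 * np.pi) - 0.5 * np.sum(z**2)
        return lp

    def log_post(theta, latent):
        lp = log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        fixed, fx, sig, gamma = unpack(theta)
        eta = group_log_hazards(*fixed[:4])
        ll = data.per_month_loglik(eta, fx, fixed[4], gamma, latent).sum()
        if data.n_missing:
            lp += np.log(pi_rows[np.arange(data.n_missing), latent]).sum()
        return lp + ll

    def gamma_components(theta, latent, block):
        fixed, fx, sig, gamma = unpack(theta)
        z = theta[_SIGMA_POS + 1 : _SIGMA_POS + 1 + B]
        eta = group_log_hazards(*fixed[:4])
        ll = data.per_month_loglik(eta, fx, fixed[4], gamma, latent)
        per_bird = np.bincount(data.bird_idx, weights=ll, minlength=B)
        return per_bird - 0.5 * z**2

    def gibbs(theta, latent, rng):
        if not data.n_missing:
            return latent
        fixed, fx, sig, gamma = unpack(theta)
        eta = group_log_hazards(*fixed[:4])
        lin = fx[m_cal] + fixed[4] * m_yr + gamma[m_bird]
        uh = np.exp(eta[None, :] + lin[:, None])  # (n_missing, 4)
        lik = np.where(m_dead[:, None], -np.expm1(-uh), np.exp(-uh))
        w = pi_rows * lik
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random((data.n_missing, 1))
        return (np.cumsum(w, axis=1) < u).sum(axis=1).astype(int)

    return unpack, log_post, gamma_components, gibbs


def fit_adult_model(
    histories: Sequence[AdultMonthlyHistory],
    pi: PiMatrix,
    config: SamplerConfig,
    study_months: StudyMonths | None = None,
) -> ChainSet:
    """Fit the adult shared-frailty model by MCMC with Gibbs imputation.

    Missing bird-month BACIPS groups are latent categorical parameters with
    prior ``pi`` and are re-sampled from their exact full conditional once
    per iteration. Returns a ChainSet over the structural parameters
    (``mu``, ``tau``, ``rho``, ``delta``, ``beta_yearling``, the 11 free
    month effects, ``sigma_gamma``) plus per-bird frailties.
    """
    study_months = study_months or StudyMonths()
    data = AdultData.from_histories(histories, study_months)
    miss = data.missing_slot >= 0
    order = np.argsort(data.missing_slot[miss])
    pi_rows = pi.weights[data.study_month[miss][order]]
    unpack, log_post, gamma_components, gibbs = _theta_logpost(data, pi_rows)
    B = data.n_birds

    # crude baseline: overall monthly death rate
    deaths = data.dead.sum()
    mu0 = np.log(np.clip((deaths + 0.5) / len(data.bird_idx), 1e-4, 0.5))

    def init(chain, rng):
        theta = np.zeros(_SIGMA_POS + 1 + B)
        theta[0] = mu0 + 0.3 * rng.standard_normal()
        theta[1:4] = 0.3 * rng.standard_normal(3)
        theta[4] = 0.2 * rng.standard_normal()
        theta[_N_FIXED:_SIGMA_POS] = 0.1 * rng.standard_normal(_N_FX_FREE)
        theta[_SIGMA_POS] = 0.3 + 0.4 * rng.random()
        theta[_SIGMA_POS + 1 :] = 0.1 * rng.standard_normal(B)
        return theta

    def latent_init(chain, rng):
        if not data.n_missing:
            return np.zeros(0, int)
        u = rng.random((data.n_missing, 1))
        return (np.cumsum(pi_rows, axis=1) < u).sum(axis=1).astype(int)

    names = ADULT_STRUCTURAL + [f"z[{b}]" for b in data.bird_ids]
    blocks = [
        Block(name=n, idx=np.array([j]), scale=0.2)
        for j, n in enumerate(ADULT_STRUCTURAL)
    ]
    blocks.append(
        Block(
            name="gamma",
            idx=np.arange(_SIGMA_POS + 1, _SIGMA_POS + 1 + B),
            independent=True,
            scale=0.5,
        )
    )
    return run_mcmc(
        log_post,
        init,
        config,
        blocks=blocks,
        component_log_posterior=lambda th, lat, blk: gamma_components(th, lat, blk),
        gibbs=gibbs,
        latent_init=latent_init,
        param_names=names,
    )


def derive_annual_survival(chains: ChainSet, group: BacipsGroup) -> np.ndarray:
    """Posterior draws of annual survival for one BACIPS group.

    Per draw, the 12 calendar-month hazards are composed once each in
    calendar order with the group held fixed:
    ``S_g = exp(-sum_m exp(eta_g + month_fx[m]))`` at the adult reference
    class and median frailty.
    """
    for name in ("mu", "tau", "rho", "delta"):
        if name not in chains.param_names:
            raise ValueError(f"chains are missing parameter {name!r}")
    group = BacipsGroup(group)
    g = int(group) - 1
    eta = (
        chains.flat("mu")
        + chains.flat("tau") * _IMPACT[g]
        + chains.flat("rho") * _AFTER[g]
        + chains.flat("delta") * _IMPACT[g] * _AFTER[g]
    )
    fx_free = np.stack([chains.flat(f"month_fx[{m}]") for m in range(1, 12)])
    fx12 = -fx_free.sum(axis=0)
    cum = np.exp(eta + fx12)
    for m in range(11):
        cum += np.exp(eta + fx_free[m])
    return np.exp(-cum)
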
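"""Blocked Metropolis-Hastings inference for the operon model.

The data are three steady-state total-monomer abundances: KorA and KorB in
the wild type and KorB in the cooperativity-knockout mutant.  Each enters
the likelihood as an independent lognormal factor whose analytic mode is the
measured value and whose coefficient of variation reflects the measurement
error (50% for Western-blot abundances; 10% for the tighter runs used to
estimate the partial-repression scaling factors).

Parameters with measured values (affinities k1..k4, DNA abundance D0,
dimerization rates, dilution rate) carry lognormal priors specified by mode
and cv.  The unmeasured synthesis and monomerization rates carry wide
log-uniform priors, and the scaling factors pi_X, pi_Y are uniform on
[0, 1].  The sampler random-walks the positive parameters on the log scale
(multiplicative lognormal proposals, jointly in one block) and the two pi's
additively in their own blocks, visiting blocks in a fixed rotation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core_model import (
    CHAIN_STATIONARY,
    PARAM_NAMES,
    KineticParameters,
    SteadyStateError,
    _enumerate_roots,
    _monomer_from_total,
    _newton_2d,
    _state_from_monomers,
    make_mutant,
    steady_state,
)

__all__ = [
    "Observations",
    "Prior",
    "PosteriorChain",
    "DEFAULT_PROPOSAL_SCALES",
    "lognormal_from_mode_cv",
    "default_priors",
    "log_likelihood",
    "propose",
    "mh_run",
    "summarize_posterior",
    "joint_histogram",
    "pairwise_correlation",
    "tune_acceptance",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: (sd of the normal deviate added to log rate parameters,
#:  sd of the normal deviate added to pi_X / pi_Y)
DEFAULT_PROPOSAL_SCALES = (0.05, 0.08)

RATE_BLOCK, PI_X_BLOCK, PI_Y_BLOCK = 0, 1, 2


@dataclass(frozen=True)
class Observations:
    """Measured steady-state total-monomer abundances (nM) and their cv."""

    A_tot_wt: float = 1600.0
    B_tot_wt: float = 400.0
    B_tot_mut: float = 920.0
    cv: float = 0.5

    def __post_init__(self):
        for name in ("A_tot_wt", "B_tot_wt", "B_tot_mut", "cv"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def lognormal_from_mode_cv(mode: float, cv: float) -> tuple[float, float]:
    """Log-scale location mu and shape s of the lognormal with the given
    analytic mode and coefficient of variation.

    s^2 = ln(1 + cv^2) fixes sd/mean = cv, and mu = ln(mode) + s^2 places
    the density maximum exp(mu - s^2) at ``mode``.
    """
    if not (mode > 0 and cv > 0):
        raise ValueError(f"mode and cv must be > 0, got mode={mode}, cv={cv}")
    s2 = math.log1p(cv * cv)
    return math.log(mode) + s2, math.sqrt(s2)


@dataclass(frozen=True)
class Prior:
    """One parameter's prior: lognormal (mode, cv), uniform or log-uniform
    on ``bounds``, or a point mass (parameter held fixed)."""

    family: str  # "lognormal" | "uniform" | "loguniform" | "point"
    mode: float | None = None
    cv: float | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family == "lognormal":
            if not (self.mode and self.mode > 0 and self.cv and self.cv > 0):
                raise ValueError("lognormal prior needs mode > 0 and cv > 0")
        elif self.family in ("uniform", "loguniform"):
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError(f"{self.family} prior needs lower < upper bounds")
            if self.family == "loguniform" and self.bounds[0] <= 0:
                raise ValueError("loguniform bounds must be positive")
        elif self.family == "point":
            if self.mode is None:
                raise ValueError("point prior needs a value in 'mode'")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")

    # log density on the natural (x) scale
    def logpdf(self, x: float) -> float:
        if self.family == "lognormal":
            if x <= 0:
                return -math.inf
            mu, s = lognormal_from_mode_cv(self.mode, self.cv)
            z = (math.log(x) - mu) / s
            return -math.log(x * s) - 0.5 * (_LOG_2PI + z * z)
        if self.family == "uniform":
            lo, hi = self.bounds
            return -math.log(hi - lo) if lo <= x <= hi else -math.inf
        if self.family == "loguniform":
            lo, hi = self.bounds
            if not (lo <= x <= hi):
                return -math.inf
            return -math.log(x) - math.log(math.log(hi / lo))
        return 0.0  # point: constant (never proposed)

    # log density on the sampling scale (log scale for positive families)
    def logpdf_sampling(self, x: float) -> float:
        if self.family in ("lognormal", "loguniform"):
            lp = self.logpdf(x)
            return lp + math.log(x) if x > 0 and math.isfinite(lp) else -math.inf
        return self.logpdf(x)

    def cdf(self, x: float) -> float:
        if self.family == "lognormal":
            if x <= 0:
                return 0.0
            mu, s = lognormal_from_mode_cv(self.mode, self.cv)
            return 0.5 * (1.0 + math.erf((math.log(x) - mu) / (s * math.sqrt(2))))
        if self.family == "uniform":
            lo, hi = self.bounds
            return min(1.0, max(0.0, (x - lo) / (hi - lo)))
        if self.family == "loguniform":
            lo, hi = self.bounds
            if x <= lo:
                return 0.0
            if x >= hi:
                return 1.0
            return math.log(x / lo) / math.log(hi / lo)
        return 1.0 if x >= self.mode else 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "lognormal":
            mu, s = lognormal_from_mode_cv(self.mode, self.cv)
            return np.exp(rng.normal(mu, s, size))
        if self.family == "uniform":
            lo, hi = self.bounds
            return rng.uniform(lo, hi, size)
        if self.family == "loguniform":
            lo, hi = self.bounds
            return np.exp(rng.uniform(math.log(lo), math.log(hi), size))
        return np.full(size, self.mode) if size else self.mode

    @property
    def initial(self) -> float:
        """Default chain starting value."""
        if self.family == "lognormal" or self.family == "point":
            return self.mode
        if self.family == "uniform":
            lo, hi = self.bounds
            return 0.5 * (lo + hi)
        lo, hi = self.bounds
        return math.exp(0.5 * (math.log(lo) + math.log(hi)))


def default_priors(tight: bool = False,
                   synthesis_bounds: tuple[float, float] = (1e-5, 1e5),
                   monomerization_bounds: tuple[float, float] = (1e-30, 1e10),
                   ) -> dict[str, Prior]:
    """Prior table of the full model.

    ``tight=True`` caps the measured-parameter cvs at 10%, the setting used
    for the scaling-parameter (variant) fits; the dimerization and dilution
    priors keep their tighter 5% either way.
    """
    cv_meas = 0.1 if tight else 0.5
    return {
        "k_A": Prior("loguniform", bounds=synthesis_bounds),
        "k_B": Prior("loguniform", bounds=synthesis_bounds),
        "k1": Prior("lognormal", mode=12.9, cv=cv_meas),
        "k2": Prior("lognormal", mode=9.3, cv=cv_meas),
        "k3": Prior("lognormal", mode=3.1, cv=cv_meas),
        "k4": Prior("lognormal", mode=3.1, cv=cv_meas),
        "sigma_A": Prior("loguniform", bounds=monomerization_bounds),
        "sigma_B": Prior("loguniform", bounds=monomerization_bounds),
        "lambda_A": Prior("lognormal", mode=0.001, cv=0.05),
        "lambda_B": Prior("lognormal", mode=0.001, cv=0.05),
        "gamma_P": Prior("lognormal", mode=0.0003875, cv=0.05),
        "pi_X": Prior("uniform", bounds=(0.0, 1.0)),
        "pi_Y": Prior("uniform", bounds=(0.0, 1.0)),
        "D0": Prior("lognormal", mode=4.5, cv=cv_meas),
    }


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _lognormal_logpdf(x: float, mode: float, cv: float) -> float:
    if x <= 0:
        return -math.inf
    s2 = math.log1p(cv * cv)
    mu = math.log(mode) + s2
    z = (math.log(x) - mu) / math.sqrt(s2)
    return -math.log(x) - 0.5 * (math.log(s2) + _LOG_2PI + z * z)


class _FastSteady:
    """Warm-started steady-state totals for the sampler's inner loop."""

    def __init__(self, convention: str):
        self.convention = convention
        self.warm: dict[str, tuple[float, float]] = {}

    def totals(self, p: KineticParameters, key: str) -> tuple[float, float]:
        start = self.warm.get(key)
        if start is None:
            totA = p.D0 * p.k_A / p.gamma_P
            totB = p.D0 * p.k_B / p.gamma_P
            a0 = _monomer_from_total(0.1 * totA, p.lambda_A, p.sigma_A, p.gamma_P)
            b0 = _monomer_from_total(0.1 * totB, p.lambda_B, p.sigma_B, p.gamma_P)
            start = (math.log(a0), math.log(b0))
        sol = _newton_2d(p, start[0], start[1], self.convention)
        if sol is None:
            roots = _enumerate_roots(p, self.convention)
            if not roots:
                raise SteadyStateError("steady state not found")
            st = roots[0]
            sol = (math.log(max(st.A1, 1e-300)), math.log(max(st.B1, 1e-300)))
        st = _state_from_monomers(math.exp(sol[0]), math.exp(sol[1]), p)
        self.warm[key + "_cand"] = sol
        return st.A_tot, st.B_tot

    def commit(self):
        for key in ("wt", "mut"):
            cand = self.warm.pop(key + "_cand", None)
            if cand is not None:
                self.warm[key] = cand


def _loglik_params(p: KineticParameters, obs: Observations, fast: _FastSteady):
    try:
        A_wt, B_wt = fast.totals(p, "wt")
        _, B_mut = fast.totals(make_mutant(p), "mut")
    except (SteadyStateError, OverflowError):
        return -math.inf
    return (_lognormal_logpdf(A_wt, obs.A_tot_wt, obs.cv)
            + _lognormal_logpdf(B_wt, obs.B_tot_wt, obs.cv)
            + _lognormal_logpdf(B_mut, obs.B_tot_mut, obs.cv))


def log_likelihood(params: KineticParameters, obs: Observations,
                   convention: str = CHAIN_STATIONARY) -> float:
    """Sum of the three lognormal log densities (wild-type KorA and KorB,
    mutant KorB), each with mode at the measured value and sd/mean = obs.cv,
    evaluated at the model's steady-state predictions.

    Steady-state failure yields -inf (the sampler treats it as rejection).
    """
    try:
        wt = steady_state(params, convention=convention)
        mut = steady_state(make_mutant(params), convention=convention)
    except SteadyStateError:
        return -math.inf
    return (_lognormal_logpdf(wt.A_tot, obs.A_tot_wt, obs.cv)
            + _lognormal_logpdf(wt.B_tot, obs.B_tot_wt, obs.cv)
            + _lognormal_logpdf(mut.B_tot, obs.B_tot_mut, obs.cv))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def propose(block: str, current: np.ndarray,
            scales: tuple[float, float] = DEFAULT_PROPOSAL_SCALES,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a candidate for one block of parameters.

    ``block="rates"``: each value is multiplied by exp(N(0, scales[0])) --
    a lognormal proposal, symmetric on the log scale, that keeps rates
    strictly positive.  ``block="pi_X"``/``"pi_Y"``: additive N(0, scales[1]).
    """
    rng = rng or np.random.default_rng()
    current = np.asarray(current, dtype=float)
    if block == "rates":
        return current * np.exp(rng.normal(0.0, scales[0], current.shape))
    if block in ("pi_X", "pi_Y"):
        return current + rng.normal(0.0, scales[1], current.shape)
    raise ValueError(f"unknown block {block!r}")


@dataclass
class PosteriorChain:
    """Ordered MCMC output: one full parameter vector per iteration, plus
    per-iteration block and acceptance bookkeeping."""

    names: tuple[str, ...]
    sampled: tuple[str, ...]
    samples: np.ndarray          # (iterations, len(names))
    log_posterior: np.ndarray
    block_id: np.ndarray
    accepted: np.ndarray
    seed: int
    scales: tuple[float, float]
    priors: dict[str, Prior] = field(repr=False)

    def __len__(self):
        return self.samples.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.names))
        df["log_posterior"] = self.log_posterior
        df["block"] = self.block_id
        df["accepted"] = self.accepted.astype(int)
        return df

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def thinned(self, burn_in: float = 0.1, thinning: int = 360) -> np.ndarray:
        start = int(round(burn_in * len(self)))
        return self.samples[start::thinning]


def mh_run(priors: dict[str, Prior],
           obs: Observations | None,
           iterations: int,
           seed: int,
           scales: tuple[float, float] = DEFAULT_PROPOSAL_SCALES,
           init: dict[str, float] | None = None,
           convention: str = CHAIN_STATIONARY,
           stall_warn: int = 5000) -> PosteriorChain:
    """Blocked Metropolis-Hastings run.

    Parameters with non-point priors are sampled; all positive-scale ones
    form one block updated jointly with multiplicative lognormal proposals
    (sd ``scales[0]`` per log coordinate), and pi_X / pi_Y form two
    single-parameter blocks with additive normal proposals (sd ``scales[1]``).
    Blocks are visited in fixed rotation, one block per iteration.  Positive
    parameters are random-walked on the log scale, with priors transformed
    accordingly, so the acceptance ratio is the posterior ratio.

    ``obs=None`` runs with a flat likelihood (prior-only), used to validate
    the sampler against its invariant distribution.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    missing = [n for n in PARAM_NAMES if n not in priors]
    if missing:
        raise ValueError(f"priors missing for parameters: {missing}")

    names = PARAM_NAMES
    n_par = len(names)
    prior_list = [priors[n] for n in names]
    sampled_idx = [i for i, pr in enumerate(prior_list) if pr.family != "point"]
    sampled = tuple(names[i] for i in sampled_idx)
    rate_idx = [i for i in sampled_idx if names[i] not in ("pi_X", "pi_Y")]
    blocks: list[tuple[int, list[int], str]] = []
    if rate_idx:
        blocks.append((RATE_BLOCK, rate_idx, "rates"))
    if "pi_X" in sampled:
        blocks.append((PI_X_BLOCK, [names.index("pi_X")], "pi_X"))
    if "pi_Y" in sampled:
        blocks.append((PI_Y_BLOCK, [names.index("pi_Y")], "pi_Y"))
    if not blocks:
        raise ValueError("no free parameters to sample")

    rng = np.random.default_rng(seed)
    cur = np.array([prior_list[i].initial for i in range(n_par)], dtype=float)
    if init:
        for k, v in init.items():
            cur[names.index(k)] = v

    fast = _FastSteady(convention)

    def log_prior(vec):
        lp = 0.0
        for i in sampled_idx:
            lp += prior_list[i].logpdf_sampling(vec[i])
            if lp == -math.inf:
                return lp
        return lp

    def log_lik(vec):
        if obs is None:
            return 0.0
        return _loglik_params(KineticParameters.from_array(vec), obs, fast)

    lp_cur = log_prior(cur)
    if lp_cur == -math.inf:
        raise ValueError("initial state has zero prior density")
    ll_cur = log_lik(cur)
    fast.commit()

    samples = np.empty((iterations, n_par))
    log_post = np.empty(iterations)
    block_id = np.empty(iterations, dtype=np.int8)
    accepted = np.zeros(iterations, dtype=bool)
    n_blocks = len(blocks)
    rate_sd, pi_sd = scales
    any_accept = False

    for it in range(iterations):
        bid, idx, kind = blocks[it % n_blocks]
        cand = cur.copy()
        if kind == "rates":
            cand[idx] = cur[idx] * np.exp(rng.normal(0.0, rate_sd, len(idx)))
        else:
            cand[idx[0]] = cur[idx[0]] + rng.normal(0.0, pi_sd)
        log_u = math.log(rng.random())

        lp_cand = log_prior(cand)
        if lp_cand > -math.inf:
            ll_cand = log_lik(cand)
            if log_u < (lp_cand + ll_cand) - (lp_cur + ll_cur):
                cur, lp_cur, ll_cur = cand, lp_cand, ll_cand
                accepted[it] = True
                any_accept = True
                fast.commit()
        samples[it] = cur
        log_post[it] = lp_cur + ll_cur
        block_id[it] = bid
        if it + 1 == stall_warn and not any_accept:
            warnings.warn(
                f"no proposal accepted in the first {stall_warn} iterations; "
                "check the starting point and proposal scales", RuntimeWarning)

    return PosteriorChain(names=names, sampled=sampled, samples=samples,
                          log_posterior=log_post, block_id=block_id,
                          accepted=accepted, seed=seed, scales=scales,
                          priors=dict(priors))


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics
# ---------------------------------------------------------------------------


def _kde_mode(x: np.ndarray, log_scale: bool, grid_size: int = 512) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    y = np.log(x) if log_scale else x
    kde = gaussian_kde(y)
    pad = 0.1 * np.ptp(y)
    grid = np.linspace(y.min() - pad, y.max() + pad, grid_size)
    dens = kde(grid)
    if log_scale:
        # density of x = density of ln x times 1/x: maximise log f_y(y) - y
        with np.errstate(divide="ignore"):
            m = grid[int(np.argmax(np.log(dens) - grid))]
        return float(math.exp(m))
    return float(grid[int(np.argmax(dens))])


def summarize_posterior(chain: PosteriorChain,
                        burn_in: float = 0.1,
                        thinning: int = 360,
                        level: float = 0.9) -> pd.DataFrame:
    """Per-parameter posterior summaries over thinned post-burn-in samples.

    The mode is a kernel-density estimate on the log scale for positive
    parameters and on the linear scale for pi_X/pi_Y; cv is sd/mean on the
    natural scale; the credible interval is the central ``level`` mass.
    """
    kept = chain.thinned(burn_in, thinning)
    if kept.shape[0] < 100:
        raise ValueError(
            f"only {kept.shape[0]} samples after burn-in and thinning; "
            "need >= 100 (reduce thinning or run longer)")
    qlo, qhi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = {}
    for name in chain.sampled:
        x = kept[:, chain.names.index(name)]
        log_scale = name not in ("pi_X", "pi_Y") and np.all(x > 0)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows[name] = {
            "mode": _kde_mode(x, log_scale),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean != 0 else math.nan,
            f"q{100 * qlo:g}": float(np.quantile(x, qlo)),
            "median": float(np.quantile(x, 0.5)),
            f"q{100 * qhi:g}": float(np.quantile(x, qhi)),
            "n": int(x.size),
        }
    return pd.DataFrame(rows).T


def joint_histogram(chain: PosteriorChain, name_x: str, name_y: str,
                    bins: int = 60, burn_in: float = 0.1, thinning: int = 360,
                    log_scale: bool | None = None):
    """2-D histogram of a pair of parameters (density-normalised).

    Returns (H, x_edges, y_edges); edges are on the log10 scale for positive
    rate parameters unless ``log_scale=False``.
    """
    kept = chain.thinned(burn_in, thinning)
    x = kept[:, chain.names.index(name_x)]
    y = kept[:, chain.names.index(name_y)]
    if log_scale is None:
        log_scale = (name_x not in ("pi_X", "pi_Y")
                     and name_y not in ("pi_X", "pi_Y"))
    if log_scale:
        x, y = np.log10(x), np.log10(y)
    H, xe, ye = np.histogram2d(x, y, bins=bins, density=True)
    return H, xe, ye


def pairwise_correlation(chain: PosteriorChain, names=None,
                         burn_in: float = 0.1, thinning: int = 360,
                         log_scale: bool = True) -> pd.DataFrame:
    """Pearson correlation matrix of the (log-scale) thinned samples."""
    names = tuple(names) if names else chain.sampled
    kept = chain.thinned(burn_in, thinning)
    cols = {}
    for n in names:
        x = kept[:, chain.names.index(n)]
        cols[n] = np.log(x) if log_scale and n not in ("pi_X", "pi_Y") else x
    return pd.DataFrame(cols).corr()


def tune_acceptance(chain: PosteriorChain, target: float = 0.234) -> pd.DataFrame:
    """Per-block acceptance fractions with advisory scale adjustments.

    The suggested factor nudges each proposal scale toward the target
    acceptance; it is advisory only (scales were fixed by hand in the
    original study design).
    """
    rows = []
    for bid in np.unique(chain.block_id):
        mask = chain.block_id == bid
        n = int(mask.sum())
        acc = float(chain.accepted[mask].mean()) if n else math.nan
        label = {RATE_BLOCK: "rates", PI_X_BLOCK: "pi_X", PI_Y_BLOCK: "pi_Y"}[int(bid)]
        factor = math.exp(acc - target) if n else math.nan
        rows.append({"block": label, "iterations": n, "acceptance": acc,
                     "target": target, "suggested_scale_factor": factor})
    return pd.DataFrame(rows).set_index("block")
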
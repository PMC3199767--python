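"""Synthetic observation triplets for closed-loop sampler validation.

Emulates the study's observation model: steady-state total-monomer
abundances of KorA (wild type), KorB (wild type) and KorB (cooperativity
knockout), each perturbed independently by lognormal measurement noise with
analytic mode at the noiseless value and a stated coefficient of variation.
Generating data from known ground truth and re-fitting lets the package
check parameter recovery and credible-interval calibration without any
external measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CHAIN_STATIONARY, KineticParameters, make_mutant, steady_state
from .bayes_inference import (
    Observations,
    Prior,
    lognormal_from_mode_cv,
    mh_run,
    summarize_posterior,
)
from .repression_variants import make_variant

__all__ = ["SyntheticDataset", "truth_preset", "noiseless_triplet",
           "generate", "recovery_experiment"]


def truth_preset(label: str = "uu") -> KineticParameters:
    """Ground-truth presets: the fitted uu / u0 parameterizations, so that
    recovery experiments exercise the same regime as the real fits."""
    if label not in ("uu", "u0"):
        raise ValueError(f"truth preset must be 'uu' or 'u0', got {label!r}")
    return make_variant(label)


def noiseless_triplet(truth: KineticParameters,
                      convention: str = CHAIN_STATIONARY) -> tuple[float, float, float]:
    """(A_tot_wt, B_tot_wt, B_tot_mut) steady states of the ground truth."""
    wt = steady_state(truth, convention=convention)
    mut = steady_state(make_mutant(truth), convention=convention)
    return wt.A_tot, wt.B_tot, mut.B_tot


@dataclass(frozen=True)
class SyntheticDataset:
    """Ground truth, its noiseless steady-state triplet, and noisy draws."""

    truth: KineticParameters = field(repr=False)
    noiseless: tuple[float, float, float]
    observations: Observations
    cv: float
    seed: int


def generate(truth: KineticParameters,
             cv: float = 0.5,
             seed: int = 0,
             convention: str = CHAIN_STATIONARY,
             noiseless: tuple[float, float, float] | None = None) -> SyntheticDataset:
    """Draw one synthetic observation triplet from the ground truth.

    Each observation is lognormal with mode at the noiseless steady state
    and coefficient of variation ``cv``; the three draws are independent.
    ``cv=0`` returns the noiseless values exactly.  ``noiseless`` may carry
    a precomputed triplet to avoid re-solving the steady states when many
    replicate datasets are drawn from the same truth.
    """
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    clean = noiseless if noiseless is not None else noiseless_triplet(truth, convention)
    if cv == 0.0:
        noisy = clean
    else:
        rng = np.random.default_rng(seed)
        noisy = tuple(
            math.exp(rng.normal(*lognormal_from_mode_cv(value, cv)))
            for value in clean)
    obs = Observations(A_tot_wt=noisy[0], B_tot_wt=noisy[1],
                       B_tot_mut=noisy[2], cv=max(cv, 1e-6))
    return SyntheticDataset(truth=truth, noiseless=clean, observations=obs,
                            cv=cv, seed=seed)


def _recovery_priors(truth: KineticParameters, free: tuple[str, ...],
                     synthesis_bounds=(1e-5, 1e5)) -> dict[str, Prior]:
    priors: dict[str, Prior] = {}
    for name in truth.to_dict():
        value = getattr(truth, name)
        if name in free:
            if name in ("pi_X", "pi_Y"):
                priors[name] = Prior("uniform", bounds=(0.0, 1.0))
            else:
                priors[name] = Prior("loguniform", bounds=synthesis_bounds)
        else:
            priors[name] = Prior("point", mode=value)
    return priors


def recovery_experiment(truth: KineticParameters | None = None,
                        cv: float = 0.1,
                        free: tuple[str, ...] = ("k_A", "k_B"),
                        iterations: int = 6000,
                        burn_in: float = 0.25,
                        thinning: int = 5,
                        replicates: int = 20,
                        seed: int = 0,
                        level: float = 0.9,
                        convention: str = CHAIN_STATIONARY):
    """Closed-loop coverage check: generate, fit, count interval hits.

    For each replicate a fresh noisy triplet is drawn from ``truth``
    (default: the uu preset), the free parameters are re-fitted by the
    blocked sampler with everything else held at truth, and the central
    ``level`` credible interval is compared against the true value.

    Returns ``(per_replicate, coverage)``: a tidy DataFrame with one row per
    replicate and free parameter (ci_low, ci_high, truth, covered, mode),
    and a dict of coverage fractions per free parameter.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    truth = truth if truth is not None else truth_preset("uu")
    priors = _recovery_priors(truth, tuple(free))
    # independent child seeds, kept below 2**31 for portability
    child_seeds = [int(s) & 0x7FFFFFFF for s in
                   np.random.SeedSequence(seed).generate_state(2 * replicates)]
    rows = []
    for rep in range(replicates):
        ds = generate(truth, cv=cv, seed=child_seeds[2 * rep],
                      convention=convention)
        init = {name: getattr(truth, name) for name in free}
        chain = mh_run(priors, ds.observations, iterations=iterations,
                       seed=child_seeds[2 * rep + 1], init=init,
                       convention=convention)
        summary = summarize_posterior(chain, burn_in=burn_in,
                                      thinning=thinning, level=level)
        qlo = f"q{100 * (1 - level) / 2:g}"
        qhi = f"q{100 * (1 - (1 - level) / 2):g}"
        for name in free:
            lo, hi = summary.loc[name, qlo], summary.loc[name, qhi]
            tv = getattr(truth, name)
            rows.append({"replicate": rep, "parameter": name,
                         "ci_low": lo, "ci_high": hi, "truth": tv,
                         "mode": summary.loc[name, "mode"],
                         "covered": bool(lo <= tv <= hi)})
    per_replicate = pd.DataFrame(rows)
    coverage = (per_replicate.groupby("parameter")["covered"].mean().to_dict())
    return per_replicate, coverage
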
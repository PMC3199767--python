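"""Partial-repression model variants and repression-ratio analysis.

Five nested variants of the operon model differ only in what happens when a
single repressor occupies the promoter.  The two-character label gives the
synthesis scaling for the KorA-bound (first symbol) and KorB-bound (second
symbol) states: ``1`` full expression (pi = 1), ``0`` total repression
(pi = 0), ``u`` partial repression (pi free, fitted).  Monomerization is
set to zero in all variants.

The discriminating statistic is the repression ratio: steady-state KorA
abundance with repressor binding disabled (closed form D0*k_A/gamma_P)
divided by the regulated steady state.  An induction experiment puts this
ratio at 91.8-fold at physiological (~11) plasmid copies, so sweeping the
plasmid copy number and locating where each variant's curve crosses 91.8
ranks the variants by plausibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    CHAIN_STATIONARY,
    CellGeometry,
    KineticParameters,
    molecules_to_nM,
    steady_state,
    unrepressed_total,
)
from .bayes_inference import PosteriorChain

__all__ = [
    "VARIANT_LABELS",
    "VARIANT_FITS",
    "REPRESSION_BENCHMARK",
    "RepressionResult",
    "variant_pi",
    "make_variant",
    "repression_ratio",
    "ratio_curve",
    "crossing_copy_number",
    "ensemble_ratio",
]

VARIANT_LABELS = ("11", "uu", "u0", "0u", "00")

#: Experimentally reported fold-repression at physiological copy number.
REPRESSION_BENCHMARK = 91.8

#: Posterior summaries (mode m, cv) of the per-variant fits: synthesis rates
#: and, where free, the partial-repression scaling factors.
VARIANT_FITS: dict[str, dict[str, float]] = {
    "11": {"k_A": 7.9, "k_A_cv": 0.2, "k_B": 2.3, "k_B_cv": 0.2,
           "pi_X": 1.0, "pi_Y": 1.0},
    "uu": {"k_A": 11.5, "k_A_cv": 1.4, "k_B": 3.2, "k_B_cv": 1.3,
           "pi_X": 0.72, "pi_X_cv": 0.5, "pi_Y": 0.72, "pi_Y_cv": 0.4},
    "u0": {"k_A": 14.0, "k_A_cv": 2.4, "k_B": 4.0, "k_B_cv": 2.5,
           "pi_X": 0.75, "pi_X_cv": 0.45, "pi_Y": 0.0},
    "0u": {"k_A": 43.0, "k_A_cv": 1.5, "k_B": 11.6, "k_B_cv": 1.6,
           "pi_X": 0.0, "pi_Y": 0.8, "pi_Y_cv": 0.4},
    "00": {"k_A": 735.0, "k_A_cv": 0.3, "k_B": 231.0, "k_B_cv": 0.2,
           "pi_X": 0.0, "pi_Y": 0.0},
}


def variant_pi(label: str) -> tuple[float | None, float | None]:
    """(pi_X, pi_Y) constraints implied by a label; None means free."""
    if label not in VARIANT_LABELS:
        raise ValueError(f"unknown variant label {label!r}; "
                         f"expected one of {VARIANT_LABELS}")
    fixed = {"1": 1.0, "0": 0.0, "u": None}
    return fixed[label[0]], fixed[label[1]]


def make_variant(label: str,
                 base: KineticParameters | None = None,
                 k_A: float | None = None,
                 k_B: float | None = None,
                 pi_X: float | None = None,
                 pi_Y: float | None = None) -> KineticParameters:
    """Parameter set for one variant: label-implied pi constraints applied,
    monomerization zeroed, synthesis rates installed.

    Synthesis rates and free pi's default to the fitted modes in
    ``VARIANT_FITS``; other parameters come from ``base`` (default: the
    measured modes).
    """
    cX, cY = variant_pi(label)
    fit = VARIANT_FITS[label]
    k_A = fit["k_A"] if k_A is None else k_A
    k_B = fit["k_B"] if k_B is None else k_B
    px = cX if cX is not None else (fit["pi_X"] if pi_X is None else pi_X)
    py = cY if cY is not None else (fit["pi_Y"] if pi_Y is None else pi_Y)
    fields = base.to_dict() if base is not None else {}
    fields.update(k_A=k_A, k_B=k_B, pi_X=px, pi_Y=py,
                  sigma_A=0.0, sigma_B=0.0)
    return KineticParameters(**fields)


@dataclass(frozen=True)
class RepressionResult:
    """Repression ratio of one variant at one promoter-DNA abundance."""

    variant: str
    copy_number: float | None
    D0: float                 # nM
    A_tot_repressed: float    # nM
    A_tot_unrepressed: float  # nM
    ratio: float


def repression_ratio(params: KineticParameters,
                     copy_number: float | None = None,
                     geometry: CellGeometry = CellGeometry(),
                     variant: str = "",
                     convention: str = CHAIN_STATIONARY) -> RepressionResult:
    """Unrepressed-to-repressed ratio of steady-state total KorA.

    If ``copy_number`` is given, D0 is the concentration of that many
    plasmids in the cell volume; otherwise ``params.D0`` is used directly
    (the printed physiological column uses D0 = 4.5 nM exactly).
    """
    if copy_number is not None:
        if copy_number <= 0:
            raise ValueError(f"copy_number must be > 0, got {copy_number}")
        D0 = molecules_to_nM(copy_number, geometry)
        params = KineticParameters(**{**params.to_dict(), "D0": D0})
    else:
        D0 = params.D0
    repressed = steady_state(params, convention=convention).A_tot
    unrepressed = unrepressed_total(params.k_A, D0, params.gamma_P)
    return RepressionResult(variant=variant, copy_number=copy_number, D0=D0,
                            A_tot_repressed=repressed,
                            A_tot_unrepressed=unrepressed,
                            ratio=unrepressed / repressed)


def ratio_curve(label: str,
                copies=range(1, 61),
                params: KineticParameters | None = None,
                geometry: CellGeometry = CellGeometry(),
                convention: str = CHAIN_STATIONARY,
                warn_non_monotone: bool = True) -> pd.DataFrame:
    """Repression ratio of one variant across a plasmid copy-number range.

    Returns a DataFrame (copy_number, D0, A_tot_repressed, A_tot_unrepressed,
    ratio).  The ratio is expected to grow with copy number; a violation is
    reported as a warning rather than an error.
    """
    params = params if params is not None else make_variant(label)
    rows = []
    for n in copies:
        r = repression_ratio(params, copy_number=n, geometry=geometry,
                             variant=label, convention=convention)
        rows.append({"copy_number": n, "D0": r.D0,
                     "A_tot_repressed": r.A_tot_repressed,
                     "A_tot_unrepressed": r.A_tot_unrepressed,
                     "ratio": r.ratio})
    df = pd.DataFrame(rows)
    if warn_non_monotone and not np.all(np.diff(df["ratio"]) >= -1e-9):
        import warnings
        warnings.warn(f"repression-ratio curve for variant {label!r} is not "
                      "monotone in copy number", RuntimeWarning)
    return df


def crossing_copy_number(curve: pd.DataFrame,
                         threshold: float = REPRESSION_BENCHMARK):
    """Smallest copy number whose ratio meets the threshold, or None."""
    if curve.empty:
        raise ValueError("empty ratio curve")
    hit = curve[curve["ratio"] >= threshold]
    return None if hit.empty else int(hit["copy_number"].iloc[0])


def ensemble_ratio(chain: PosteriorChain,
                   label: str,
                   copies=range(1, 61),
                   thinning: int = 360,
                   burn_in: float = 0.1,
                   geometry: CellGeometry = CellGeometry(),
                   convention: str = CHAIN_STATIONARY) -> pd.DataFrame:
    """Posterior-ensemble repression ratios across copy numbers.

    Every ``thinning``-th post-burn-in sample is treated as an uncorrelated
    parameter set; for each sample and copy number the repression ratio is
    computed, and per copy number a lognormal is fitted to the ensemble by
    log-moments.  Columns: copy_number, mode (of the fitted lognormal), se
    (standard error of the mode via the delta method on the log-mean), n.
    """
    cX, cY = variant_pi(label)
    kept = chain.thinned(burn_in, thinning)
    if kept.shape[0] == 0:
        raise ValueError("no samples left after burn-in and thinning")
    copies = list(copies)
    log_ratios = np.empty((kept.shape[0], len(copies)))
    for i, vec in enumerate(kept):
        fields = dict(zip(chain.names, vec))
        fields["sigma_A"] = fields["sigma_B"] = 0.0
        if cX is not None:
            fields["pi_X"] = cX
        if cY is not None:
            fields["pi_Y"] = cY
        p = KineticParameters(**fields)
        for j, n in enumerate(copies):
            r = repression_ratio(p, copy_number=n, geometry=geometry,
                                 variant=label, convention=convention)
            log_ratios[i, j] = math.log(r.ratio)
    mu = log_ratios.mean(axis=0)
    s = log_ratios.std(axis=0, ddof=1) if kept.shape[0] > 1 else np.zeros(len(copies))
    mode = np.exp(mu - s ** 2)
    se = mode * s / math.sqrt(kept.shape[0])
    return pd.DataFrame({"copy_number": copies, "mode": mode, "se": se,
                         "n": kept.shape[0]})
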
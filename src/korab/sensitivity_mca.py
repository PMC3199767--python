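"""Metabolic control analysis of the operon steady state.

Concentration control coefficients C_p^S = (p/S) dS/dp quantify how the
steady-state total abundances of KorA and KorB respond to each kinetic
parameter.  They are computed as central differences of ln S with respect
to ln p on the steady-state solver, with the step halved until successive
estimates agree; this keeps the calculation robust to the multi-start root
finder while matching an implicit-function-theorem calculation on smooth
cases.

Because the steady state is invariant under a common rescaling of every
time-dimensioned rate (synthesis, monomerization, dimerization, dilution),
the control coefficients of those parameters sum to zero for each output --
a structural check exposed by the test-suite and useful as a consistency
diagnostic on any evaluation point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core_model import (
    CHAIN_STATIONARY,
    KineticParameters,
    SteadyStateError,
    steady_state,
)

__all__ = [
    "MCA_PARAMETERS",
    "RATE_PARAMETERS",
    "ControlCoefficientTable",
    "control_coefficient",
    "coefficient_table",
]

#: Parameters reported in the control-coefficient table (no pi's, no D0).
MCA_PARAMETERS = ("k_A", "k_B", "k1", "k2", "k3", "k4",
                  "sigma_A", "sigma_B", "lambda_A", "lambda_B", "gamma_P")

#: Time-dimensioned rates whose coefficients sum to zero per output.
RATE_PARAMETERS = ("k_A", "k_B", "sigma_A", "sigma_B",
                   "lambda_A", "lambda_B", "gamma_P")

_OUTPUTS = ("A_tot", "B_tot")


def _steady_output(params: KineticParameters, output: str, convention: str) -> float:
    st = steady_state(params, convention=convention)
    return getattr(st, output)


def control_coefficient(params: KineticParameters,
                        param_name: str,
                        output: str = "A_tot",
                        h0: float = 0.1,
                        rtol: float = 1e-4,
                        convention: str = CHAIN_STATIONARY,
                        max_halvings: int = 12) -> float:
    """Concentration control coefficient (p/S) dS/dp at ``params``.

    Central log-log difference [ln S(p e^h) - ln S(p e^-h)] / (2h), with h
    halved from ``h0`` until two successive estimates agree to ``rtol``
    (absolute floor 1e-6 for near-zero coefficients).

    A parameter held at zero (e.g. sigma in the variant models) has no
    multiplicative perturbation; its coefficient is exactly 0 and is
    returned as such.
    """
    if param_name not in MCA_PARAMETERS:
        raise ValueError(f"unknown MCA parameter {param_name!r}")
    if output not in _OUTPUTS:
        raise ValueError(f"output must be one of {_OUTPUTS}, got {output!r}")
    p0 = getattr(params, param_name)
    if p0 == 0.0:
        return 0.0

    def estimate(h: float) -> float:
        up = params.to_dict(); up[param_name] = p0 * math.exp(h)
        dn = params.to_dict(); dn[param_name] = p0 * math.exp(-h)
        try:
            s_up = _steady_output(KineticParameters(**up), output, convention)
            s_dn = _steady_output(KineticParameters(**dn), output, convention)
        except SteadyStateError as exc:
            raise SteadyStateError(
                f"steady state failed while perturbing {param_name} "
                f"(h={h:g}): {exc}") from exc
        return (math.log(s_up) - math.log(s_dn)) / (2.0 * h)

    h = h0
    prev = estimate(h)
    for _ in range(max_halvings):
        h *= 0.5
        cur = estimate(h)
        if abs(cur - prev) <= max(rtol * abs(cur), 1e-6):
            return cur
        prev = cur
    return prev


@dataclass(frozen=True)
class ControlCoefficientTable:
    """Control-coefficient matrix with its evaluation point."""

    coefficients: pd.DataFrame          # rows: outputs, cols: parameters
    classification: pd.DataFrame        # strong / moderate / negligible
    params: KineticParameters = field(repr=False)

    def to_long(self) -> pd.DataFrame:
        long = (self.coefficients.stack().rename("coefficient").reset_index())
        long.columns = ["output", "parameter", "coefficient"]
        long["classification"] = [
            self.classification.loc[o, p] for o, p in
            zip(long["output"], long["parameter"])]
        return long


def coefficient_table(params: KineticParameters,
                      outputs=_OUTPUTS,
                      parameters=MCA_PARAMETERS,
                      thresholds: tuple[float, float] = (0.5, 0.05),
                      convention: str = CHAIN_STATIONARY,
                      **kwargs) -> ControlCoefficientTable:
    """Full table of control coefficients with a magnitude classification.

    ``thresholds=(strong, negligible)``: |C| >= strong is "strong",
    |C| < negligible is "negligible", anything between is "moderate".
    """
    strong, negligible = thresholds
    coef = pd.DataFrame(index=list(outputs), columns=list(parameters),
                        dtype=float)
    for out in outputs:
        for par in parameters:
            coef.loc[out, par] = control_coefficient(
                params, par, out, convention=convention, **kwargs)
    cls = coef.abs().map(
        lambda c: "strong" if c >= strong
        else ("negligible" if c < negligible else "moderate"))
    return ControlCoefficientTable(coefficients=coef, classification=cls,
                                   params=params)
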
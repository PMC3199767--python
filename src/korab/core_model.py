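"""Deterministic core of the RK2 central control operon model.

The central control operon (*cco*) of the broad-host-range plasmid RK2
encodes its own repressors, KorA and KorB, which bind as dimers to operator
sites flanking the korAp promoter and repress it cooperatively.  This module
implements the four-species ODE model of that negative feedback loop:

* ``A1``/``B1`` -- KorA/KorB monomers (nM)
* ``A2``/``B2`` -- KorA/KorB dimers (nM); only dimers bind DNA

Promoter binding is assumed fast compared with protein synthesis and
dilution (quasi-steady state), so at each instant the promoter DNA is
partitioned over four configurations: unoccupied (``D``), KorA-bound
(``X``), KorB-bound (``Y``) and doubly bound (``Z``).  Synthesis proceeds at
full rate from ``D``, at a fraction ``pi_X``/``pi_Y`` of full rate from
``X``/``Y`` (partial repression) and not at all from ``Z``.

The measured dissociation constants violate thermodynamic cycle closure
(``k1*k4 != k2*k3``), so an equilibrium partition is not uniquely defined.
The default partition is therefore the stationary distribution of the
four-state association/dissociation chain ``D <-> X <-> Z <-> Y <-> D`` with
a single association rate constant (which cancels); the two path-equilibrium
conventions are available for comparison and all three coincide whenever the
thermodynamic cycle closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "AVOGADRO",
    "PARAM_NAMES",
    "TABLE_MODES",
    "CHAIN_STATIONARY",
    "PATH_A_FIRST",
    "PATH_B_FIRST",
    "PARTITION_CONVENTIONS",
    "ModelError",
    "SteadyStateError",
    "IntegrationError",
    "CellGeometry",
    "KineticParameters",
    "SpeciesState",
    "PromoterOccupancy",
    "molecules_to_nM",
    "nM_to_molecules",
    "promoter_occupancy",
    "ode_rhs",
    "simulate",
    "steady_state",
    "unrepressed_total",
    "make_mutant",
    "disable_binding",
]

AVOGADRO = 6.02214076e23  # mol^-1

# Partition conventions for the promoter-state distribution.
CHAIN_STATIONARY = "chain_stationary"
PATH_A_FIRST = "path_A_first"  # Z weight A2*B2/(k1*k4)
PATH_B_FIRST = "path_B_first"  # Z weight A2*B2/(k2*k3)
PARTITION_CONVENTIONS = (CHAIN_STATIONARY, PATH_A_FIRST, PATH_B_FIRST)

# Canonical parameter ordering used throughout (sampler vectors, tables).
PARAM_NAMES = (
    "k_A", "k_B",
    "k1", "k2", "k3", "k4",
    "sigma_A", "sigma_B",
    "lambda_A", "lambda_B",
    "gamma_P",
    "pi_X", "pi_Y",
    "D0",
)

# Measured modes of the informative parameters (nM, s^-1, nM^-1 s^-1).
TABLE_MODES = {
    "k1": 12.9,
    "k2": 9.3,
    "k3": 3.1,
    "k4": 3.1,
    "lambda_A": 0.001,
    "lambda_B": 0.001,
    "gamma_P": 0.0003875,
    "D0": 4.5,
}


class ModelError(Exception):
    """Base class for model-level failures."""


class SteadyStateError(ModelError):
    """No steady state could be located."""


class IntegrationError(ModelError):
    """ODE integration failed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """Cell volume used to convert molecule counts to concentrations.

    The default 4.15 um^3 is the estimated E. coli volume in the growth
    phase of the abundance measurements; at this volume one molecule per
    cell is ~0.4 nM and the measured 4000 KorA monomers correspond to
    1600 nM.
    """

    volume: float = 4.15  # um^3

    def __post_init__(self):
        if not (self.volume > 0 and math.isfinite(self.volume)):
            raise ValueError(f"cell volume must be positive, got {self.volume}")

    @property
    def litres(self) -> float:
        return self.volume * 1e-15


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, affinities and scaling factors of one model instance.

    Units: synthesis (``k_A``, ``k_B``), monomerization (``sigma_*``) and
    dilution (``gamma_P``) in s^-1; dimerization (``lambda_*``) in
    nM^-1 s^-1; dissociation constants ``k1``..``k4`` and the promoter DNA
    concentration ``D0`` in nM; ``pi_X``/``pi_Y`` dimensionless in [0, 1].
    """

    k_A: float
    k_B: float
    k1: float = TABLE_MODES["k1"]
    k2: float = TABLE_MODES["k2"]
    k3: float = TABLE_MODES["k3"]
    k4: float = TABLE_MODES["k4"]
    sigma_A: float = 0.0
    sigma_B: float = 0.0
    lambda_A: float = TABLE_MODES["lambda_A"]
    lambda_B: float = TABLE_MODES["lambda_B"]
    gamma_P: float = TABLE_MODES["gamma_P"]
    pi_X: float = 1.0
    pi_Y: float = 1.0
    D0: float = TABLE_MODES["D0"]

    def __post_init__(self):
        for name in ("k_A", "k_B", "sigma_A", "sigma_B", "lambda_A", "lambda_B"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("k1", "k2", "k3", "k4", "D0", "gamma_P"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("pi_X", "pi_Y"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "KineticParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SpeciesState:
    """Monomer and dimer concentrations (nM)."""

    A1: float
    A2: float
    B1: float
    B2: float

    @property
    def A_tot(self) -> float:
        return self.A1 + 2.0 * self.A2

    @property
    def B_tot(self) -> float:
        return self.B1 + 2.0 * self.B2

    def to_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.B1, self.B2], dtype=float)

    @classmethod
    def zero(cls) -> "SpeciesState":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PromoterOccupancy:
    """Fractions of promoter DNA in each binding configuration."""

    fD: float
    fX: float
    fY: float
    fZ: float

    def to_array(self) -> np.ndarray:
        return np.array([self.fD, self.fX, self.fY, self.fZ], dtype=float)

    def concentrations(self, D0: float) -> np.ndarray:
        """Concentrations (nM) of D, X, Y, Z at total DNA ``D0``."""
        return D0 * self.to_array()


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------


def molecules_to_nM(count: float, geometry: CellGeometry = CellGeometry()) -> float:
    """Convert a per-cell molecule count to a concentration in nM."""
    if count < 0:
        raise ValueError(f"molecule count must be >= 0, got {count}")
    return count / (AVOGADRO * geometry.litres) * 1e9


def nM_to_molecules(conc: float, geometry: CellGeometry = CellGeometry()) -> float:
    """Convert a concentration in nM to a per-cell molecule count."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return conc * 1e-9 * AVOGADRO * geometry.litres


# ---------------------------------------------------------------------------
# promoter partition
# ---------------------------------------------------------------------------


def _occupancy(a: float, b: float, k1: float, k2: float, k3: float, k4: float,
               convention: str) -> tuple[float, float, float, float]:
    """Fractions (fD, fX, fY, fZ) for dimer concentrations a=A2, b=B2.

    The chain-stationary weights are the spanning-tree sums of the four-state
    cycle D<->X<->Z<->Y<->D (Markov chain tree theorem); the single
    association rate constant cancels.
    """
    if convention == CHAIN_STATIONARY:
        wD = k1 * k2 * (k3 + k4) + b * k2 * k3 + a * k1 * k4
        wX = a * (k2 * (k3 + k4) + k4 * (a + b))
        wY = b * (k1 * (k3 + k4) + k3 * (a + b))
        wZ = a * b * (a + b + k1 + k2)
    elif convention == PATH_A_FIRST:
        wD = 1.0
        wX = a / k1
        wY = b / k2
        wZ = a * b / (k1 * k4)
    elif convention == PATH_B_FIRST:
        wD = 1.0
        wX = a / k1
        wY = b / k2
        wZ = a * b / (k2 * k3)
    else:
        raise ValueError(f"unknown partition convention {convention!r}")
    s = wD + wX + wY + wZ
    return wD / s, wX / s, wY / s, wZ / s


def promoter_occupancy(A2: float, B2: float, params: KineticParameters,
                       convention: str = CHAIN_STATIONARY) -> PromoterOccupancy:
    """Quasi-steady-state partition of promoter DNA over D, X, Y, Z.

    ``A2``/``B2`` are free dimer concentrations (nM).  Fractions sum to 1.
    """
    for name, v in (("A2", A2), ("B2", B2)):
        if not (math.isfinite(v) and v >= 0):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    fD, fX, fY, fZ = _occupancy(A2, B2, params.k1, params.k2, params.k3,
                                params.k4, convention)
    return PromoterOccupancy(fD, fX, fY, fZ)


def _synthesis_fraction(a, b, k1, k2, k3, k4, pi_X, pi_Y, convention):
    """phi = fD + pi_X*fX + pi_Y*fY, the promoter activity in [0, 1]."""
    fD, fX, fY, _ = _occupancy(a, b, k1, k2, k3, k4, convention)
    return fD + pi_X * fX + pi_Y * fY


# ---------------------------------------------------------------------------
# ODE right-hand side and time integration
# ---------------------------------------------------------------------------


def _rhs(A1, A2, B1, B2, p: KineticParameters, convention):
    phi = _synthesis_fraction(A2, B2, p.k1, p.k2, p.k3, p.k4,
                              p.pi_X, p.pi_Y, convention)
    synth = phi * p.D0
    dA1 = synth * p.k_A + 2.0 * p.sigma_A * A2 - p.lambda_A * A1 * A1 - p.gamma_P * A1
    dA2 = 0.5 * p.lambda_A * A1 * A1 - p.sigma_A * A2 - p.gamma_P * A2
    dB1 = synth * p.k_B + 2.0 * p.sigma_B * B2 - p.lambda_B * B1 * B1 - p.gamma_P * B1
    dB2 = 0.5 * p.lambda_B * B1 * B1 - p.sigma_B * B2 - p.gamma_P * B2
    return dA1, dA2, dB1, dB2


def ode_rhs(state: SpeciesState, params: KineticParameters,
            convention: str = CHAIN_STATIONARY) -> SpeciesState:
    """Time derivative of the four species (nM/s), as a ``SpeciesState``.

    Synthesis of both proteins is driven by the shared promoter activity
    ``fD + pi_X*fX + pi_Y*fY`` (the operon is co-transcribed), dimers form
    at ``lambda/2 * monomer^2`` and dissociate at ``sigma``, and every
    species is diluted at ``gamma_P``.
    """
    for name in ("A1", "A2", "B1", "B2"):
        v = getattr(state, name)
        if not (math.isfinite(v) and v >= 0):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    return SpeciesState(*_rhs(state.A1, state.A2, state.B1, state.B2,
                              params, convention))


def simulate(params: KineticParameters,
             initial: SpeciesState | None = None,
             t_end: float = 6.0e4,
             reltol: float = 1e-8,
             abstol: float = 1e-10,
             n_points: int = 200,
             convention: str = CHAIN_STATIONARY) -> pd.DataFrame:
    """Integrate the ODEs from ``initial`` (default: empty cell) to ``t_end``.

    Returns a DataFrame with columns t, A1, A2, B1, B2, A_tot, B_tot and the
    instantaneous promoter fractions fD, fX, fY, fZ.  Uses a stiff-capable
    solver; t_end defaults to many dilution half-lives so the endpoint is
    effectively the attracting fixed point.
    """
    if not (t_end > 0):
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if not (reltol > 0 and abstol > 0):
        raise ValueError("tolerances must be > 0")
    y0 = (initial or SpeciesState.zero()).to_array()

    def f(_t, y):
        return _rhs(y[0], y[1], y[2], y[3], params, convention)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(f, (0.0, t_end), y0, method="LSODA", rtol=reltol,
                    atol=abstol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    A1, A2, B1, B2 = sol.y
    occ = np.array([_occupancy(a2, b2, params.k1, params.k2, params.k3,
                               params.k4, convention)
                    for a2, b2 in zip(A2, B2)])
    return pd.DataFrame({
        "t": sol.t, "A1": A1, "A2": A2, "B1": B1, "B2": B2,
        "A_tot": A1 + 2 * A2, "B_tot": B1 + 2 * B2,
        "fD": occ[:, 0], "fX": occ[:, 1], "fY": occ[:, 2], "fZ": occ[:, 3],
    })


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------
#
# At any fixed point the dimer balance gives A2 = lambda_A*A1^2/(2(sigma_A+gamma_P))
# (and likewise for B), so the 4-D root problem reduces exactly to two
# equations in (A1, B1):
#
#   g_A(A1, B1) = phi(A2(A1), B2(B1)) * D0 * k_A - gamma_P * (A1 + 2*A2(A1)) = 0
#   g_B(A1, B1) = phi(A2(A1), B2(B1)) * D0 * k_B - gamma_P * (B1 + 2*B2(B1)) = 0
#
# phi is non-increasing in each dimer concentration (repressors only reduce
# synthesis), so each g is strictly decreasing in its own variable, which
# makes nested bracketing/bisection globally reliable; a damped Newton on
# (log A1, log B1) is used as the fast path.


def _reduced_residuals(lnA1, lnB1, p: KineticParameters, convention):
    A1 = math.exp(lnA1)
    B1 = math.exp(lnB1)
    A2 = p.lambda_A * A1 * A1 / (2.0 * (p.sigma_A + p.gamma_P))
    B2 = p.lambda_B * B1 * B1 / (2.0 * (p.sigma_B + p.gamma_P))
    phi = _synthesis_fraction(A2, B2, p.k1, p.k2, p.k3, p.k4,
                              p.pi_X, p.pi_Y, convention)
    gA = phi * p.D0 * p.k_A - p.gamma_P * (A1 + 2.0 * A2)
    gB = phi * p.D0 * p.k_B - p.gamma_P * (B1 + 2.0 * B2)
    return gA, gB


def _monomer_from_total(tot, lam, sigma, gamma):
    """A1 solving A1 + lambda*A1^2/(sigma+gamma) = tot (positive root)."""
    if tot <= 0:
        return 0.0
    c = lam / (sigma + gamma)
    if c == 0:
        return tot
    return (math.sqrt(1.0 + 4.0 * c * tot) - 1.0) / (2.0 * c)


def _state_from_monomers(A1, B1, p: KineticParameters) -> SpeciesState:
    A2 = p.lambda_A * A1 * A1 / (2.0 * (p.sigma_A + p.gamma_P))
    B2 = p.lambda_B * B1 * B1 / (2.0 * (p.sigma_B + p.gamma_P))
    return SpeciesState(A1, A2, B1, B2)


def _newton_2d(p: KineticParameters, lnA1, lnB1, convention,
               tol=1e-11, max_iter=60):
    """Damped Newton on (ln A1, ln B1); returns (lnA1, lnB1) or None."""
    scaleA = p.gamma_P * p.D0 * p.k_A + 1e-300
    scaleB = p.gamma_P * p.D0 * p.k_B + 1e-300
    gA, gB = _reduced_residuals(lnA1, lnB1, p, convention)
    err = abs(gA) / scaleA + abs(gB) / scaleB
    for _ in range(max_iter):
        if err < tol:
            return lnA1, lnB1
        h = 1e-7
        gA_a, gB_a = _reduced_residuals(lnA1 + h, lnB1, p, convention)
        gA_b, gB_b = _reduced_residuals(lnA1, lnB1 + h, p, convention)
        j11 = (gA_a - gA) / h
        j12 = (gA_b - gA) / h
        j21 = (gB_a - gB) / h
        j22 = (gB_b - gB) / h
        det = j11 * j22 - j12 * j21
        if det == 0 or not math.isfinite(det):
            return None
        dA = -(gA * j22 - gB * j12) / det
        dB = -(j11 * gB - j21 * gA) / det
        # cap the log step; damp until the residual decreases
        mag = max(abs(dA), abs(dB))
        if mag > 5.0:
            dA *= 5.0 / mag
            dB *= 5.0 / mag
        step = 1.0
        for _ls in range(30):
            nA, nB = lnA1 + step * dA, lnB1 + step * dB
            gA_n, gB_n = _reduced_residuals(nA, nB, p, convention)
            err_n = abs(gA_n) / scaleA + abs(gB_n) / scaleB
            if err_n < err or err_n < tol:
                lnA1, lnB1, gA, gB, err = nA, nB, gA_n, gB_n, err_n
                break
            step *= 0.5
        else:
            # line search stalled at the floating-point noise floor
            return (lnA1, lnB1) if err < 1e-9 else None
    return (lnA1, lnB1) if err < 1e-9 else None


def _solve_A_given_B(p: KineticParameters, lnB1, convention):
    """Inner 1-D solve: ln A1 with g_A = 0 at fixed B1 (g_A is decreasing)."""
    totA_max = p.D0 * p.k_A / p.gamma_P
    hi = math.log(_monomer_from_total(totA_max, p.lambda_A, p.sigma_A,
                                      p.gamma_P)) + 1e-9
    lo = hi - 80.0

    def f(lnA1):
        return _reduced_residuals(lnA1, lnB1, p, convention)[0]

    flo, fhi = f(lo), f(hi)
    if flo <= 0:  # root below the scanned window; extend down
        for _ in range(8):
            hi, fhi = lo, flo
            lo -= 80.0
            flo = f(lo)
            if flo > 0:
                break
        else:
            raise SteadyStateError("could not bracket the KorA monomer root")
    if fhi > 0:
        return hi  # unrepressed edge case: root at the closed-form total
    return brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)


def _enumerate_roots(p: KineticParameters, convention, n_grid=48):
    """Scan the outer residual h(B1) = g_B(A1*(B1), B1) for sign changes."""
    totB_max = p.D0 * p.k_B / p.gamma_P
    hi = math.log(_monomer_from_total(totB_max, p.lambda_B, p.sigma_B,
                                      p.gamma_P)) + 1e-9
    lo = hi - 60.0

    def h(lnB1):
        lnA1 = _solve_A_given_B(p, lnB1, convention)
        return _reduced_residuals(lnA1, lnB1, p, convention)[1]

    grid = np.linspace(lo, hi, n_grid)
    vals = [h(g) for g in grid]
    roots = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=1e-13,
                                rtol=8.9e-16))
    if vals[-1] >= 0:  # root pinned at the unrepressed edge
        roots.append(grid[-1])
    states = []
    for lnB1 in roots:
        lnA1 = _solve_A_given_B(p, lnB1, convention)
        states.append(_state_from_monomers(math.exp(lnA1), math.exp(lnB1), p))
    return states


def _dedupe_states(states, rtol=1e-3):
    kept: list[SpeciesState] = []
    for s in states:
        for k in kept:
            if (abs(s.A_tot - k.A_tot) <= rtol * max(k.A_tot, 1e-12)
                    and abs(s.B_tot - k.B_tot) <= rtol * max(k.B_tot, 1e-12)):
                break
        else:
            kept.append(s)
    return kept


def steady_state(params: KineticParameters,
                 convention: str = CHAIN_STATIONARY,
                 starts: str = "auto",
                 return_info: bool = False):
    """Locate the steady state of the model.

    ``starts="auto"`` tries a damped Newton from heuristic seeds (the
    unrepressed closed form scaled by 1, 1/10, 1/100) and falls back to a
    bracketing scan; ``starts="scan"`` enumerates roots exhaustively over
    the admissible range.  If distinct roots are found, the one reached by
    integrating from the empty cell is returned as canonical and the
    multiplicity is reported in the info dict.
    """
    p = params
    # boundary cases: a protein with zero synthesis vanishes at steady state
    if p.k_A == 0.0 and p.k_B == 0.0:
        st = SpeciesState.zero()
        return (st, {"n_roots": 1, "multiple": False}) if return_info else st
    if p.k_A == 0.0 or p.k_B == 0.0:
        # absent partner: exact 1-D problem with the other species at zero
        present = "B" if p.k_A == 0.0 else "A"
        k_syn = p.k_B if present == "B" else p.k_A
        lam = p.lambda_B if present == "B" else p.lambda_A
        sig = p.sigma_B if present == "B" else p.sigma_A
        tot_max = p.D0 * k_syn / p.gamma_P
        hi = math.log(_monomer_from_total(tot_max, lam, sig, p.gamma_P)) + 1e-9

        def g1(ln1):
            m1 = math.exp(ln1)
            d2 = lam * m1 * m1 / (2.0 * (sig + p.gamma_P))
            a2, b2 = (0.0, d2) if present == "B" else (d2, 0.0)
            phi = _synthesis_fraction(a2, b2, p.k1, p.k2, p.k3, p.k4,
                                      p.pi_X, p.pi_Y, convention)
            return phi * p.D0 * k_syn - p.gamma_P * (m1 + 2.0 * d2)

        lo = hi - 80.0
        if g1(hi) > 0:
            ln1 = hi
        else:
            ln1 = brentq(g1, lo, hi, xtol=1e-13, rtol=8.9e-16)
        m1 = math.exp(ln1)
        st = (_state_from_monomers(0.0, m1, p) if present == "B"
              else _state_from_monomers(m1, 0.0, p))
        return (st, {"n_roots": 1, "multiple": False}) if return_info else st

    found: list[SpeciesState] = []
    if starts == "auto":
        totA = p.D0 * p.k_A / p.gamma_P
        totB = p.D0 * p.k_B / p.gamma_P
        for frac in (1.0, 0.1, 0.01):
            a0 = _monomer_from_total(frac * totA, p.lambda_A, p.sigma_A, p.gamma_P)
            b0 = _monomer_from_total(frac * totB, p.lambda_B, p.sigma_B, p.gamma_P)
            sol = _newton_2d(p, math.log(a0), math.log(b0), convention)
            if sol is not None:
                found.append(_state_from_monomers(math.exp(sol[0]),
                                                  math.exp(sol[1]), p))
        found = _dedupe_states(found)
    if not found or starts == "scan":
        found = _dedupe_states(_enumerate_roots(p, convention))
    if not found:
        raise SteadyStateError("no steady state found from any start")

    multiple = len(found) > 1
    if multiple:
        # canonical root: the one the empty cell relaxes to
        traj = simulate(p, t_end=30.0 / p.gamma_P, n_points=5,
                        convention=convention)
        end = traj.iloc[-1]
        found.sort(key=lambda s: abs(s.A_tot - end.A_tot) + abs(s.B_tot - end.B_tot))
    st = found[0]
    if return_info:
        return st, {"n_roots": len(found), "multiple": multiple,
                    "roots": found}
    return st


def unrepressed_total(k_syn: float, D0: float, gamma_P: float) -> float:
    """Steady-state total monomers (nM) when no repressor can bind.

    With all promoter DNA permanently unoccupied, synthesis is ``D0*k_syn``
    and the only loss is dilution of total monomers, so the closed form is
    ``D0*k_syn/gamma_P`` (dimerization merely repartitions monomers).
    """
    if k_syn < 0 or D0 < 0:
        raise ValueError("k_syn and D0 must be >= 0")
    if gamma_P <= 0:
        raise ValueError(f"gamma_P must be > 0, got {gamma_P}")
    return D0 * k_syn / gamma_P


def make_mutant(params: KineticParameters) -> KineticParameters:
    """Cooperativity-knockout variant: bind-to-complex affinities revert to
    the naked-DNA values (k3 := k1, k4 := k2).

    Models the tyrosine-84 KorA mutant in which the KorA-KorB interaction
    is abolished; the resulting cycle satisfies detailed balance exactly.
    """
    return replace(params, k3=params.k1, k4=params.k2)


def disable_binding(params: KineticParameters,
                    factor: float = 1e16) -> KineticParameters:
    """Variant with operator binding effectively abolished (huge Kd's),
    so the steady state approaches the unrepressed closed form."""
    return replace(params, k1=factor, k2=factor, k3=factor, k4=factor)
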
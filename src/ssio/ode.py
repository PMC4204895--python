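"""Sigmoid transcription kinetics, the network ODE right-hand side, stiff
integration and equilibrium finding.

Each gene i evolves as dY_i/dt = F_i(A_i) − d_i·Y_i, where A_i is the
signed weighted sum of its regulators' levels (genes and external signals)
and F_i is a saturating sigmoid bounded by the maximal rate k1.  Genes with
no regulators transcribe at a constant basal rate.  mRNA decay is
first-order.  The system is stiff on realistic parameter sets, so the
default integrator is the BDF (Gear-type implicit multistep) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import (
    EquilibriumNotFoundError,
    IntegrationError,
    InvalidKineticsError,
    MissingRegulatorError,
)
from .network import (
    GeneKinetics,
    RegulatoryNetwork,
    SignalSchedule,
    WeightVector,
)


@dataclass
class ModelState:
    """Expression levels of all genes at one instant."""

    t: float
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("non-finite state levels")


# ---------------------------------------------------------------------------
# Rate laws

def transcription_rate(
    kin: GeneKinetics, A: float, dominant_negative: bool | str = "auto"
) -> float:
    """Sigmoid transcription rate F(A), bounded in (0, k1).

    Canonical form F(A) = k1 / (1 + k2·e^(−k3·A)).  When repressors
    dominate the combined input (A < 0) the reflected form
    k1·k2·e^(k3·A) / (1 + k2·e^(k3·A)) applies, decaying to 0 as A → −∞.
    ``dominant_negative`` may be True/False to force a branch, or "auto"
    to select the reflected branch exactly when A < 0.
    """
    if min(kin.k1, kin.k2, kin.k3, kin.d) <= 0:
        raise InvalidKineticsError(f"non-positive kinetics {kin}")
    use_reflected = (A < 0) if dominant_negative == "auto" else bool(dominant_negative)
    z = kin.k3 * A
    if use_reflected:
        # k1*k2*e^z/(1+k2*e^z) == k1/(1 + e^{-z}/k2): same sigmoid, k2 -> 1/k2
        if z > 0:
            return kin.k1 / (1.0 + np.exp(-z) / kin.k2)
        e = kin.k2 * np.exp(z)
        return kin.k1 * e / (1.0 + e)
    if z < 0:
        e = np.exp(z)
        return kin.k1 * e / (e + kin.k2)
    return kin.k1 / (1.0 + kin.k2 * np.exp(-z))


def constitutive_rate(kin: GeneKinetics) -> float:
    """Basal transcription rate of an unregulated gene: k1/(1+k2)."""
    if min(kin.k1, kin.k2, kin.k3, kin.d) <= 0:
        raise InvalidKineticsError(f"non-positive kinetics {kin}")
    return kin.k1 / (1.0 + kin.k2)


def combine_regulators(
    weights: WeightVector,
    target: str,
    levels: dict[str, float],
    signals: dict[str, float] | None = None,
) -> float:
    """Signed weighted sum A = Σ q_ij·X_ij over the target's regulators."""
    signals = signals or {}
    A = 0.0
    found = False
    for (tgt, src), q in weights.entries.items():
        if tgt != target:
            continue
        found = True
        if src in levels:
            A += q * levels[src]
        elif src in signals:
            A += q * signals[src]
        else:
            raise MissingRegulatorError(f"no level for regulator {src!r} of {target!r}")
    if not found:
        return 0.0
    return A


# ---------------------------------------------------------------------------
# Compiled dynamics

class GRNDynamics:
    """Network + parameters compiled to index arrays for fast RHS evaluation.

    Regulator weights sourced from ``net.zero_weight_sources`` are forced
    to zero at compile time (e.g. human GATA2).
    """

    def __init__(
        self,
        net: RegulatoryNetwork,
        weights: WeightVector,
        kinetics: dict[str, GeneKinetics],
        schedule: SignalSchedule | None = None,
    ):
        self.net = net
        self.weights = weights
        self.kinetics = kinetics
        self.schedule = schedule or SignalSchedule.silent(net.signals)
        self.genes = list(net.genes)
        self._gi = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        self.k1 = np.array([kinetics[g].k1 for g in self.genes])
        self.k2 = np.array([kinetics[g].k2 for g in self.genes])
        self.k3 = np.array([kinetics[g].k3 for g in self.genes])
        self.d = np.array([kinetics[g].d for g in self.genes])
        # per gene: (gene-regulator indices, their q), (signal ids, their q)
        self._greg: list[tuple[np.ndarray, np.ndarray]] = []
        self._sreg: list[tuple[list[str], np.ndarray]] = []
        self.regulated = np.zeros(n, dtype=bool)
        for i, g in enumerate(self.genes):
            gidx, gq, sids, sq = [], [], [], []
            for r in net.regulators_of(g):
                q = weights.entries.get((g, r.source), 0.0)
                if r.source in net.zero_weight_sources:
                    q = 0.0
                if r.source in self._gi:
                    gidx.append(self._gi[r.source])
                    gq.append(q)
                else:
                    sids.append(r.source)
                    sq.append(q)
                self.regulated[i] = True
            self._greg.append((np.array(gidx, dtype=int), np.array(gq)))
            self._sreg.append((sids, np.array(sq)))

    def combined_inputs(self, t: float, y: np.ndarray) -> np.ndarray:
        """A_i for every gene at time t and state y."""
        sig = {s: self.schedule.level(s, t) for s in self.net.signals}
        A = np.zeros(len(self.genes))
        for i in range(len(self.genes)):
            gidx, gq = self._greg[i]
            if gidx.size:
                A[i] += gq @ y[gidx]
            sids, sq = self._sreg[i]
            for s, q in zip(sids, sq):
                A[i] += q * sig[s]
        return A

    def rates(self, t: float, y: np.ndarray) -> np.ndarray:
        """Transcription rate F_i for every gene."""
        A = self.combined_inputs(t, y)
        z = self.k3 * A
        z = np.clip(z, -500.0, 500.0)
        pos = A >= 0
        F = np.empty_like(A)
        # canonical branch (A >= 0), computed overflow-safely
        ez = np.exp(-np.abs(z))
        F[pos] = self.k1[pos] / (1.0 + self.k2[pos] * ez[pos])
        # reflected branch (A < 0): k1/(1 + e^{-z}/k2)
        neg = ~pos
        e = self.k2[neg] * ez[neg]  # k2 * e^{z}, z<0
        F[neg] = self.k1[neg] * e / (1.0 + e)
        # constitutive genes transcribe at the A=0 basal rate
        cons = ~self.regulated
        F[cons] = self.k1[cons] / (1.0 + self.k2[cons])
        return F

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.rates(t, y) - self.d * y

    def state_levels(self, y: np.ndarray) -> dict[str, float]:
        return {g: float(y[i]) for g, i in self._gi.items()}


def rhs(
    state: ModelState,
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    schedule: SignalSchedule | None = None,
) -> np.ndarray:
    """dY/dt at ``state`` (convenience wrapper over :class:`GRNDynamics`)."""
    dyn = GRNDynamics(net, weights, kinetics, schedule)
    return dyn.rhs(state.t, state.levels)


# ---------------------------------------------------------------------------
# Integration

def simulate(
    initial: ModelState,
    t_grid: np.ndarray,
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    schedule: SignalSchedule | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "BDF",
) -> np.ndarray:
    """Integrate the network ODEs, returning levels at ``t_grid``.

    Uses a Gear-type implicit multistep (BDF) solver by default.  Output
    levels are floored at 0 (tiny negative solver excursions are clamped
    in the report only, never fed back into the solver state).
    Returns an array of shape ``(len(t_grid), n_genes)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise IntegrationError("t_grid must be increasing")
    if abs(t_grid[0] - initial.t) > 1e-12:
        raise IntegrationError("t_grid must start at the initial state's time")
    dyn = GRNDynamics(net, weights, kinetics, schedule)
    if t_grid.size == 1:
        return np.maximum(initial.levels[None, :], 0.0)
    sol = solve_ivp(
        dyn.rhs,
        (t_grid[0], t_grid[-1]),
        initial.levels,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    return np.maximum(sol.y.T, 0.0)


def find_equilibrium(
    initial: ModelState,
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    schedule: SignalSchedule | None = None,
    horizon: float = 100.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Steady-state levels reached from ``initial``.

    Integrates over an adequately long horizon (default 100 days), then
    polishes the endpoint by trust-region root finding on the autonomous
    RHS.  The result satisfies ‖dY/dt‖∞ < ``tol``; otherwise
    :class:`EquilibriumNotFoundError` is raised.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    dyn = GRNDynamics(net, weights, kinetics, schedule)
    t_end = initial.t + horizon
    sol = solve_ivp(
        dyn.rhs,
        (initial.t, t_end),
        initial.levels,
        method="BDF",
        rtol=1e-6,
        atol=1e-8,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    endpoint = np.maximum(sol.y[:, -1], 0.0)
    res = least_squares(
        lambda y: dyn.rhs(t_end, y),
        endpoint,
        method="trf",
        bounds=(0.0, np.inf),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    resid = np.max(np.abs(dyn.rhs(t_end, res.x)))
    if resid >= tol:
        raise EquilibriumNotFoundError(
            f"||rhs||_inf = {resid:.3e} >= {tol} after polishing"
        )
    return res.x
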
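"""Synthetic networks, parameters and noisy expression time courses.

The generators emulate the statistical structure of short differentiation
time courses: few timepoints (4–9, down to mouse-style day −2/0/2/7
grids), expression in arbitrary units floored at 20, trajectories produced
by the sigmoid-kinetics ODE model, and multiplicative log-normal noise.
Four curated recovery cases with known ground truth exercise the whole
pipeline without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .expression import ExpressionSeries, truncate_floor
from .network import (
    ACTIVATION,
    REPRESSION,
    GeneKinetics,
    Regulation,
    RegulatoryNetwork,
    SignalProfile,
    SignalSchedule,
    WeightVector,
)
from .ode import GRNDynamics, ModelState, simulate


@dataclass
class SyntheticSpec:
    """Knobs of the random generators (defaults emulate the study data)."""

    n_genes: int = 5
    edge_density: float = 0.3
    fraction_repressors: float = 0.25
    timepoints: list[float] = field(
        default_factory=lambda: [-2.0, 0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 14.0]
    )
    noise_cv: float = 0.1
    floor: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_density <= 1.0:
            raise ConfigError("edge_density must be in (0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ConfigError("timepoints must be increasing")


def generate_network(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Random signed network at the requested edge density.

    Each ordered non-self gene pair becomes an edge with probability
    ``edge_density``.  When the draw leaves no constitutive gene (and the
    network is not fully dense), the incoming edges of ``G1`` are dropped
    so the system keeps an exogenous driver.  Deterministic in
    ``spec.seed``.
    """
    if spec.n_genes < 2:
        raise ConfigError("need >= 2 genes")
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1}" for i in range(spec.n_genes)]
    regs: list[Regulation] = []
    for src in genes:
        for tgt in genes:
            if src == tgt:
                continue
            if rng.random() <= spec.edge_density:
                sign = (
                    REPRESSION
                    if rng.random() < spec.fraction_repressors
                    else ACTIVATION
                )
                regs.append(Regulation(src, tgt, sign))
    targets = {r.target for r in regs}
    if spec.edge_density < 1.0 and all(g in targets for g in genes):
        regs = [r for r in regs if r.target != genes[0]]
    if not regs:
        raise ConfigError(
            f"edge_density {spec.edge_density} produced no edges at seed {spec.seed}"
        )
    return RegulatoryNetwork(
        genes=genes, regulations=regs, name=f"synthetic-{spec.n_genes}g-seed{spec.seed}"
    )


def generate_timeseries(
    net: RegulatoryNetwork,
    kinetics: dict[str, GeneKinetics],
    weights: WeightVector,
    spec: SyntheticSpec,
    schedule: SignalSchedule | None = None,
    initial_levels: np.ndarray | None = None,
) -> ExpressionSeries:
    """Simulate the model and corrupt it with multiplicative noise.

    The initial state defaults to a seeded uniform draw on [floor, 2·floor]
    per gene.  Noise is log-normal with unit mean and coefficient of
    variation ``spec.noise_cv`` (respecting positivity of expression);
    the result is floor-truncated and sampled at ``spec.timepoints``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    t = np.asarray(spec.timepoints, dtype=float)
    if initial_levels is None:
        initial_levels = spec.floor * (1.0 + rng.random(len(net.genes)))
    traj = simulate(
        ModelState(t=t[0], levels=np.asarray(initial_levels, float)),
        t,
        net,
        weights,
        kinetics,
        schedule,
    )
    values = traj.T  # gene x time
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
        values = values * noise
    return ExpressionSeries(
        gene_ids=list(net.genes),
        times=t,
        values=truncate_floor(values, spec.floor),
        floor=spec.floor,
    )


# ---------------------------------------------------------------------------
# Curated recovery cases

@dataclass
class RecoveryCase:
    """A generated instance with ground truth for pipeline tests."""

    name: str
    network: RegulatoryNetwork
    kinetics: dict[str, GeneKinetics]
    weights: WeightVector
    schedule: SignalSchedule
    series: ExpressionSeries
    spec: SyntheticSpec
    truth: dict


def _cascade3() -> RecoveryCase:
    """Three-gene cascade G1 → G2 → G3 (G1 also feeds G3 directly).

    Noiseless, 20 timepoints over 10 days, expression in the tens-to-
    hundreds with floor 20.  Truth: all regulation signs positive and the
    per-target weight ranking of G3 (G1 above G2).
    """
    net = RegulatoryNetwork(
        genes=["G1", "G2", "G3"],
        regulations=[
            Regulation("G1", "G2", ACTIVATION),
            Regulation("G1", "G3", ACTIVATION),
            Regulation("G2", "G3", ACTIVATION),
        ],
        name="cascade3",
    )
    kinetics = {
        "G1": GeneKinetics(k1=200.0, k2=1.0, k3=1.0, d=0.5),
        "G2": GeneKinetics(k1=150.0, k2=5.0, k3=1.0, d=0.4),
        "G3": GeneKinetics(k1=120.0, k2=3.0, k3=1.0, d=0.3),
    }
    weights = WeightVector(
        {
            ("G2", "G1"): 0.02,
            ("G3", "G1"): 0.015,
            ("G3", "G2"): 0.005,
        }
    )
    spec = SyntheticSpec(
        n_genes=3,
        timepoints=list(np.linspace(0.0, 10.0, 20)),
        noise_cv=0.0,
        floor=20.0,
        seed=20,
    )
    schedule = SignalSchedule.silent([])
    series = generate_timeseries(
        net, kinetics, weights, spec, schedule, initial_levels=np.array([40.0, 30.0, 25.0])
    )
    return RecoveryCase(
        name="cascade3",
        network=net,
        kinetics=kinetics,
        weights=weights,
        schedule=schedule,
        series=series,
        spec=spec,
        truth={
            "signs": {k: np.sign(v) for k, v in weights.entries.items()},
            "rank_G3": ["G1", "G2"],
        },
    )


def _feedback_bistable2() -> RecoveryCase:
    """Two genes in mutual activation — a bistable switch.

    At the reference parameters the 1-D reduced fixed-point map has
    exactly two stable roots (verified by brute-force enumeration, see
    :func:`count_fixed_points_2gene`); raising G1's maximal rate k1 past
    a saddle-node removes the low state.
    """
    net = RegulatoryNetwork(
        genes=["G1", "G2"],
        regulations=[
            Regulation("G2", "G1", ACTIVATION),
            Regulation("G1", "G2", ACTIVATION),
        ],
        name="feedback_bistable2",
    )
    kinetics = {
        "G1": GeneKinetics(k1=300.0, k2=60.0, k3=0.04, d=1.0),
        "G2": GeneKinetics(k1=300.0, k2=60.0, k3=0.04, d=1.0),
    }
    weights = WeightVector({("G1", "G2"): 1.0, ("G2", "G1"): 1.0})
    spec = SyntheticSpec(
        n_genes=2,
        timepoints=list(np.linspace(0.0, 8.0, 9)),
        noise_cv=0.0,
        floor=1.0,
        seed=21,
    )
    schedule = SignalSchedule.silent([])
    series = generate_timeseries(
        net, kinetics, weights, spec, schedule, initial_levels=np.array([5.0, 5.0])
    )
    return RecoveryCase(
        name="feedback_bistable2",
        network=net,
        kinetics=kinetics,
        weights=weights,
        schedule=schedule,
        series=series,
        spec=spec,
        truth={"n_stable_states": 2, "low_init": [1.0, 1.0], "high_init": [300.0, 300.0]},
    )


def _adipo_mini5() -> RecoveryCase:
    """Five-gene mini differentiation motif with a stimulus schedule.

    U is a constitutive driver; B is driven by the cAMP signal, U and a
    feedback from P; A ← {B, P}; P ← {B, A}; R is repressed by B.  The
    transient signal drives B high, B pushes the mutually-activating A↔P
    pair past its basin boundary, and the latched P holds B high after
    signal withdrawal; without the signal all three markers stay low.
    Truth: the reference parameters are behavioral.
    """
    net = RegulatoryNetwork(
        genes=["U", "B", "A", "P", "R"],
        regulations=[
            Regulation("U", "B", ACTIVATION),
            Regulation("cAMP", "B", ACTIVATION),
            Regulation("P", "B", ACTIVATION),
            Regulation("B", "A", ACTIVATION),
            Regulation("P", "A", ACTIVATION),
            Regulation("B", "P", ACTIVATION),
            Regulation("A", "P", ACTIVATION),
            Regulation("B", "R", REPRESSION),
        ],
        signals=["cAMP"],
        name="adipo_mini5",
    )
    kinetics = {
        "U": GeneKinetics(k1=100.0, k2=1.0, k3=1.0, d=0.5),
        "B": GeneKinetics(k1=200.0, k2=30.0, k3=0.03, d=0.8),
        "A": GeneKinetics(k1=250.0, k2=200.0, k3=0.08, d=0.5),
        "P": GeneKinetics(k1=250.0, k2=200.0, k3=0.08, d=0.5),
        "R": GeneKinetics(k1=80.0, k2=0.5, k3=0.05, d=0.5),
    }
    weights = WeightVector(
        {
            ("B", "U"): 0.2,
            ("B", "cAMP"): 1.0,
            ("B", "P"): 0.5,
            ("A", "B"): 0.5,
            ("A", "P"): 0.5,
            ("P", "B"): 0.5,
            ("P", "A"): 0.5,
            ("R", "B"): -0.4,
        }
    )
    schedule = SignalSchedule(
        {"cAMP": SignalProfile(0.0, 3.0, 150.0, 0.0, "decreasing")}
    )
    spec = SyntheticSpec(
        n_genes=5,
        timepoints=[-2.0, 0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 14.0],
        noise_cv=0.0,
        floor=20.0,
        seed=22,
    )
    series = generate_timeseries(
        net,
        kinetics,
        weights,
        spec,
        schedule,
        initial_levels=np.array([150.0, 30.0, 25.0, 25.0, 60.0]),
    )
    return RecoveryCase(
        name="adipo_mini5",
        network=net,
        kinetics=kinetics,
        weights=weights,
        schedule=schedule,
        series=series,
        spec=spec,
        truth={"behavioral": True, "markers": ["B", "A", "P"]},
    )


def _model1_like15() -> RecoveryCase:
    """The built-in 15-gene core topology with invented parameters.

    A synthetic end-to-end smoke instance: the kinetics and weights are
    generated values on realistic scales, NOT fitted values from any real
    adipogenesis dataset.
    """
    from .network import build_adipogenesis_network, default_signal_schedule

    net = build_adipogenesis_network("model1", "mouse")
    rng = np.random.default_rng(15)
    kinetics: dict[str, GeneKinetics] = {}
    entries: dict[tuple[str, str], float] = {}
    for g in net.genes:
        kinetics[g] = GeneKinetics(
            k1=float(rng.uniform(100.0, 400.0)),
            k2=float(rng.uniform(1.0, 20.0)),
            k3=float(rng.uniform(0.005, 0.02)),
            d=float(rng.uniform(0.3, 0.9)),
        )
    for r in net.regulations:
        mag = float(rng.uniform(0.05, 0.5))
        entries[(r.target, r.source)] = r.sign * mag
    weights = WeightVector(entries)
    schedule = default_signal_schedule("mouse", intensity=100.0)
    spec = SyntheticSpec(
        n_genes=15,
        timepoints=[-2.0, 0.0, 2.0, 7.0],
        noise_cv=0.1,
        floor=20.0,
        seed=23,
    )
    series = generate_timeseries(
        net,
        kinetics,
        weights,
        spec,
        schedule,
        initial_levels=rng.uniform(20.0, 200.0, len(net.genes)),
    )
    return RecoveryCase(
        name="model1_like15",
        network=net,
        kinetics=kinetics,
        weights=weights,
        schedule=schedule,
        series=series,
        spec=spec,
        truth={"n_genes": 15, "sparse_grid": True},
    )


_CASES = {
    "cascade3": _cascade3,
    "feedback_bistable2": _feedback_bistable2,
    "adipo_mini5": _adipo_mini5,
    "model1_like15": _model1_like15,
}


def make_recovery_case(name: str) -> RecoveryCase:
    """Build one of the curated cases: cascade3, feedback_bistable2,
    adipo_mini5 or model1_like15."""
    try:
        builder = _CASES[name]
    except KeyError:
        raise ConfigError(
            f"unknown recovery case {name!r}; choose from {sorted(_CASES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Brute-force fixed-point oracle for two-gene switches

def count_fixed_points_2gene(
    kinetics: dict[str, GeneKinetics],
    weights: WeightVector,
    n_grid: int = 20001,
) -> tuple[int, list[float]]:
    """Enumerate equilibria of a two-gene mutual-activation circuit.

    At equilibrium Y2 = F2(q21·Y1)/d2, so Y1 must satisfy the 1-D equation
    g(Y1) = F1(q12·F2(q21·Y1)/d2)/d1 − Y1 = 0.  Roots are located by sign
    changes of g on a dense grid over [0, k1_1/d1] — an independent check
    that needs no ODE integration.  Returns (n_stable, stable_Y1_roots);
    stability alternates for a monotone 1-D map, so with the endpoints
    attracting the odd-indexed roots (0-based 1st, 3rd, ...) are unstable.
    """
    k1, k2 = kinetics["G1"], kinetics["G2"]
    q12 = weights.entries[("G1", "G2")]
    q21 = weights.entries[("G2", "G1")]

    def F(kin: GeneKinetics, A: np.ndarray) -> np.ndarray:
        z = np.clip(kin.k3 * A, -500.0, 500.0)
        ez = np.exp(-np.abs(z))
        pos = A >= 0
        out = np.empty_like(z)
        out[pos] = kin.k1 / (1.0 + kin.k2 * ez[pos])
        e = kin.k2 * ez[~pos]
        out[~pos] = kin.k1 * e / (1.0 + e)
        return out

    y1_hi = k1.k1 / k1.d
    grid = np.linspace(0.0, 1.05 * y1_hi, n_grid)
    g = F(k1, q12 * F(k2, q21 * grid) / k2.d) / k1.d - grid
    roots: list[float] = []
    for i in range(n_grid - 1):
        if g[i] == 0.0:
            roots.append(float(grid[i]))
        elif g[i] * g[i + 1] < 0:
            # linear refinement of the crossing
            frac = g[i] / (g[i] - g[i + 1])
            roots.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    stable = roots[0::2]
    return len(stable), stable


def saddle_node_k1(
    kinetics: dict[str, GeneKinetics],
    weights: WeightVector,
    k1_grid: np.ndarray,
) -> float | None:
    """Brute-force location of the saddle-node where the low state of a
    two-gene switch disappears as G1.k1 increases: the first grid value at
    which the stable-root count drops from 2 to 1 with only the high root
    remaining."""
    prev_two = False
    for c in np.asarray(k1_grid, dtype=float):
        kin = dict(kinetics)
        base = kin["G1"]
        kin["G1"] = GeneKinetics(k1=float(c), k2=base.k2, k3=base.k3, d=base.d)
        n_stable, stable = count_fixed_points_2gene(kin, weights)
        if n_stable >= 2:
            prev_two = True
        elif prev_two and n_stable == 1 and stable[0] > 0.5 * base.k1 / base.d:
            return float(c)
    return None
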
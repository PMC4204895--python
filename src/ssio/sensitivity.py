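"""Downstream analyses of a fitted network model: Metropolis–Hastings
regional (behavioral) sensitivity analysis, bistability/hysteresis scans,
local sensitivity, regulator-importance ranking, and cross-species
comparison of weighted expression levels.

Regional sensitivity follows the classic behavioral scheme: parameter
vectors are sampled by an independence Metropolis sampler whose stationary
density is reciprocal to the model's residual error; each sample is
classified behavioral (key markers respond properly to external signals)
or non-behavioral, and each parameter is scored by the Kolmogorov–Smirnov
distance between the two conditional sample distributions — a large
distance means the system's qualitative behaviour is sensitive to that
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .errors import ConfigError, EquilibriumNotFoundError, IntegrationError
from .network import GeneKinetics, RegulatoryNetwork, SignalSchedule, WeightVector
from .ode import ModelState, find_equilibrium, simulate

# ---------------------------------------------------------------------------
# Priors

@dataclass
class PriorSpec:
    """Independent uniform(lo, hi) prior per named parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigError(f"prior for {name}: lo {lo} !< hi {hi}")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self._arrays()
        return lo + (hi - lo) * rng.random(len(self.bounds))

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        return lo, hi


def build_prior(theta: dict[str, float], roles: dict[str, str]) -> PriorSpec:
    """Uniform sampling ranges from fitted values and parameter roles.

    degradation : ±0.1 around the fitted value (floored above 0) — decay
        rates outside a narrow band destroy boundedness or responsiveness.
    weight      : uniform(0, 1) — regulatory coefficients are explored over
        their whole natural range.
    other       : uniform(0, 2v) when v > 0.25, else uniform(0, 0.5).
    """
    bounds: dict[str, tuple[float, float]] = {}
    for name, v in theta.items():
        role = roles.get(name)
        if role == "degradation":
            bounds[name] = (max(v - 0.1, 1e-6), v + 0.1)
        elif role == "weight":
            bounds[name] = (0.0, 1.0)
        elif role == "other":
            bounds[name] = (0.0, 2.0 * v) if v > 0.25 else (0.0, 0.5)
        else:
            raise ConfigError(f"unknown role {role!r} for parameter {name!r}")
    return PriorSpec(bounds)


# ---------------------------------------------------------------------------
# Metropolis sampling

@dataclass
class MCMCSample:
    theta: np.ndarray
    err: float
    behavioral: bool
    accepted: bool


@dataclass
class MCMCTrace:
    samples: list[MCMCSample] = field(default_factory=list)
    burn_in: int = 0
    param_names: list[str] = field(default_factory=list)

    def chain(self) -> np.ndarray:
        """Post-burn-in chain states, shape (n_kept, n_params)."""
        return np.array([s.theta for s in self.samples[self.burn_in :]])

    def behavioral_flags(self) -> np.ndarray:
        return np.array([s.behavioral for s in self.samples[self.burn_in :]], dtype=bool)

    @property
    def acceptance_rate(self) -> float:
        if not self.samples:
            return float("nan")
        return float(np.mean([s.accepted for s in self.samples]))

    def behavioral_fraction(self) -> float:
        flags = self.behavioral_flags()
        return float(flags.mean()) if flags.size else float("nan")

    def to_tsv(self) -> str:
        cols = "\t".join(self.param_names)
        lines = [f"# {cols}\terr\tbehavioral\taccepted"]
        for s in self.samples:
            th = "\t".join(format(v, ".8g") for v in s.theta)
            lines.append(f"{th}\t{s.err:.8g}\t{int(s.behavioral)}\t{int(s.accepted)}")
        return "\n".join(lines) + "\n"


def metropolis_step(
    theta_n: np.ndarray,
    err_n: float,
    prior: PriorSpec,
    rng: np.random.Generator,
    err_fn: Callable[[np.ndarray], float],
    exponent: float = 1.0,
    proposal: str = "independence",
    step_frac: float = 0.1,
) -> tuple[np.ndarray, float, bool]:
    """One Metropolis–Hastings move on the reciprocal-error posterior.

    A candidate θ* is proposed (by default independently from the uniform
    prior, making the transition kernel symmetric in the acceptance ratio)
    and accepted with probability α = min(1, (err_n/err*)^exponent): moves
    that reduce the residual error are always accepted.  Returns
    ``(theta_next, err_next, accepted)``.
    """
    if err_n <= 0:
        raise ValueError("err_n must be > 0")
    lo, hi = prior._arrays()
    if proposal == "independence":
        theta_star = prior.sample(rng)
    elif proposal == "random_walk":
        theta_star = theta_n + step_frac * (hi - lo) * rng.standard_normal(lo.size)
        theta_star = np.clip(theta_star, lo, hi)
    else:
        raise ConfigError(f"unknown proposal {proposal!r}")
    err_star = float(err_fn(theta_star))
    if not np.isfinite(err_star) or err_star <= 0:
        return theta_n, err_n, False
    alpha = min(1.0, (err_n / err_star) ** exponent)
    if rng.random() < alpha:
        return theta_star, err_star, True
    return theta_n, err_n, False


def run_mcmc(
    prior: PriorSpec,
    err_fn: Callable[[np.ndarray], float],
    behavioral_fn: Callable[[np.ndarray], bool],
    n_steps: int,
    seed: int,
    burn_in: int = 10000,
    theta0: np.ndarray | None = None,
    exponent: float = 1.0,
    proposal: str = "independence",
) -> MCMCTrace:
    """Sample the reciprocal-error posterior and classify every chain state.

    The recorded chain holds the state *after* each step (repeats on
    rejection, as the stationary distribution requires).  ``burn_in``
    states are excluded from all downstream statistics (default 10000).
    """
    rng = np.random.default_rng(seed)
    theta = prior.sample(rng) if theta0 is None else np.asarray(theta0, float)
    err = float(err_fn(theta))
    if not np.isfinite(err) or err <= 0:
        err = np.finfo(float).max / 1e6
    behav = bool(behavioral_fn(theta))
    trace = MCMCTrace(burn_in=min(burn_in, n_steps), param_names=prior.names)
    for _ in range(n_steps):
        theta_new, err_new, accepted = metropolis_step(
            theta, err, prior, rng, err_fn, exponent, proposal
        )
        if accepted:
            theta, err = theta_new, err_new
            behav = bool(behavioral_fn(theta))
        trace.samples.append(
            MCMCSample(theta=theta.copy(), err=err, behavioral=behav, accepted=accepted)
        )
    return trace


def classify_behavioral(
    series,
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    schedule: SignalSchedule,
    markers: list[str] | None = None,
) -> bool:
    """Behavioral iff key markers end high with signals and low without
    (midpoint thresholds; exact ties and failed integrations are
    non-behavioral)."""
    from .fit import response_to_signals

    try:
        ok, _ = response_to_signals(series, net, weights, kinetics, schedule, markers)
    except (IntegrationError, EquilibriumNotFoundError):
        return False
    return ok


# ---------------------------------------------------------------------------
# K-S regional sensitivity

@dataclass
class SensitivityTable:
    """Per-parameter K–S distance between behavioral and non-behavioral
    marginal sample distributions (NaN when one class is empty)."""

    statistic: dict[str, float]
    n_behavioral: int
    n_nonbehavioral: int
    bins: int

    @property
    def defined(self) -> bool:
        return self.n_behavioral > 0 and self.n_nonbehavioral > 0

    def to_tsv(self) -> str:
        lines = [
            f"# n_behavioral={self.n_behavioral} n_nonbehavioral={self.n_nonbehavioral} bins={self.bins}",
            "parameter\tks_statistic",
        ]
        for name, s in self.statistic.items():
            lines.append(f"{name}\t{s:.6g}")
        return "\n".join(lines) + "\n"


def ks_sensitivity(trace: MCMCTrace, prior: PriorSpec, bins: int = 10) -> SensitivityTable:
    """Max |CDF_behavioral − CDF_nonbehavioral| per parameter on a fixed
    grid of ``bins`` intervals spanning the prior (default 10)."""
    chain = trace.chain()
    flags = trace.behavioral_flags()
    nb, nn = int(flags.sum()), int((~flags).sum())
    stat: dict[str, float] = {}
    lo, hi = prior._arrays()
    for j, name in enumerate(prior.names):
        if nb == 0 or nn == 0:
            stat[name] = float("nan")
            continue
        edges = np.linspace(lo[j], hi[j], bins + 1)
        cb = np.histogram(chain[flags, j], bins=edges)[0].cumsum() / nb
        cn = np.histogram(chain[~flags, j], bins=edges)[0].cumsum() / nn
        stat[name] = float(np.max(np.abs(cb - cn)))
    return SensitivityTable(statistic=stat, n_behavioral=nb, n_nonbehavioral=nn, bins=bins)


# ---------------------------------------------------------------------------
# Bistability

@dataclass
class ScanResult:
    control: tuple[str, str]             # (gene, parameter), e.g. ("CEBPB", "k1")
    grid: np.ndarray
    low_branch: np.ndarray               # (n_grid, n_tracked)
    high_branch: np.ndarray
    tracked_genes: list[str]
    trigger_level: float | None
    failed_points: list[int] = field(default_factory=list)

    def to_tsv(self) -> str:
        hdr = ["control"] + [f"low:{g}" for g in self.tracked_genes] + [
            f"high:{g}" for g in self.tracked_genes
        ]
        lines = [
            f"# control={self.control[0]}.{self.control[1]} trigger_level="
            f"{'none' if self.trigger_level is None else format(self.trigger_level, 'g')}",
            "\t".join(hdr),
        ]
        for i, c in enumerate(self.grid):
            row = [format(c, "g")]
            row += [format(v, ".6g") for v in self.low_branch[i]]
            row += [format(v, ".6g") for v in self.high_branch[i]]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def bistability_scan(
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    control: tuple[str, str],
    grid: np.ndarray,
    low_init: np.ndarray,
    high_init: np.ndarray,
    tracked_genes: list[str] | None = None,
    separation: float | None = None,
    horizon: float = 100.0,
) -> ScanResult:
    """Scan a control parameter for bistability/hysteresis.

    External signals are held at zero.  At each control value (typically a
    key gene's maximal transcription rate k1) equilibria are computed from
    a low and a high initial state.  Where the system is bistable the two
    branches separate; the trigger level is the smallest control value at
    which the previously-separated low branch has jumped up to the high
    branch (the saddle-node where the low state disappears).
    """
    gene, pname = control
    if pname not in ("k1", "k2", "k3", "d"):
        raise ConfigError(f"unknown control parameter {pname!r}")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("control grid must be increasing")
    tracked = tracked_genes or list(net.genes)
    silent = SignalSchedule.silent(net.signals)
    t_idx = [net.genes.index(g) for g in tracked]
    low_b = np.full((grid.size, len(tracked)), np.nan)
    high_b = np.full((grid.size, len(tracked)), np.nan)
    failed: list[int] = []
    for i, c in enumerate(grid):
        kin = dict(kinetics)
        base = kinetics[gene]
        kin[gene] = GeneKinetics(
            **{**{"k1": base.k1, "k2": base.k2, "k3": base.k3, "d": base.d}, pname: float(c)}
        )
        try:
            lo = find_equilibrium(
                ModelState(0.0, low_init), net, weights, kin, silent, horizon
            )
            hi = find_equilibrium(
                ModelState(0.0, high_init), net, weights, kin, silent, horizon
            )
        except (EquilibriumNotFoundError, IntegrationError):
            failed.append(i)
            continue
        low_b[i] = lo[t_idx]
        high_b[i] = hi[t_idx]
    # branch gap on the first tracked gene decides separation
    gap = np.abs(high_b[:, 0] - low_b[:, 0])
    if separation is None:
        scale = np.nanmax(np.abs(high_b[:, 0])) if np.isfinite(high_b[:, 0]).any() else 1.0
        separation = max(1e-3, 0.05 * scale)
    trigger = None
    was_separated = False
    for i in range(grid.size):
        if not np.isfinite(gap[i]):
            continue
        if gap[i] > separation:
            was_separated = True
        elif was_separated:
            trigger = float(grid[i])
            break
    return ScanResult(
        control=control,
        grid=grid,
        low_branch=low_b,
        high_branch=high_b,
        tracked_genes=tracked,
        trigger_level=trigger,
        failed_points=failed,
    )


@dataclass
class LocalSensitivityEntry:
    delta: float
    bistable: bool
    trigger_level: float | None
    trigger_shift: float | None


def local_sensitivity(
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    control: tuple[str, str],
    grid: np.ndarray,
    low_init: np.ndarray,
    high_init: np.ndarray,
    perturb: tuple[str, str],
    deltas: list[float],
    **scan_kwargs,
) -> list[LocalSensitivityEntry]:
    """Re-run the bistability scan with one parameter perturbed by each
    relative ``delta``; report whether bistability persists and how far
    the trigger level moves."""
    p_gene, p_name = perturb
    ref = bistability_scan(
        net, weights, kinetics, control, grid, low_init, high_init, **scan_kwargs
    )
    out: list[LocalSensitivityEntry] = []
    for delta in deltas:
        kin = dict(kinetics)
        base = kin[p_gene]
        vals = {"k1": base.k1, "k2": base.k2, "k3": base.k3, "d": base.d}
        vals[p_name] = vals[p_name] * (1.0 + delta)
        if vals[p_name] <= 0:
            out.append(LocalSensitivityEntry(delta, False, None, None))
            continue
        kin[p_gene] = GeneKinetics(**vals)
        scan = bistability_scan(
            net, weights, kin, control, grid, low_init, high_init, **scan_kwargs
        )
        bistable = scan.trigger_level is not None
        shift = (
            scan.trigger_level - ref.trigger_level
            if bistable and ref.trigger_level is not None
            else None
        )
        out.append(LocalSensitivityEntry(delta, bistable, scan.trigger_level, shift))
    return out


# ---------------------------------------------------------------------------
# Importance ranking

def _sigmoid_derivative(kin: GeneKinetics, A: float) -> float:
    """dF/dA of the sigmoid (reflected branch when A < 0)."""
    z = np.clip(kin.k3 * A, -500.0, 500.0)
    if A >= 0:
        e = kin.k2 * np.exp(-z)
        return kin.k1 * kin.k3 * e / (1.0 + e) ** 2
    e = kin.k2 * np.exp(z)
    return kin.k1 * kin.k3 * e / (1.0 + e) ** 2


def importance_rank(
    net: RegulatoryNetwork,
    weights: WeightVector,
    kinetics: dict[str, GeneKinetics],
    stage_states: dict[str, ModelState],
    schedule: SignalSchedule | None = None,
    targets: list[str] | None = None,
) -> dict[str, dict[str, list[tuple[str, float]]]]:
    """Rank each target's regulators by |∂(dY_target/dt)/∂X_i| · X_i.

    The Jacobian entry for a sigmoid-regulated target is F′(A)·q_i, so
    the importance is |F′(A)·q_i|·X_i evaluated at each stage's state.
    Returns ``{stage: {target: [(regulator, importance), ...desc]}}``.
    """
    schedule = schedule or SignalSchedule.silent(net.signals)
    targets = targets or [g for g in net.genes if net.regulators_of(g)]
    gi = {g: i for i, g in enumerate(net.genes)}
    out: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for stage, state in stage_states.items():
        sig = {s: schedule.level(s, state.t) for s in net.signals}
        per_target: dict[str, list[tuple[str, float]]] = {}
        for tgt in targets:
            regs = net.regulators_of(tgt)
            A = 0.0
            lv: dict[str, float] = {}
            for r in regs:
                x = (
                    state.levels[gi[r.source]]
                    if r.source in gi
                    else sig.get(r.source, 0.0)
                )
                q = weights.entries.get((tgt, r.source), 0.0)
                if r.source in net.zero_weight_sources:
                    q = 0.0
                A += q * x
                lv[r.source] = (float(x), q)
            dF = _sigmoid_derivative(kinetics[tgt], A)
            ranked = sorted(
                (
                    (src, abs(dF * q) * x if np.isfinite(dF) else 0.0)
                    for src, (x, q) in lv.items()
                ),
                key=lambda it: (-it[1], it[0]),
            )
            per_target[tgt] = [(s, float(v)) for s, v in ranked]
        out[stage] = per_target
    return out


def importance_table_tsv(
    ranking: dict[str, dict[str, list[tuple[str, float]]]]
) -> str:
    lines = ["stage\ttarget\trank\tregulator\timportance"]
    for stage, per_target in ranking.items():
        for tgt, ranked in per_target.items():
            for rank, (src, val) in enumerate(ranked, start=1):
                lines.append(f"{stage}\t{tgt}\t{rank}\t{src}\t{val:.6g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cross-species weighted-expression comparison

DEFAULT_STAGES = ("proliferating", "preadipocyte", "immature", "mature")


def default_stage_days(species: str, series_times: np.ndarray) -> dict[str, float]:
    """Stage → day mapping: proliferating = day −2, preadipocyte = day 0,
    immature = day 3 (human) / 2 (mouse), mature = the final day."""
    immature = 3.0 if species == "human" else 2.0
    return {
        "proliferating": -2.0,
        "preadipocyte": 0.0,
        "immature": immature,
        "mature": float(np.max(series_times)),
    }


def weighted_expression_compare(
    weights_a: WeightVector,
    series_a,
    weights_b: WeightVector,
    series_b,
    target: str,
    stages_a: dict[str, float],
    stages_b: dict[str, float],
    stage_order: tuple[str, ...] = DEFAULT_STAGES,
    method: str = "asymp",
) -> dict[str, tuple[float, float]] | None:
    """Two-sample K–S comparison of regulator weighted-expression changes.

    For each species the weighted expression q_i·X_i of every regulator of
    ``target`` is evaluated at the four differentiation stages; the three
    stage-to-stage change vectors (one value per regulator) are z-score
    normalized within species and compared between species by the
    two-sample K–S test.  Returns ``{transition: (D, p)}``, or ``None``
    when either species has fewer than two regulators.
    """
    out: dict[str, tuple[float, float]] = {}
    prof_a = _weighted_profiles(weights_a, series_a, target, stages_a, stage_order)
    prof_b = _weighted_profiles(weights_b, series_b, target, stages_b, stage_order)
    if prof_a is None or prof_b is None:
        return None
    for k in range(len(stage_order) - 1):
        trans = f"{stage_order[k]}->{stage_order[k + 1]}"
        da = _zscore(prof_a[:, k + 1] - prof_a[:, k])
        db = _zscore(prof_b[:, k + 1] - prof_b[:, k])
        res = stats.ks_2samp(da, db, method=method)
        out[trans] = (float(res.statistic), float(res.pvalue))
    return out


def _weighted_profiles(
    weights: WeightVector,
    series,
    target: str,
    stage_days: dict[str, float],
    stage_order: tuple[str, ...],
) -> np.ndarray | None:
    qmap = weights.for_target(target)
    regs = [s for s in qmap if s in series.gene_ids]
    if len(regs) < 2:
        return None
    prof = np.empty((len(regs), len(stage_order)))
    for i, src in enumerate(regs):
        for k, stage in enumerate(stage_order):
            prof[i, k] = qmap[src] * series.level(src, stage_days[stage])
    return prof


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd
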
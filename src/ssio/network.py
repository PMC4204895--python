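"""Regulatory-network topology, signal schedules, and the built-in
adipogenesis models.

A :class:`RegulatoryNetwork` lists genes, signed TF→target regulations and
external signals (cAMP, glucocorticoid-receptor (GR) and insulin-receptor
(IR) signalling).  Two curated 15-gene adipogenesis topologies ship with
the package: ``model1`` (the literature-derived core network around the key
markers CEBPB, CEBPA and PPARG) and ``model2`` (the same network plus five
candidate feedback edges from the key markers onto differentially-expressed
genes).  Anti-adipogenic factors (KLF4, GATA2, GATA3, KLF2) repress by
default; every sign is overridable in the topology file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

# ---------------------------------------------------------------------------
# Core types

ACTIVATION = +1
REPRESSION = -1


@dataclass(frozen=True)
class Regulation:
    """One signed edge: ``source`` (gene or signal) regulates ``target``."""

    source: str
    target: str
    sign: int = ACTIVATION

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ConfigError(f"sign must be +1/-1, got {self.sign}")
        if not self.source or not self.target:
            raise ConfigError("regulation endpoints must be non-empty")


@dataclass
class RegulatoryNetwork:
    """Genes, signed regulations and external-signal inputs.

    ``zero_weight_sources`` lists sources whose outgoing regulatory weights
    are frozen at zero during fitting (used for human GATA2, whose levels
    sit at the truncation floor and carry no information).
    """

    genes: list[str]
    regulations: list[Regulation]
    signals: list[str] = field(default_factory=list)
    zero_weight_sources: set[str] = field(default_factory=set)
    name: str = "network"

    def regulators_of(self, target: str) -> list[Regulation]:
        return [r for r in self.regulations if r.target == target]

    def is_constitutive(self, gene: str) -> bool:
        return not any(r.target == gene for r in self.regulations)

    @property
    def constitutive_genes(self) -> list[str]:
        return [g for g in self.genes if self.is_constitutive(g)]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r.source, r.target) for r in self.regulations}

    def sign_of(self, source: str, target: str) -> int:
        for r in self.regulations:
            if r.source == source and r.target == target:
                return r.sign
        raise KeyError(f"no regulation {source} -> {target}")


def validate_network(net: RegulatoryNetwork) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    declared = set(net.genes) | set(net.signals)
    if len(net.genes) != len(set(net.genes)):
        violations.append("duplicate gene ids in gene list")
    seen: set[tuple[str, str]] = set()
    for r in net.regulations:
        if r.source not in declared:
            violations.append(f"edge {r.source}->{r.target}: undeclared source")
        if r.target not in set(net.genes):
            violations.append(f"edge {r.source}->{r.target}: undeclared target gene")
        if (r.source, r.target) in seen:
            violations.append(f"duplicated regulator {r.source} for target {r.target}")
        seen.add((r.source, r.target))
    return violations


# ---------------------------------------------------------------------------
# Built-in adipogenesis topologies

#: The 15 genes of the adipogenesis models (three key markers first).
ADIPO_GENES = [
    "CEBPB", "CEBPA", "PPARG",
    "CEBPD", "CREB1", "CREB3", "CREB5",
    "KLF4", "KLF5", "KLF2", "KLF15",
    "GATA2", "GATA3", "STAT5A", "STAT5B",
]

#: Anti-adipogenic factors: their outgoing regulations default to repression.
ANTI_ADIPOGENIC = {"KLF4", "GATA2", "GATA3", "KLF2"}

KEY_MARKERS = ["CEBPB", "CEBPA", "PPARG"]

# Regulator sets of the key markers (core network, model 1).
_MODEL1_TARGETS = {
    "CEBPB": ["CREB3", "CREB1", "PPARG", "KLF4", "CREB5"],
    "CEBPA": ["CEBPD", "CEBPB", "GATA3", "PPARG", "GATA2"],
    "PPARG": ["STAT5B", "STAT5A", "CEBPB", "CEBPD", "CEBPA",
              "KLF15", "KLF5", "GATA2", "KLF2", "GATA3"],
}

# Five candidate feedbacks from key markers onto differentially expressed
# genes (KLF4/GATA2 down-, STAT5A/STAT5B/KLF15 up-regulated), model 2 only.
_MODEL2_FEEDBACKS = [
    ("PPARG", "STAT5A", ACTIVATION),
    ("CEBPB", "STAT5B", ACTIVATION),
    ("CEBPB", "KLF15", ACTIVATION),
    ("CEBPB", "KLF4", REPRESSION),
    ("CEBPB", "GATA2", REPRESSION),
]

# External signals: cAMP and GR drive CEBPB from induction; IR signalling
# drives PPARG from the immature-adipocyte stage.
_SIGNAL_EDGES = [
    ("cAMP", "CEBPB", ACTIVATION),
    ("GR", "CEBPB", ACTIVATION),
    ("IR", "PPARG", ACTIVATION),
]

ADIPO_SIGNALS = ["cAMP", "GR", "IR"]


def build_adipogenesis_network(
    variant: str = "model1", species: str = "human"
) -> RegulatoryNetwork:
    """Construct the built-in 15-gene adipogenesis topology.

    Parameters
    ----------
    variant : {"model1", "model2"}
        ``model2`` adds the five key-marker feedback edges.
    species : {"human", "mouse"}
        For human, GATA2-sourced weights are frozen at zero (GATA2 levels
        are floor-truncated in the human data).
    """
    if variant not in ("model1", "model2"):
        raise ConfigError(f"unknown variant {variant!r}")
    if species not in ("human", "mouse"):
        raise ConfigError(f"unknown species {species!r}")
    regs: list[Regulation] = []
    for target, sources in _MODEL1_TARGETS.items():
        for src in sources:
            sign = REPRESSION if src in ANTI_ADIPOGENIC else ACTIVATION
            regs.append(Regulation(src, target, sign))
    for src, tgt, sign in _SIGNAL_EDGES:
        regs.append(Regulation(src, tgt, sign))
    if variant == "model2":
        for src, tgt, sign in _MODEL2_FEEDBACKS:
            regs.append(Regulation(src, tgt, sign))
    zero = {"GATA2"} if species == "human" else set()
    return RegulatoryNetwork(
        genes=list(ADIPO_GENES),
        regulations=regs,
        signals=list(ADIPO_SIGNALS),
        zero_weight_sources=zero,
        name=f"adipogenesis-{variant}-{species}",
    )


# ---------------------------------------------------------------------------
# Parameters

@dataclass
class GeneKinetics:
    """Sigmoid transcription kinetics and first-order decay of one gene.

    k1 : maximal transcription rate (a.u./day), > 0
    k2 : sigmoid shape coefficient (dimensionless), > 0
    k3 : sigmoid steepness (1/a.u.), > 0
    d  : first-order degradation rate constant (1/day), > 0
    """

    k1: float
    k2: float
    k3: float
    d: float

    def __post_init__(self) -> None:
        from .errors import InvalidKineticsError

        if min(self.k1, self.k2, self.k3, self.d) <= 0:
            raise InvalidKineticsError(f"non-positive kinetics: {self}")


@dataclass
class WeightVector:
    """Regulatory coefficients q keyed by (target, regulator)."""

    entries: dict[tuple[str, str], float]

    def for_target(self, target: str) -> dict[str, float]:
        return {src: q for (tgt, src), q in self.entries.items() if tgt == target}

    def copy(self) -> "WeightVector":
        return WeightVector(dict(self.entries))

    def as_array(self, keys: list[tuple[str, str]]) -> np.ndarray:
        return np.array([self.entries[k] for k in keys])

    @classmethod
    def zeros(cls, net: RegulatoryNetwork) -> "WeightVector":
        return cls({(r.target, r.source): 0.0 for r in net.regulations})


# ---------------------------------------------------------------------------
# External-signal schedules

@dataclass
class SignalProfile:
    """Intensity of one external signal over time.

    mode:
      - "decreasing": linear chord from ``v_onset`` (at onset) down to
        ``v_offset`` (at offset); 0 outside [onset, offset].
      - "constant": ``v_onset`` throughout [onset, offset], 0 outside.
      - "step_on": 0 before onset, ``v_onset`` ever after (IR-style).
    """

    onset: float
    offset: float
    v_onset: float
    v_offset: float = 0.0
    mode: str = "decreasing"

    def __post_init__(self) -> None:
        if self.mode not in ("decreasing", "constant", "step_on"):
            raise ConfigError(f"unknown signal mode {self.mode!r}")
        if self.mode != "step_on" and not self.onset < self.offset:
            raise ConfigError("signal onset must precede offset")
        if self.v_onset < 0 or self.v_offset < 0:
            raise ConfigError("signal intensities must be >= 0")
        if self.mode == "decreasing" and self.v_offset > self.v_onset:
            raise ConfigError("decreasing profile must not increase")

    def level(self, t: float) -> float:
        if t < self.onset:
            return 0.0
        if self.mode == "step_on":
            return self.v_onset
        if t > self.offset:
            return 0.0
        if self.mode == "constant":
            return self.v_onset
        frac = (t - self.onset) / (self.offset - self.onset)
        return self.v_onset + frac * (self.v_offset - self.v_onset)


@dataclass
class SignalSchedule:
    """Per-signal intensity profiles; missing signal → KeyError."""

    profiles: dict[str, SignalProfile] = field(default_factory=dict)

    def level(self, signal: str, t: float) -> float:
        return self.profiles[signal].level(t)

    def levels(self, signals: list[str], t: float) -> dict[str, float]:
        return {s: self.level(s, t) for s in signals}

    @classmethod
    def silent(cls, signals: list[str]) -> "SignalSchedule":
        """All signals identically zero (stimulus-free simulation)."""
        return cls({s: SignalProfile(0.0, 1.0, 0.0, 0.0, "constant") for s in signals})


def signal_level(schedule: SignalSchedule, signal: str, t: float) -> float:
    """Intensity of ``signal`` at day ``t`` under ``schedule``."""
    return schedule.level(signal, t)


def default_signal_schedule(species: str = "human", intensity: float = 1.0) -> SignalSchedule:
    """Stimulation protocol of adipocyte differentiation.

    cAMP and GR signalling switch on at induction (day 0) and are withdrawn
    at the immature-adipocyte stage (day 3 human, day 2 mouse), when IR
    signalling takes over and stays on.  Human cAMP/GR intensities decrease
    linearly to zero over the stimulation window; the sparse mouse grid has
    no intermediate observations, so mouse intensities are held constant.
    """
    if species not in ("human", "mouse"):
        raise ConfigError(f"unknown species {species!r}")
    immature = 3.0 if species == "human" else 2.0
    mode = "decreasing" if species == "human" else "constant"
    return SignalSchedule(
        {
            "cAMP": SignalProfile(0.0, immature, intensity, 0.0, mode),
            "GR": SignalProfile(0.0, immature, intensity, 0.0, mode),
            "IR": SignalProfile(immature, float("inf"), intensity, mode="step_on"),
        }
    )


# ---------------------------------------------------------------------------
# Serialization: JSON (canonical) and SIF import/export

def network_to_json(net: RegulatoryNetwork) -> str:
    doc = {
        "name": net.name,
        "genes": net.genes,
        "signals": net.signals,
        "edges": [
            {"source": r.source, "target": r.target, "sign": r.sign}
            for r in net.regulations
        ],
        "zero_weight_sources": sorted(net.zero_weight_sources),
    }
    return json.dumps(doc, indent=2)


def network_from_json(text: str) -> RegulatoryNetwork:
    doc = json.loads(text)
    try:
        net = RegulatoryNetwork(
            genes=list(doc["genes"]),
            regulations=[
                Regulation(e["source"], e["target"], int(e.get("sign", ACTIVATION)))
                for e in doc["edges"]
            ],
            signals=list(doc.get("signals", [])),
            zero_weight_sources=set(doc.get("zero_weight_sources", [])),
            name=doc.get("name", "network"),
        )
    except KeyError as exc:
        raise ConfigError(f"network JSON missing field {exc}") from exc
    bad = validate_network(net)
    if bad:
        raise ConfigError("invalid network: " + "; ".join(bad))
    return net


def load_network(path: str) -> RegulatoryNetwork:
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".sif"):
        return network_from_sif(text)
    return network_from_json(text)


def save_network(net: RegulatoryNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(network_to_sif(net) if path.endswith(".sif") else network_to_json(net))


def network_to_sif(net: RegulatoryNetwork) -> str:
    rel = {ACTIVATION: "activates", REPRESSION: "represses"}
    lines = [f"{r.source}\t{rel[r.sign]}\t{r.target}" for r in net.regulations]
    return "\n".join(lines) + "\n"


def network_from_sif(text: str, signals: list[str] | None = None) -> RegulatoryNetwork:
    """Import a SIF edge list; nodes not listed in ``signals`` become genes."""
    signals = signals or []
    regs: list[Regulation] = []
    genes: list[str] = []
    for ln in text.splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 3:
            raise ConfigError(f"malformed SIF line: {ln!r}")
        src, rel, tgt = parts
        if rel not in ("activates", "represses"):
            raise ConfigError(f"unknown SIF relation {rel!r}")
        regs.append(Regulation(src, tgt, ACTIVATION if rel == "activates" else REPRESSION))
        for node in (src, tgt):
            if node not in genes and node not in signals:
                genes.append(node)
    return RegulatoryNetwork(genes=genes, regulations=regs, signals=list(signals))
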
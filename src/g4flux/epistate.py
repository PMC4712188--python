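"""Branching-process simulation of irreversible epigenetic silencing.

Models the clonal expansion of cells carrying a G4-bearing reporter locus
whose expression occupies one of three discrete, ordered states
(HIGH > MEDIUM > LOW). Replication stalling at the quadruplex triggers,
with some per-division probability, a step down the ladder; steps are
sequential (at most one per division) and irreversible. Expanding a clone
from ~2 founder cells through ~20 divisions (~10^6 cells) and measuring the
fraction no longer HIGH is the readout inverted by the fluctuation module.

Two allele-coupling regimes are supported. When both alleles carry the G4
and silencing at either one propagates to the monitored allele (a
transvection-like coupling), the per-division hazard of leaving HIGH is
h = 1 - (1 - p)^2; with the G4 knocked into a single allele only, h = p;
with no G4, h = 0. At small p this makes the single-allele instability
approximately half the two-allele value.

Two engines produce the same clone-size distributions: an agent engine
tracking every cell (the reference implementation, feasible to ~10^6-10^7
cells) and a counts engine propagating binomial state counts per
generation (used for large replicate sweeps during inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Literal, Optional, Tuple

import numpy as np

__all__ = [
    "ExpressionState",
    "AlleleConfig",
    "TransitionParams",
    "SimConfig",
    "CloneState",
    "division_hazard",
    "simulate_clone",
    "simulate_clone_agent",
    "simulate_clone_counts",
    "simulate_clones_batch",
    "expected_loss_fraction",
]

#: Agent-engine population guard: n_start * 2**n_divisions cells are held in
#: memory, so divisions beyond this are refused (use the counts engine).
MAX_AGENT_DIVISIONS = 22


class ExpressionState(IntEnum):
    """Ordered reporter expression states; transitions only move downward."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


@dataclass(frozen=True)
class AlleleConfig:
    """Which alleles carry the G4 motif and whether silencing is coupled
    between them (transvection-like effect)."""

    g4_on_A: bool = True
    g4_on_B: bool = True
    transvection: bool = True

    @classmethod
    def both_coupled(cls) -> "AlleleConfig":
        return cls(True, True, True)

    @classmethod
    def single_A(cls) -> "AlleleConfig":
        return cls(True, False, False)

    @classmethod
    def none(cls) -> "AlleleConfig":
        return cls(False, False, False)


@dataclass(frozen=True)
class TransitionParams:
    """Per-division transition probabilities.

    ``p`` is the probability, per G4-bearing allele per division, of the
    triggering event that moves a HIGH cell to MEDIUM; ``q`` is the
    MEDIUM -> LOW probability. ``q`` defaults to ``p`` — it is a nuisance
    parameter, since the headline statistic (fraction of cells not HIGH)
    does not depend on it.
    """

    p: float
    q: Optional[float] = None
    alleles: AlleleConfig = field(default_factory=AlleleConfig.both_coupled)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.q is None:
            object.__setattr__(self, "q", self.p)
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")


@dataclass(frozen=True)
class SimConfig:
    """Clonal expansion design: ~2 founder cells through ~20 divisions."""

    n_divisions: int = 20
    n_start: int = 2
    seed: int = 0
    engine: Literal["agent", "counts"] = "counts"

    def __post_init__(self) -> None:
        if self.n_divisions < 0:
            raise ValueError("n_divisions must be >= 0")
        if self.n_start < 1:
            raise ValueError("n_start must be >= 1")
        if self.engine not in ("agent", "counts"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def final_population(self) -> int:
        return self.n_start * 2**self.n_divisions


@dataclass(frozen=True)
class CloneState:
    """Counts of cells per expression state in one expanded clone."""

    counts: Dict[ExpressionState, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def fraction_not_high(self) -> float:
        n = self.n_total
        if n == 0:
            raise ValueError("empty clone")
        return 1.0 - self.counts.get(ExpressionState.HIGH, 0) / n

    @property
    def pct_loss(self) -> float:
        return 100.0 * self.fraction_not_high


def division_hazard(params: TransitionParams) -> float:
    """Per-division probability that a HIGH cell's monitored allele steps
    down to MEDIUM.

    With transvection, a triggering event at either G4-bearing allele
    silences the monitored allele, so h = 1 - (1 - p)^k with k the number
    of G4-bearing alleles. Without coupling only the monitored A allele's
    own G4 matters.
    """
    a = params.alleles
    if a.transvection:
        k = int(a.g4_on_A) + int(a.g4_on_B)
    else:
        k = int(a.g4_on_A)
    return 1.0 - (1.0 - params.p) ** k


def simulate_clone_agent(tp: TransitionParams, sc: SimConfig) -> CloneState:
    """Expand a clone tracking every cell individually.

    Each division every daughter cell independently steps down at most one
    state: HIGH -> MEDIUM with probability ``division_hazard(tp)``,
    MEDIUM -> LOW with probability ``q``. Identical seed, identical output.
    """
    if sc.n_divisions > MAX_AGENT_DIVISIONS:
        raise ValueError(
            f"agent engine limited to {MAX_AGENT_DIVISIONS} divisions "
            f"({sc.n_start * 2**sc.n_divisions} cells requested); use the counts engine"
        )
    rng = np.random.default_rng(sc.seed)
    h = division_hazard(tp)
    states = np.full(sc.n_start, int(ExpressionState.HIGH), dtype=np.int8)
    for _ in range(sc.n_divisions):
        states = np.repeat(states, 2)
        u = rng.random(states.size)
        was_high = states == ExpressionState.HIGH
        was_med = states == ExpressionState.MEDIUM
        # decisions based on pre-division state: one step max per division
        states[was_high & (u < h)] = ExpressionState.MEDIUM
        states[was_med & (u < tp.q)] = ExpressionState.LOW
    counts = {s: int(np.sum(states == s)) for s in ExpressionState}
    return CloneState(counts)


def simulate_clone_counts(tp: TransitionParams, sc: SimConfig) -> CloneState:
    """Expand a clone propagating per-state counts with binomial draws.

    Distributionally equivalent to the agent engine: per generation each
    state count doubles, then the number of HIGH -> MEDIUM and
    MEDIUM -> LOW transitions among the daughters is binomial.
    """
    rng = np.random.default_rng(sc.seed)
    high, med, low = _propagate_counts(
        rng,
        division_hazard(tp),
        tp.q,
        sc.n_divisions,
        np.array([sc.n_start], dtype=np.int64),
    )
    return CloneState(
        {
            ExpressionState.HIGH: int(high[0]),
            ExpressionState.MEDIUM: int(med[0]),
            ExpressionState.LOW: int(low[0]),
        }
    )


def _propagate_counts(
    rng: np.random.Generator,
    h: float,
    q: float,
    n_divisions: int,
    start_high: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised count propagation for a batch of clones."""
    high = start_high.astype(np.int64).copy()
    med = np.zeros_like(high)
    low = np.zeros_like(high)
    for _ in range(n_divisions):
        high *= 2
        med *= 2
        low *= 2
        h_to_m = rng.binomial(high, h)
        m_to_l = rng.binomial(med, q)
        high -= h_to_m
        med += h_to_m - m_to_l
        low += m_to_l
    return high, med, low


def simulate_clone(tp: TransitionParams, sc: SimConfig) -> CloneState:
    """Dispatch on ``sc.engine``."""
    if sc.engine == "agent":
        return simulate_clone_agent(tp, sc)
    return simulate_clone_counts(tp, sc)


def simulate_clones_batch(
    tp: TransitionParams,
    n_divisions: int,
    n_start: int,
    n_clones: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n_clones`` independent clones with the counts engine and
    return their fraction-not-HIGH values (shape ``(n_clones,)``).

    This is the hot path of the Monte-Carlo inversion; it shares the
    per-generation binomial law with :func:`simulate_clone_counts`.
    """
    start = np.full(n_clones, n_start, dtype=np.int64)
    high, med, low = _propagate_counts(rng, division_hazard(tp), tp.q, n_divisions, start)
    total = high + med + low
    return 1.0 - high / total


def expected_loss_fraction(p: float, n: int, alleles: Optional[AlleleConfig] = None) -> float:
    """Expected fraction of cells not in HIGH after ``n`` divisions.

    A lineage remains HIGH iff every one of its ``n`` division steps avoids
    the hazard, so the expectation is 1 - (1 - h)^n with
    h = division_hazard. Exact for the per-daughter-cell hazard model.
    """
    tp = TransitionParams(p=p, alleles=alleles or AlleleConfig.both_coupled())
    h = division_hazard(tp)
    return 1.0 - (1.0 - h) ** n
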
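"""Synthetic-data generation with known ground truth.

Every input the analysis consumes can be generated here: FASTA with
quadruplex motifs planted at recorded coordinates, fluctuation datasets
simulated at a known per-division loss probability, and ChIP/bisulphite
tables realised around known ratio/methylation truths. Each generator is a
pure function of its spec and seed, and each emits a truth sidecar
sufficient to score the downstream stage that consumes it.

The fluctuation defaults mirror the experimental design being emulated:
clones grown from 2 founder cells through 20 divisions, ~10^4 cells
analysed per clone on the cytometer with ~1% gate misclassification, and
both alleles carrying the G4 with transvection-like coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .epistate import AlleleConfig, SimConfig, TransitionParams, simulate_clones_batch
from .fluctuation import CloneMeasurement, FACSNoise, FluctuationDataset, measure_fractions

__all__ = ["PlantedMotif", "SyntheticSpec", "make_fasta", "make_fluctuation", "make_chip_and_meth"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedMotif:
    sequence: str
    copies: int = 1
    strand: str = "+"


def _default_chip_truth() -> Dict[Tuple[str, str], float]:
    # silenced populations progressively lose the active mark
    return {
        ("high", "tss"): 1.0,
        ("medium", "tss"): 0.4,
        ("low", "tss"): 0.1,
    }


def _default_meth_truth() -> Dict[str, float]:
    return {"minus0.5kb": 0.6, "plus0.5kb": 0.15}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and design parameters for all generators."""

    seed: int = 0
    n_clones: int = 50
    true_p: float = 0.067
    alleles: AlleleConfig = field(default_factory=AlleleConfig.both_coupled)
    n_divisions: int = 20
    n_start: int = 2
    noise: FACSNoise = field(default_factory=FACSNoise)
    planted_motifs: Tuple[PlantedMotif, ...] = ()
    chip_truth: Dict[Tuple[str, str], float] = field(default_factory=_default_chip_truth)
    meth_truth: Dict[str, float] = field(default_factory=_default_meth_truth)
    # generator details
    background_length: int = 1000
    gc_content: float = 0.5
    max_g_run: Optional[int] = None  # cap on G/C runs in background (exclusive bound = run < cap)
    chip_noise_sd: float = 0.0
    n_bisulphite_clones: int = 10
    n_cpg_per_clone: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_p <= 1.0:
            raise ValueError("true_p must be in [0, 1]")
        for r, m in self.meth_truth.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"meth_truth[{r!r}] must be in [0, 1]")


# ---------------------------------------------------------------------------
# FASTA with planted motifs


def _random_background(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = rng.choice(_BASES, size=spec.background_length, p=probs)
    if spec.max_g_run is not None:
        # break any G or C run reaching the cap so negative controls are
        # guaranteed motif-free on both strands
        for base, repl in (("G", "AT"), ("C", "AT")):
            run = 0
            for i in range(seq.size):
                run = run + 1 if seq[i] == base else 0
                if run >= spec.max_g_run:
                    seq[i] = rng.choice(list(repl))
                    run = 0
    return seq


def make_fasta(spec: SyntheticSpec, sequence_id: str = "synthetic") -> Tuple[str, str]:
    """Emit (FASTA text, truth BED text) with each planted motif inserted
    at recorded, non-overlapping coordinates on its recorded strand."""
    rng = np.random.default_rng(spec.seed)
    seq = _random_background(rng, spec)
    placements: List[Tuple[int, int, str, str]] = []  # start, end, name, strand
    occupied: List[Tuple[int, int]] = []
    for mi, pm in enumerate(spec.planted_motifs):
        ins = pm.sequence.upper()
        if set(ins) - set("ACGT"):
            raise ValueError(f"planted motif {mi} is not plain DNA: {pm.sequence!r}")
        if pm.strand == "-":
            ins = str(Seq(ins).reverse_complement())
        for copy in range(pm.copies):
            for _ in range(1000):
                start = int(rng.integers(0, spec.background_length - len(ins) + 1))
                end = start + len(ins)
                # keep a 1-nt buffer so flanking background cannot extend a tract
                if all(end + 1 <= s or start >= e + 1 for s, e in occupied):
                    break
            else:
                raise ValueError("could not place motifs without overlap; sequence too short")
            occupied.append((start, end))
            seq[start:end] = list(ins)
            placements.append((start, end, f"motif{mi}_copy{copy}", pm.strand))
    fasta = f">{sequence_id}\n" + "".join(seq) + "\n"
    placements.sort()
    bed = "".join(
        f"{sequence_id}\t{s}\t{e}\t{name}\t0\t{strand}\n" for s, e, name, strand in placements
    )
    return fasta, bed


# ---------------------------------------------------------------------------
# Fluctuation datasets


def make_fluctuation(spec: SyntheticSpec, genotype: str = "synthetic") -> FluctuationDataset:
    """Simulate ``n_clones`` independent expanded clones at ``true_p``
    through the branching-process simulator and the FACS readout."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    tp = TransitionParams(p=spec.true_p, alleles=spec.alleles)
    fractions = simulate_clones_batch(tp, spec.n_divisions, spec.n_start, spec.n_clones, rng)
    pct = measure_fractions(fractions, spec.noise, rng)
    clones = tuple(
        CloneMeasurement(f"{genotype}_{i:03d}", float(v)) for i, v in enumerate(pct)
    )
    return FluctuationDataset(genotype, clones)


# ---------------------------------------------------------------------------
# ChIP and bisulphite tables


def make_chip_and_meth(spec: SyntheticSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emit (ChIP table, bisulphite table) realised around the spec truths.

    ChIP signals carry multiplicative lognormal noise (mean-one, sd
    ``chip_noise_sd`` on the log scale), qPCR-like; with zero noise the
    double normalization recovers ``chip_truth`` exactly. Bisulphite CpG
    calls are Bernoulli at the per-region ``meth_truth`` rate.
    """
    regions = {r for _, r in spec.chip_truth}
    for r in regions:
        if ("high", r) not in spec.chip_truth or spec.chip_truth[("high", r)] != 1.0:
            raise ValueError(f"chip_truth must contain the reference ('high', {r!r}) at 1.0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    sd = spec.chip_noise_sd
    rows = []
    for (pop, region), ratio in sorted(spec.chip_truth.items()):
        h3 = 100.0 * (np.exp(rng.normal(-sd**2 / 2, sd)) if sd > 0 else 1.0)
        noise = np.exp(rng.normal(-sd**2 / 2, sd)) if sd > 0 else 1.0
        rows.append(
            {
                "population": pop,
                "region": region,
                "target_signal": ratio * h3 * noise,
                "h3_signal": h3,
            }
        )
    chip_df = pd.DataFrame(rows)

    meth_rows = []
    for region, rate in sorted(spec.meth_truth.items()):
        for c in range(spec.n_bisulphite_clones):
            calls = rng.random(spec.n_cpg_per_clone) < rate
            for i, methylated in enumerate(calls):
                meth_rows.append(
                    {
                        "clone_id": f"bis_{region}_{c:02d}",
                        "region": region,
                        "cpg_index": i,
                        "call": "M" if methylated else "U",
                    }
                )
    return chip_df, pd.DataFrame(meth_rows)
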
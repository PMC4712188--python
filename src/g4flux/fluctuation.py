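"""Fluctuation analysis: FACS readout, summaries, rate inference, testing.

The experimental design is Luria-Delbruck-like: many clones are expanded
from ~2 cells for ~20 divisions, and for each clone the percentage of cells
that have lost HIGH reporter expression is measured by flow cytometry. The
spread of these per-clone percentages reflects when, in each lineage, the
stochastic silencing events happened. This module

* emulates the flow-cytometry readout of a simulated clone, including a
  symmetric gate-misclassification rate and the ~10% quantification floor
  below which the assay cannot resolve the per-division probability;
* summarizes a dataset by median and interquartile range, as such data are
  conventionally plotted;
* inverts the simulator by grid search to recover the per-division loss
  probability p (simulation-based, likelihood-free estimation), with a
  bootstrap confidence interval over clones;
* compares two genotypes with an exact conditional Fisher test on
  percentages binned at 20% width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .epistate import (
    AlleleConfig,
    CloneState,
    SimConfig,
    TransitionParams,
    simulate_clones_batch,
)

__all__ = [
    "FACSNoise",
    "CloneMeasurement",
    "FluctuationDataset",
    "EstimateResult",
    "measure_clone",
    "measure_fractions",
    "summarize",
    "estimate_p",
    "compare_fluctuations",
    "fisher_exact_2xk",
    "default_grid",
]


@dataclass(frozen=True)
class FACSNoise:
    """Gate-level noise model of the flow-cytometry readout.

    ``n_events`` cells are sampled per clone; each is assigned to the wrong
    side of the HIGH gate with probability ``misclass`` (symmetric by
    default). Estimates from datasets whose median loss lies below
    ``quant_floor`` are flagged unreliable: assay noise swamps the signal
    when loss populations are under ~10%.
    """

    n_events: int = 10_000
    misclass: float = 0.01
    quant_floor: float = 0.10

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.misclass < 0.5:
            raise ValueError("misclass must be in [0, 0.5)")
        if not 0.0 <= self.quant_floor <= 1.0:
            raise ValueError("quant_floor must be in [0, 1]")


@dataclass(frozen=True)
class CloneMeasurement:
    clone_id: str
    pct_loss: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_loss <= 100.0:
            raise ValueError(f"pct_loss must be in [0, 100], got {self.pct_loss}")


@dataclass(frozen=True)
class FluctuationDataset:
    """Per-clone percent-loss measurements for one genotype."""

    genotype: str
    clones: Tuple[CloneMeasurement, ...]

    def __post_init__(self) -> None:
        if len(self.clones) == 0:
            raise ValueError("a fluctuation dataset needs >= 1 clone")

    @property
    def pct_values(self) -> np.ndarray:
        return np.array([c.pct_loss for c in self.clones], dtype=float)

    @classmethod
    def from_values(cls, genotype: str, values: Sequence[float]) -> "FluctuationDataset":
        return cls(
            genotype,
            tuple(CloneMeasurement(f"{genotype}_{i:03d}", float(v)) for i, v in enumerate(values)),
        )

    @classmethod
    def from_tsv(cls, path, genotype: str = "unknown") -> "FluctuationDataset":
        df = pd.read_csv(path, sep="\t")
        if not {"clone_id", "pct_loss"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns clone_id, pct_loss")
        clones = tuple(
            CloneMeasurement(str(r.clone_id), float(r.pct_loss)) for r in df.itertuples()
        )
        return cls(genotype, clones)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"clone_id": [c.clone_id for c in self.clones], "pct_loss": self.pct_values}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EstimateResult:
    """Per-division loss probability inferred by Monte-Carlo inversion."""

    p_hat: float
    ci_low: float
    ci_high: float
    grid: Tuple[Tuple[float, float], ...]
    n_reps: int
    distance_metric: Literal["median", "ks"]
    reliable: bool

    def report(self) -> str:
        lines = [
            f"p_hat\t{self.p_hat:.4f}",
            f"ci_low\t{self.ci_low:.4f}",
            f"ci_high\t{self.ci_high:.4f}",
            f"reliable\t{self.reliable}",
            f"metric\t{self.distance_metric}",
            f"n_reps\t{self.n_reps}",
            "grid_p\tdistance",
        ]
        lines += [f"{p:.4f}\t{d:.4f}" for p, d in self.grid]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FACS readout emulation


def measure_clone(state: CloneState, noise: FACSNoise, seed: int) -> CloneMeasurement:
    """Emulate flow-cytometry analysis of one expanded clone.

    Samples ``n_events`` cells with replacement in proportion to the
    clone's state counts, flips each HIGH/not-HIGH call with probability
    ``misclass``, and returns the observed percent loss.
    """
    if state.n_total == 0:
        raise ValueError("cannot measure an empty clone")
    rng = np.random.default_rng(seed)
    f = state.fraction_not_high
    n_not_high = rng.binomial(noise.n_events, f)
    n_high = noise.n_events - n_not_high
    # symmetric gate misclassification, each call flipped independently
    observed_not_high = (
        rng.binomial(n_not_high, 1.0 - noise.misclass)
        + rng.binomial(n_high, noise.misclass)
    )
    pct = 100.0 * observed_not_high / noise.n_events
    return CloneMeasurement(clone_id=f"sim_{seed}", pct_loss=pct)


def measure_fractions(
    fractions: np.ndarray, noise: FACSNoise, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised readout of many clones' true not-HIGH fractions.

    The two-stage draw in :func:`measure_clone` collapses to a single
    binomial with success probability f(1-eps) + (1-f)eps, which is what
    this hot path uses.
    """
    p_obs = fractions * (1.0 - noise.misclass) + (1.0 - fractions) * noise.misclass
    return 100.0 * rng.binomial(noise.n_events, p_obs) / noise.n_events


# ---------------------------------------------------------------------------
# Summaries


def summarize(ds: FluctuationDataset) -> Tuple[float, Tuple[float, float]]:
    """Median and (25th, 75th) percentiles of per-clone percent loss,
    with numpy's linear interpolation convention."""
    v = ds.pct_values
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return float(q50), (float(q25), float(q75))


# ---------------------------------------------------------------------------
# Monte-Carlo inversion


def default_grid(p_max: float = 0.25, step: float = 0.0025) -> np.ndarray:
    return np.round(np.arange(0.0, p_max + step / 2, step), 10)


def _sim_pct_losses(
    p: float,
    tp_template: TransitionParams,
    sc: SimConfig,
    noise: FACSNoise,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Simulate ``n_reps`` measured clones at probability ``p``.

    The substream is derived from (seed, p) so any grid point is
    reproducible independently of evaluation order.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(int(round(p * 1e8)),))
    rng = np.random.default_rng(ss)
    tp = TransitionParams(p=p, q=tp_template.q, alleles=tp_template.alleles)
    fractions = simulate_clones_batch(tp, sc.n_divisions, sc.n_start, n_reps, rng)
    return measure_fractions(fractions, noise, rng)


def _ks_stat(sim_sorted: np.ndarray, obs: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup-norm of ECDF gap)."""
    all_v = np.union1d(sim_sorted, obs)
    cdf_sim = np.searchsorted(sim_sorted, all_v, side="right") / sim_sorted.size
    cdf_obs = np.searchsorted(np.sort(obs), all_v, side="right") / obs.size
    return float(np.max(np.abs(cdf_sim - cdf_obs)))


def estimate_p(
    ds: FluctuationDataset,
    tp_template: Optional[TransitionParams] = None,
    sc: Optional[SimConfig] = None,
    noise: Optional[FACSNoise] = None,
    grid: Optional[Sequence[float]] = None,
    n_reps: int = 400,
    seed: int = 0,
    distance_metric: Literal["median", "ks"] = "median",
    refine: bool = True,
    n_boot: int = 200,
) -> EstimateResult:
    """Estimate the per-division loss probability by grid-search inversion.

    For each candidate p the full pipeline (clonal expansion + FACS
    readout) is simulated ``n_reps`` times and compared with the observed
    per-clone distribution; the default distance is the absolute difference
    of medians (robust, and the median is the summary such data are
    reported with), a two-sample KS statistic optionally. Ties break toward
    smaller p. A percentile bootstrap over the observed clones gives the
    interval. Deterministic given (seed, grid, n_reps).
    """
    if tp_template is None:
        tp_template = TransitionParams(p=0.0)
    if sc is None:
        sc = SimConfig()
    if noise is None:
        noise = FACSNoise()
    grid_arr = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if grid_arr.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be strictly increasing")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")

    obs = ds.pct_values
    obs_median = float(np.median(obs))
    reliable = obs_median >= noise.quant_floor * 100.0

    # degenerate datasets carry no distributional information
    if np.all(obs == 0.0) or np.all(obs == 100.0):
        at_zero = bool(np.all(obs == 0.0))
        boundary = float(grid_arr[0]) if at_zero else float(grid_arr[-1])
        warnings.warn(
            f"degenerate dataset (all clones at {'0' if at_zero else '100'}%): "
            "returning boundary estimate",
            stacklevel=2,
        )
        return EstimateResult(
            p_hat=boundary,
            ci_low=boundary,
            ci_high=boundary,
            grid=(),
            n_reps=n_reps,
            distance_metric=distance_metric,
            reliable=reliable and not at_zero,
        )

    def distances_for(ps: np.ndarray, target: np.ndarray) -> np.ndarray:
        d = np.empty(ps.size)
        for i, p in enumerate(ps):
            sim = _sim_pct_losses(float(p), tp_template, sc, noise, n_reps, seed)
            if distance_metric == "median":
                d[i] = abs(np.median(sim) - np.median(target))
            else:
                d[i] = _ks_stat(np.sort(sim), target)
        return d

    # cache per-p simulated summaries so bootstrap reuses the same draws
    sim_medians = np.empty(grid_arr.size)
    sim_sorted: List[np.ndarray] = []
    for i, p in enumerate(grid_arr):
        sim = _sim_pct_losses(float(p), tp_template, sc, noise, n_reps, seed)
        sim_medians[i] = np.median(sim)
        if distance_metric == "ks":
            sim_sorted.append(np.sort(sim))

    if distance_metric == "median":
        coarse_d = np.abs(sim_medians - obs_median)
    else:
        coarse_d = np.array([_ks_stat(s, obs) for s in sim_sorted])
    best = int(np.argmin(coarse_d))  # first occurrence: ties go to smaller p
    p_hat = float(grid_arr[best])
    trace = list(zip(grid_arr.tolist(), coarse_d.tolist()))

    if refine and grid_arr.size > 1:
        step = float(np.min(np.diff(grid_arr)))
        fine_step = step / 5.0
        lo = max(float(grid_arr[0]), p_hat - step)
        hi = min(float(grid_arr[-1]), p_hat + step)
        fine = np.round(np.arange(lo, hi + fine_step / 2, fine_step), 10)
        fine = fine[~np.isin(fine, grid_arr)]
        if fine.size:
            fine_d = distances_for(fine, obs)
            all_p = np.concatenate([grid_arr, fine])
            all_d = np.concatenate([coarse_d, fine_d])
            order = np.argsort(all_p, kind="stable")
            all_p, all_d = all_p[order], all_d[order]
            p_hat = float(all_p[int(np.argmin(all_d))])
            trace = list(zip(all_p.tolist(), all_d.tolist()))

    # percentile bootstrap over clones, against the cached coarse-grid draws
    boot_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xB007,)))
    boot_hats = np.empty(n_boot)
    for b in range(n_boot):
        idx = boot_rng.integers(0, obs.size, obs.size)
        res = obs[idx]
        if distance_metric == "median":
            d = np.abs(sim_medians - np.median(res))
        else:
            d = np.array([_ks_stat(s, res) for s in sim_sorted])
        boot_hats[b] = grid_arr[int(np.argmin(d))]
    ci_low, ci_high = np.percentile(boot_hats, [2.5, 97.5])
    ci_low = float(min(ci_low, p_hat))
    ci_high = float(max(ci_high, p_hat))

    return EstimateResult(
        p_hat=p_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        grid=tuple((float(p), float(d)) for p, d in trace),
        n_reps=n_reps,
        distance_metric=distance_metric,
        reliable=reliable,
    )


# ---------------------------------------------------------------------------
# Exact conditional test on binned percentages


def _bin_counts(values: np.ndarray, bin_width: int) -> np.ndarray:
    k = 100 // bin_width
    idx = np.minimum((values // bin_width).astype(int), k - 1)  # 100% joins top bin
    return np.bincount(idx, minlength=k)


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2 x k contingency table.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of those no more probable
    than the observed table (the two-sided convention of the classical
    2 x 2 Fisher test, generalised to k columns). Columns empty in both
    rows must be dropped by the caller; feasible for the clone counts used
    here (tens of observations per group, k <= 5).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    col = t.sum(axis=0)
    keep = col > 0
    t, col = t[:, keep], col[keep]
    k = t.shape[1]
    r1 = int(t[0].sum())
    n_total = int(t.sum())
    if k <= 1 or r1 == 0 or r1 == n_total:
        return 1.0

    lgam = gammaln(np.arange(n_total + 2))

    def log_choose(n: int, m: int) -> float:
        return lgam[n + 1] - lgam[m + 1] - lgam[n - m + 1]

    log_denom = log_choose(n_total, r1)
    log_obs = sum(log_choose(int(col[j]), int(t[0, j])) for j in range(k)) - log_denom
    suffix = np.concatenate([np.cumsum(col[::-1])[::-1], [0]])

    total = 0.0

    def recurse(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = acc + log_choose(int(col[j]), remaining) - log_denom
                if lp <= log_obs + 1e-9:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(suffix[j + 1]))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, acc + log_choose(int(col[j]), a))

    recurse(0, r1, 0.0)
    return min(total, 1.0)


def compare_fluctuations(
    a: FluctuationDataset, b: FluctuationDataset, bin_width: int = 20
) -> float:
    """Fisher's exact test between two genotypes' per-clone loss values,
    binned at ``bin_width`` percent (bins [0,20), ..., [80,100])."""
    if 100 % bin_width != 0:
        raise ValueError("bin_width must divide 100")
    table = np.vstack(
        [_bin_counts(a.pct_values, bin_width), _bin_counts(b.pct_values, bin_width)]
    )
    return fisher_exact_2xk(table)
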
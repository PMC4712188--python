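"""Chromatin-mark utilities: ChIP-qPCR double normalization, Welch's t
test, and bisulphite CpG methylation percentages.

These are the exactly-specified readouts used to characterise the silenced
expression states: histone-mark ChIP signals are normalized first to total
H3 and then to the HIGH-expressing reference population, groups are
compared with Welch's unequal-variance t test, and per-region CpG
methylation is summarised as percent methylated calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChipMeasurement",
    "BisulphiteClone",
    "chip_normalize",
    "welch_t",
    "methylation_percent",
]


@dataclass(frozen=True)
class ChipMeasurement:
    """One ChIP-qPCR observation: linear-scale signals (already converted
    from Ct) for the mark of interest and for total H3 at one region in one
    sorted expression population."""

    population: str
    region: str
    target_signal: float
    h3_signal: float

    def __post_init__(self) -> None:
        if self.target_signal <= 0 or self.h3_signal <= 0:
            raise ValueError(
                f"qPCR signals must be positive, got target={self.target_signal}, "
                f"h3={self.h3_signal}"
            )


@dataclass(frozen=True)
class BisulphiteClone:
    """CpG calls for one sequenced bisulphite clone in one region."""

    clone_id: str
    region: str
    cpg_calls: Tuple[bool, ...]  # True = methylated

    def __post_init__(self) -> None:
        if len(self.cpg_calls) == 0:
            raise ValueError("a bisulphite clone needs >= 1 CpG call")


def chip_normalize(
    measurements: Sequence[ChipMeasurement], reference: str = "high"
) -> Dict[Tuple[str, str], float]:
    """Double-normalize ChIP signals: target/H3, then relative to the
    reference population of the same region.

    Returns a map (population, region) -> ratio; the reference population
    maps to 1.0 exactly. Scale-invariant per region by construction.
    """
    per_h3: Dict[Tuple[str, str], float] = {}
    for m in measurements:
        key = (m.population, m.region)
        if key in per_h3:
            raise ValueError(f"duplicate measurement for {key}")
        per_h3[key] = m.target_signal / m.h3_signal
    regions = {r for _, r in per_h3}
    for r in regions:
        if (reference, r) not in per_h3:
            raise ValueError(f"missing reference population {reference!r} for region {r!r}")
    return {(pop, r): v / per_h3[(reference, r)] for (pop, r), v in per_h3.items()}


def welch_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, float]:
    """Welch's unequal-variance t test, two-sided.

    Returns (t, Satterthwaite df, p). With equal variances and equal n the
    df reduces to 2n - 2.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both groups have zero variance and different means")
    res = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / x.size, vy / y.size
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def methylation_percent(
    clones: Sequence[BisulphiteClone], region: str
) -> Tuple[float, Dict[str, float]]:
    """Percent methylated CpG calls in ``region``, pooled across clones.

    Returns (pooled percentage, per-clone percentages). Pooling weights
    clones by their number of calls; the per-clone values allow the
    mean-of-clones aggregation instead.
    """
    selected = [c for c in clones if c.region == region]
    if not selected:
        raise ValueError(f"no bisulphite clones for region {region!r}")
    meth = sum(sum(c.cpg_calls) for c in selected)
    total = sum(len(c.cpg_calls) for c in selected)
    per_clone = {
        c.clone_id: 100.0 * sum(c.cpg_calls) / len(c.cpg_calls) for c in selected
    }
    return 100.0 * meth / total, per_clone


# ---------------------------------------------------------------------------
# TSV readers for the CLI


def read_chip_tsv(path) -> List[ChipMeasurement]:
    df = pd.read_csv(path, sep="\t")
    required = {"population", "region", "target_signal", "h3_signal"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        ChipMeasurement(str(r.population), str(r.region), float(r.target_signal), float(r.h3_signal))
        for r in df.itertuples()
    ]


def read_bisulphite_tsv(path) -> List[BisulphiteClone]:
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "region", "cpg_index", "call"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if not set(df["call"].unique()) <= {"M", "U"}:
        raise ValueError(f"{path}: calls must be 'M' or 'U'")
    clones = []
    for (cid, region), grp in df.groupby(["clone_id", "region"], sort=True):
        grp = grp.sort_values("cpg_index")
        clones.append(
            BisulphiteClone(str(cid), str(region), tuple(grp["call"] == "M"))
        )
    return clones
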
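"""G-quadruplex motif detection and replication-fork orientation.

A G-quadruplex (G4) motif is defined here, as throughout the field, by four
or more tracts of consecutive guanines separated by short non-G loops; the
stacked Hoogsteen-bonded G-quartets form from the tracts, while loop length
is the principal sequence covariate of structure stability and of the
epigenetic instability the downstream modules model.

Coordinates are 0-based, half-open, and always reported on the forward
strand axis, including for minus-strand motifs (BED convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Literal, Sequence, Tuple

from Bio.Seq import Seq

__all__ = [
    "GTract",
    "G4Motif",
    "ForkContext",
    "find_g_tracts",
    "scan_g4",
    "classify_fork_orientation",
    "motifs_to_bed",
    "motifs_to_tsv",
]

_DNA_RE = re.compile(r"^[ACGTN]*$")

#: Default minimum G-tract length. Three is the canonical quadruplex scan
#: threshold; two must remain selectable because weak motifs built from GG
#: tracts (e.g. thermodynamically unstable model quadruplexes) still fold.
DEFAULT_G_MIN = 3
DEFAULT_LOOP_MIN = 1
DEFAULT_LOOP_MAX = 7


@dataclass(frozen=True)
class GTract:
    """A maximal run of >= g_min consecutive guanines."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class G4Motif:
    """A detected quadruplex-forming motif.

    ``tracts`` are ordered 5'->3' on the scanned strand but expressed in
    forward-axis coordinates; ``loops`` are the inter-tract gap lengths in
    scanned-strand order, so ``len(loops) == len(tracts) - 1``.
    """

    sequence_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    tracts: Tuple[GTract, ...]
    loops: Tuple[int, ...]
    g_min: int

    @property
    def max_loop(self) -> int:
        return max(self.loops)

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)


@dataclass(frozen=True)
class ForkContext:
    """Direction a replication fork enters the locus, plus which strand is
    G-rich (``top`` corresponds to a + strand motif)."""

    fork_entry: Literal["left", "right"]
    g_rich_strand: Literal["top", "bottom"] = "top"

    def __post_init__(self) -> None:
        if self.fork_entry not in ("left", "right"):
            raise ValueError(f"fork_entry must be 'left' or 'right', got {self.fork_entry!r}")
        if self.g_rich_strand not in ("top", "bottom"):
            raise ValueError(f"g_rich_strand must be 'top' or 'bottom', got {self.g_rich_strand!r}")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return seq


def find_g_tracts(sequence: str, g_min: int = DEFAULT_G_MIN) -> List[GTract]:
    """Return all maximal runs of >= ``g_min`` consecutive G, left to right.

    N never extends a tract. A run of k > g_min guanines is a single tract
    of length k, not several overlapping ones.
    """
    if g_min < 2:
        raise ValueError(f"g_min must be >= 2, got {g_min}")
    seq = _validate_sequence(sequence)
    pattern = re.compile("G{%d,}" % g_min)
    return [GTract(m.start(), m.end()) for m in pattern.finditer(seq)]


def _chain_tracts(
    tracts: Sequence[GTract], loop_min: int, loop_max: int
) -> Iterator[List[GTract]]:
    """Split tracts into maximal chains whose consecutive gaps lie in
    [loop_min, loop_max]; only chains of >= 4 tracts can form a quadruplex."""
    chain: List[GTract] = []
    for t in tracts:
        if chain and loop_min <= t.start - chain[-1].end <= loop_max:
            chain.append(t)
        else:
            if len(chain) >= 4:
                yield chain
            chain = [t]
    if len(chain) >= 4:
        yield chain


def _motifs_on_plus(
    seq: str,
    sequence_id: str,
    g_min: int,
    loop_min: int,
    loop_max: int,
    all_windows: bool,
) -> Iterator[Tuple[Tuple[GTract, ...], Tuple[int, ...]]]:
    tracts = find_g_tracts(seq, g_min)
    for chain in _chain_tracts(tracts, loop_min, loop_max):
        if all_windows:
            for i in range(len(chain) - 3):
                window = chain[i : i + 4]
                yield tuple(window), tuple(
                    window[j + 1].start - window[j].end for j in range(3)
                )
        else:
            yield tuple(chain), tuple(
                chain[j + 1].start - chain[j].end for j in range(len(chain) - 1)
            )


def scan_g4(
    sequence: str,
    g_min: int = DEFAULT_G_MIN,
    loop_min: int = DEFAULT_LOOP_MIN,
    loop_max: int = DEFAULT_LOOP_MAX,
    both_strands: bool = False,
    sequence_id: str = "seq",
    all_windows: bool = False,
) -> List[G4Motif]:
    """Scan a sequence for G4 motifs.

    By default each maximal chain of >= 4 qualifying tracts is reported as a
    single motif extending over every tract in the chain (loop statistics
    are per-motif, and treating a locus motif as one unit matches how such
    motifs are handled experimentally). With ``all_windows`` every 4-tract
    decomposition within each chain is emitted instead.

    With ``both_strands`` the reverse complement is scanned as well; minus
    strand motifs are reported with strand ``-`` and forward-axis
    coordinates, tract order remaining 5'->3' on the G-rich strand.
    """
    if loop_min < 1:
        raise ValueError(f"loop_min must be >= 1, got {loop_min}")
    if loop_max < loop_min:
        raise ValueError(f"loop_max ({loop_max}) < loop_min ({loop_min})")
    seq = _validate_sequence(sequence)
    if not seq:
        return []

    motifs: List[G4Motif] = []
    for tracts, loops in _motifs_on_plus(seq, sequence_id, g_min, loop_min, loop_max, all_windows):
        motifs.append(
            G4Motif(
                sequence_id=sequence_id,
                start=tracts[0].start,
                end=tracts[-1].end,
                strand="+",
                tracts=tracts,
                loops=loops,
                g_min=g_min,
            )
        )
    if both_strands:
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for tracts, loops in _motifs_on_plus(rc, sequence_id, g_min, loop_min, loop_max, all_windows):
            # map revcomp coordinates [s, e) back onto the forward axis
            fwd_tracts = tuple(GTract(n - t.end, n - t.start) for t in tracts)
            motifs.append(
                G4Motif(
                    sequence_id=sequence_id,
                    start=fwd_tracts[-1].start,
                    end=fwd_tracts[0].end,
                    strand="-",
                    tracts=fwd_tracts,
                    loops=loops,
                    g_min=g_min,
                )
            )
    motifs.sort(key=lambda m: (m.start, m.strand))
    return motifs


def classify_fork_orientation(motif: G4Motif, ctx: ForkContext) -> str:
    """Classify whether the G-rich strand of ``motif`` is replicated as the
    leading- or lagging-strand template for the given fork.

    A fork entering from the right copies the top strand as its
    leading-strand template, so a top-strand (+) G4 faces the leading-strand
    polymerase; inverting either the motif strand or the fork entry
    direction flips the call.
    """
    g_on_top = motif.strand == "+"
    return "leading" if g_on_top == (ctx.fork_entry == "right") else "lagging"


def scan_fasta(records: Iterable, **kwargs) -> List[G4Motif]:
    """Scan an iterable of Bio.SeqRecord objects; convenience for CLI/files."""
    out: List[G4Motif] = []
    for rec in records:
        out.extend(scan_g4(str(rec.seq), sequence_id=rec.id, **kwargs))
    return out


def motifs_to_bed(motifs: Sequence[G4Motif]) -> str:
    """BED6: name carries the maximum loop length, score the tract count."""
    lines = [
        f"{m.sequence_id}\t{m.start}\t{m.end}\tmaxloop:{m.max_loop}\t{m.n_tracts}\t{m.strand}"
        for m in motifs
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def motifs_to_tsv(motifs: Sequence[G4Motif]) -> str:
    header = "sequence_id\tstart\tend\tstrand\tn_tracts\tloops\tmax_loop\tg_min"
    lines = [header]
    for m in motifs:
        loops = ",".join(str(x) for x in m.loops)
        lines.append(
            f"{m.sequence_id}\t{m.start}\t{m.end}\t{m.strand}\t{m.n_tracts}\t{loops}\t{m.max_loop}\t{m.g_min}"
        )
    return "\n".join(lines) + "\n"
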
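"""Synthetic sequencing data for an insertion library.

Emulates the wet-lab readout: sample clones from an insertion library,
PCR-amplify each fusion (with plasmid flanks), shear amplicons to 300-400 bp
fragments, and sequence one 300-nt single-end read per fragment with i.i.d.
substitution errors.  Read names encode full provenance (source event,
fragment coordinates, strand) so the mapper can be tested as an exact inverse
of the simulator at zero noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constructs import (
    InsertDesign,
    InsertionEvent,
    TargetConstruct,
    build_insertion_cds,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LibrarySpec",
    "ReadSimSpec",
    "FastqRead",
    "sample_library",
    "build_amplicon",
    "shear_and_read",
    "write_fastq",
    "parse_read_name",
    "pool_from_events",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class LibrarySpec:
    """How the transposition step populated the library.

    ``position_weights`` is a probability vector over gap coordinates
    0..L-d (uniform when None).  ``reverse_fraction`` is the probability of an
    antisense insertion (Mu inserts in both orientations; default 0.5).
    ``n_clones`` defaults to 190-fold coverage of the available positions,
    the colony coverage reported for the transposition reaction.
    """

    target: TargetConstruct
    design: InsertDesign
    n_clones: int | None = None
    position_weights: np.ndarray | None = None
    reverse_fraction: float = 0.5
    variant: str = "LOV02"

    DEFAULT_FOLD = 190

    def __post_init__(self) -> None:
        n_pos = self.n_positions
        if self.n_clones is None:
            self.n_clones = self.DEFAULT_FOLD * n_pos
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0.0 <= self.reverse_fraction <= 1.0:
            raise ValueError("reverse_fraction must be in [0, 1]")
        if self.position_weights is not None:
            w = np.asarray(self.position_weights, dtype=float)
            if w.shape != (n_pos,):
                raise ValueError(
                    f"position_weights must have length {n_pos}, got {w.shape}"
                )
            if w.sum() <= 0:
                raise ValueError("position_weights sum to zero")
            self.position_weights = w / w.sum()

    @property
    def n_positions(self) -> int:
        return self.target.length - self.design.tsd_len + 1


@dataclass
class ReadSimSpec:
    """Fragmentation and sequencing parameters (MiSeq-like defaults)."""

    fragment_len_range: tuple[int, int] = (300, 400)
    read_len: int = 300
    per_base_error: float = 0.001
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_len_range
        if not (0 < lo <= hi):
            raise ValueError("invalid fragment_len_range")
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must be in [0, 1]")


@dataclass
class FastqRead:
    name: str
    seq: str
    qual: str


def sample_library(spec: LibrarySpec, rng_seed: int) -> list[InsertionEvent]:
    """Draw ``n_clones`` i.i.d. insertion events (position x orientation)."""
    rng = np.random.default_rng(rng_seed)
    n_pos = spec.n_positions
    positions = rng.choice(n_pos, size=spec.n_clones, p=spec.position_weights)
    reverse = rng.random(spec.n_clones) < spec.reverse_fraction
    return [
        InsertionEvent(
            p=int(p),
            orientation="reverse" if r else "forward",
            variant=spec.variant,
        )
        for p, r in zip(positions, reverse)
    ]


def build_amplicon(
    event: InsertionEvent, target: TargetConstruct, design: InsertDesign
) -> str:
    """PCR amplicon: upstream flank + fusion CDS + downstream flank."""
    fusion = build_insertion_cds(target, event, design)
    return target.upstream_flank + fusion + target.downstream_flank


def pool_from_events(
    events: list[InsertionEvent],
    target: TargetConstruct,
    design: InsertDesign,
    weights: np.ndarray | None = None,
) -> list[tuple[str, str, float]]:
    """Weighted amplicon pool ``(label, sequence, weight)`` from events.

    Duplicate events are collapsed; weights default to event multiplicity.
    """
    agg: dict[InsertionEvent, float] = {}
    if weights is None:
        for ev in events:
            agg[ev] = agg.get(ev, 0.0) + 1.0
    else:
        if len(weights) != len(events):
            raise ValueError("weights must match events")
        for ev, w in zip(events, weights):
            agg[ev] = agg.get(ev, 0.0) + float(w)
    pool = []
    for ev, w in agg.items():
        label = f"p={ev.p};orient={ev.orientation};variant={ev.variant}"
        pool.append((label, build_amplicon(ev, target, design), w))
    return pool


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        orig = arr[hit]
        repl = _BASES[rng.integers(0, 4, size=hit.size)]
        clash = repl == orig
        while clash.any():
            repl[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = repl == orig
        arr[hit] = repl
    return arr.tobytes().decode()


def shear_and_read(
    pool: list[tuple[str, str, float]], spec: ReadSimSpec
) -> list[FastqRead]:
    """Shear a weighted amplicon pool and emit single-end error-bearing reads.

    Per read: an amplicon is drawn with probability proportional to weight, a
    fragment start uniform within it, a fragment length uniform in
    ``fragment_len_range``, and the read is taken from a uniformly chosen
    fragment end/strand, truncated to ``read_len``.  Fragments that do not fit
    the amplicon are skipped with a logged warning (read count shrinks
    accordingly).  Deterministic given ``spec.seed``.
    """
    if not pool:
        raise ValueError("empty amplicon pool")
    rng = np.random.default_rng(spec.seed)
    labels = [x[0] for x in pool]
    seqs = [x[1] for x in pool]
    w = np.array([x[2] for x in pool], dtype=float)
    if w.sum() <= 0:
        raise ValueError("pool weights sum to zero")
    w = w / w.sum()
    lo, hi = spec.fragment_len_range

    if spec.per_base_error > 0:
        q = min(40, max(2, round(-10 * math.log10(spec.per_base_error))))
    else:
        q = 40
    qchar = chr(q + 33)

    picks = rng.choice(len(pool), size=spec.n_reads, p=w)
    frag_lens = rng.integers(lo, hi + 1, size=spec.n_reads)
    u_start = rng.random(spec.n_reads)
    ends = rng.integers(0, 2, size=spec.n_reads)  # 0: left end/+, 1: right end/-

    reads: list[FastqRead] = []
    n_skipped = 0
    for i in range(spec.n_reads):
        amp = seqs[picks[i]]
        flen = int(frag_lens[i])
        if flen > len(amp):
            n_skipped += 1
            continue
        start = int(u_start[i] * (len(amp) - flen + 1))
        frag = amp[start : start + flen]
        if ends[i] == 0:
            strand = "+"
            read_seq = frag[: spec.read_len]
        else:
            strand = "-"
            read_seq = reverse_complement(frag)[: spec.read_len]
        read_seq = _apply_errors(read_seq, spec.per_base_error, rng)
        name = (
            f"{labels[picks[i]]};frag={start}:{start + flen};"
            f"strand={strand};i={i}"
        )
        reads.append(FastqRead(name=name, seq=read_seq, qual=qchar * len(read_seq)))
    if n_skipped:
        logger.warning(
            "skipped %d/%d fragments longer than their amplicon", n_skipped, spec.n_reads
        )
    return reads


def parse_read_name(name: str) -> dict[str, str]:
    """Invert the provenance encoding in simulated read names."""
    out: dict[str, str] = {}
    for part in name.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_fastq(reads: list[FastqRead], path) -> None:
    """Plain 4-line FASTQ, Phred+33."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
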
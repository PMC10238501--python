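"""Junction-read mapping: from FASTQ to per-position insertion counts.

A junction read spans the boundary between target sequence and the inserted
domain cassette.  Detection is anchor-based: the first/last ``anchor_len``
bases of the cassette (s5+domain+s3) and their reverse complements are located
in each read with a small edit tolerance; the target-derived flank adjacent to
each junction is then looked up exactly (with <=1 mismatch fallback) in a
k-mer index of the target CDS.  The insertion position ``p`` follows the
target-site-duplication convention: the duplicated d-mer belongs to the left
junction, and every call is normalised to the leftmost position consistent
with the fusion sequence, so left and right junctions of the same insert agree.

Target CDSs here are short (~0.6-1 kb), so an exact k-mer dictionary is both
robust and fast; no external aligner is involved.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .constructs import (
    InsertDesign,
    TargetConstruct,
    normalize_position,
    reverse_complement,
)

__all__ = [
    "TargetIndex",
    "MapParams",
    "InsertionCall",
    "InsertionProfile",
    "index_target",
    "find_junctions",
    "call_insertion",
    "build_profile",
]


class TargetIndex:
    """Exact k-mer -> offset lookup over both strands of a target CDS."""

    def __init__(self, cds: str, k: int = 20):
        if k > len(cds):
            raise ValueError(f"k={k} exceeds target length {len(cds)}")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.cds = cds.upper()
        self.k = k
        index: dict[str, list[tuple[int, str]]] = {}
        for i in range(len(self.cds) - k + 1):
            kmer = self.cds[i : i + k]
            index.setdefault(kmer, []).append((i, "+"))
            index.setdefault(reverse_complement(kmer), []).append((i, "-"))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[int, str]]:
        return self._index.get(kmer, [])

    def lookup_approx(self, kmer: str, max_mm: int = 1) -> list[tuple[int, str, int]]:
        """Hits as (offset, strand, mismatches); exact first, else 1-mm neighbours."""
        hits = [(o, s, 0) for o, s in self.lookup(kmer)]
        if hits or max_mm < 1:
            return hits
        seen = set()
        for i, base in enumerate(kmer):
            for b in "ACGT":
                if b == base:
                    continue
                neighbour = kmer[:i] + b + kmer[i + 1 :]
                for o, s in self.lookup(neighbour):
                    if (o, s) not in seen:
                        seen.add((o, s))
                        hits.append((o, s, 1))
        return hits


def index_target(cds: str, k: int = 20) -> TargetIndex:
    return TargetIndex(cds, k=k)


@dataclass
class MapParams:
    k: int = 20
    anchor_len: int = 15
    max_anchor_edits: int = 1
    max_flank_mismatches: int = 1
    min_flank: int = 20

    def __post_init__(self) -> None:
        if self.anchor_len < 12:
            raise ValueError("anchor_len must be >= 12")
        if self.min_flank < self.k:
            raise ValueError("min_flank must be >= index k")


@dataclass(frozen=True)
class InsertionCall:
    p: int
    orientation: str
    side: str  # left | right | both
    mismatches: int


@dataclass
class InsertionProfile:
    """Per-(position, orientation) junction-read counts with read accounting."""

    counts: dict[tuple[int, str], int] = field(default_factory=dict)
    label: str = ""
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    ambiguous: int = 0
    non_junction: int = 0

    def add(self, call: InsertionCall) -> None:
        key = (call.p, call.orientation)
        self.counts[key] = self.counts.get(key, 0) + 1

    def positions(self, orientation: str | None = None) -> set[int]:
        return {
            p
            for (p, o), c in self.counts.items()
            if c > 0 and (orientation is None or o == orientation)
        }

    def count_at(self, p: int, orientation: str | None = None) -> int:
        if orientation is not None:
            return self.counts.get((p, orientation), 0)
        return sum(c for (q, _), c in self.counts.items() if q == p)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"p": p, "orientation": o, "count": c}
            for (p, o), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["p", "orientation", "count"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key in ("label", "total", "mapped", "unmapped", "ambiguous", "non_junction"):
                fh.write(f"# {key}: {getattr(self, key)}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InsertionProfile":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        prof = cls(
            label=meta.get("label", ""),
            total=int(meta.get("total", 0)),
            mapped=int(meta.get("mapped", 0)),
            unmapped=int(meta.get("unmapped", 0)),
            ambiguous=int(meta.get("ambiguous", 0)),
            non_junction=int(meta.get("non_junction", 0)),
        )
        for _, row in df.iterrows():
            prof.counts[(int(row["p"]), str(row["orientation"]))] = int(row["count"])
        return prof


def _find_anchor(anchor: str, read: str, max_edits: int) -> tuple[int, int, int] | None:
    """Leftmost occurrence of ``anchor`` in ``read`` with <= max_edits edits.

    Exact substring search first; edlib infix alignment as the tolerant
    fallback (edit distance, so rare indels — including anchors truncated by
    the fragment boundary — are tolerated).  Returns (start, end_exclusive,
    edits); the alignment's own end coordinate matters because a deletion in
    the anchor shifts where the adjacent flank begins.
    """
    pos = read.find(anchor)
    if pos >= 0:
        return pos, pos + len(anchor), 0
    if max_edits < 1:
        return None
    res = edlib.align(anchor, read, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    start = 0 if start is None else start
    return start, end + 1, res["editDistance"]


def find_junctions(
    read: str,
    design: InsertDesign,
    variant: str = "LOV02",
    anchor_len: int = 15,
    max_edits: int = 1,
) -> list[tuple[str, int, str]]:
    """All cassette-end anchor hits in a read: (side, read offset, orientation).

    Sides/orientations refer to the forward-amplicon interpretation of the
    read as given (callers also scan the reverse complement of the read).
    """
    ins = design.insert_seq(variant)
    a = min(anchor_len, len(ins))
    anchors = [
        ("left", "forward", ins[:a]),
        ("right", "forward", ins[-a:]),
        ("left", "reverse", reverse_complement(ins)[:a]),
        ("right", "reverse", reverse_complement(ins)[-a:]),
    ]
    hits = []
    for side, orient, anchor in anchors:
        found = _find_anchor(anchor, read, max_edits)
        if found is not None:
            hits.append((side, found[0], orient))
    return hits


def _junction_hits(
    read: str, design: InsertDesign, variant: str, anchor_len: int, max_edits: int
) -> list[tuple[str, int, int, str]]:
    """Like :func:`find_junctions` but with the anchor end coordinate too."""
    ins = design.insert_seq(variant)
    a = min(anchor_len, len(ins))
    anchors = [
        ("left", "forward", ins[:a]),
        ("right", "forward", ins[-a:]),
        ("left", "reverse", reverse_complement(ins)[:a]),
        ("right", "reverse", reverse_complement(ins)[-a:]),
    ]
    hits = []
    for side, orient, anchor in anchors:
        found = _find_anchor(anchor, read, max_edits)
        if found is not None:
            hits.append((side, found[0], found[1], orient))
    return hits


def call_insertion(
    read: str,
    index: TargetIndex,
    design: InsertDesign,
    variant: str = "LOV02",
    params: MapParams | None = None,
) -> tuple[InsertionCall | None, str]:
    """Call the insertion supported by one read.

    Returns ``(call, category)`` with category one of mapped / unmapped /
    ambiguous / non-junction.  Both read orientations are scanned; for each
    junction the target flank k-mer adjacent to the cassette is looked up on
    the forward strand of the index, ``p`` is derived (left junction:
    flank-end offset minus d; right junction: matched offset) and normalised
    to the leftmost consistent position.  Calls from multiple junctions must
    agree, otherwise the read is ambiguous.
    """
    if params is None:
        params = MapParams()
    d = design.tsd_len
    ins = design.insert_seq(variant)
    a = min(params.anchor_len, len(ins))
    L = len(index.cds)

    calls: list[tuple[int, str, str, int]] = []  # p, orientation, side, mismatches
    any_flanked = False
    multi_locus = False

    for r in (read, reverse_complement(read)):
        for side, pos, end, orient in _junction_hits(
            r, design, variant, anchor_len=a, max_edits=params.max_anchor_edits
        ):
            if side == "left":
                flank = r[:pos]
                if len(flank) < params.min_flank:
                    continue
                kmer = flank[-index.k :]
            else:
                flank = r[end:]
                if len(flank) < params.min_flank:
                    continue
                kmer = flank[: index.k]
            any_flanked = True
            hits = [
                h
                for h in index.lookup_approx(kmer, params.max_flank_mismatches)
                if h[1] == "+"
            ]
            offsets = {h[0] for h in hits}
            if len(offsets) > 1:
                multi_locus = True
                continue
            if not offsets:
                continue
            o, _, mm = hits[0]
            if side == "left":
                p = o + index.k - d
            else:
                p = o
            if not 0 <= p <= L - d:
                continue
            p = normalize_position(index.cds, p, d)
            calls.append((p, orient, side, mm))

    if not any_flanked:
        # no anchor at all, or anchors without enough adjacent target sequence
        return None, "non-junction"
    if multi_locus and not calls:
        return None, "ambiguous"
    if not calls:
        return None, "unmapped"
    keys = {(p, orient) for p, orient, _, _ in calls}
    if len(keys) > 1:
        return None, "ambiguous"
    p, orient = keys.pop()
    sides = {side for _, _, side, _ in calls}
    side = "both" if len(sides) > 1 else sides.pop()
    mm = min(m for _, _, _, m in calls)
    return InsertionCall(p=p, orientation=orient, side=side, mismatches=mm), "mapped"


def _iter_fastq(path):
    """Yield (name, seq) from a (possibly gzipped) 4-line FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                break
            record += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if (
                not header.startswith("@")
                or not plus.startswith("+")
                or not seq
                or not qual
                or len(qual.strip()) != len(seq.strip())
            ):
                raise ValueError(f"malformed FASTQ record #{record} in {path}")
            yield header[1:].strip(), seq.strip().upper()


def build_profile(
    fastq_paths,
    target: TargetConstruct,
    design: InsertDesign,
    variant: str = "LOV02",
    params: MapParams | None = None,
    label: str = "",
) -> InsertionProfile:
    """Aggregate per-read insertion calls over one or more FASTQ files.

    The accounting identity total == mapped + unmapped + ambiguous +
    non_junction holds for every run.
    """
    if params is None:
        params = MapParams()
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    index = TargetIndex(target.cds, k=params.k)
    profile = InsertionProfile(label=label)
    for path in fastq_paths:
        for _name, seq in _iter_fastq(path):
            profile.total += 1
            call, category = call_insertion(seq, index, design, variant, params)
            if category == "mapped":
                profile.mapped += 1
                profile.add(call)
            elif category == "unmapped":
                profile.unmapped += 1
            elif category == "ambiguous":
                profile.ambiguous += 1
            else:
                profile.non_junction += 1
    return profile
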
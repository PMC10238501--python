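"""In-silico model of domain-insertion constructs.

A transposase-generated insertion library places a domain cassette at (almost)
every nucleotide position of a target CDS.  Mu transposition duplicates a short
target-site sequence (``d`` nucleotides, 5 by default) at the insertion point,
and the cassette carries a few extra "scar" bases at its 5'/3' ends.  Three
frame variants of the cassette (LOV01/LOV02/LOV03, differing only in scar
length) guarantee that for every insertion position exactly one variant places
the domain in frame with the target.

Coordinates: an insertion position ``p`` is a 0-based gap coordinate — the
number of target-CDS nucleotides 5' of the insertion point.  The duplicated
d-mer ``cds[p:p+d]`` is attributed to the left junction, and ``p`` is always
normalised to the leftmost position producing an identical fusion sequence
(locally repetitive targets make several ``p`` indistinguishable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "TargetConstruct",
    "FrameVariant",
    "InsertDesign",
    "InsertionEvent",
    "FrameCall",
    "translate_cds",
    "reverse_complement",
    "reverse_translate",
    "build_insertion_cds",
    "classify_frame",
    "assign_aa_site",
    "enumerate_in_frame_positions",
    "normalize_position",
    "construct_report",
]

_VALID = set("ACGT")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

# fixed one-codon-per-amino-acid table used by reverse_translate (naive scheme,
# no codon-usage optimisation; chosen codons can never form an in-frame stop)
_AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_nt(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)} in {what}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return _check_nt(seq)[::-1].translate(_COMPLEMENT)


def translate_cds(seq: str) -> str:
    """Translate a nucleotide sequence with the standard genetic code.

    Stop codons are rendered as ``*``; a trailing partial codon is ignored.
    Raises ``ValueError`` on non-ACGT input or length < 3.
    """
    seq = _check_nt(seq)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    n = len(seq) // 3 * 3
    return "".join(_CODON_TABLE[seq[i : i + 3]] for i in range(0, n, 3))


def reverse_translate(protein: str) -> str:
    """Deterministic naive reverse translation (one fixed codon per residue)."""
    try:
        return "".join(_AA_TO_CODON[aa] for aa in protein.upper())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot reverse-translate residue {exc}") from exc


@dataclass(frozen=True)
class TargetConstruct:
    """A target CDS with optional plasmid flanks and its protein translation."""

    name: str
    cds: str
    upstream_flank: str = ""
    downstream_flank: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", _check_nt(self.cds, "cds"))
        object.__setattr__(
            self, "upstream_flank", _check_nt(self.upstream_flank, "upstream_flank")
        )
        object.__setattr__(
            self, "downstream_flank", _check_nt(self.downstream_flank, "downstream_flank")
        )
        if len(self.cds) % 3 != 0:
            raise ValueError(f"CDS length {len(self.cds)} is not a multiple of 3")

    @property
    def length(self) -> int:
        return len(self.cds)

    @property
    def protein(self) -> str:
        """Translation of the CDS up to (not including) a terminal stop."""
        aa = translate_cds(self.cds)
        return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class FrameVariant:
    """One frame-shifted version of the insert: scar bases flanking the domain.

    The default trio follows the library design: LOV01 carries one extra base
    5' of the domain, LOV02 two extra bases at both ends, LOV03 one extra base
    3' of the domain.  Frame arithmetic depends only on the scar *lengths*;
    the default scar base identities are a documented convention.
    """

    name: str
    s5: str = ""
    s3: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "s5", _check_nt(self.s5, "s5"))
        object.__setattr__(self, "s3", _check_nt(self.s3, "s3"))


DEFAULT_VARIANTS = (
    FrameVariant("LOV01", s5="G", s3=""),
    FrameVariant("LOV02", s5="GG", s3="CC"),
    FrameVariant("LOV03", s5="", s3="C"),
)


@dataclass(frozen=True)
class InsertDesign:
    """The domain insert plus frame-variant scars and target-site duplication.

    ``tsd_len`` is the Mu target-site duplication (5 bp).  Every variant must
    preserve the downstream reading frame:
    ``(tsd_len + len(s5) + len(domain) + len(s3)) % 3 == 0``.
    """

    domain_seq: str
    tsd_len: int = 5
    variants: tuple[FrameVariant, ...] = DEFAULT_VARIANTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_seq", _check_nt(self.domain_seq, "domain_seq"))
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        object.__setattr__(self, "variants", tuple(self.variants))
        for v in self.variants:
            total = self.tsd_len + len(v.s5) + len(self.domain_seq) + len(v.s3)
            if total % 3 != 0:
                raise ValueError(
                    f"variant {v.name}: inserted length {total} (tsd+s5+domain+s3) "
                    "is not a multiple of 3 — downstream frame not preserved"
                )

    def variant(self, name: str) -> FrameVariant:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(f"unknown frame variant {name!r}")

    def insert_seq(self, variant: str | FrameVariant) -> str:
        """s5 + domain + s3 for the given variant (forward orientation)."""
        v = variant if isinstance(variant, FrameVariant) else self.variant(variant)
        return v.s5 + self.domain_seq + v.s3


@dataclass(frozen=True)
class InsertionEvent:
    """A single insertion: gap coordinate ``p``, orientation, frame variant."""

    p: int
    orientation: str = "forward"
    variant: str = "LOV02"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")
        if self.p < 0:
            raise ValueError(f"insertion position {self.p} < 0")


@dataclass(frozen=True)
class FrameCall:
    domain_in_frame: bool
    downstream_in_frame: bool
    stop_in_linker: bool
    functional: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "functional",
            self.functional
            and self.domain_in_frame
            and self.downstream_in_frame
            and not self.stop_in_linker,
        )


def _validate_event(event: InsertionEvent, target: TargetConstruct, design: InsertDesign) -> None:
    L = target.length
    if not 0 <= event.p <= L:
        raise ValueError(f"insertion position p={event.p} outside [0, {L}]")
    if event.p + design.tsd_len > L:
        raise ValueError(
            f"duplication does not fit: p={event.p} + d={design.tsd_len} > L={L}"
        )


def build_insertion_cds(
    target: TargetConstruct, event: InsertionEvent, design: InsertDesign
) -> str:
    """Fusion CDS for one insertion event.

    Forward orientation returns ``cds[0:p+d] + s5 + domain + s3 + cds[p:L]``;
    the d-mer ``cds[p:p+d]`` appears twice (target-site duplication).  Reverse
    orientation inserts the reverse complement of ``s5+domain+s3`` between the
    same target segments.
    """
    _validate_event(event, target, design)
    insert = design.insert_seq(event.variant)
    if event.orientation == "reverse":
        insert = reverse_complement(insert)
    d = design.tsd_len
    cds = target.cds
    return cds[: event.p + d] + insert + cds[event.p :]


def _linker_regions(p: int, d: int, s5: str, domain: str, s3: str) -> list[tuple[int, int]]:
    """Fusion-coordinate ranges of the duplication/scar bases at both junctions."""
    left = (p, p + d + len(s5))
    right_start = p + d + len(s5) + len(domain)
    right = (right_start, right_start + len(s3) + d)
    return [left, right]


def classify_frame(
    event: InsertionEvent, design: InsertDesign, target: TargetConstruct
) -> FrameCall:
    """Frame bookkeeping for one insertion.

    The domain is in frame iff its first base lands on a codon boundary of the
    target frame, i.e. ``(p + d + len(s5)) % 3 == 0`` (forward orientation only
    — an antisense insert cannot encode the domain).  The downstream target is
    in frame iff the total inserted length is a multiple of 3.  ``stop_in_linker``
    scans codons of the built fusion overlapping the duplication/scar regions.
    """
    _validate_event(event, target, design)
    v = design.variant(event.variant)
    d = design.tsd_len
    forward = event.orientation == "forward"
    domain_in_frame = forward and (event.p + d + len(v.s5)) % 3 == 0
    total_insert = d + len(v.s5) + len(design.domain_seq) + len(v.s3)
    downstream_in_frame = total_insert % 3 == 0

    fusion = build_insertion_cds(target, event, design)
    aa = translate_cds(fusion)
    stop_in_linker = False
    for start, end in _linker_regions(event.p, d, v.s5, design.domain_seq, v.s3):
        first_codon = start // 3
        last_codon = (end - 1) // 3 if end > start else first_codon - 1
        for c in range(first_codon, min(last_codon + 1, len(aa))):
            if aa[c] == "*":
                stop_in_linker = True
    return FrameCall(
        domain_in_frame=domain_in_frame,
        downstream_in_frame=downstream_in_frame,
        stop_in_linker=stop_in_linker,
        functional=forward,
    )


def assign_aa_site(fusion_cds: str, target_protein: str) -> int:
    """Amino-acid insertion-site label via translation-prefix matching.

    Returns the length of the longest common prefix of the fusion's translation
    and the intact target protein; a construct with site ``s`` is labelled
    "after residue s" (site 22 = insertion between residues 22 and 23).
    """
    aa = translate_cds(fusion_cds)
    site = 0
    for a, b in zip(aa, target_protein):
        if a != b:
            break
        site += 1
    return site


def normalize_position(cds: str, p: int, d: int) -> int:
    """Leftmost insertion position producing an identical fusion sequence.

    Shifting the insertion point one base left leaves the fusion unchanged iff
    ``cds[p-1] == cds[p+d-1]`` (the duplicated window slides over equal bases).
    """
    while p > 0 and cds[p - 1] == cds[p + d - 1]:
        p -= 1
    return p


def enumerate_in_frame_positions(
    target: TargetConstruct, design: InsertDesign
) -> dict[int, str | None]:
    """Map every insertion position to the variant that is fully in frame.

    With the default LOV01/LOV02/LOV03 scars and d=5 the three variants
    partition the positions by residue class mod 3 (LOV01: p≡0, LOV03: p≡1,
    LOV02: p≡2).  Raises if any position is claimed by more than one variant.
    """
    out: dict[int, str | None] = {}
    for p in range(0, target.length - design.tsd_len + 1):
        claimed = []
        for v in design.variants:
            ev = InsertionEvent(p=p, orientation="forward", variant=v.name)
            call = classify_frame(ev, design, target)
            if call.domain_in_frame and call.downstream_in_frame:
                claimed.append(v.name)
        if len(claimed) > 1:
            raise ValueError(f"position {p} claimed by multiple variants: {claimed}")
        out[p] = claimed[0] if claimed else None
    return out


def construct_report(
    target: TargetConstruct,
    design: InsertDesign,
    events: list[InsertionEvent],
):
    """Tabular construct report (pandas DataFrame).

    Columns: p, variant, orientation, domain_in_frame, downstream_in_frame,
    stop_in_linker, functional, aa_site.
    """
    import pandas as pd

    rows = []
    for ev in events:
        call = classify_frame(ev, design, target)
        fusion = build_insertion_cds(target, ev, design)
        site = assign_aa_site(fusion, target.protein) if call.functional else None
        rows.append(
            {
                "p": ev.p,
                "variant": ev.variant,
                "orientation": ev.orientation,
                "domain_in_frame": call.domain_in_frame,
                "downstream_in_frame": call.downstream_in_frame,
                "stop_in_linker": call.stop_in_linker,
                "functional": call.functional,
                "aa_site": site,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "p",
            "variant",
            "orientation",
            "domain_in_frame",
            "downstream_in_frame",
            "stop_in_linker",
            "functional",
            "aa_site",
        ],
    )
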
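"""Packaged reference sequences and the bundled demo pipeline config.

The two FASTA files are *synthetic reconstructions*: the study plasmids are
not public as sequence files, so the CDSs here were produced by reverse
translation (fixed codon per residue) of the canonical protein sequences —
the Gal4 DNA-binding domain residues 1-147 (with its Zn2Cys6 cysteines at
positions 11/14/21/28/31/38 and the Ser22/Lys23/Ala29 hit region) fused via a
GS linker to a 4xVP16 VP64 activation domain, and the AsLOV2 photosensor
domain, residues 408-543 of Avena sativa phototropin 1 (408 nt).  Everything
downstream (frame arithmetic, mapping, screening) depends only on sequence
lengths and the local bases around insertion points, not on codon choice.
"""

from __future__ import annotations

from importlib import resources

from Bio import SeqIO

from ..constructs import InsertDesign, TargetConstruct

GAL4_VP64_FASTA = "gal4_vp64_synthetic_cds.fasta"
ASLOV2_FASTA = "aslov2_408_543_synthetic_cds.fasta"
DEMO_CONFIG = "demo_config.yaml"


def _read_single_fasta(name: str) -> tuple[str, str]:
    with resources.files(__package__).joinpath(name).open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return rec.id, str(rec.seq).upper()


def load_gal4_vp64() -> TargetConstruct:
    """The Gal4(1-147)-VP64 target construct (600-nt CDS incl. stop codon)."""
    name, cds = _read_single_fasta(GAL4_VP64_FASTA)
    return TargetConstruct(name=name, cds=cds)


def load_aslov2_design(**kwargs) -> InsertDesign:
    """Default insert design: AsLOV2(408-543) domain, 5-bp TSD, LOV01/02/03 scars."""
    _, domain = _read_single_fasta(ASLOV2_FASTA)
    return InsertDesign(domain_seq=domain, **kwargs)


def demo_config_path() -> str:
    """Filesystem path of the bundled demo pipeline config."""
    return str(resources.files(__package__).joinpath(DEMO_CONFIG))
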
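"""Bundled synthetic default inputs.

Everything in this directory is a synthetic stand-in, generated
deterministically by ``scripts/build_bundled_data.py``: a 3096 bp GC-rich
lacZ-like reference, an eight-signature SBS-like set on human-genome-like
composition, and genome-like human/mouse trinucleotide frequency tables.
They exercise every pipeline stage with known ground truth; none of them is
measured biological data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..reference import ContextFrequencyTable, ReferenceSequence
from ..reference import load_reference as _load_fasta
from ..signatures import SignatureSet


def _path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def load_reference() -> ReferenceSequence:
    """The bundled synthetic 3096 bp lacZ-like reference."""
    return _load_fasta(_path("lacz_synthetic.fa"))


def load_signatures() -> SignatureSet:
    """The bundled synthetic SBS-like signature set (raw, human composition)."""
    return SignatureSet.from_tsv(_path("signatures_synthetic.tsv"))


def load_context_table(genome: str = "human") -> ContextFrequencyTable:
    """Bundled genome-like trinucleotide frequency table ('human' or 'mouse')."""
    if genome not in ("human", "mouse"):
        raise ValueError("genome must be 'human' or 'mouse'")
    return ContextFrequencyTable.from_tsv(
        _path(f"context_freq_{genome}_synthetic.tsv"), source=f"{genome}-synthetic"
    )
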
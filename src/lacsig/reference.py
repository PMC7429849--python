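"""Reference-sequence handling for the lacZ transgene.

The MutaMouse lacZ reporter is scored on its coding sequence; all positional
coordinates in this package are 1-based, closed, on the coding strand.
This module loads and validates the reference FASTA, computes its
pyrimidine-collapsed trinucleotide composition, enumerates the mutable SNV
space, and harmonises mutation coordinates reported under older conventions
(plasmid or E. coli V00296.1 CDS numbering) into the assay's CDS coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .channels import BASES, CONTEXTS_32, PYRIMIDINES, collapse_context

logger = logging.getLogger(__name__)

_ALPHABET = set(BASES)


@dataclass(frozen=True)
class ReferenceSequence:
    """A validated reporter-gene coding sequence.

    Positions are 1-based on the coding strand; ``context(pos)`` returns the
    trinucleotide centred on ``pos`` and is undefined at the two terminal
    positions, which have no in-CDS flanking base.
    """

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 3:
            raise ValueError("reference must be at least 3 bp")
        for i, b in enumerate(self.bases, start=1):
            if b not in _ALPHABET:
                raise ValueError(
                    f"non-ACGT character {b!r} at position {i} of {self.name}"
                )

    @property
    def length(self) -> int:
        return len(self.bases)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.bases[position - 1]

    def context(self, position: int) -> str:
        """Coding-strand trinucleotide centred on a 1-based position."""
        if not 2 <= position <= self.length - 1:
            raise IndexError(
                f"position {position} has no in-CDS trinucleotide context"
            )
        return self.bases[position - 2 : position + 1]


def load_reference(path: str | Path) -> ReferenceSequence:
    """Load a single-record FASTA as a :class:`ReferenceSequence`.

    The sequence is uppercased on ingest; a multi-record file or any
    non-ACGT character is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(f"expected a single record in {path}, found {len(records)}")
    rec = records[0]
    return ReferenceSequence(name=rec.id, bases=str(rec.seq).upper())


@dataclass(frozen=True)
class ContextFrequencyTable:
    """Relative frequencies of the 32 pyrimidine-centred trinucleotides.

    The 64 strand-specific trinucleotides are collapsed by reverse complement
    onto the pyrimidine-centred representatives, matching the channel
    convention of SBS signatures.
    """

    frequencies: pd.Series  # indexed by CONTEXTS_32
    source: str = "custom"

    def __post_init__(self) -> None:
        freq = self.frequencies.reindex(list(CONTEXTS_32))
        if freq.isna().any():
            missing = sorted(set(CONTEXTS_32) - set(self.frequencies.index))
            raise ValueError(f"missing contexts: {missing}")
        if (freq < 0).any():
            raise ValueError("context frequencies must be non-negative")
        if abs(float(freq.sum()) - 1.0) > 1e-9:
            raise ValueError(f"context frequencies sum to {freq.sum()}, not 1")
        object.__setattr__(self, "frequencies", freq.astype(float))

    def __getitem__(self, context: str) -> float:
        return float(self.frequencies[context])

    @classmethod
    def from_counts(cls, counts: dict[str, float] | pd.Series, source: str = "custom"):
        s = pd.Series(counts, dtype=float).reindex(list(CONTEXTS_32)).fillna(0.0)
        total = float(s.sum())
        if total <= 0:
            raise ValueError("no context counts")
        return cls(frequencies=s / total, source=source)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None):
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"context", "frequency"} <= set(df.columns):
            raise ValueError(f"{path}: need columns 'context' and 'frequency'")
        s = df.set_index("context")["frequency"]
        return cls(frequencies=s, source=source or Path(path).stem)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frequencies.rename("frequency").rename_axis("context").reset_index()
        out.to_csv(path, sep="\t", index=False)


def count_contexts(ref: ReferenceSequence, source: str | None = None) -> ContextFrequencyTable:
    """Pyrimidine-collapsed trinucleotide composition of a reference.

    Every one of the L-2 windows on the coding strand contributes one count:
    to its own context if pyrimidine-centred, else to the reverse complement.
    """
    counts: dict[str, int] = {c: 0 for c in CONTEXTS_32}
    b = ref.bases
    for i in range(len(b) - 2):
        counts[collapse_context(b[i : i + 3])] += 1
    return ContextFrequencyTable.from_counts(counts, source=source or ref.name)


def enumerate_possible_snvs(ref: ReferenceSequence) -> int:
    """Number of distinct SNV events the reference supports (3 per position)."""
    return 3 * ref.length


@dataclass(frozen=True)
class CoordinateAdjustment:
    """Offset rules mapping a source coordinate convention onto assay CDS coordinates.

    Each rule ``(threshold, offset)`` shifts source positions strictly greater
    than ``threshold`` by ``offset`` (offsets accumulate across rules); a
    positive offset models an insertion in the assay reference relative to the
    source. Assay positions that fall inside such an insertion have no source
    counterpart and are flagged when inverted. ``variant_positions`` lists
    assay positions whose base differs from the source reference by a
    substitution, where a reported ref allele cannot be re-validated.
    """

    rules: tuple[tuple[int, int], ...] = ()
    variant_positions: frozenset[int] = frozenset()
    source: str = "plasmid"

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.rules]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("rule thresholds must be strictly increasing")
        object.__setattr__(self, "rules", tuple((int(t), int(o)) for t, o in self.rules))
        object.__setattr__(self, "variant_positions", frozenset(self.variant_positions))

    def adjust(self, position: int) -> int:
        """Map a source-convention position to the assay CDS coordinate.

        Raises :class:`GapPositionError` for source positions deleted in the
        assay reference (inside a negative-offset segment).
        """
        shift = 0
        for threshold, offset in self.rules:
            if position <= threshold:
                break
            if offset < 0 and position <= threshold - offset:
                raise GapPositionError(
                    f"source position {position} is deleted in the assay "
                    f"reference (after source position {threshold})"
                )
            shift += offset
        return position + shift

    def invert(self, position: int) -> int:
        """Map an assay CDS position back to the source convention.

        Raises :class:`GapPositionError` for positions inside an inserted
        segment, which have no image in the source coordinate system.
        """
        shift = 0
        for threshold, offset in self.rules:
            lo = threshold + shift  # assay coordinate of the rule boundary
            if position <= lo:
                break
            if offset > 0 and position <= lo + offset:
                raise GapPositionError(
                    f"assay position {position} lies inside the insertion after "
                    f"source position {threshold}"
                )
            shift += offset
        return position - shift

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "custom"):
        df = pd.read_csv(path, sep="\t", comment="#")
        rules = tuple(
            (int(r.threshold), int(r.offset)) for r in df.itertuples(index=False)
        )
        return cls(rules=rules, source=source)


class GapPositionError(ValueError):
    """An assay coordinate with no counterpart under the source convention."""


#: The assay lacZ reference differs from the E. coli V00296.1 CDS by a 15 bp
#: insertion into codon 8 (after nucleotide 24) plus substitution variants.
V00296_CDS_ADJUSTMENT = CoordinateAdjustment(rules=((24, 15),), source="V00296.1-CDS")


def adjust_coordinates(
    records: pd.DataFrame,
    adjustment: CoordinateAdjustment,
    ref: ReferenceSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-express mutation positions in assay CDS coordinates.

    Takes a catalog-style frame with at least ``position`` and ``ref``
    columns. Returns ``(accepted, rejected)``; rejected records carry a
    ``reason`` column (post-adjustment ref mismatch, out-of-range position).
    SNV ref alleles are re-validated against the reference after adjustment
    except at documented substitution-variant positions.
    """
    out = records.copy()
    reasons = pd.Series("", index=out.index, dtype=object)
    adjusted = []
    for idx, p in zip(out.index, out["position"]):
        try:
            adjusted.append(adjustment.adjust(int(p)))
        except GapPositionError as exc:
            adjusted.append(int(p))
            reasons[idx] = str(exc)
    out["position"] = adjusted
    if ref is not None:
        for idx, row in out.iterrows():
            if reasons[idx]:
                continue
            pos = int(row["position"])
            if not 1 <= pos <= ref.length:
                reasons[idx] = f"adjusted position {pos} outside reference"
            elif (
                row.get("class", "SNV") == "SNV"
                and pos not in adjustment.variant_positions
                and ref.base(pos) != row["ref"]
            ):
                reasons[idx] = (
                    f"ref {row['ref']} does not match reference base "
                    f"{ref.base(pos)} at adjusted position {pos}"
                )
    bad = reasons != ""
    rejected = out[bad].assign(reason=reasons[bad])
    if len(rejected):
        for _, row in rejected.iterrows():
            logger.warning("excluding record: %s", row["reason"])
    return out[~bad].copy(), rejected
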
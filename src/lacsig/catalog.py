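"""Typed mutation catalogs.

A catalog is the tidy record of independent mutations recovered from the
assay: one row per mutation per animal, annotated with the exposure agent,
tissue, mutation class (SNV, insertion, deletion) and sequencing source
(NGS or Sanger). It is the common currency between the calling, profiling
and fitting stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .channels import BASES

COLUMNS = ["animal", "agent", "tissue", "position", "ref", "alt", "class", "source"]

MUTATION_CLASSES = ("SNV", "insertion", "deletion")
SOURCES = ("NGS", "Sanger")


@dataclass
class MutationCatalog:
    """A validated table of mutation records.

    ``records`` carries the columns ``animal, agent, tissue, position, ref,
    alt, class, source``. SNV records must have single-base ref/alt drawn
    from {A,C,G,T} with ref != alt; indel records carry the inserted or
    deleted bases in ``alt``/``ref`` respectively.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        df["position"] = df["position"].astype(int)
        bad_class = set(df["class"]) - set(MUTATION_CLASSES)
        if bad_class:
            raise ValueError(f"unknown mutation classes: {sorted(bad_class)}")
        bad_source = set(df["source"]) - set(SOURCES)
        if bad_source:
            raise ValueError(f"unknown sources: {sorted(bad_source)}")
        snv = df[df["class"] == "SNV"]
        for col in ("ref", "alt"):
            bad = snv[~snv[col].isin(list(BASES))]
            if len(bad):
                raise ValueError(
                    f"SNV {col} must be a single ACGT base; offending rows: "
                    f"{bad.index[:5].tolist()}"
                )
        if (snv["ref"] == snv["alt"]).any():
            raise ValueError("SNV records with ref == alt")
        if (df["position"] < 1).any():
            raise ValueError("positions must be >= 1")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snvs(self) -> pd.DataFrame:
        return self.records[self.records["class"] == "SNV"]

    def subset(self, **conditions) -> "MutationCatalog":
        """Rows matching all ``column=value`` (or ``column=list``) conditions."""
        df = self.records
        for col, val in conditions.items():
            values = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            df = df[df[col].isin(list(values))]
        return MutationCatalog(df)

    def concat(self, other: "MutationCatalog") -> "MutationCatalog":
        return MutationCatalog(
            pd.concat([self.records, other.records], ignore_index=True)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCatalog":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"ref": str, "alt": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)
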
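"""SBS signature sets, lacZ normalization, and the empirical background signature.

SBS signatures are probability distributions over the 96 substitution
channels, derived from human tumour genomes. Before refitting reporter-gene
data against them, each signature is re-weighted by the ratio of target
(lacZ) to human trinucleotide frequencies, so that a signature expresses the
mutation density expected on the reporter's own sequence composition; each
row is then renormalized to sum 1. The observed profiles are never
re-weighted — the signatures are mapped into lacZ context space, not the
data into human space.

The spontaneous background is represented by an empirical "control"
signature built from control-animal mutations, appended to the candidate
set so that refitting can separate induced from spontaneous mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .channels import CHANNELS_96, channel_context
from .profiles import Profile96, build_profile96
from .reference import ContextFrequencyTable, ReferenceSequence

#: lacZ positions whose Sanger-reported spontaneous SNVs are dropped when
#: building the control signature: recurrent hotspot records in the published
#: Sanger compilations are heavily biased toward these five positions.
SANGER_HOTSPOT_POSITIONS = frozenset({1072, 1090, 1187, 1627, 2374})

RAW = "raw-COSMIC"
NORMALIZED = "lacZ-normalized"
WITH_CONTROL = "includes-control"


@dataclass
class SignatureSet:
    """An ordered set of row-stochastic signatures over the 96 channels."""

    names: tuple[str, ...]
    weights: np.ndarray  # (n_signatures, 96)
    provenance: str = RAW

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 96:
            raise ValueError(f"weights must be (n, 96), got {w.shape}")
        if w.shape[0] != len(self.names):
            raise ValueError("names/weights length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        if (w < 0).any():
            raise ValueError("negative signature weights")
        sums = w.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = [self.names[i] for i in np.where(np.abs(sums - 1.0) > 1e-9)[0]]
            raise ValueError(f"signature rows must sum to 1: {bad}")
        self.weights = w

    def __len__(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        return self.weights[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(tuple(names), self.weights[idx], self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights.T, index=list(CHANNELS_96), columns=list(self.names)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = RAW) -> "SignatureSet":
        df = df.reindex(list(CHANNELS_96))
        if df.isna().any().any():
            raise ValueError("signature table missing channels")
        return cls(tuple(df.columns), df.to_numpy(dtype=float).T, provenance)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = RAW) -> "SignatureSet":
        """Read the COSMIC dialect: a mutation-type column plus one column per signature."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index(df.columns[0])
        # rows may arrive in any order; renormalize away rounding error
        sigs = df.reindex(list(CHANNELS_96))
        if sigs.isna().any().any():
            raise ValueError(f"{path}: missing mutation types")
        w = sigs.to_numpy(dtype=float).T
        w = w / w.sum(axis=1, keepdims=True)
        return cls(tuple(df.columns), w, provenance)

    def to_tsv(self, path: str | Path) -> None:
        out = self.to_frame().rename_axis("MutationType").reset_index()
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            out.to_csv(fh, sep="\t", index=False)


def normalize_signatures(
    cosmic: SignatureSet,
    f_target: ContextFrequencyTable,
    f_human: ContextFrequencyTable,
) -> SignatureSet:
    """Re-weight signatures into the target (lacZ) trinucleotide composition.

    Each channel weight is multiplied by f_target(ctx)/f_human(ctx) for the
    channel's pyrimidine-centred context, and rows are renormalized to sum 1.
    Double normalization is refused via the provenance tag.
    """
    if cosmic.provenance != RAW:
        raise ValueError(
            f"refusing to normalize a set with provenance {cosmic.provenance!r}; "
            "normalization is not idempotent"
        )
    ratio = np.empty(96)
    for j, channel in enumerate(CHANNELS_96):
        ctx = channel_context(channel)
        fh = f_human[ctx]
        if fh == 0.0:
            if (cosmic.weights[:, j] > 0).any():
                raise ValueError(
                    f"human frequency is zero for context {ctx} where signature "
                    "weight is positive"
                )
            ratio[j] = 0.0
        else:
            ratio[j] = f_target[ctx] / fh
    w = cosmic.weights * ratio
    sums = w.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        bad = [cosmic.names[i] for i in np.where(sums.ravel() <= 0)[0]]
        raise ValueError(f"normalization annihilated signatures: {bad}")
    return SignatureSet(cosmic.names, w / sums, provenance=NORMALIZED)


@dataclass
class ControlSignature:
    """Empirical background signature from control-animal mutations."""

    weights: np.ndarray  # length 96, sums to 1
    excluded_positions: frozenset[int]
    sources: tuple[str, ...]
    name: str = "Control"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (96,):
            raise ValueError("control signature must have 96 channels")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("control signature must be a distribution")
        self.weights = w


def build_control_signature(
    controls: MutationCatalog,
    ref: ReferenceSequence,
    sanger_excluded: Iterable[int] = SANGER_HOTSPOT_POSITIONS,
) -> ControlSignature:
    """Build the background signature from control-group mutations.

    Sanger-source SNVs at the excluded hotspot positions are dropped (their
    recurrence reflects publication bias, not spontaneous mutation rates);
    NGS records at the same positions are kept. The remaining SNVs form a
    96-channel profile whose relative frequencies are the signature.
    """
    excluded = frozenset(int(p) for p in sanger_excluded)
    df = controls.records
    drop = (
        (df["source"] == "Sanger")
        & (df["class"] == "SNV")
        & (df["position"].isin(excluded))
    )
    kept = MutationCatalog(df[~drop])
    if len(kept.snvs) == 0:
        raise ValueError("no control SNVs left after hotspot exclusion")
    profile = build_profile96(kept, ref, name="Control")
    if profile.n == 0:
        raise ValueError("control catalog produced an empty profile")
    return ControlSignature(
        weights=profile.freqs,
        excluded_positions=excluded,
        sources=tuple(sorted(set(df["source"]))),
    )


def with_control(sigs: SignatureSet, control: ControlSignature) -> SignatureSet:
    """Append the control signature as an extra fitting candidate."""
    if control.name in sigs.names:
        raise ValueError(f"signature set already contains {control.name!r}")
    return SignatureSet(
        sigs.names + (control.name,),
        np.vstack([sigs.weights, control.weights]),
        provenance=WITH_CONTROL,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative channel vectors (scale-invariant)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vector length mismatch")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("vectors must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for the zero vector")
    return float(np.dot(a, b) / (na * nb))


def similarity_heatmap(
    profiles: Sequence[Profile96],
    sigs: SignatureSet,
    floor: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cosine matrix of profiles (rows) against signatures (columns).

    Returns ``(full, masked)``: the complete matrix, and a report view with
    entries below ``floor`` masked as NaN.
    """
    data = np.array(
        [
            [cosine_similarity(p.freqs, sigs.weights[i]) for i in range(len(sigs))]
            for p in profiles
        ]
    )
    full = pd.DataFrame(data, index=[p.name for p in profiles], columns=list(sigs.names))
    masked = full.where(full >= floor)
    return full, masked
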
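"""Mutation calling from pooled-plaque amplicon depth matrices.

Mutant plaques recovered from one animal are pooled and the pool is PCR
amplified twice; the two technical replicates are sequenced independently so
that PCR/sequencing artefacts, which do not reproduce across replicates, can
be filtered. A true mutation carried by ``k`` of the ``P`` plaques in the
pool appears at a variant allele fraction near ``k/P`` in both replicates.

A variant is called when, after subtracting the per-read background error
rate (estimated by sequencing non-mutant plaques), its allele fraction
reaches at least ``1/P`` in both replicates and the two replicate fractions
do not diverge by 50% or more (``|v1 - v2| / max(v1, v2) < 0.5``). Clonally
expanded mutants — the same event recovered from several plaques of one
animal — are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import COLUMNS as CATALOG_COLUMNS
from .catalog import MutationCatalog

DEPTH_COLUMNS = ["replicate", "position", "ref", "alt", "depth", "coverage"]

#: Replicate discordance above which a candidate is discarded.
DISCORDANCE_LIMIT = 0.5


@dataclass
class PoolDepths:
    """Per-pool read depths for both technical replicates.

    ``depths`` is a long-format frame with columns ``replicate`` (1 or 2),
    ``position``, ``ref``, ``alt``, ``depth`` (reads supporting the variant)
    and ``coverage`` (total reads at the position in that replicate).
    ``background_rate`` is the per-read error fraction, either a scalar or a
    Series indexed by ``(position, alt)``.
    """

    pool_id: str
    animal_id: str
    plaque_count: int
    depths: pd.DataFrame
    background_rate: float | pd.Series = 0.0
    corrected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.plaque_count < 1:
            raise ValueError("plaque_count must be >= 1")
        df = self.depths
        missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"depth table missing columns: {missing}")
        if not set(df["replicate"]) <= {1, 2}:
            raise ValueError("replicate must be 1 or 2")
        if (df["depth"] < 0).any() or (df["coverage"] <= 0).any():
            raise ValueError("depth must be >= 0 and coverage > 0")
        if (df["depth"] > df["coverage"]).any():
            raise ValueError("depth exceeds coverage")

    def background_at(self, position: int, alt: str) -> float:
        if isinstance(self.background_rate, pd.Series):
            return float(self.background_rate.get((position, alt), 0.0))
        return float(self.background_rate)


@dataclass(frozen=True)
class MutationCall:
    """A background-corrected variant call from one pool."""

    position: int
    ref: str
    alt: str
    vaf: tuple[float, float]
    pool_id: str
    animal_id: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if not all(0.0 <= v <= 1.0 for v in self.vaf):
            raise ValueError(f"VAF outside [0, 1]: {self.vaf}")


def background_correct(pool: PoolDepths) -> PoolDepths:
    """Compute background-corrected allele fractions for every candidate cell.

    Candidates are the (position, ref, alt) cells present in the depth table.
    Every candidate must carry coverage in both replicates; the corrected
    fraction is ``max(0, depth/coverage - background_rate)``.
    """
    df = pool.depths
    wide = df.pivot_table(
        index=["position", "ref", "alt"],
        columns="replicate",
        values=["depth", "coverage"],
        aggfunc="first",
    )
    for rep in (1, 2):
        if ("coverage", rep) not in wide.columns:
            wide[("coverage", rep)] = np.nan
        if ("depth", rep) not in wide.columns:
            wide[("depth", rep)] = np.nan
    # a cell missing from one replicate's table gets depth 0 at that
    # replicate's position coverage, if known
    pos_cov = {
        rep: df[df["replicate"] == rep].groupby("position")["coverage"].first()
        for rep in (1, 2)
    }
    records = []
    for (position, ref, alt), row in wide.iterrows():
        depths_ = [row[("depth", rep)] for rep in (1, 2)]
        any_signal = any(not pd.isna(d) and d > 0 for d in depths_)
        vafs = []
        for rep, depth in zip((1, 2), depths_):
            cov = row[("coverage", rep)]
            if pd.isna(cov):
                cov = pos_cov[rep].get(position, np.nan)
            if pd.isna(cov):
                if any_signal:
                    raise ValueError(
                        f"pool {pool.pool_id}: no replicate-{rep} coverage at "
                        f"position {position} with nonzero depth"
                    )
                vafs.append(0.0)
                continue
            depth = 0.0 if pd.isna(depth) else float(depth)
            vafs.append(max(0.0, depth / float(cov) - pool.background_at(position, alt)))
        records.append((position, ref, alt, vafs[0], vafs[1]))
    corrected = pd.DataFrame(
        records, columns=["position", "ref", "alt", "vaf1", "vaf2"]
    )
    return replace(pool, corrected=corrected)


def call_mutations(pool: PoolDepths) -> list[MutationCall]:
    """Apply the threshold and replicate-concordance filters to one pool.

    A call is emitted iff both corrected allele fractions reach ``1/P`` and
    the symmetric discordance ``|v1 - v2| / max(v1, v2)`` is below 0.5.
    """
    if pool.corrected is None:
        pool = background_correct(pool)
    threshold = 1.0 / pool.plaque_count
    calls = []
    for row in pool.corrected.itertuples(index=False):
        v1, v2 = float(row.vaf1), float(row.vaf2)
        if v1 < threshold or v2 < threshold:
            continue
        if abs(v1 - v2) / max(v1, v2) >= DISCORDANCE_LIMIT:
            continue
        calls.append(
            MutationCall(
                position=int(row.position),
                ref=row.ref,
                alt=row.alt,
                vaf=(min(v1, 1.0), min(v2, 1.0)),
                pool_id=pool.pool_id,
                animal_id=pool.animal_id,
            )
        )
    calls.sort(key=lambda c: (c.position, c.ref, c.alt))
    return calls


def collapse_clonal(
    calls: Iterable[MutationCall],
    agent: str = "",
    tissue: str = "",
    sanger_catalog: MutationCatalog | None = None,
) -> MutationCatalog:
    """Collapse clonally expanded mutants into independent mutations.

    Within each animal, identical (position, ref, alt) events — whether from
    several plaques of the NGS pool or duplicated between NGS and Sanger
    records — are counted once. The result is deterministic (sorted) and
    idempotent.
    """
    rows = [
        {
            "animal": c.animal_id,
            "agent": agent,
            "tissue": tissue,
            "position": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "class": "SNV",
            "source": "NGS",
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if sanger_catalog is not None:
        df = pd.concat([df, sanger_catalog.records], ignore_index=True)
    if len(df) == 0:
        raise ValueError("no calls to collapse")
    df = (
        df.sort_values(["animal", "position", "ref", "alt", "source"])
        .drop_duplicates(subset=["animal", "position", "ref", "alt"], keep="first")
        .reset_index(drop=True)
    )
    return MutationCatalog(df)


@dataclass(frozen=True)
class MutantFrequencyRecord:
    """Mutant plaque-forming units over total plaque-forming units for one animal."""

    animal_id: str
    mutant_plaques: int
    total_pfu: int

    def __post_init__(self) -> None:
        if self.total_pfu <= 0:
            raise ValueError("total_pfu must be positive")
        if not 0 <= self.mutant_plaques <= self.total_pfu:
            raise ValueError("mutant_plaques outside [0, total_pfu]")

    @property
    def mf(self) -> float:
        return self.mutant_plaques / self.total_pfu


def group_mutant_frequency(records: Sequence[MutantFrequencyRecord]) -> float:
    """Pooled group mutant frequency: total mutants over total pfu."""
    if not records:
        raise ValueError("empty group")
    return sum(r.mutant_plaques for r in records) / sum(r.total_pfu for r in records)


def mutant_frequency_fold(
    exposed: Sequence[MutantFrequencyRecord],
    control: Sequence[MutantFrequencyRecord],
) -> float:
    """Fold change of pooled mutant frequency, exposed over control."""
    mf_control = group_mutant_frequency(control)
    if mf_control == 0:
        raise ZeroDivisionError("control mutant frequency is zero; fold undefined")
    return group_mutant_frequency(exposed) / mf_control


def read_pool_depths(path: str | Path) -> list[PoolDepths]:
    """Read pools from a long-format TSV.

    Columns: pool_id, animal_id, plaque_count, replicate, position, ref, alt,
    depth, coverage, and optionally background_rate (per position/alt).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ref": str, "alt": str})
    pools = []
    for pool_id, grp in df.groupby("pool_id", sort=True):
        background: float | pd.Series = 0.0
        if "background_rate" in grp.columns:
            background = (
                grp.drop_duplicates(subset=["position", "alt"])
                .set_index(["position", "alt"])["background_rate"]
                .astype(float)
            )
        pools.append(
            PoolDepths(
                pool_id=str(pool_id),
                animal_id=str(grp["animal_id"].iloc[0]),
                plaque_count=int(grp["plaque_count"].iloc[0]),
                depths=grp[DEPTH_COLUMNS].reset_index(drop=True),
                background_rate=background,
            )
        )
    return pools


def write_pool_depths(pools: Sequence[PoolDepths], path: str | Path) -> None:
    frames = []
    for p in pools:
        df = p.depths.copy()
        df.insert(0, "pool_id", p.pool_id)
        df.insert(1, "animal_id", p.animal_id)
        df.insert(2, "plaque_count", p.plaque_count)
        df["background_rate"] = [
            p.background_at(int(pos), alt) for pos, alt in zip(df["position"], df["alt"])
        ]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
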
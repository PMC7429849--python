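"""96-channel mutation profiles and spectrum statistics.

A mutation catalog is reduced to the standard 96-channel representation:
six pyrimidine substitution classes by sixteen flanking-base pairs, with
purine-reference SNVs complemented onto the pyrimidine strand. Catalogs are
also summarised as 8-class patterns (the six substitution classes plus
insertions and deletions) and compared between groups with Fisher's exact
test — exact on per-class 2x2 sub-tables, Monte Carlo over the whole
spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .catalog import MutationCatalog
from .channels import (
    CHANNEL_INDEX,
    CHANNELS_96,
    PATTERN_CLASSES,
    channel_for,
)
from .reference import ReferenceSequence

logger = logging.getLogger(__name__)


@dataclass
class Profile96:
    """Counts and relative frequencies over the 96 channels.

    ``counts`` follows the canonical COSMIC channel order. ``freqs`` is
    undefined for an empty profile (``n == 0``) and raises there.
    """

    counts: np.ndarray
    name: str = "profile"

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (96,):
            raise ValueError(f"expected 96 channels, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("negative channel counts")
        self.counts = arr

    @property
    def n(self) -> int:
        return int(round(float(self.counts.sum())))

    @property
    def freqs(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ValueError(f"profile {self.name!r} is empty; frequencies undefined")
        return self.counts / total

    def to_series(self, relative: bool = False) -> pd.Series:
        values = self.freqs if relative else self.counts
        return pd.Series(values, index=list(CHANNELS_96), name=self.name)

    @classmethod
    def from_series(cls, s: pd.Series, name: str | None = None) -> "Profile96":
        values = s.reindex(list(CHANNELS_96))
        if values.isna().any():
            missing = sorted(set(CHANNELS_96) - set(s.index))
            raise ValueError(f"missing channels: {missing[:5]}...")
        return cls(counts=values.to_numpy(dtype=float), name=name or str(s.name))


def build_profile96(
    catalog: MutationCatalog,
    ref: ReferenceSequence,
    name: str = "profile",
) -> Profile96:
    """Project a catalog's SNVs onto the 96 channels.

    The trinucleotide context is read off the coding strand of the
    reference; purine-reference substitutions are complemented into the
    pyrimidine convention. SNVs at the terminal positions (no in-CDS
    flanking base) are excluded with a warning; ref-mismatching records are
    rejected with a log message.
    """
    counts = np.zeros(96)
    for row in catalog.snvs.itertuples(index=False):
        pos = int(row.position)
        if pos < 1 or pos > ref.length:
            logger.warning("rejecting SNV at position %d: outside reference", pos)
            continue
        if pos in (1, ref.length):
            logger.warning(
                "excluding SNV at terminal position %d: no trinucleotide context", pos
            )
            continue
        if ref.base(pos) != row.ref:
            logger.warning(
                "rejecting SNV at position %d: ref %s does not match reference %s",
                pos,
                row.ref,
                ref.base(pos),
            )
            continue
        channel = channel_for(ref.context(pos), row.ref, row.alt)
        counts[CHANNEL_INDEX[channel]] += 1
    return Profile96(counts=counts, name=name)


def write_profile_tsv(profiles: Sequence[Profile96], path: str | Path, relative: bool = False) -> None:
    """Write profiles as the standard 96-row COSMIC mutation-type table."""
    df = pd.concat([p.to_series(relative=relative) for p in profiles], axis=1)
    df.rename_axis("MutationType").reset_index().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> list[Profile96]:
    df = pd.read_csv(path, sep="\t", comment="#")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    return [Profile96.from_series(df[c], name=c) for c in df.columns]


@dataclass
class PatternSummary:
    """Proportions of the 8 mutation classes with binomial standard errors."""

    proportions: pd.Series  # indexed by PATTERN_CLASSES
    se: pd.Series
    n: int

    def __post_init__(self) -> None:
        self.proportions = self.proportions.reindex(list(PATTERN_CLASSES)).astype(float)
        self.se = self.se.reindex(list(PATTERN_CLASSES)).astype(float)
        if abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if (self.se < 0).any():
            raise ValueError("negative standard error")


def pattern_counts(catalog: MutationCatalog) -> pd.Series:
    """Pooled counts per 8-class pattern (6 SBS classes + insertion + deletion)."""
    counts = pd.Series(0, index=list(PATTERN_CLASSES), dtype=int)
    pyr = {"C", "T"}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for row in catalog.records.itertuples(index=False):
        cls = row[6]  # 'class' is a reserved word, so itertuples renames it
        if cls == "insertion":
            counts["insertion"] += 1
        elif cls == "deletion":
            counts["deletion"] += 1
        else:
            ref, alt = row.ref, row.alt
            if ref not in pyr:
                ref, alt = comp[ref], comp[alt]
            counts[f"{ref}>{alt}"] += 1
    return counts


def build_pattern_summary(catalog: MutationCatalog) -> PatternSummary:
    """8-class proportions with per-class binomial standard errors.

    The SE of each proportion p over n pooled mutations is
    sqrt(p (1 - p) / n), the binomial error-propagation estimate.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    counts = pattern_counts(catalog)
    n = int(counts.sum())
    p = counts / n
    se = np.sqrt(p * (1 - p) / n)
    return PatternSummary(proportions=p, se=se, n=n)


def _log_table_probability(table: np.ndarray) -> float:
    """Log hypergeometric probability of an R x C table with fixed margins."""
    table = np.asarray(table, dtype=np.int64)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_montecarlo(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte Carlo Fisher exact p for a 2 x C spectrum table.

    Tables are sampled with both margins fixed (multivariate hypergeometric
    draws of row A given the column totals); the p-value is the fraction of
    sampled tables at most as probable as the observed one, with the +1
    correction so p is never 0 and is reproducible given the seed.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    observed = np.stack([a, b])
    if observed.sum() == 0:
        raise ValueError("all-zero table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_p_obs = _log_table_probability(observed)
    colsums = observed.sum(axis=0)
    n_a = int(a.sum())
    draws = rng.multivariate_hypergeometric(colsums, n_a, size=reps)
    # the second row is forced by the margins
    hits = 0
    tol = 1e-9  # tables equally probable up to float error count as extreme
    for row_a in draws:
        table = np.stack([row_a, colsums - row_a])
        if _log_table_probability(table) <= log_p_obs + tol:
            hits += 1
    return (hits + 1) / (reps + 1)


def compare_spectra(
    counts_a: pd.Series | Mapping[str, int],
    counts_b: pd.Series | Mapping[str, int],
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> dict:
    """Compare two mutation spectra class by class and as a whole.

    Returns the whole-spectrum Monte Carlo Fisher p, per-class two-sided
    exact 2x2 Fisher p-values, and Bonferroni-adjusted significance flags.
    The correction family defaults to the mutation classes within this
    comparison; pass ``family_size`` to correct over a wider family (e.g.
    classes x exposure groups).
    """
    a = pd.Series(counts_a, dtype=int)
    b = pd.Series(counts_b, dtype=int)
    classes = list(a.index)
    if list(b.index) != classes:
        raise ValueError("spectra must share the same class labels")
    total_a, total_b = int(a.sum()), int(b.sum())
    if total_a + total_b == 0:
        raise ValueError("all-zero table")
    overall_p = fisher_montecarlo(a.to_numpy(), b.to_numpy(), reps=reps, seed=seed)
    per_class = {}
    for cls in classes:
        table = [
            [int(a[cls]), total_a - int(a[cls])],
            [int(b[cls]), total_b - int(b[cls])],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        per_class[cls] = float(p)
    m = family_size if family_size is not None else len(classes)
    flags = {cls: p <= alpha / m for cls, p in per_class.items()}
    return {
        "overall_p": overall_p,
        "per_class_p": per_class,
        "bonferroni_alpha": alpha / m,
        "significant": flags,
        "reps": reps,
        "seed": seed,
    }
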
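"""Robustness checks: downsampling stability and context-randomization nulls.

Two complementary checks probe whether a signature attribution is a property
of the data rather than of the fitting machinery: (1) refitting repeated 50%
subsamples of the catalog — a real association should survive halving the
input; (2) refitting catalogs whose mutations are randomly reassigned to
trinucleotide channels — a context-free null in which only flat signatures
should appear and reconstruction quality should collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .channels import CHANNELS_96, CONTEXTS_32, channel_context
from .fitting import (
    ForwardSelectionSignatureFitter,
    NNLSSignatureFitter,
    consensus_filter,
    fit_forward_selection,
    fit_nnls,
)
from .profiles import Profile96, build_profile96
from .reference import ReferenceSequence, count_contexts
from .signatures import SignatureSet


@dataclass
class DownsampleReport:
    """Detection stability of each signature under repeated subsampling."""

    fraction: float
    replicate_accepted: tuple[tuple[str, ...], ...]
    stability: pd.Series  # per-signature fraction of replicates accepted
    full_accepted: tuple[str, ...]
    seed: int

    @property
    def reps(self) -> int:
        return len(self.replicate_accepted)


def _dual_fit_consensus(
    profile: Profile96, sigs: SignatureSet, min_contrib: float, min_cos: float
):
    fit_fs = fit_forward_selection(profile, sigs)
    fit_mp = fit_nnls(profile, sigs)
    return fit_fs, fit_mp, consensus_filter(
        fit_fs, fit_mp, profile, sigs, min_contrib=min_contrib, min_cos=min_cos
    )


def downsample_refit(
    catalog: MutationCatalog,
    ref: ReferenceSequence,
    sigs: SignatureSet,
    fraction: float = 0.5,
    reps: int = 20,
    seed: int = 0,
    min_contrib: float = 0.20,
    min_cos: float = 0.5,
) -> DownsampleReport:
    """Refit ``reps`` without-replacement subsamples of the SNV catalog.

    ``fraction`` = 1.0 is allowed as a degenerate boundary (every replicate
    sees the whole catalog). Reports which signatures pass the dual-fit
    consensus in each replicate and the per-signature detection stability.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    snvs = catalog.snvs.reset_index(drop=True)
    n_take = max(1, int(round(len(snvs) * fraction)))
    rng = np.random.default_rng(seed)

    full_profile = build_profile96(catalog, ref, name="full")
    _, _, full_consensus = _dual_fit_consensus(full_profile, sigs, min_contrib, min_cos)

    accepted_sets = []
    for _ in range(reps):
        if fraction >= 1.0:
            sub = snvs
        else:
            idx = rng.choice(len(snvs), size=n_take, replace=False)
            sub = snvs.iloc[np.sort(idx)]
        profile = build_profile96(MutationCatalog(sub), ref, name="subsample")
        _, _, consensus = _dual_fit_consensus(profile, sigs, min_contrib, min_cos)
        accepted_sets.append(tuple(consensus.accepted))
    stability = pd.Series(
        [np.mean([name in s for s in accepted_sets]) for name in sigs.names],
        index=list(sigs.names),
    )
    return DownsampleReport(
        fraction=fraction,
        replicate_accepted=tuple(accepted_sets),
        stability=stability,
        full_accepted=tuple(full_consensus.accepted),
        seed=seed,
    )


@dataclass
class NullResampleReport:
    """Context-randomization null against the real-data fit."""

    null_cosines: np.ndarray  # nnls reconstruction cosine per null replicate
    real_cosine: float
    null_mean_contributions: pd.Series
    real_contributions: pd.Series
    mode: str
    seed: int

    @property
    def reps(self) -> int:
        return len(self.null_cosines)

    def null_quantile(self, q: float = 0.95) -> float:
        return float(np.quantile(self.null_cosines, q))


def resample_null(
    catalog: MutationCatalog,
    ref: ReferenceSequence,
    sigs: SignatureSet,
    reps: int = 100,
    seed: int = 0,
    mode: str = "lacz",
) -> NullResampleReport:
    """Refit catalogs with mutations randomly reassigned to channels.

    Each replicate redraws every SNV's channel: the trinucleotide context is
    drawn with probability proportional to its availability in the reference
    (``mode='lacz'``, preserving the transgene's sequence bias) or uniformly
    over the 96 channels (``mode='uniform'``); the substitution is uniform
    among the three alternates. Reports the non-negative least-squares
    reconstruction cosines of the null fits next to the real fit.
    """
    n = len(catalog.snvs)
    if n == 0:
        raise ValueError("catalog has no SNVs")
    if mode == "lacz":
        ctx_freq = count_contexts(ref)
        context_p = np.array([ctx_freq[channel_context(c)] for c in CHANNELS_96])
        channel_p = context_p / 3.0
        channel_p = channel_p / channel_p.sum()
    elif mode == "uniform":
        channel_p = np.full(96, 1.0 / 96.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    real_profile = build_profile96(catalog, ref, name="real")
    real_fit = fit_nnls(real_profile, sigs)

    null_cosines = np.zeros(reps)
    null_contribs = np.zeros((reps, len(sigs)))
    for i in range(reps):
        counts = rng.multinomial(n, channel_p)
        null_fit = fit_nnls(Profile96(counts.astype(float), name=f"null{i}"), sigs)
        null_cosines[i] = null_fit.reconstruction_cosine
        null_contribs[i] = null_fit.contributions.to_numpy()
    return NullResampleReport(
        null_cosines=null_cosines,
        real_cosine=real_fit.reconstruction_cosine,
        null_mean_contributions=pd.Series(
            null_contribs.mean(axis=0), index=list(sigs.names)
        ),
        real_contributions=real_fit.contributions,
        mode=mode,
        seed=seed,
    )
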
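"""Canonical 96-channel single-base-substitution conventions.

Mutations are expressed on the pyrimidine strand: a substitution at a purine
is reported as the complementary pyrimidine change, with the flanking
trinucleotide context reverse-complemented. The channel order is the standard
COSMIC order: the six substitution classes C>A, C>G, C>T, T>A, T>C, T>G, each
expanded over the 16 combinations of 5' and 3' flanking bases sorted A,C,G,T
("A[C>A]A", "A[C>A]C", ..., "T[T>G]T").
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in canonical COSMIC order.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

#: The 32 pyrimidine-centred trinucleotide contexts (NCN then NTN).
CONTEXTS_32 = tuple(
    f"{five}{center}{three}"
    for center in PYRIMIDINES
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_32)}

#: Extended mutation classes used for spectrum summaries.
PATTERN_CLASSES = SUBSTITUTION_CLASSES + ("insertion", "deletion")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_context(context: str) -> str:
    """Map a trinucleotide to its pyrimidine-centred representative.

    Purine-centred trinucleotides are reverse-complemented; pyrimidine-centred
    ones are returned unchanged.
    """
    if len(context) != 3:
        raise ValueError(f"expected a trinucleotide, got {context!r}")
    if context[1] in PYRIMIDINES:
        return context
    return reverse_complement(context)


def channel_for(context: str, ref: str, alt: str) -> str:
    """Channel label for a substitution ``ref>alt`` in coding-strand ``context``.

    ``context[1]`` must equal ``ref``. Purine-reference substitutions are
    complemented into the pyrimidine convention.
    """
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r})")
    if ref in PYRIMIDINES:
        return f"{context[0]}[{ref}>{alt}]{context[2]}"
    rc = reverse_complement(context)
    return f"{rc[0]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{rc[2]}"


def channel_context(channel: str) -> str:
    """Pyrimidine-centred trinucleotide context of a channel label."""
    return channel[0] + channel[2] + channel[6]


def channel_substitution(channel: str) -> tuple[str, str]:
    """(ref, alt) pair of a channel label, on the pyrimidine strand."""
    return channel[2], channel[4]
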
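"""Regenerate the bundled synthetic data shipped under ``lacsig/data``.

All bundled inputs are synthetic stand-ins, generated deterministically from
fixed seeds so this script reproduces them byte for byte:

* ``lacz_synthetic.fa`` — a 3096 bp GC-rich coding-sequence-like reference
  with the length and base-composition character of the lacZ transgene.
* ``signatures_synthetic.tsv`` — eight SBS-like row-stochastic signatures
  with distinct, well-separated substitution-class peaks plus one flat
  clock-like component.
* ``context_freq_human_synthetic.tsv`` / ``context_freq_mouse_synthetic.tsv``
  — genome-like pyrimidine-collapsed trinucleotide frequency tables with
  CpG depletion, standing in for whole-genome hg38/mm10 counts.

Run from the repository root: ``python scripts/build_bundled_data.py``
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lacsig.channels import (  # noqa: E402
    BASES,
    CHANNELS_96,
    CONTEXTS_32,
    SUBSTITUTION_CLASSES,
    channel_context,
    collapse_context,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "lacsig" / "data"

LACZ_LENGTH = 3096


def build_reference(seed: int = 20200814) -> str:
    """GC-rich (~56%) random coding-like sequence, all 32 contexts present."""
    rng = np.random.default_rng(seed)
    probs = {"A": 0.22, "C": 0.28, "G": 0.28, "T": 0.22}
    seq = "".join(rng.choice(list(probs), size=LACZ_LENGTH, p=list(probs.values())))
    present = {collapse_context(seq[i : i + 3]) for i in range(LACZ_LENGTH - 2)}
    missing = set(CONTEXTS_32) - present
    if missing:
        raise RuntimeError(f"synthetic reference lacks contexts: {missing}")
    return seq


def genome_context_table(seed: int, cpg_depletion: float) -> pd.Series:
    """Genome-like context frequencies: ~41% GC with CpG dinucleotide depletion."""
    rng = np.random.default_rng(seed)
    base_p = {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
    freq = {}
    for ctx in CONTEXTS_32:
        five, center, three = ctx
        p = base_p[five] * base_p[center] * base_p[three]
        # count both strands of the collapsed pair
        p *= 2.0
        # deplete CpG dinucleotides on either strand of the context
        rc = ctx.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for s in (ctx, rc):
            if "CG" in s:
                p *= cpg_depletion
        # mild genome-specific wobble so human and mouse tables differ
        p *= float(np.exp(rng.normal(0.0, 0.08)))
        freq[ctx] = p
    s = pd.Series(freq)
    return s / s.sum()


def build_signatures(seed: int = 7) -> pd.DataFrame:
    """Eight SBS-like signatures with distinct class/context peaks."""
    rng = np.random.default_rng(seed)
    specs = {
        # name: (favored substitution, context predicate, peak concentration)
        "SBSsim1": ("C>T", lambda c: c[1] + c[2] == "CG", 40.0),  # CpG deamination
        "SBSsim2": ("C>G", lambda c: c[0] == "T", 30.0),  # APOBEC-like
        "SBSsim3": (None, lambda c: True, 0.0),  # flat clock-like
        "SBSsim4": ("C>A", lambda c: c[2] == "G", 25.0),  # bulky-adduct-like
        "SBSsim5": ("T>A", lambda c: True, 20.0),  # thymine-alkylation-like
        "SBSsim6": ("T>C", lambda c: c[0] == "A", 30.0),  # MMR-deficiency-like
        "SBSsim7": ("C>T", lambda c: c[0] in "CT" and c[2] != "G", 25.0),
        "SBSsim8": ("T>G", lambda c: c[2] == "T", 30.0),  # 17b-like
    }
    cols = {}
    for name, (sub, predicate, conc) in specs.items():
        w = rng.gamma(1.0, 1.0, size=96) * 0.15  # diffuse floor
        for j, channel in enumerate(CHANNELS_96):
            ctx = channel_context(channel)
            if sub is None:
                w[j] = 1.0 + 0.3 * rng.random()  # flat
            elif channel[2:5] == sub and predicate(ctx):
                w[j] += conc * (0.5 + rng.random())
        cols[name] = w / w.sum()
    return pd.DataFrame(cols, index=list(CHANNELS_96))


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)

    seq = build_reference()
    with open(DATA_DIR / "lacz_synthetic.fa", "w") as fh:
        fh.write(">lacZ_synthetic synthetic 3096 bp stand-in for the lacZ CDS\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")

    for name, seed, depletion in (("human", 101, 0.22), ("mouse", 202, 0.25)):
        table = genome_context_table(seed, depletion)
        out = table.rename("frequency").rename_axis("context").reset_index()
        path = DATA_DIR / f"context_freq_{name}_synthetic.tsv"
        with open(path, "w") as fh:
            fh.write(f"# synthetic genome-like ({name}) trinucleotide frequencies\n")
            out.to_csv(fh, sep="\t", index=False)

    sigs = build_signatures()
    path = DATA_DIR / "signatures_synthetic.tsv"
    with open(path, "w") as fh:
        fh.write("# synthetic SBS-like signature set (raw, human-composition)\n")
        sigs.rename_axis("MutationType").reset_index().to_csv(fh, sep="\t", index=False)

    print(f"wrote bundled data to {DATA_DIR}")


if __name__ == "__main__":
    main()
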
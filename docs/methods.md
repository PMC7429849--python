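# Methods

## The problem

The MutaMouse transgenic-rodent assay recovers a neutral bacterial `lacZ`
reporter gene from exposed animal tissue; mutant phage plaques are selected,
pooled per animal, amplicon-sequenced as two technical PCR replicates, and
the recovered mutations are compared against COSMIC-style single-base-
substitution (SBS) signatures to ask which mutational processes an exposure
activates. `lacsig` implements that analysis chain as a library: mutation
calling from pooled-plaque depth matrices, 96-channel profile construction,
trinucleotide normalization of a signature set into reporter context space,
an empirical background signature, dual-algorithm signature refitting with a
consensus rule, and robustness checks — together with a synthetic-data
generator so every stage is testable against known ground truth.

Coordinates are 1-based, closed, on the coding strand throughout. All
channel work uses the pyrimidine convention: a substitution at a purine is
reported as the complementary pyrimidine change with reverse-complemented
flanking context, over the canonical 96-channel order (six substitution
classes × sixteen flank pairs).

## Mutation calling

A pool contains the `P` mutant plaques of one animal; a mutation carried by
`k` plaques has template allele fraction `k/P`. Per candidate cell
(position, ref, alt) and technical replicate, the variant allele fraction is
background-corrected as `max(0, depth/coverage − ε)`, where ε is the
per-read error rate estimated from sequencing non-mutant plaques. A call
requires

1. corrected VAF ≥ `1/P` in **both** replicates (threshold inclusive — a
   single plaque's worth of signal qualifies), and
2. replicate concordance: `|v1 − v2| / max(v1, v2) < 0.5`. The `max`
   denominator makes the filter symmetric in replicate order and scale-free.

The threshold is applied after background correction. Clonally expanded
mutants — identical (position, ref, alt) within one animal, whether across
plaques or across NGS/Sanger sources — are collapsed to one independent
mutation (deterministic and idempotent). Indel records are carried through
catalogs as class-labelled rows but excluded from 96-channel profiling.

A structural property worth knowing: a singleton mutation's true VAF is
*exactly* the threshold `1/P`, so under binomial read sampling each
replicate falls below threshold about half the time and singleton
sensitivity is intrinsically capped (≈14% joint detection at coverage
5000, P=20), while clonally duplicated mutations (VAF `2/P`) are recovered
essentially always and background cells (VAF ≈ ε ≪ 1/P) essentially never
— precision stays ≈1. Raising sensitivity for singletons would require a
threshold below one plaque's allele fraction, which the assay's logic (a
real mutant must constitute at least one plaque) argues against.

## Profiles and spectrum statistics

Catalog SNVs are projected onto the 96 channels using the reference's
coding-strand trinucleotide at the mutated position; records mismatching
the reference are rejected with a log message, and SNVs at the two terminal
positions (no in-CDS flank) are excluded with a warning. Eight-class
pattern summaries (six substitution classes + insertions + deletions, indels
in the denominator) carry binomial standard errors `sqrt(p(1−p)/n)` on
pooled counts. Spectra are compared with Fisher's exact test: exact
two-sided 2×2 per class, and Monte Carlo over the whole spectrum — tables
with both margins fixed are drawn by multivariate hypergeometric sampling,
and the p-value is the `(hits+1)/(reps+1)`-corrected fraction of tables at
most as probable as the observed one (10,000 replicates by default,
seed-controlled). Bonferroni correction defaults to the family of mutation
classes within a comparison; `family_size` widens the family when many
exposure groups are tested.

## Signature normalization and the background signature

COSMIC-style signatures are estimated from human genomes, whose
trinucleotide composition differs strongly from the GC-rich reporter. Each
signature row is therefore re-weighted channel-wise by
`f_lacZ(ctx) / f_human(ctx)` — the ratio of reporter to human frequencies of
the channel's pyrimidine-centred context — and renormalized to sum 1. The
observed profiles are never re-weighted; the signatures are mapped into
reporter context space, not the data into genome space, because the
signature estimates rest on far more mutations and carry less variance.
All 64 strand-specific trinucleotides are collapsed by reverse complement
onto the 32 pyrimidine-centred representatives before forming the ratio,
matching the channel convention. Normalization is not idempotent, so
signature sets carry a provenance tag (`raw-COSMIC`, `lacZ-normalized`,
`includes-control`) and re-normalizing a normalized set is an error.

The spontaneous background is represented by an empirical **control
signature**: the 96-channel relative-frequency profile of control-animal
SNVs, appended to the candidate set so refitting can separate induced from
spontaneous mutations. Sanger-derived SNVs at five recurrent hotspot
positions (1072, 1090, 1187, 1627, 2374) are excluded when building it —
their recurrence in older compilations reflects reporting bias — while NGS
records at the same positions are kept.

## Refitting and the consensus rule

Profiles are fitted as relative frequencies. Two independent algorithms
decompose a profile `m` over candidate rows `W`:

* **NNLS** solves `min ‖m − Wᵀc‖₂, c ≥ 0` exactly
  (`scipy.optimize.nnls`); contributions are reported as `c/Σc` and the
  residual as the relative reconstruction error `‖m − Wᵀc‖/‖m‖`.
* **Greedy forward selection**: both `m` and every signature row sum to 1,
  so absolute weights are meaningful. Each iteration runs a golden-section
  search over every candidate's weight in [0, 1] against the L2 error of
  the *unnormalized* reconstruction `wᵀW` (a scale-free error would be flat
  in the first signature's weight and ill-posed) and accepts the single
  best coordinate update — an update may also lower a weight set too high
  earlier. Iteration stops when the error improvement drops below
  `error_tol` (default 1e-3, the reference implementation's documented
  scale); signatures below 6% relative weight (`weight_cutoff = 0.06`) are
  zeroed; the residual is `1 − Σ contributions`, the unexplained or
  discarded profile mass. Ties break toward the lexicographically first
  signature name, for determinism.

Both fitters are scikit-learn estimators (`fit` on an `(n_samples, 96)`
matrix; fitted `contributions_`, `residuals_`, `reconstructed_`,
`reconstruction_cosines_`), so they compose with sklearn model selection;
`fit_nnls` / `fit_forward_selection` wrap them for single profiles.

A signature is **accepted by consensus** only if (i) both algorithms detect
it (contribution > 0), (ii) both assign it at least 20% (inclusive), and
(iii) its own cosine similarity with the observed profile exceeds 0.5 —
criterion (iii) uses the candidate row against the profile, not the
reconstruction, whose cosine is reported separately. Rejections are
annotated with the most informative failed criterion. The rule is monotone:
raising either threshold never adds a signature. `stringency_sweep`
recomputes the consensus at cosine floors 0.5–0.8.

## Robustness checks

* **Downsampling**: repeated without-replacement 50% subsamples of the SNV
  catalog, full dual fit + consensus per subsample, per-signature detection
  stability. A real association should survive halving the input.
* **Context-randomization null**: each replicate redraws every SNV's
  channel with probability proportional to the reporter's availability of
  the channel's context (preserving the transgene's sequence bias; a
  uniform-over-96 mode is provided for comparison) and substitution uniform
  among the three alternates. Null fits should collapse to flat signatures
  and low reconstruction cosines relative to the real fit.

## Synthetic data: what it emulates, and what it does not

The generator draws mutation channels from a known mixture `Σ πₛ wₛ` of
normalized signatures, places each mutation uniformly among reference
positions whose pyrimidine-strand context matches the channel, assigns
animals round-robin, duplicates mutations clonally at a configured rate,
and simulates two-replicate pool depths as independent
`Binomial(coverage, k/P)` draws plus background errors at rate ε per
(position, alternate) read.

Default study conditions: 6 animals per group; 20 mutant plaques per pool;
5000× coverage per replicate; ε = 1e-4; clonal duplication rate 0.5 (about
two recovered plaques per independent mutation, the assay's typical
clonality); 500 mutations per catalog-level group and 60 for pool-level
fixtures (so every pool fits inside its 20 plaques even fully duplicated).
The default recovery mixture is `{SBSsim4: 0.6, SBSsim8: 0.4}` — two
context-peaked, mutually well-separated signatures (pairwise cosine ≈ 0.34
after normalization) of comparable row norm, so both true components,
including the 0.4 minority, keep cosine ≈ 0.8 with the exact mixture and
the ground truth is detectable by the consensus rule *by construction*.
That is a real constraint of the method, not an artifact: a minority
signature whose row norm is dominated by the majority's can fall below the
0.5 cosine floor even when its contribution is estimated accurately.

Not modelled: functional selection of detectable (non-silent) mutations
(an optional user-supplied detectable-position mask is accepted);
PCR-jackpot amplification beyond the clonal-duplication knob; read-level
artifacts (the pipeline consumes depth matrices, alignment is upstream);
multi-mutation plaques (off by default, matching the mutant-selection
design). Passing tests therefore demonstrate algorithmic correctness under
binomial sequencing noise and known mixtures — not robustness to
alignment error, selection bias, or real spontaneous-mutation structure.

All bundled inputs are synthetic stand-ins generated deterministically by
`scripts/build_bundled_data.py`: a 3096 bp GC-rich lacZ-like reference (all
32 contexts present), an eight-signature SBS-like set, and CpG-depleted
genome-like human/mouse context tables. Checks that require the original
published reference tables (normalized signature matrix, per-agent
profiles) run only when those third-party files are supplied under
`data/published/`.

## Numerical choices and degenerate inputs

Golden-section tolerance 1e-5 on the weight; signature rows validated to
sum 1 within 1e-9; empty profiles, all-zero tables, zero vectors, and
mismatched signature sets raise rather than propagate NaNs. Monte Carlo
p-values use the +1 correction and are reproducible given the seed; ties in
table probability are counted as extreme within 1e-9 log-probability.
Problem sizes in the test suite and acceptance script (20 recovery seeds ×
500 mutations, 100 null replicates, 20 downsample replicates, 10,000
Fisher replicates) were chosen as the smallest sizes at which the measured
quantities are stable to well within the asserted margins.
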
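# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that make runs reproducible. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and conventions

All reported coordinates are 1-based inclusive on the protein (or the
forward strand of the transcript), matching the `K47R` residue-numbering
convention used in the prohormone literature. Any internal half-open
arithmetic is converted at module boundaries. A cleavage site is labelled
by the position of its **first** basic residue; the scissile bond lies
after the **last** basic residue of the matched run, and the run itself is
consumed (carboxypeptidase trimming of exposed basics is implicit). An
alternative policy that retains trailing basics on the N-terminal fragment
and strips them during PTM processing is available
(`PtmRules.strip_trailing_basics`, on by default), since both conventions
appear in the literature.

## ORF extraction (`seq_io`)

Six-frame translation under the standard codon table; codons containing N
translate to `X`; `X` never satisfies a fixed motif position downstream.
ORFs run from the first ATG after the previous in-frame stop to the next
in-frame stop (maximal; nested ORFs suppressed) and must be
stop-terminated. `find_orfs(..., require_start=False)` switches to
stop-to-stop open reading for partial precursors (C-terminally truncated
or signal-less transcripts do occur in real assemblies). Track minima:
50 aa for the neuropeptide track — comfortably below the shortest real
precursors (~78 aa) while suppressing spurious micro-ORFs — and 150 aa for
the receptor track, the standard completeness cutoff for GPCR vetting.

## Signal peptides (`precursor`)

Full neural-network signal-peptide predictors are deliberately out of
scope; the stage is a transparent three-region heuristic in the von
Heijne tradition, plus an override table (`SignalConfig.external`) for
spans computed by external tools, returned verbatim per record id.

For each candidate cleavage position `c` in `[15, 40]` the score is

```
0.2 * n + 0.5 * h + 0.3 * c_ctx
```

* `n` — 1.0 if a K/R occurs in residues 2–6 (the charged n-region), else 0.4;
* `h` — the best 8-residue mean Kyte–Doolittle hydropathy inside the
  candidate signal (positions 3..c−3), divided by 3.5 and clipped to
  [0, 1]. The saturation means any canonically hydrophobic core scores
  1.0, so the cleavage-context term, not small fluctuations in core
  hydrophobicity, decides the cut position;
* `c_ctx` — 0.5 each for a small residue (A/G/S/C/T) at −1 and −3.

The best-scoring `c` wins, ties resolved toward the shortest signal; a
prediction is emitted when the score reaches 0.6. Proteins under 30 aa
skip the heuristic (score 0, absent). Precursors with no detectable signal
are annotated with an absent span and processed anyway — real repertoires
contain signal-less and partial precursors.

## Cleavage sites

Maximal `[KR]+` runs are scanned left to right; within a run, enabled
patterns are matched greedily, longest first: tribasic `KKR/RKR`, then
dibasic `KR/RR/KK/RK`, then monobasic. Runs wholly inside the signal span
are skipped. Interior monobasic cleavage is context-dependent and off by
default (`CleavageRules.interior_monobasic`); monobasic K/R **near the
C-terminus** (within `terminal_window = 4` residues) is on by default,
which covers the two patterns seen in real precursors — a terminal lone K
and a lone R three residues from the end — without inviting spurious
interior cuts. Unmatched basics within a run stay in the flanking
fragments and are trimmed by the PTM stage if terminal.

Excision takes the maximal intervals between the signal span, the matched
runs, and the termini; empty intervals are dropped, and the signal + runs
+ fragments always tile the precursor exactly (a property asserted on
1,000 random precursors). A degenerate all-basic precursor yields zero
fragments and a warning, not an error.

## PTMs and disulfides

C-terminal amidation consumes a terminal glycine (never a lone-G
fragment); N-terminal pyroglutamate is flagged for Q (E optional,
off by default — reported examples are uniformly pQ). Rendered strings use
the `pQ...amide` convention; `invert_rendering` is its exact inverse, and
the round-trip is the identity on fragments without trailing basics.
Peptide length is reported both with and without the donor glycine, since
published per-family lengths are inconsistent about which is meant.

Disulfide bookkeeping enumerates rather than predicts: n cysteines give
n/2 bridges and (n−1)!! distinct perfect pairings (listed for n ≤ 12);
odd counts are flagged as an unpaired-cysteine condition. Externally
reported connectivities are validated as perfect matchings of the
cysteine order of appearance, not scored chemically.

## Family classification (`families`)

The built-in library holds 31 family signatures in an explicit dialect
(`X` wildcard, `[FL]` alternatives, `X{m,n}` bounded repeats — the repeat
form exists only for the natalisin `W...Ramide` signature, encoded as W,
2–13 arbitrary residues, then amidated R). Specificity = number of
position-restricted slots. Winner-takes-all by specificity, ties broken by
longer matched span then lexical family order; runner-ups are surfaced in
`competing` rather than resolved silently. PTM gates (`requires_amide`,
`requires_pyroglu`) are hard constraints. Exact-sequence families (CCAP,
corazonin, RPCH, SIFamide, proctolin, myosuppressin, ETH, ...) are
`full_match` patterns; cross-species fuzzy matching is intentionally not
the default.

The CHH/MIH/ITP superfamily has no short linear signature and is
recognised by a cysteine skeleton: exactly six cysteines, consecutive-C
spacing in [2, 35], peptide length in [50, 90] (reported CHH matures run
~70 aa; the length floor keeps the 29-aa, also six-cysteine trissin out).

Library entries whose source sections print a signature but no complete
peptide carry a **synthetic** exemplar — a direct instantiation of the
motif, flagged `synthetic_exemplar=True` — so the library-wide
self-consistency check (every signature matches its own exemplar) covers
all 31 families.

## GPCR triage (`gpcr`)

The transmembrane caller is a documented stand-in for HMM-based topology
predictors: a centered Kyte–Doolittle moving average (window 19, edges use
shrunken windows) thresholded at 1.6 — the classic criterion for a
membrane-spanning segment. Raw supra-threshold runs of a 19-window profile
are ~6 residues narrower than the underlying helix because the window
averages in flanking loop residues, so runs (≥ 5 positions, to reject
noise spikes) are widened to the window length before the helix-length
bounds [15, 30] are applied; this mirrors how a hydropathy plot is read.
Runs separated by less than 5 residues merge; over-long runs split evenly.
The acceptance band is exactly {7} by default and configurable to 6–8,
because real topology calling is noisy; per-id external TM annotations can
bypass the heuristic entirely. Segment counts are non-increasing in the
threshold on the synthetic panel (with sub-minimum loops a merged pair can
split as the threshold rises, so the property is asserted on the panel,
not universally).

Distances between 7-TM domains are `1 − identities/alignment_length` from
a global alignment under BLOSUM62 with affine gaps (open −10 on the first
gap residue, extend −0.5), fixed in code so distances are bit-reproducible;
symmetry is guaranteed by canonical argument ordering. Trees are
neighbor-joining (negative branch lengths clamped to zero, labels sorted
for deterministic tie-breaking) — a deterministic desk-scale stand-in for
maximum-likelihood phylogenetics, which is out of scope. Family assignment
is nearest-reference by alignment distance with the margin to the nearest
other-family reference reported; exact ties are left unassigned with both
contenders named. Candidates whose ORFs are partial should be flagged by
the caller rather than silently placed.

## Expression summaries (`expression`)

A transcript × tissue 0/1 matrix over the canonical nine-tissue panel (CG,
EG, Gi, Hp, Ht, Ms, Ov, VG, YO; non-canonical names accepted with a
warning). The CNS aggregate is the OR over CG, EG, VG. Published
presence/absence calls exist only as gel images, so no built-in fixture
claims to be real data; a user-curated matrix reproduces published counts
as documentation, not as a test.

## Synthetic generators (`synthetic`)

`generate_precursor` assembles signal + optional precursor-related peptide
+ payload copies separated by chosen basic runs + optional polar tail, and
records the complete truth (spans, sites, rendered matures, family
labels). Clean-mode payloads must be K/R-free (no spurious sites); the
clean family menu (AST-A, AST-B, kinin, GSEFLamide, CCHamide, vasopressin)
contains exactly the built-in families whose exemplars are K/R-free.
Generated signals are canonical by construction — `MK`, a poly-L core, an
`LSSA` cap — so the three-region heuristic's argmax (ties toward the
shortest candidate) lands exactly on the planted cleavage position; this
generator/annotator co-design is what makes clean-mode recovery exact.
Random filler (CPRP, tails) is drawn from a polar alphabet so no spurious
hydrophobic stretch can masquerade as a signal.

`reverse_translate` draws codons uniformly and builds UTRs from {C,G,T}
only: with no adenine upstream, no ATG can pre-empt the planted start, so
the planted ORF is always recovered by `find_orfs`. `generate_gpcr_like`
alternates hydrophobic blocks (19–23 aa over {L,I,V,F,A}) with polar loops
(≥ 12 aa); `generate_dataset` mixes precursor and receptor transcripts
(padding precursors above the 50-aa ORF minimum with a polar tail
fragment) into one nucleotide FASTA plus a JSON truth manifest.

The noise model substitutes payload interiors at a stated per-residue
rate, never touching basic runs, signal caps, donor glycines or leading
glutamines, and draws replacements from the K/R/G/C-free alphabet so no
new sites or donors appear; truth manifests record post-noise sequences.
What the generators do **not** emulate: assembly artifacts, sequencing
error profiles, alternative splicing, genuinely ambiguous cleavage
contexts (e.g. uncleaved interior RR within a real mature peptide), or
homology-level sequence divergence. Passing clean-mode tests therefore
demonstrates the correctness of the processing logic, not the biological
error rate on real transcriptomes.

## Problem sizes and determinism

Property suites run at: 1,000 random sequences for the cleavage/regex
equivalence and for precursor tiling; 500 PTM round-trips; disulfide
enumeration cross-checked to 10 cysteines; 20 random 5–8-leaf additive
matrices for NJ recovery; a 10-precursor + 5-receptor clean dataset (and
100 draws at 5 % noise) for end-to-end recovery. These sizes were chosen
so the whole suite and the acceptance script each complete in seconds
while exercising every rule combination. Every stochastic component takes
an explicit integer seed (numpy `default_rng`); identical configs and
seeds produce byte-identical reports.

## Known limitations

* The signal heuristic is tuned for canonical signals; unusual n-regions
  or very short h-regions will be missed (use the external override).
* Interior monobasic cleavage and uncleaved dibasic sites inside real
  matures (both occur in vivo) are not modelled — the scanner is
  rule-faithful, not context-aware.
* The cysteine-skeleton rule cannot separate CHH from MIH/ITP subtypes.
* NJ on alignment-identity distances is a classification aid, not a
  substitute for model-based phylogenetics; partial 7-TM domains distort
  distances and should be excluded or flagged by the caller.
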
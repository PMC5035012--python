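# Methods

## The problem and the model

R2 elements integrate by target-primed reverse transcription into one fixed
position of the 28S rRNA gene. Two biological facts shape everything here:

1. **Bottom-strand cleavage at the target site is strictly determined, while
   top-strand cleavage varies.** Consequently an element's 3′ junction is
   expected at the canonical site, whereas 5′ junctions may sit upstream —
   in some lineages 110–130 bp upstream, i.e. that much 28S sequence is
   replaced by the element on insertion. We express each junction as an
   **offset**: for the 5′ side, `offset5 = canonical_site − projected
   position of the last aligned upstream 28S base`; positive values mean
   upstream 28S was removed. `offset3` is defined symmetrically downstream.
2. **Clades R2A–R2D are defined by the zinc-finger complement N-terminal to
   the reverse-transcriptase domain**: (2 CCHH + 1 CCHC) → R2A,
   (1 + 1) → R2B, (2 CCHH) → R2C, (1 CCHH) → R2D; any other complement is
   reported `unknown`, never guessed.

## Pipeline steps and parameters

| step | method | key defaults |
|---|---|---|
| copy discovery | k-mer seed, diagonal chaining, ungapped X-drop extension; identity from an edit-distance alignment (edlib) | k=12, min_identity=0.7, min_len=100 (library) / 500 (pipeline) |
| junction calling | flank windows locally aligned (bespoke Gotoh SW) to the target | window=60, min_flank_identity=0.8, tol5=2, tol3=0 |
| family verdict | fraction of copies adjacent to the target | specific_fraction=0.9 |
| 3′ UTR screen | SW of 3′-terminal 300 bp vs target, stricter scoring | min_hit_len=30 |
| zinc fingers | regex `C-x(2,4)-C-x(8,20)-H-x(3,5)-[H/C]`, greedy leftmost, resume after match | scan N-terminal 40% unless an RT start is given |
| virtual PCR | exact IUPAC matching both orientations | max_len=3000, max_mismatch=0 |
| consensus | per-column majority, gap-majority columns dropped, ties → A<C<G<T and flagged | gap_rule_fraction=0.5 |
| phylogeny | p-distance (pairwise or complete deletion) + Saitou–Nei NJ + column bootstrap | n_reps=100 |

Alignment scoring is match +1, mismatch −1, gap of length L = −2 − L
(open −2, extend −1) throughout, configurable per call. The 3′ UTR screen
uses a stricter scheme (mismatch −3, open −5, extend −2): with the default
scores a local alignment can drift past an embedded segment through random
UTR sequence on lucky matches, diluting the measured identity — and an
*exact* UTR copy of the target must measure exactly 1.0, because the
UTR-internal call rests on a strict inequality (segment identity < flank
identity; a segment as good as the flanks is indistinguishable from true
flanking sequence and is reported `is_utr_internal = false`).

### Junction projection

Offsets are projected to the last/first *aligned* target base of the flank
alignment. Unaligned flank bases between the alignment end and the element
boundary (junction "slop": target-site alteration on insertion, or copy
boundary error from the seed-and-extend step) are recorded and flagged
(`junction_gap_*`, with a `:large` suffix beyond 3 bp) but deliberately not
projected through: boundary slop lies on the element side of the junction,
and projecting through it double-counts the error. On simulated data this
choice recovers configured offsets exactly at 0% decay and within ±3 bp in
>95% of trials at 5% decay.

When both offsets exceed tolerance (a case outside the four-class scheme),
the copy is reported as shifted on the dominant side (larger |offset|, 5′ on
ties) and flagged `both_junctions_shifted`.

The flank-identity denominator is the examined window (60 bp), not the
aligned columns: a short perfect local hit inside a random spacer flank then
scores ~0.2–0.35 and cannot clear the 0.8 threshold, while genuine 28S
flanks score ≈1. Minus-strand copies have their flanks swapped and
reverse-complemented before projection, so offsets always live in target
coordinates.

## The simulator: what it emulates, what it does not

`syngenome` builds a tandem array: spacer + (28S unit + spacer) × n_units
(defaults: 8 units, 400 bp spacers, uniform-random spacer sequence at GC
0.5). The synthetic 28S core is the concatenated reverse complements of the
two published downstream 28S primers with the canonical site at their
junction, padded by random flanks (default 200 bp); this is a documented
convention — the construction guarantees one primer site immediately
downstream and one immediately upstream of a canonical insertion, which is
exactly the geometry the PCR strategy exploits — and not a claim about the
biological 28S sequence.

Element families are generated with a single stop-free ORF carrying the
clade's finger complement (inert spacer codons that can never complete a
finger pattern), exact RT-primer binding sites, an optional 5′ UTR ribozyme
motif (CCTCCTCGTGG; default position reproduces the avian 37–47 geometry)
and an optional decayed 28S segment in the 3′ UTR whose realised identity is
made exact by substituting a fixed count of positions. Decay of inserted
copies is i.i.d. per-base substitution at the configured rate, with optional
indels at 1/10 that rate (geometric lengths, mean 2). Truncation is 5′-only,
as in target-primed reverse transcription. Non-specific copies are placed
uniformly in spacer interiors with an 80 bp margin from unit boundaries —
without the margin a "non-specific" copy can land flush against a unit and
acquire a genuine 28S flank, making its truth label unrecoverable in
principle.

Not modelled: concerted evolution of the array, population dynamics of
element activity, sequencing error, assembly collapse of the rDNA array, and
heterogeneity among 28S units. Passing the recovery tests therefore shows
the calling logic is correct under clean tandem-array assumptions, not that
real assemblies (where rDNA is frequently collapsed or fragmented) will
yield complete copy sets.

The 12-family protein set for clade-monophyly tests draws 4 independent
random ancestors (~saturated between clades) and mutates each into 3
descendants at 10% divergence — distances comfortably inside the regime
where neighbor joining is consistent, which is the point: the test checks
the tree machinery, not hard phylogenetics.

## Numerical and design choices

- **Distance trees instead of maximum likelihood.** The acceptance surface
  is clade monophyly on synthetic data; p-distance + NJ is deterministic
  (Q-ties broken by lexicographically smallest label pair) and sufficient.
  ML inference and substitution-model selection are out of scope; column
  filtering is limited to an optional max-gap-fraction rule.
- **Negative NJ branch lengths** are clamped to zero and counted on the tree
  object.
- **Identity denominators.** `pairwise_identity` defaults to
  aligned-columns-excluding-dual-gaps, with a `shorter_seq` alternative,
  since published percent identities rarely state their convention.
- **Degenerate primers.** Template ambiguity codes match only by code
  identity (an N in the template is not a free match). Default product limit
  3000 bp (a 2-minute extension implies ~2 kb; margin added). A
  `max_mismatch` budget models primer-site divergence, the usual explanation
  for PCR-negative species.
- **Determinism.** Every stage draws from a named substream of the run seed,
  so identical (config, seed) reproduce byte-identical FASTA, truth tables
  and reports; the report carries seed, version and a hash of the scientific
  config (output paths excluded).
- **Problem sizes.** Default element length 3 kb, demo genomes ~20–40 kb,
  100-trial specificity and monophyly studies, 50-seed consensus study —
  sizes chosen so the whole suite exercises every code path in seconds while
  keeping the statistics (binomial bounds on majority-consensus error,
  offset-recovery rates) meaningful.

## Known limitations

- The copy finder is a single-family scanner; overlapping calls across
  families are resolved by the pipeline (longer, higher-identity hit wins),
  not by a joint model. Fragmented or internally deleted copies may be
  reported as multiple hits.
- A family whose 3′ UTR carries a long target-like segment produces short
  spurious per-unit hits at permissive `min_len`; the pipeline default
  (500 bp) sits above any such segment and below real copies, but a user
  scanning for very short fragments must interpret sub-500 bp hits near 28S
  with care.
- Junction calls assume the target reference matches the genome's rDNA
  closely (flank identity threshold 0.8); highly diverged or chimeric units
  will push true flanks below threshold and under-call adjacency.
- `star_align` is a projection utility (insertions relative to the reference
  are dropped), adequate for consensus rebuilding from simulated copies, not
  a general multiple aligner.
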
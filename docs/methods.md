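# Methods

## Scope and model

`nr2dbd` operationalizes the sequence grammar of two-DBD nuclear
receptors as deterministic motif scanners plus a rule-based classifier.
The underlying model is purely positional: each signature is a list of
per-position residue alternatives (wildcards allowed), with three
physicochemical classes — hydrophilic {R,K,D,E,N,Q}, neutral
{S,G,H,T,A,P}, hydrophobic {Y,V,M,C,L,F,I,W} — used where a consensus
specifies "Φ" or "h". There is no probabilistic profile (no PSSM/HMM):
a window either satisfies every position or it does not. This makes
every call exactly reproducible and auditable, at the cost of
sensitivity to divergent family members; the tolerance knobs below are
the intended mitigation.

All coordinates are 0-based half-open. The ambiguity letter `X` in
input is accepted but deliberately matches only wildcard positions,
never an anchor cysteine/histidine or a fixed consensus letter —
conservative handling so that low-quality sequence cannot fabricate a
motif.

## Scanners

**Zinc fingers.** CI, CII and CHC2 are matched with exact anchor
spacings ((2,13,2), (5,9,2), (6,9,2) with H at the third anchor).
Overlapping matches are all reported. A `spacer_tolerance` flag widens
only the long middle spacer by ±1 (13→12–14, 9→8–10); it is **off** by
default, since the canonical geometry holds with very little exception
and a strict default keeps false positives down.

**DBD assembly.** CI→CII pairing is greedy left-to-right: each CI takes
the nearest following CII starting within `max_inter_finger_gap`
(default 30) residues of the CI end; each finger is used at most once.
The 30-residue default is a judgment call — typical NR DBDs keep the
two fingers close, and the observed intra-DBD spacing in this family is
not published — so it is configurable. P-box and D-box are definitional
slices (five residues after CI anchor 3; the five residues inside CII's
C-X5-C) and are stored on the DBD at assembly time.

**Architecture.** LBD presence is operationalized as "≥1 Ti hit after
the last DBD" because Ti is the only computable LBD-specific signature
in the grammar; AF2 absence does not negate an LBD (the *A. avenae*
group-C situation). With an LBD, 1 DBD → TYPICAL_NR and ≥2 →
TWO_DBD_NR; without, any DBD → DBD_ONLY; neither → NOT_NR. More than
two DBDs is logged, flagged `multi_dbd`, and classified from the first
two — consequently the report's linker/P-P fields are defined whenever
at least two DBDs exist, a deliberate relaxation of "exactly two" so
the flagged edge case still carries its measurements.

**CTE.** The G-box search window is the 30 residues after the second
DBD end (the pre-Grip values ever observed are 5 and 8, so 30 is
generous; configurable). The group hint's variant is tried before the
general RXGRZP; Z is restricted to the hydrophobic class by default
(`gbox_z_strict=false` relaxes it to any residue). `pre_grip_len` is
measured from the last anchor cysteine of the second DBD's CII to the
G-box start — the literature does not pin the pre-Grip origin, so this
convention is ours and is mirrored by the generator, making the 5/8
values reproducible by construction. The T-box test is simply
`pre_grip_len >= 12` (the T-box is a 12-residue unit); the residue five
positions after the G-box is reported so the conserved H of group A can
be checked.

**NTSS.** The three platyhelminth patterns are scanned over the whole
A/B domain; every hit is reported (whether multiple hits are meaningful
is unknown, so we do not filter). Trailing wildcards match exactly one
residue — a literal reading of the consensus strings.

**Dimerization class.** The marker columns of the Brelivet numbering
are not recoverable from an unaligned sequence (the numbering assumes
variable inserts deleted), so `dimer_class_profile` takes an aligned
LBD row plus a user-supplied label→column map. The call uses the
strictly conserved discriminators only — RK93 (class I) versus R62
(class II) — rather than complete salt-bridge pairs, because 2DBD-NRs
are class I despite lacking KR55. The shipped default column map is
valid only for the generator's ungapped synthetic LBDs.

## Classification and naming

Group assignment is exact-match first against the four P-P signatures,
then nearest-signature by Hamming distance over the 10 P-box letters
(the two display Cs are not counted; the canonical central C is, since
it can diverge). The default budget is 1 mismatch. Distance ties go to
UNCLASSIFIED even when the tied signatures share a group — a
conservative choice that favors abstention over a coin flip. Beyond the
budget, Nematoda-flagged records become group C (that group has no
sequence signature); everything else is UNCLASSIFIED.

Gene numbering needs an ordering that sequence alone cannot supply (the
published numbering follows phylogenetic subgroups), so `number_genes`
consumes an explicit ordered (member, subgroup) list; the CLI defaults
to P-P-module identity as the subgroup key and tree-leaf order when a
newick file is given. A gene that is alone in its subgroup gets a
numeral but no variant letter; numerals are always emitted (a flag-free
simplification of the inconsistent usage for single-gene groups).

## Phylogenetic corroboration

Distances are 1 − fraction identity of a global affine-gap alignment
(BLOSUM62, open 10, extend 1 — the first gap residue costs the open
penalty, each further residue the extension) over the concatenated
first+second DBD spans. Plain p-distance, no model correction: this is
a desk-scale corroborator of the rule-based grouping, not
publication-grade phylogenetics, and is documented as such. Neighbor
joining is implemented directly (Q-matrix agglomeration, deterministic
first-minimum tie-break, final trifurcation resolved analytically);
negative branch lengths are clamped to zero with a log message. On
additive matrices the generating tree is recovered exactly — the test
suite verifies this against random 5–8-taxon trees and cross-checks the
topology against an independent library implementation.

## The synthetic generator

`synth.make_sequence` assembles a protein left to right — A/B (+NTSS at
its 3′ end), CI+CII with the requested P-/D-boxes, linker, second DBD,
pre-Grip + G-box (+H at +5 for group A), hinge, LBD with an embedded Ti
instance, class-marker residues at the default columns and an AF2 core
at the C-terminus — and records every realized value and coordinate in
a `TruthRecord`. Defaults are the family's published conditions: linker
uniform in [17,22]; pre-Grip 5 (A/B) or 8 (C); G-box RFGRQP / KSGRP /
RDRRGP per group; intra-DBD CI→CII spacing 10 (unpublished; chosen well
inside the assembler's 30 default); A/B 40, hinge 25, LBD 110 residues.
The group-C panel template is *A. avenae*-style (Ti present, AF2
absent, Nematoda taxon).

Two deliberate non-realisms, and what they imply for the tests:

* **Filler is the neutral class minus C and H** ({S,G,T,A,P}), so no
  spurious anchors, Ti starts or G-box starts can arise by chance.
  Passing round-trip tests therefore demonstrate correctness of the
  grammar, not robustness to compositionally realistic background. A
  `hard_mode` flag widens the filler to all residues except the anchor
  letters C and H and rejects-and-redraws the rare assembly whose
  filler still collides with a scanner motif. The NOT_NR decoy does use
  the full 20-letter alphabet.
* **Group members share a conserved DBD core.** DBD-internal spacer
  residues come from a fixed per-group stream (seeds 11/12/13), while
  A/B, linker, hinge and LBD filler stay independent per copy. Without
  this, within-group and between-group DBD distances would be
  identically distributed and no distance method could separate the
  groups; with it, the generator mirrors the real within-group
  conservation that the phylogenetic grouping rests on.

`make_panel(n, seed)` emits n copies of the five P-P templates and of
four decoys (single-DBD typical NR, LBD-only, CHC2-bearing protein,
random protein); all randomness flows from one `numpy` generator, so a
fixed seed reproduces panels byte-for-byte.

## Numerical and procedural choices

* Motif matching uses lookahead regular expressions so overlapping
  occurrences are all reported; scanners are re-checked in the tests
  against position-by-position brute-force matchers.
* AF2 ties resolve to the hit nearest the C-terminus (it is a
  C-terminal element); G-box ties to the leftmost hit in the window.
* The report TSV has a fixed column order and round-trips losslessly
  through its reader (TSV and JSON).
* Problem sizes in the test suite — 1,000 random 200-mers for the
  finger oracle, 100 positives for full parameter recovery, 5–8 taxa
  for the NJ oracle, a 20-sequence panel in the acceptance script —
  were chosen as the smallest panels that exercise every template and
  every alternative branch of each consensus.

## Known limitations

Exact spacing means truncated or frame-damaged DBDs are missed rather
than partially scored. Group C is only callable with taxon metadata.
The Brelivet column map must come from an external alignment for real
data. p-distance NJ underestimates divergence at large distances and
carries no support values — use it to sanity-check grouping, not to
publish a phylogeny. The generator's ground truth covers the grammar's
own features; it does not emulate evolutionary substitution processes
or realistic amino-acid composition.
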
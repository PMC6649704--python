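# Methods

This note documents the models and procedures implemented in `irphase`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real data.

## Sequence model and input handling

All analyses operate on individual protein-coding sequences (CDS) stored as
the coding strand in frame 0. GenBank input is converted from 1-based
inclusive coordinates to the internal 0-based half-open convention;
minus-strand features are reverse-complemented on read. Mitochondrial CDS
frequently end in truncated stop codons (T or TA completed by
polyadenylation); trailing incomplete codons are trimmed rather than padded,
so no nucleotides are invented. Records with ambiguity codes are excluded
with a warning because perfect-repeat identity is defined on exact
Watson–Crick complementarity; records with internal stops are excluded as
mis-framed. Genetic codes are NCBI translation tables (1, 2, 4, 5 exposed;
5, the invertebrate mitochondrial code, is the default everywhere). Under
table 5 the synonymous-family census used by the codon-usage statistics is
12 two-fold, 6 four-fold, 1 six-fold (Leu) and 1 eight-fold (Ser) family —
62 sense codons, stops TAA/TAG.

## Perfect-repeat detection

A maximal perfect inverted repeat is a pair of equal-length segments
(arm5 before arm3, non-overlapping) with arm5 equal to the reverse
complement of arm3, extendable neither outward nor inward (into the loop)
without breaking complementarity or making the arms meet. Every base pair
(i, j) of such a repeat satisfies i + j = constant, so each repeat lives on
one anti-diagonal of the self-complementarity matrix and the maximal repeats
are exactly the maximal runs of complementary pairs along anti-diagonals.
The detector enumerates all anti-diagonals with numpy run-length extraction:
O(n²) time, exact, no heuristics. Nested and overlapping repeats are all
reported (overlap complexes are themselves of interest); each arm pair is
reported once, ordered by (arm5 start, arm length descending, arm3 start).
"Repeat length" always means arm length; a loopless repeat of arm L is a
perfect palindrome of span 2L.

The unit and acceptance suites verify the detector against an independently
written string-level oracle (outermost-pair enumeration with inward
extension) on 1,000+ seeded random sequences of length 50–500 at GC 20–80%,
and assert non-extendability of every reported repeat directly.

Loop length is unbounded by default: detection runs per CDS, which bounds
the spacer implicitly, and a `max_loop` parameter exists for genome-scale
scans.

## Scored (imperfect) repeat detection

Decayed stems are found by Smith–Waterman local alignment of the sequence
against its own reverse complement with match +3, mismatch −4, linear gap
−12 and reporting threshold 15 (all configurable). Cells whose paired
positions would overlap are masked, so the 5′ partner always precedes the 3′
partner, and an optional `max_extent` bounds the hairpin span. Candidate
end-cells at or above threshold are traced back in descending score order;
a candidate touching positions already claimed by a higher-scoring stem is
dropped, yielding non-overlapping locally optimal stems with matched-column
counts for length-versus-identity scatters. This is a from-scratch dynamic
program defined by the scoring scheme above; agreement with any particular
external implementation of the same scheme is not guaranteed cell-for-cell.
With mismatch and gap penalties driven to −∞ the alignments collapse to
perfect stems, which the tests check against the perfect detector.

## Phase classification

For a repeat inside an in-frame CDS, base k of arm5 pairs with the mirrored
base of arm3, and codon positions pair according to exactly one of three
patterns (phases). With c_A the codon position (1–3) of the first base of
arm5 and c_B that of the last base of arm3 — two bases that pair with each
other — the phase is the unique k with 2k ≡ c_A + c_B (mod 3). The formula
is validated against exhaustive per-base pairing checks across phases × arm
lengths × loop lengths, and phases cycle 2→3→1 under single-base shifts of
the repeat, which the tests confirm. Repeats only partially inside a CDS are
excluded from phase analysis (logged): their pairing geometry is undefined
across gene boundaries.

Phase-resolved summaries: censuses at arm-length cutoffs (strict `>` by
default, matching "repeats >15 bp" phrasing; cumulative length sums one arm
per repeat), phase-proportion curves over minimal arm lengths (counts
non-increasing in the threshold), and a per-codon region mask in which a
codon belongs to a phase region if any of its bases lies in either arm;
overlaps resolve to the longest repeat, ties to the lower phase number.

Cross-species midpoint sharing maps each repeat's midpoint (the centre
between the arms; half-integral for odd enclosed spans) to an alignment
column of a per-gene aligned FASTA whose ungapped rows must reproduce the
CDS exactly. Half-integral midpoints keep their 0.5 offset from the column
of the position to their left — deterministic when the right neighbour sits
across a gap. Midpoints are grouped by single linkage at a column tolerance,
default 3 columns (one codon); the tolerance is a free parameter because
"same location" has no canonical width, and it is recorded in CLI output
metadata.

## Constraint calculus (permitted amino acids and entropy)

Fix a dipeptide on one arm and let X·Y range over its synonymous dicodons.
The complementary arm reads R = revcomp(X·Y) in a frame set by the phase:
phase 2 aligns codon boundaries, so R splits into the independent
complements of Y and X; phases 3 and 1 shift the frame by one and two bases,
leaving a single junction-spanning codon (R[1:4], R[2:5]) that depends on
both X and Y. The permitted-amino-acid count is the number of distinct amino
acids reachable by the junction codon (phases 1, 3) over all dicodons. The
entropy variant places the product of within-family codon probabilities on
the dicodons — observed usage renormalized per family, or uniform ("equal
codon frequencies") — propagates it to the complementary amino acid, and
reports Shannon entropy in bits. Dataset-level means weight each dipeptide
by its observed frequency in the pooled CDS set; dipeptide weights stay
observed in both entropy modes (only the codon frequencies change), and
pooling is across all input records by default.

Two deliberate conventions:

* **Phase 2.** The two complementary codons are fully determined one-by-one
  (complement of c2 is independent of c1), so the default scores the
  complement of the second codon only, keeping a one-codon-per-dipeptide
  accounting uniform across phases. A "union" variant pooling the amino
  acids of both complements is available and reported side by side by the
  CLI `table1` command; for the entropy of the union variant the two induced
  distributions enter as an equal-weight mixture. This aggregation is the
  principal reimplementation ambiguity of the procedure.
* **Stops.** A complementary codon that is a stop cannot be realized in a
  coding region; stops are excluded from the permitted set and removed from
  the entropy distribution with renormalization (tallied in debug logs).

Hand-enumerable anchor values under table 5 (tested): Met–Met gives
permitted counts 1 / 2 / 2 for phases 3 / 1 / 2, equal-frequency entropies
0 / 1 / 1 bits, and entropy H(0.9, 0.1) ≈ 0.469 bits when Met usage is
90/10 between ATA and ATG.

## Null models

Codon shuffling permutes each CDS's codon array uniformly at random
(Fisher–Yates via numpy PCG64); a k-mer-preserving shuffle at k = 1 on a
recoded codon alphabet is exactly a uniform permutation, so nothing heavier
is required. Nucleotide shuffling permutes bases. Shuffling is per-CDS,
never across genes, matching per-CDS detection; replicate seeds derive from
one top-level seed through numpy's SeedSequence spawning, so ensembles are
reproducible. Default ensemble size is 10 replicates. Over-representation is
observed count divided by mean null count at each minimal arm length,
undefined (None) where the null mean is zero. Tests verify multiset
conservation in every replicate, permutation uniformity by chi-square over
all 3! orders of a 3-codon CDS, ratio ≈ 1 on i.i.d. material (which is its
own codon-shuffle null in distribution), and growth of the ratio with
minimal length on repeat-enriched fixtures.

## Region statistics

Wright's effective number of codons: per synonymous family with n observed
codons, F̂ = (nΣp̂ᵢ² − 1)/(n − 1); F̂ values (those > 0, from families with
n ≥ 2) average within degeneracy classes, and Nc = Σ N_class / F̄_class with
single-codon families at F = 1. A class with no estimable family is imputed
by the mean of neighbouring class means (the standard convention for the
3-fold class); if nothing is estimable Nc is undefined. Closed forms used as
test anchors: one codon per amino acid → Nc = 20 under the standard code;
uniform usage over table-5 sense codons → Nc → 62. Small samples can push
F̂ below 1/family-size, so Nc can exceed the sense-codon count; such values
are reported as computed.

Composition comparison builds, per amino acid, the 2×2 table (this amino
acid vs all others) × (region vs background) and applies a two-sided Fisher
exact test — p is the total probability of tables, under fixed margins, no
more probable than the observed one (the convention matters and is pinned by
an enumeration oracle in the tests). Significance uses Bonferroni m = 20:
p < 0.0025 at α = 0.05. Codons are assigned to regions by the phase mask,
with both arms of a repeat contributing to its phase region.

Conservation profiles are consumed, not inferred: the only operation is a
central moving average with window 5 (odd windows only), the half-window
shrinking symmetrically at the series edges.

## Synthetic data: what it emulates and what it does not

The generator draws i.i.d. codons from an AT-rich usage (base probabilities
A = T = at/2 with `at` defaulting to 0.72, the middle of the 65–78% range
typical of the target genomes; realized A+T shifts slightly after stop
exclusion), rejection-resamples until no chance repeat with arm ≥ 15 bp
remains, then writes repeats of requested phase/arm/loop geometry: the 3′
arm is always the exact reverse complement of the 5′ arm, and stop codons
arising from the overwrite are repaired by re-drawing the paired 5′-arm
codon (synonyms first, then any sense codon — arm codons carry repeat
sequence and need not preserve the host protein, which is preserved for all
codons entirely outside the arms). A requested phase is reached by shifting
the start position by 0–2 bases, since phases cycle under unit shifts.
Optional decay substitutes arm3 bases to break pairing without stops, for
exercising the scored detector (a full-extent stem with m mismatches scores
3(L − m) − 4m).

The four-genome synthetic study (`study_like_specs`) embeds ~12 repeats per
genome with arms in the 15–142 bp regime (geometric-tailed around a few tens
of bases), loops Poisson around 37 bp, and long repeats biased towards
phases 1 and 2 — the qualitative arrangement the analysis is designed to
resolve. What passing tests on this material establish: the detector is
exact (oracle-verified), phase classification is correct by construction,
recall of embedded repeats is complete, and the statistics behave as derived
on material with known truth. What they do not establish: real genomes are
not i.i.d. codon streams — they have gene-specific composition, dipeptide
autocorrelation, overlapping repeat complexes with shared arms, and
imperfect annotation. Census numbers from real data therefore also depend on
counting conventions (strict vs inclusive cutoffs, per-CDS detection
boundaries) documented above. The published-data reproduction test runs only
when the deposited GenBank records are supplied locally.

## Problem sizes and determinism

Default test and acceptance runs use four synthetic genomes × 13 genes × 250
codons (~39 kb of coding sequence), 10-replicate null ensembles, and
1,000-sequence oracle batteries; these sizes were chosen so the full suite
and the acceptance script each complete in well under a minute on one CPU
while keeping every statistical check comfortably powered. All randomness
flows from explicit integer seeds through numpy generators; identical seeds
give byte-identical outputs.

## Known limitations

* The scored detector reports non-overlapping stems greedily by score; a
  lower-scoring stem overlapping a reported one is suppressed even when a
  human would call both.
* The phase-2 constraint aggregation is a convention (see above); both
  variants are computed, but only one can match any given external table.
* Nc follows Wright's estimator with class-mean imputation; other published
  variants (background-composition-corrected Nc′ etc.) are out of scope.
* No RNA secondary-structure thermodynamics: hairpin-forming potential is
  inferred from repeat geometry only.
* Direct repeats are not detected except as a by-product of overlapping
  inverted repeats.
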
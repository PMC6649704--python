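"""How strongly each repeat phase constrains the complementary amino-acid sequence.

Fix a dipeptide (two adjacent amino acids) on one arm of an in-frame inverted
repeat.  Synonymous codon choice for those two amino acids still leaves
freedom in the nucleotides, and that freedom propagates through base pairing
into the codons read on the complementary arm.  The quantities computed here
measure that freedom per phase:

* ``permitted_aa_count`` — how many distinct amino acids the complementary
  arm's reading frame can encode;
* ``permitted_aa_entropy`` — the Shannon entropy (bits) of the complementary
  amino acid, under within-family codon frequencies that are either the
  observed usage or uniform ("equal");
* ``mean_constraints`` — dipeptide-frequency-weighted means of the above,
  one row of a per-phase constraint table.

Geometry.  Write the dicodon X·Y and its reverse complement R = ~(X·Y), a
6-mer.  The complementary arm is read in a frame set by the phase: phase 2
aligns codon boundaries (R splits into two whole codons, the complements of Y
and X), while phases 3 and 1 shift the frame by one and two bases, so exactly
one *junction-spanning* codon — R[1:4] for phase 3, R[2:5] for phase 1 —
depends on both X and Y and is the carrier of the cross-arm constraint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

from .seqcore import CodonUsage, DipeptideTable, GeneticCode, STOP_SYMBOL, reverse_complement

logger = logging.getLogger(__name__)

_JUNCTION_SLICE = {3: slice(1, 4), 1: slice(2, 5)}


def complementary_codons(dicodon: tuple, phase: int, code: GeneticCode) -> list:
    """Codons read on the complementary strand's frame for one dicodon.

    Phase 2 returns both whole codons of R = revcomp(X·Y); phases 3 and 1
    return the single junction-spanning codon (R[1:4] and R[2:5]).
    """
    x, y = dicodon
    for codon in (x, y):
        if code.codon_to_aa[codon] == STOP_SYMBOL:
            raise ValueError(f"stop codon {codon} in dicodon")
    r = reverse_complement(x + y)
    if phase == 2:
        return [r[0:3], r[3:6]]
    if phase in _JUNCTION_SLICE:
        return [r[_JUNCTION_SLICE[phase]]]
    raise ValueError(f"phase must be 1, 2 or 3, got {phase}")


def _outcome_codon(c1: str, c2: str, phase: int, variant: str) -> list:
    """Complementary codon(s) whose amino acid is scored for one dicodon."""
    r = reverse_complement(c1 + c2)
    if phase == 2:
        # The two complementary codons are the separate complements of c2 and
        # c1; the complement of c2 alone is scored by default (see variant).
        return [reverse_complement(c2)] if variant == "second" else [
            reverse_complement(c2),
            reverse_complement(c1),
        ]
    return [r[_JUNCTION_SLICE[phase]]]


def permitted_aa_count(
    dipeptide: tuple,
    phase: int,
    code: GeneticCode,
    phase2_variant: str = "second",
) -> int:
    """Number of distinct amino acids the complementary frame can encode.

    All synonymous dicodons of the dipeptide are enumerated; the amino acids
    of the phase's complementary codon(s) are collected.  Complementary codons
    that are stops are excluded from the permitted set (they cannot occur in a
    coding region) and tallied in the log.

    ``phase2_variant``: for phase 2 the complementary codons are the
    independent complements of the two codons; ``"second"`` (default) scores
    the complement of the second codon only (a single-codon calculation),
    ``"union"`` pools the amino acids of both complements.
    """
    aa1, aa2 = dipeptide
    permitted = set()
    n_stop = 0
    for c1, c2 in product(code.family(aa1), code.family(aa2)):
        for comp in _outcome_codon(c1, c2, phase, phase2_variant):
            aa = code.codon_to_aa[comp]
            if aa == STOP_SYMBOL:
                n_stop += 1
            else:
                permitted.add(aa)
    if n_stop:
        logger.debug(
            "%s%s phase %d: %d complementary stop codon(s) excluded", aa1, aa2, phase, n_stop
        )
    return len(permitted)


def _aa_distribution(
    dipeptide: tuple,
    phase: int,
    code: GeneticCode,
    codon_freqs: CodonUsage | str,
    phase2_variant: str,
) -> dict:
    """Probability over complementary amino acids induced by codon choice."""
    aa1, aa2 = dipeptide
    probs = {}
    for aa in dipeptide:
        if aa == STOP_SYMBOL:
            raise ValueError("stop is not a dipeptide residue")
    if codon_freqs == "equal":
        cond = {
            aa: {c: 1.0 / len(code.family(aa)) for c in code.family(aa)}
            for aa in (aa1, aa2)
        }
    else:
        cond = {aa: codon_freqs.family_conditional(aa) for aa in (aa1, aa2)}
    dist: dict = {}
    for c1, c2 in product(code.family(aa1), code.family(aa2)):
        p = cond[aa1][c1] * cond[aa2][c2]
        if p == 0:
            continue
        outcomes = _outcome_codon(c1, c2, phase, phase2_variant)
        for comp in outcomes:
            aa = code.codon_to_aa[comp]
            dist[aa] = dist.get(aa, 0.0) + p / len(outcomes)
    # stops cannot be realized in a coding region: drop and renormalize
    stop_mass = dist.pop(STOP_SYMBOL, 0.0)
    if stop_mass:
        total = sum(dist.values())
        if total == 0:
            return {}
        dist = {aa: p / total for aa, p in dist.items()}
    return dist


def permitted_aa_entropy(
    dipeptide: tuple,
    phase: int,
    code: GeneticCode,
    codon_freqs: CodonUsage | str = "equal",
    phase2_variant: str = "second",
) -> float:
    """Shannon entropy (bits) of the complementary amino acid.

    The dicodon distribution is the product of within-family codon
    probabilities — observed usage renormalized per synonymous family, or
    uniform per family when ``codon_freqs="equal"``.
    """
    dist = _aa_distribution(dipeptide, phase, code, codon_freqs, phase2_variant)
    return -sum(p * math.log2(p) for p in dist.values() if p > 0)


@dataclass
class ConstraintRow:
    phase: int
    mean_permitted_aa: float
    mean_entropy_actual: float
    mean_entropy_equal: float


def mean_constraints(
    dipeptides: DipeptideTable,
    phase: int,
    code: GeneticCode,
    codon_freqs: CodonUsage,
    phase2_variant: str = "second",
) -> ConstraintRow:
    """Dipeptide-frequency-weighted means of count and both entropy variants.

    Dipeptide weights stay at their observed values in both entropy modes;
    "equal" refers only to the within-family codon frequencies.
    """
    mean_count = 0.0
    mean_h_actual = 0.0
    mean_h_equal = 0.0
    for dipep, w in dipeptides.frequencies.items():
        if w == 0:
            continue
        pair = (dipep[0], dipep[1])
        mean_count += w * permitted_aa_count(pair, phase, code, phase2_variant)
        mean_h_actual += w * permitted_aa_entropy(
            pair, phase, code, codon_freqs, phase2_variant
        )
        mean_h_equal += w * permitted_aa_entropy(
            pair, phase, code, "equal", phase2_variant
        )
    return ConstraintRow(
        phase=phase,
        mean_permitted_aa=mean_count,
        mean_entropy_actual=mean_h_actual,
        mean_entropy_equal=mean_h_equal,
    )


def constraint_table(
    dipeptides: DipeptideTable,
    code: GeneticCode,
    codon_freqs: CodonUsage,
    phase2_variant: str = "second",
) -> dict:
    """Constraint rows for all three phases: {phase: ConstraintRow}."""
    return {
        phase: mean_constraints(dipeptides, phase, code, codon_freqs, phase2_variant)
        for phase in (1, 2, 3)
    }
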
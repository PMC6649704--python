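"""Reading-frame phase of in-frame inverted repeats, and phase-resolved summaries.

When both arms of an inverted repeat lie inside a protein-coding sequence,
base pairing couples codon positions of one arm to codon positions of the
other.  Exactly one codon position k pairs with itself across the arms; that
k is the *phase* of the repeat:

* phase 1 pairs codon positions (1,1), (2,3), (3,2) — the functionally
  definitive position 2 is tied to the degenerate position 3, the weakest
  constraint;
* phase 2 pairs (2,2), (1,3), (3,1);
* phase 3 pairs (3,3), (1,2), (2,1) — positions 1 and 2 of opposite arms are
  mutually tied, the strictest constraint.

Let cA be the codon position (1..3) of the first base of the 5' arm and cB the
codon position of the last base of the 3' arm.  These two bases pair with each
other, so cA + cB ≡ 2k (mod 3), giving phase k = 1, 2, 3 for
(cA + cB) mod 3 = 2, 1, 0 respectively.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .repeats import InvertedRepeat, find_perfect_irs
from .seqcore import CdsRecord

logger = logging.getLogger(__name__)

_PHASE_FROM_SUM = {2: 1, 1: 2, 0: 3}

#: pairing sets (codon position of arm5 base, codon position of arm3 base)
PHASE_PAIRINGS = {
    1: {(1, 1), (2, 3), (3, 2)},
    2: {(2, 2), (1, 3), (3, 1)},
    3: {(3, 3), (1, 2), (2, 1)},
}


class PhaseError(ValueError):
    """Repeat geometry is incompatible with phase classification."""


@dataclass(frozen=True)
class PhasedRepeat:
    base: InvertedRepeat
    phase: int
    cds: CdsRecord

    @property
    def arm_len(self) -> int:
        return self.base.arm_len


def classify_phase(repeat: InvertedRepeat, cds: CdsRecord) -> int:
    """Phase (1, 2 or 3) of a repeat lying entirely within an in-frame CDS."""
    n = len(cds.seq)
    if repeat.arm5[0] < 0 or repeat.arm3[1] > n:
        raise PhaseError(
            f"repeat {repeat.arm5}/{repeat.arm3} extends outside CDS of length {n}"
        )
    c_a = repeat.arm5[0] % 3 + 1
    c_b = (repeat.arm3[1] - 1) % 3 + 1
    return _PHASE_FROM_SUM[(c_a + c_b) % 3]


def classify_repeats(cds: CdsRecord, repeats: list) -> list:
    """Attach phases; repeats only partially inside the CDS are dropped (logged)."""
    out = []
    for rep in repeats:
        try:
            out.append(PhasedRepeat(base=rep, phase=classify_phase(rep, cds), cds=cds))
        except PhaseError as exc:
            logger.warning("%s/%s: %s", cds.species, cds.gene, exc)
    return out


def phase_census(
    phased: list, arm_len_cutoffs: tuple = (15, 30), strict: bool = True
) -> dict:
    """Per-phase repeat counts and cumulative arm lengths above each cutoff.

    Cumulative length sums one arm per repeat.  Cutoffs are strict (> cutoff)
    by default, matching censuses phrased as "repeats >15 bp".
    """
    census: dict = {}
    for cutoff in arm_len_cutoffs:
        keep = [
            p
            for p in phased
            if (p.arm_len > cutoff if strict else p.arm_len >= cutoff)
        ]
        census[cutoff] = {
            phase: {
                "count": sum(1 for p in keep if p.phase == phase),
                "cumulative_length": sum(p.arm_len for p in keep if p.phase == phase),
            }
            for phase in (1, 2, 3)
        }
    return census


@dataclass
class PhaseCurve:
    """Phase proportions as a function of the minimal arm length."""

    thresholds: list
    counts: dict  # phase -> list of counts, aligned with thresholds
    totals: list

    @property
    def proportions(self) -> dict:
        props = {}
        for phase in (1, 2, 3):
            props[phase] = [
                c / t if t else float("nan")
                for c, t in zip(self.counts[phase], self.totals)
            ]
        return props


def phase_proportion_curve(phased: list, thresholds=range(5, 51)) -> PhaseCurve:
    """Counts and proportions of each phase at every minimal arm length.

    A repeat is counted at threshold t when its arm length is >= t, so totals
    are non-increasing in t.
    """
    thresholds = list(thresholds)
    arm_lens = {phase: sorted(p.arm_len for p in phased if p.phase == phase) for phase in (1, 2, 3)}
    counts = {
        phase: [len(lens) - bisect_right(lens, t - 1) for t in thresholds]
        for phase, lens in arm_lens.items()
    }
    totals = [sum(counts[ph][k] for ph in (1, 2, 3)) for k in range(len(thresholds))]
    return PhaseCurve(thresholds=thresholds, counts=counts, totals=totals)


def phase_region_mask(cds: CdsRecord, phased: list) -> np.ndarray:
    """Per-codon assignment to a phase region (1/2/3) or non-repeat (0).

    A codon belongs to a phase region when at least one of its bases lies in
    either arm of a repeat of that phase.  Codons contested between phases go
    to the longest repeat; ties go to the lower phase number.
    """
    n_codons = len(cds.seq) // 3
    mask = np.zeros(n_codons, dtype=np.int8)
    for p in sorted(phased, key=lambda p: (-p.arm_len, p.phase)):
        for start, end in (p.base.arm5, p.base.arm3):
            first, last = start // 3, (end - 1) // 3
            for k in range(first, last + 1):
                if mask[k] == 0:
                    mask[k] = p.phase
    return mask


def scan_cds_set(
    cds_set: list, min_arm: int = 2, max_loop: int | None = None
) -> dict:
    """Detect and classify perfect repeats in every CDS of a set.

    Returns {CdsRecord: list of PhasedRepeat}; detection is strictly per-CDS.
    """
    out = {}
    for cds in cds_set:
        reps = find_perfect_irs(cds.seq, min_arm=min_arm, max_loop=max_loop, seq_id=f"{cds.species}|{cds.gene}")
        out[cds] = classify_repeats(cds, reps)
    return out


def _ungapped_to_column(aligned: str) -> list:
    """Map each ungapped sequence position to its alignment column."""
    return [col for col, ch in enumerate(aligned) if ch != "-"]


def _midpoint_column(mid: float, colmap: list) -> float:
    """Alignment column of a (possibly half-integral) sequence midpoint.

    Half-integral midpoints keep their .5 offset relative to the column of the
    position to their left, which is deterministic when the right-hand
    neighbour sits across an alignment gap.
    """
    lo = int(np.floor(mid))
    lo = min(lo, len(colmap) - 1)
    return colmap[lo] + (mid - lo)


def shared_midpoints(
    alignments: dict,
    phased_by_species: dict,
    tolerance: float = 3,
) -> dict:
    """Group repeats whose hairpin midpoints fall at homologous alignment columns.

    Parameters
    ----------
    alignments
        {gene: {species: aligned sequence (with ``-`` gaps)}}.  Ungapped rows
        must reproduce the corresponding CDS sequences exactly.
    phased_by_species
        {species: {gene: list of PhasedRepeat}}.
    tolerance
        Maximal column distance (single linkage) for two midpoints to be
        considered shared; the default of 3 columns is one codon.

    Returns {gene: list of groups}; each group records its members
    (species, repeat) and the number of distinct species involved.
    """
    result: dict = {}
    for gene, rows in alignments.items():
        members = []  # (column, species, PhasedRepeat)
        for species, aligned in rows.items():
            reps = phased_by_species.get(species, {}).get(gene, [])
            if not reps:
                continue
            cds = reps[0].cds
            ungapped = aligned.replace("-", "")
            if ungapped != cds.seq:
                raise ValueError(
                    f"alignment row for {species}/{gene} does not match its CDS sequence"
                )
            colmap = _ungapped_to_column(aligned)
            for p in reps:
                members.append((_midpoint_column(p.base.midpoint, colmap), species, p))
        members.sort(key=lambda t: t[0])
        groups = []
        current: list = []
        for item in members:
            if current and item[0] - current[-1][0] > tolerance:
                groups.append(current)
                current = []
            current.append(item)
        if current:
            groups.append(current)
        result[gene] = [
            {
                "columns": [m[0] for m in grp],
                "members": [(m[1], m[2]) for m in grp],
                "n_species": len({m[1] for m in grp}),
                "size": len(grp),
            }
            for grp in groups
        ]
    return result
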
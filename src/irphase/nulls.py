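"""Shuffle-based null models for repeat abundance and phase proportions.

The codon shuffle permutes the codon sequence of each CDS uniformly at
random, preserving the codon multiset (hence codon frequencies and the
encoded amino-acid composition as a multiset) while destroying positional
structure.  The nucleotide shuffle permutes single bases, preserving only
base composition.  Both are Fisher–Yates permutations on the recoded array,
driven by numpy's seedable PCG64 generator; a shuffle preserving k-mer
frequencies at k = 1 is exactly a uniform permutation, so no heavier
machinery is needed.

Shuffling is always per-CDS, matching per-CDS repeat detection; counts are
pooled across the set afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phases import PhaseCurve, classify_repeats, phase_proportion_curve
from .repeats import find_perfect_irs
from .seqcore import CdsRecord, FrameError


def _rng_streams(seed: int, n: int) -> list:
    """Independent child generators derived from one top-level seed."""
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def shuffle_codons(cds: CdsRecord, rng: np.random.Generator | int) -> CdsRecord:
    """Uniformly random permutation of the codon sequence of one CDS."""
    if len(cds.seq) % 3:
        raise FrameError("CDS length not divisible by 3")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    codons = np.array(cds.codons)
    rng.shuffle(codons)
    return CdsRecord(
        species=cds.species, gene=cds.gene, seq="".join(codons), genome_coords=cds.genome_coords
    )


def shuffle_nucleotides(cds: CdsRecord, rng: np.random.Generator | int) -> CdsRecord:
    """Uniformly random permutation of the bases of one CDS."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    bases = np.array(list(cds.seq))
    rng.shuffle(bases)
    return CdsRecord(
        species=cds.species, gene=cds.gene, seq="".join(bases), genome_coords=cds.genome_coords
    )


_SHUFFLERS = {"codon": shuffle_codons, "nucleotide": shuffle_nucleotides}


@dataclass
class NullEnsemble:
    """Per-replicate repeat counts by minimal arm length under shuffling."""

    mode: str
    n_replicates: int
    seed: int
    min_lengths: list
    counts: np.ndarray  # shape (n_replicates, len(min_lengths))

    def __post_init__(self) -> None:
        if self.counts.shape != (self.n_replicates, len(self.min_lengths)):
            raise ValueError("counts shape inconsistent with replicates / lengths")

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sd_counts(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1) if self.n_replicates > 1 else np.zeros(len(self.min_lengths))


def _pooled_counts(cds_set: list, min_lengths: list, max_loop=None) -> np.ndarray:
    """Perfect-repeat counts pooled over a CDS set, per minimal arm length."""
    lo = min(min_lengths)
    arm_lens = []
    for cds in cds_set:
        arm_lens.extend(
            r.arm_len for r in find_perfect_irs(cds.seq, min_arm=max(2, lo), max_loop=max_loop)
        )
    arm_lens = np.array(arm_lens or [0])
    return np.array([(arm_lens >= m).sum() for m in min_lengths])


def expected_counts(
    cds_set: list,
    mode: str = "codon",
    n_replicates: int = 10,
    min_lengths=range(5, 31, 5),
    seed: int = 0,
    max_loop: int | None = None,
) -> tuple:
    """Observed versus shuffled-null repeat counts and over-representation ratios.

    Returns ``(ensemble, observed, ratios)``: the null ensemble, the observed
    pooled counts at each minimal arm length, and observed/mean-null ratios
    (None where the null mean is zero).  Detection parameters are identical
    for observed and shuffled material.
    """
    shuffler = _SHUFFLERS[mode]
    min_lengths = list(min_lengths)
    observed = _pooled_counts(cds_set, min_lengths, max_loop=max_loop)
    streams = _rng_streams(seed, n_replicates)
    counts = np.zeros((n_replicates, len(min_lengths)), dtype=int)
    for r, rng in enumerate(streams):
        shuffled = [shuffler(cds, rng) for cds in cds_set]
        counts[r] = _pooled_counts(shuffled, min_lengths, max_loop=max_loop)
    ens = NullEnsemble(
        mode=mode, n_replicates=n_replicates, seed=seed, min_lengths=min_lengths, counts=counts
    )
    means = ens.mean_counts
    ratios = [
        float(o) / m if m > 0 else None for o, m in zip(observed, means)
    ]
    return ens, observed, ratios


def null_phase_proportions(
    cds_set: list,
    mode: str = "codon",
    thresholds=range(5, 51),
    seed: int = 0,
    min_arm: int = 5,
) -> PhaseCurve:
    """Phase-proportion curve on one shuffled replicate of the CDS set."""
    shuffler = _SHUFFLERS[mode]
    rng = np.random.default_rng(seed)
    phased = []
    for cds in cds_set:
        shuffled = shuffler(cds, rng)
        reps = find_perfect_irs(shuffled.seq, min_arm=min_arm)
        phased.extend(classify_repeats(shuffled, reps))
    return phase_proportion_curve(phased, thresholds=thresholds)
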
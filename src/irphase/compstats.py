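"""Codon-usage uniformity and amino-acid composition statistics per region.

Repeat regions of each phase are compared against the non-repeat remainder of
the coding sequences: Wright's effective number of codons (Nc) measures how
uniform the synonymous codon usage is within a region, and a per-amino-acid
Fisher exact test with Bonferroni correction flags compositional shifts.
A central-moving-average smoother is included for plotting externally
supplied per-site conservation profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .phases import phase_region_mask
from .seqcore import CodonUsage, GeneticCode, STOP_SYMBOL

REGIONS = ("phase-1", "phase-2", "phase-3", "non-repeat")


@dataclass
class RegionUsage:
    region: str
    codon_counts: CodonUsage

    @property
    def aa_counts(self) -> dict:
        code = self.codon_counts.code
        out: Counter = Counter()
        for codon, n in self.codon_counts.counts.items():
            aa = code.codon_to_aa[codon]
            if aa != STOP_SYMBOL:
                out[aa] += n
        return dict(out)


def region_usage(scan: dict, code: GeneticCode) -> dict:
    """Pool codon counts by repeat-phase region across a scanned CDS set.

    ``scan`` is {CdsRecord: list of PhasedRepeat} as returned by
    ``phases.scan_cds_set``; codons are assigned to regions by
    ``phase_region_mask`` (both arms of a repeat contribute to its region).
    """
    counts = {region: Counter() for region in REGIONS}
    for cds, phased in scan.items():
        mask = phase_region_mask(cds, phased)
        for k, codon in enumerate(cds.codons):
            if codon in code.stop_codons:
                continue
            region = REGIONS[mask[k] - 1] if mask[k] else "non-repeat"
            counts[region][codon] += 1
    return {
        region: RegionUsage(region=region, codon_counts=CodonUsage(counts=dict(c), code=code))
        for region, c in counts.items()
    }


def effective_number_of_codons(usage: CodonUsage, code: GeneticCode | None = None) -> float | None:
    """Wright's effective number of codons (Nc).

    Per synonymous family the codon homozygosity is estimated as
    F̂ = (n·Σp̂ᵢ² − 1)/(n − 1); F̂ values are averaged within degeneracy
    classes and Nc = Σ_classes N_class / F̄_class, with single-codon families
    contributing F = 1.  A class with no estimable family is imputed by the
    mean of the neighbouring class means (Wright's convention for the 3-fold
    class); if no imputation is possible Nc is undefined (None).  Small
    samples can push F̂ below 1/family-size, so Nc above the sense-codon count
    is possible and reported as computed.
    """
    code = code or usage.code
    class_f: dict = {}
    class_n: dict = {}
    for size, aas in code.degeneracy_classes.items():
        class_n[size] = len(aas)
        if size == 1:
            class_f[size] = 1.0
            continue
        fs = []
        for aa in aas:
            fam = code.family(aa)
            counts = np.array([usage.counts.get(c, 0) for c in fam], dtype=float)
            n = counts.sum()
            if n < 2:
                continue
            p = counts / n
            f_hat = (n * (p**2).sum() - 1) / (n - 1)
            if f_hat > 0:
                fs.append(f_hat)
        if fs:
            class_f[size] = float(np.mean(fs))
    sizes = sorted(class_n)
    for size in sizes:
        if size in class_f:
            continue
        neighbours = [class_f[s] for s in (size - 1, size + 1) if s in class_f] or [
            class_f[s] for s in sizes if s in class_f and s > 1
        ]
        if not neighbours:
            return None
        class_f[size] = float(np.mean(neighbours))
    return float(sum(class_n[s] / class_f[s] for s in sizes))


def composition_compare(
    region: dict,
    background: dict,
    alpha: float = 0.05,
    n_tests: int = 20,
) -> pd.DataFrame:
    """Per-amino-acid enrichment of a region against a background.

    For each amino acid a 2×2 table (this amino acid vs all others, region vs
    background) is tested with a two-sided Fisher exact test (p = sum of the
    probabilities of all tables, under fixed margins, no more probable than
    the observed one).  Significance is Bonferroni-corrected:
    p < alpha / n_tests, i.e. 0.05/20 = 0.0025 by default.

    ``region`` and ``background`` are amino-acid count mappings (e.g.
    ``RegionUsage.aa_counts``).
    """
    tot_r = sum(region.values())
    tot_b = sum(background.values())
    if tot_r == 0 or tot_b == 0:
        raise ValueError("empty amino-acid counts")
    rows = []
    for aa in sorted(set(region) | set(background)):
        a = region.get(aa, 0)
        b = background.get(aa, 0)
        table = [[a, tot_r - a], [b, tot_b - b]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "aa": aa,
                "region_count": a,
                "background_count": b,
                "region_freq": a / tot_r,
                "background_freq": b / tot_b,
                "odds_ratio": odds,
                "p_value": p,
                "significant": p < alpha / n_tests,
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def smooth_profile(values, window: int = 5) -> np.ndarray:
    """Central moving average with symmetric edge shrinkage.

    At positions closer than window//2 to either end, the half-window shrinks
    symmetrically to the available sites, so a constant series is unchanged
    everywhere including the edges.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    half = window // 2
    n = values.size
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out
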
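"""Detection of inverted repeats within a single DNA sequence.

Two detectors are provided.  ``find_perfect_irs`` enumerates *maximal perfect*
inverted repeats: arm pairs that are exact reverse complements of each other
and that can be extended neither outward (away from the loop) nor inward
(shrinking the loop) without breaking complementarity or making the arms
overlap.  ``find_scored_irs`` is a local-alignment detector for imperfect
repeats: the sequence is aligned against its own reverse complement under a
match/mismatch/gap scoring scheme with a reporting threshold, so decayed
stems with mismatches or indels are still found.

Coordinates are 0-based half-open throughout.  "Repeat length" always means
arm length; the full palindromic span of a loopless repeat is twice that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import AlphabetError

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
# complementary bases sum to 3 under A=0, C=1, G=2, T=3


def _encode(seq: str) -> np.ndarray:
    x = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (x < 0).any():
        raise AlphabetError("non-ACGT characters in sequence")
    return x


@dataclass(frozen=True)
class InvertedRepeat:
    """One inverted repeat: a 5' arm, a 3' arm and the loop between them."""

    seq_id: str
    arm5: tuple  # (start, end), 0-based half-open
    arm3: tuple
    arm_len: int
    loop_len: int
    n_match: int
    score: int | None = None  # scored detector only

    def __post_init__(self) -> None:
        if self.arm5[1] > self.arm3[0]:
            raise ValueError("arms overlap")

    @property
    def midpoint(self) -> float:
        """Center of the loop; half-integral when the enclosed span is odd."""
        return (self.arm5[1] + self.arm3[0]) / 2

    @property
    def span(self) -> tuple:
        return (self.arm5[0], self.arm3[1])

    def arm_sequences(self, seq: str) -> tuple:
        return seq[slice(*self.arm5)], seq[slice(*self.arm3)]


def find_perfect_irs(
    seq: str,
    min_arm: int = 2,
    max_loop: int | None = None,
    seq_id: str = "",
) -> list:
    """All maximal perfect inverted repeats with arm length >= ``min_arm``.

    Every base pair (i, j) of an inverted repeat satisfies i + j = const, so
    repeats live on anti-diagonals of the self-complementarity matrix; maximal
    runs of complementary pairs along one anti-diagonal are exactly the
    maximal repeats.  Nested and overlapping repeats are all reported (they
    sit on different anti-diagonals); each arm pair is reported once, sorted
    by (arm5 start, arm length descending).
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    x = _encode(seq)
    n = len(x)
    out = []
    for c in range(1, 2 * n - 2):  # c = i + j over pairs with 0 <= i < j < n
        i_min = max(0, c - n + 1)
        i_max = (c - 1) // 2
        if i_max - i_min + 1 < min_arm:
            continue
        idx = np.arange(i_min, i_max + 1)
        m = x[idx] + x[c - idx] == 3
        edges = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            arm = int(e - s)
            if arm < min_arm:
                continue
            lo = i_min + int(s)
            hi = i_min + int(e) - 1
            loop = c - 2 * hi - 1
            if max_loop is not None and loop > max_loop:
                continue
            out.append(
                InvertedRepeat(
                    seq_id=seq_id,
                    arm5=(lo, hi + 1),
                    arm3=(c - hi, c - lo + 1),
                    arm_len=arm,
                    loop_len=loop,
                    n_match=arm,
                )
            )
    out.sort(key=lambda r: (r.arm5[0], -r.arm_len, r.arm3[0]))
    return out


def find_scored_irs(
    seq: str,
    match: int = 3,
    mismatch: int = -4,
    gap: int = -12,
    threshold: int = 15,
    max_extent: int | None = None,
    seq_id: str = "",
) -> list:
    """Imperfect inverted repeats by local alignment against the reverse complement.

    A Smith–Waterman-style dynamic program aligns the sequence with its own
    reverse complement, restricted to cells whose paired positions do not
    overlap (the 5' partner must precede the 3' partner).  Locally optimal
    stems with score >= ``threshold`` are traced back in descending score
    order; a stem whose arms touch positions already claimed by a
    higher-scoring stem is dropped, so reported stems are non-overlapping.
    ``n_match`` counts matched columns (for length-versus-identity scatters).

    ``max_extent`` optionally bounds the distance between paired positions
    (i.e. the maximal hairpin span).
    """
    if gap > 0 or mismatch > 0 or match <= 0:
        raise ValueError("expected match > 0 and mismatch, gap <= 0")
    x = _encode(seq)
    n = len(x)
    if n < 2:
        return []
    rc = 3 - x[::-1]  # encoded reverse complement
    g = -gap
    jidx = np.arange(1, n + 1)
    decay = g * jidx
    H = np.zeros((n + 1, n + 1), dtype=np.int64)
    for i in range(1, n + 1):
        prev = H[i - 1]
        sub = np.where(rc[: n] == x[i - 1], match, mismatch)
        cand = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        np.maximum(cand, 0, out=cand)
        # left-gap closure: H[i,j] = max_{k<=j} cand[k] - g*(j-k)
        row = np.maximum.accumulate(cand + decay) - decay
        # forbid arm overlap: cell (i, j) pairs positions i-1 and n-j
        cut = n - i
        if cut < n:
            row[cut:] = 0
        if max_extent is not None:
            far = (n - jidx) - (i - 1) > max_extent
            row[far] = 0
        H[i, 1:] = row

    cells = np.argwhere(H >= threshold)
    if cells.size == 0:
        return []
    order = np.argsort(-H[cells[:, 0], cells[:, 1]], kind="stable")
    used = np.zeros(n, dtype=bool)
    out = []
    for i0, j0 in cells[order]:
        rep = _traceback(H, x, rc, int(i0), int(j0), match, mismatch, gap, n, seq_id)
        if rep is None:
            continue
        pos = np.concatenate(
            [np.arange(*rep.arm5), np.arange(*rep.arm3)]
        )
        if used[pos].any():
            continue
        used[pos] = True
        out.append(rep)
    out.sort(key=lambda r: (r.arm5[0], -r.arm_len))
    return out


def _traceback(H, x, rc, i, j, match, mismatch, gap, n, seq_id):
    score = int(H[i, j])
    n_match = 0
    i_end, j_end = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = match if rc[j - 1] == x[i - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            if sub == match:
                n_match += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        elif H[i, j] == H[i, j - 1] + gap:
            j -= 1
        else:
            break
    if i == i_end or j == j_end:
        return None
    arm5 = (i, i_end)  # s positions i .. i_end-1
    arm3 = (n - j_end, n - j)  # rc columns map to original position n - j
    if arm5[1] > arm3[0]:
        return None
    return InvertedRepeat(
        seq_id=seq_id,
        arm5=arm5,
        arm3=arm3,
        arm_len=arm5[1] - arm5[0],
        loop_len=arm3[0] - arm5[1],
        n_match=n_match,
        score=score,
    )


def repeat_at_content(rep: InvertedRepeat, seq: str) -> float:
    """A+T fraction over both arms of one repeat, in percent."""
    a5, a3 = rep.arm_sequences(seq)
    both = a5 + a3
    return 100.0 * sum(b in "AT" for b in both) / len(both)


def repeat_summary(repeats: list, seqs: dict | str | None = None) -> dict:
    """Census of a repeat list: count, arm-length and loop-length means/maxima.

    ``seqs`` maps seq_id to sequence (or is a single sequence for single-input
    scans) and enables per-repeat AT content.  Means are reported to one
    decimal; on an empty list the means are None.
    """
    if not repeats:
        return {
            "count": 0,
            "mean_arm_len": None,
            "max_arm_len": None,
            "mean_loop_len": None,
            "mean_at_content": None,
            "at_content": [],
        }
    arms = [r.arm_len for r in repeats]
    loops = [r.loop_len for r in repeats]
    summary = {
        "count": len(repeats),
        "mean_arm_len": round(float(np.mean(arms)), 1),
        "max_arm_len": int(max(arms)),
        "mean_loop_len": round(float(np.mean(loops)), 1),
        "mean_at_content": None,
        "at_content": [],
    }
    if seqs is not None:
        getter = (lambda r: seqs) if isinstance(seqs, str) else (lambda r: seqs[r.seq_id])
        at = [repeat_at_content(r, getter(r)) for r in repeats]
        summary["at_content"] = at
        summary["mean_at_content"] = round(float(np.mean(at)), 1)
    return summary
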
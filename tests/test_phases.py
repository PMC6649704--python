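"""Phase classification, phase-resolved censuses and cross-species midpoints."""

import numpy as np
import pytest

from irphase import (
    CdsRecord,
    classify_phase,
    classify_repeats,
    embed_repeat,
    find_perfect_irs,
    phase_census,
    phase_proportion_curve,
    phase_region_mask,
    shared_midpoints,
)
from irphase.phases import PHASE_PAIRINGS, PhaseError, PhasedRepeat
from irphase.repeats import InvertedRepeat
from irphase.synthetic_data import at_rich_usage, generate_cds


def _codon_pos(i: int) -> int:
    return i % 3 + 1


def pairing_positions(rep: InvertedRepeat):
    """Exhaustive per-base pairing: base k of arm5 pairs the mirrored base of arm3."""
    for k in range(rep.arm_len):
        i = rep.arm5[0] + k
        j = rep.arm3[1] - 1 - k
        yield _codon_pos(i), _codon_pos(j)


class TestClassifyPhase:
    def test_worked_example_phase2(self):
        cds = CdsRecord("sp", "g", "ATGAAATTTCAT")
        rep = InvertedRepeat("sp|g", (3, 6), (6, 9), 3, 0, 3)
        assert classify_phase(rep, cds) == 2

    def test_phases_cycle_under_unit_shifts(self):
        # the same AAA/TTT stem moved +1 and +2 nt downstream
        for shift, expected in ((0, 2), (1, 3), (2, 1)):
            seq = "ATG" + "G" * shift + "AAATTT" + "G" * ((3 - shift) % 3) + "CAT"
            cds = CdsRecord("sp", "g", seq)
            rep = InvertedRepeat("sp|g", (3 + shift, 6 + shift), (6 + shift, 9 + shift), 3, 0, 3)
            assert classify_phase(rep, cds) == expected

    def test_every_base_pair_lies_in_the_phase_pairing_set(self, table5, usage_at):
        rng = np.random.default_rng(77)
        for phase in (1, 2, 3):
            for arm, loop in ((6, 0), (9, 7), (21, 30), (30, 50)):
                host = generate_cds(60, usage_at, table5, rng)
                cds, rep = embed_repeat(
                    host, arm_len=arm, loop_len=loop, phase=phase, rng=rng, code=table5
                )
                assert classify_phase(rep, cds) == phase
                assert set(pairing_positions(rep)) <= PHASE_PAIRINGS[phase]

    def test_arm_outside_cds_raises(self):
        cds = CdsRecord("sp", "g", "ATGAAATTT")
        rep = InvertedRepeat("sp|g", (3, 6), (6, 12), 3, 0, 3)
        with pytest.raises(PhaseError):
            classify_phase(rep, cds)

    def test_classify_repeats_drops_out_of_bounds(self, caplog):
        cds = CdsRecord("sp", "g", "ATGAAATTT")
        good = InvertedRepeat("sp|g", (3, 6), (6, 9), 3, 0, 3)
        bad = InvertedRepeat("sp|g", (3, 6), (6, 12), 3, 0, 3)
        with caplog.at_level("WARNING"):
            out = classify_repeats(cds, [good, bad])
        assert len(out) == 1 and out[0].phase == 2


def _phased(phase, arm_len, cds=None):
    cds = cds or CdsRecord("s", "g", "ATG" * 200)
    rep = InvertedRepeat("s|g", (0, arm_len), (arm_len, 2 * arm_len), arm_len, 0, arm_len)
    return PhasedRepeat(base=rep, phase=phase, cds=cds)


class TestCensusAndCurve:
    def test_census_arithmetic(self):
        phased = [_phased(1, 20), _phased(1, 31), _phased(1, 40)]
        census = phase_census(phased, arm_len_cutoffs=(30,))
        assert census[30][1] == {"count": 2, "cumulative_length": 71}
        assert census[30][2] == {"count": 0, "cumulative_length": 0}

    def test_census_strict_versus_inclusive(self):
        phased = [_phased(2, 30)]
        assert phase_census(phased, (30,))[30][2]["count"] == 0
        assert phase_census(phased, (30,), strict=False)[30][2]["count"] == 1

    def test_empty_input_gives_zeros(self):
        census = phase_census([], arm_len_cutoffs=(15, 30))
        assert all(
            census[c][p] == {"count": 0, "cumulative_length": 0}
            for c in (15, 30)
            for p in (1, 2, 3)
        )

    def test_census_totals_equal_classified_counts(self):
        rng = np.random.default_rng(3)
        phased = [_phased(int(rng.integers(1, 4)), int(rng.integers(5, 60))) for _ in range(50)]
        census = phase_census(phased, arm_len_cutoffs=(0,))
        assert sum(census[0][p]["count"] for p in (1, 2, 3)) == len(phased)

    def test_pure_phase1_set_has_unit_proportion(self):
        phased = [_phased(1, 30), _phased(1, 28)]
        curve = phase_proportion_curve(phased, thresholds=[25])
        assert curve.proportions[1] == [1.0]
        assert curve.proportions[2] == [0.0]

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        phased = [_phased(int(rng.integers(1, 4)), int(rng.integers(5, 80))) for _ in range(200)]
        curve = phase_proportion_curve(phased, thresholds=range(5, 60))
        assert all(a >= b for a, b in zip(curve.totals, curve.totals[1:]))

    def test_proportions_sum_to_one_where_counted(self):
        rng = np.random.default_rng(5)
        phased = [_phased(int(rng.integers(1, 4)), int(rng.integers(5, 40))) for _ in range(60)]
        curve = phase_proportion_curve(phased, thresholds=range(5, 30))
        for k, total in enumerate(curve.totals):
            if total:
                s = sum(curve.proportions[p][k] for p in (1, 2, 3))
                assert s == pytest.approx(1.0)


class TestRegionMask:
    def test_single_repeat_marks_its_codons(self):
        cds = CdsRecord("s", "g", "ATG" * 6)
        rep = InvertedRepeat("s|g", (3, 6), (6, 9), 3, 0, 3)
        mask = phase_region_mask(cds, [PhasedRepeat(rep, 2, cds)])
        assert mask.tolist() == [0, 2, 2, 0, 0, 0]

    def test_no_repeats_all_non_repeat(self):
        cds = CdsRecord("s", "g", "ATG" * 5)
        assert phase_region_mask(cds, []).tolist() == [0] * 5

    def test_longest_repeat_wins_overlap(self):
        cds = CdsRecord("s", "g", "ATG" * 40)
        long1 = PhasedRepeat(InvertedRepeat("s|g", (0, 30), (60, 90), 30, 30, 30), 1, cds)
        short3 = PhasedRepeat(InvertedRepeat("s|g", (24, 36), (40, 52), 12, 4, 12), 3, cds)
        mask = phase_region_mask(cds, [long1, short3])
        # codons 8-9 (bases 24-30) contested: the 30 bp phase-1 repeat wins
        assert mask[8] == 1 and mask[9] == 1
        assert mask[11] == 3  # bases 33-36, phase-3 only

    def test_phase_tie_goes_to_lower_phase(self):
        cds = CdsRecord("s", "g", "ATG" * 40)
        a = PhasedRepeat(InvertedRepeat("s|g", (0, 12), (24, 36), 12, 12, 12), 3, cds)
        b = PhasedRepeat(InvertedRepeat("s|g", (6, 18), (40, 52), 12, 22, 12), 2, cds)
        mask = phase_region_mask(cds, [a, b])
        assert mask[2] == 2  # contested codon 2 (bases 6-9): same arm_len, lower phase wins


def _aligned_set(n_species=4, arm=9, loop=6):
    rng = np.random.default_rng(10)
    from irphase.seqcore import GeneticCode

    code = GeneticCode.from_ncbi(5)
    usage = at_rich_usage(code)
    host = generate_cds(40, usage, code, rng, species="template", gene="nad1")
    cds, rep = embed_repeat(host, arm_len=arm, loop_len=loop, phase=1, rng=rng, code=code)
    species = [f"sp{i}" for i in range(1, n_species + 1)]
    alignments = {"nad1": {s: cds.seq for s in species}}
    phased_by_species = {}
    for s in species:
        rec = CdsRecord(s, "nad1", cds.seq)
        reps = find_perfect_irs(rec.seq, min_arm=arm)
        phased_by_species[s] = {"nad1": classify_repeats(rec, reps)}
    return alignments, phased_by_species


class TestSharedMidpoints:
    def test_identical_cds_share_one_group_of_four(self):
        alignments, phased = _aligned_set()
        groups = shared_midpoints(alignments, phased, tolerance=0)
        top = [g for g in groups["nad1"] if g["n_species"] == 4]
        assert len(top) >= 1

    def test_tolerance_threshold_semantics(self):
        cds_a = CdsRecord("a", "g", "ATGGAATTCTTT")  # GAA/TTC stem, midpoint 6.0
        cds_b = CdsRecord("b", "g", "ATGGGGAATTCT")  # same stem 2 nt later on a shifted row
        rep_a = classify_repeats(cds_a, find_perfect_irs(cds_a.seq, min_arm=3))
        rep_b = classify_repeats(cds_b, find_perfect_irs(cds_b.seq, min_arm=3))
        aln = {"g": {"a": cds_a.seq + "--", "b": cds_b.seq + "--"}}
        phased = {"a": {"g": rep_a}, "b": {"g": rep_b}}
        wide = shared_midpoints(aln, phased, tolerance=3)["g"]
        narrow = shared_midpoints(aln, phased, tolerance=1)["g"]
        assert any(g["n_species"] == 2 for g in wide)
        assert all(g["n_species"] == 1 for g in narrow)

    def test_alignment_cds_mismatch_raises(self):
        alignments, phased = _aligned_set()
        alignments["nad1"]["sp1"] = alignments["nad1"]["sp1"][:-3] + "GGG"
        with pytest.raises(ValueError, match="sp1"):
            shared_midpoints(alignments, phased)
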
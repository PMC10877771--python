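"""CCF engine: the copy-number correction, filters, QC and purity refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonetracer as ct
from clonetracer.ccf import refine_purity, segment_qc, impute_cn_profile
from clonetracer.types import CnState, Segment, SegmentProfile


def _seg(n_major, n_minor, chrom="1", start=1, end=10**8, frac=1.0,
         state2=None):
    return Segment(chrom, start, end, CnState(n_major, n_minor, frac),
                   state2)


class TestFilterTlod:
    def test_inclusive_at_threshold(self):
        def rec(score):
            return ct.SnvRecord("1", 100, "A", "G", (5,), (10,), score)
        kept = ct.filter_tlod([rec(6.99), rec(7.00), rec(7.01)])
        assert [r.somatic_score for r in kept] == [7.00, 7.01]

    def test_zero_threshold_keeps_all(self):
        recs = [ct.SnvRecord("1", i + 1, "A", "G", (1,), (2,), 0.5)
                for i in range(5)]
        cfg = ct.AnalysisConfig(tlod_min=0.0)
        assert len(ct.filter_tlod(recs, cfg)) == 5

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 14, size=100)
        recs = [ct.SnvRecord("1", i + 1, "A", "G", (1,), (2,), float(s))
                for i, s in enumerate(scores)]
        kept = ct.filter_tlod(recs)
        assert len(kept) == sum(1 for s in scores if s >= 7.0)


class TestComputeCcf:
    @pytest.mark.parametrize("alt,total,seg,purity,exp_m,exp_ccf", [
        # fully clonal diploid pure tumour
        (50, 100, _seg(1, 1), 1.0, 1, 1.0),
        # half purity, diploid: m_hat = 0.25*2/0.5 = 1
        (25, 100, _seg(1, 1), 0.5, 1, 1.0),
        # n_t=3 (2+1), rho=0.8: denom=2.8, m_hat=2.1 -> m=2, CCF=1.05
        (60, 100, _seg(2, 1), 0.8, 2, 1.05),
    ])
    def test_hand_worked_examples(self, alt, total, seg, purity,
                                  exp_m, exp_ccf):
        ccf, m, flagged = ct.compute_ccf(alt, total, seg, purity)
        assert m == exp_m
        assert ccf == pytest.approx(exp_ccf)
        assert not flagged  # all examples below the 1.2 ceiling

    def test_flag_above_ceiling_value_retained(self):
        ccf, m, flagged = ct.compute_ccf(90, 100, _seg(1, 1), 0.9)
        assert flagged and ccf > 1.2

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            ct.compute_ccf(0, 0, _seg(1, 1), 0.5)

    @given(alt=st.integers(0, 50), total=st.integers(1, 50),
           scale=st.integers(2, 10))
    @settings(max_examples=50, deadline=None)
    def test_scale_consistency(self, alt, total, scale):
        """Doubling both alt and total reads leaves the CCF unchanged."""
        alt = min(alt, total)
        a = ct.compute_ccf(alt, total, _seg(2, 1), 0.6)
        b = ct.compute_ccf(alt * scale, total * scale, _seg(2, 1), 0.6)
        assert a[0] == pytest.approx(b[0])
        assert a[1] == b[1]

    def test_multiplicity_capped_by_major_cn(self):
        # VAF implies m ~ 3 but n_major = 2
        _, m, _ = ct.compute_ccf(95, 100, _seg(2, 2), 1.0)
        assert m == 2


class TestComputeCcfMatrix:
    def test_uncovered_locus_marked_unusable(self):
        recs = [ct.SnvRecord("1", 100, "A", "G", (5, 5), (10, 10), 9.0),
                ct.SnvRecord("2", 100, "A", "G", (5, 5), (10, 10), 9.0)]
        prof1 = SegmentProfile("S1", [_seg(1, 1, chrom="1")])
        prof2 = SegmentProfile("S2", [_seg(1, 1, chrom="1"),
                                      _seg(1, 1, chrom="2")])
        mat = ct.compute_ccf_matrix(recs, ["S1", "S2"],
                                    {"S1": prof1, "S2": prof2},
                                    {"S1": 0.5, "S2": 0.5})
        assert mat.usable.tolist() == [True, False]
        assert len(mat.loci) == 2  # kept, not dropped

    def test_zero_depth_marks_unusable(self):
        recs = [ct.SnvRecord("1", 100, "A", "G", (0, 5), (0, 10), 9.0)]
        prof = SegmentProfile("S", [_seg(1, 1)])
        mat = ct.compute_ccf_matrix(recs, ["S1", "S2"],
                                    {"S1": prof, "S2": prof},
                                    {"S1": 0.5, "S2": 0.5})
        assert not mat.usable[0]

    def test_rmse_decreases_with_depth(self):
        """Per-clone mean CCF error shrinks as depth grows (30/100/300)."""
        rmses = []
        for depth in (30, 100, 300):
            truth, records, profiles, purities = ct.simulate_cohort(
                K=4, S=2, n_snv_per_clone=150, depth=depth, purity=0.7,
                seed=21)
            rho = {p.sample_id: p.purity for p in purities}
            mat = ct.compute_ccf_matrix(records, truth.samples, profiles,
                                        rho)
            ids = {l: i for i, l in enumerate(mat.loci)}
            errs = []
            for clone in range(truth.n_clones):
                rows = [ids[r.locus_id] for r, c in
                        zip(records, truth.snv_assignment) if c == clone]
                mean = np.nanmean(mat.ccf[rows, :], axis=0)
                errs.append(mean - truth.ccf_true[:, clone])
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]


def _truncal_records(n, alt, total, samples=1, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(ct.SnvRecord(
            "1", 1000 + i, "A", "G",
            tuple([alt] * samples), tuple([total] * samples), 9.0))
    return out


class TestRefinePurity:
    def test_already_calibrated_unchanged(self):
        # diploid, m=1, rho=0.5: CCF = 2f/rho = 1 at f = 0.25
        recs = _truncal_records(30, 25, 100)
        prof = SegmentProfile("S", [_seg(1, 1)])
        assert refine_purity(recs, 0, prof, 0.5) == pytest.approx(0.5)

    def test_diploid_closed_form(self):
        """Median CCF 0.8 at rho=0.5 on a diploid genome -> rho' = 0.4."""
        recs = _truncal_records(30, 20, 100)  # f=0.2 -> CCF=0.8 at rho=0.5
        prof = SegmentProfile("S", [_seg(1, 1)])
        assert refine_purity(recs, 0, prof, 0.5) == pytest.approx(0.4,
                                                                  abs=1e-4)

    def test_recovers_misspecified_purity(self):
        """rho_input = 1.25 * rho_true: root finding lands within 0.02."""
        truth, records, profiles, purities = ct.simulate_cohort(
            K=4, S=2, n_snv_per_clone=150, depth=100, purity=0.7, seed=31)
        truncal = [r for r, c in zip(records, truth.snv_assignment)
                   if c == 0]
        for j, s in enumerate(truth.samples):
            rho = refine_purity(truncal, j, profiles[s], 0.875)
            assert rho == pytest.approx(0.7, abs=0.02)

    def test_idempotent(self):
        truth, records, profiles, purities = ct.simulate_cohort(
            K=3, S=2, n_snv_per_clone=100, depth=100, purity=0.6, seed=32)
        truncal = [r for r, c in zip(records, truth.snv_assignment)
                   if c == 0]
        r1 = refine_purity(truncal, 0, profiles["S1"], 0.75)
        r2 = refine_purity(truncal, 0, profiles["S1"], r1)
        assert abs(r2 - r1) < 1e-5

    def test_too_few_truncal_members_rejected(self):
        recs = _truncal_records(5, 25, 100)
        prof = SegmentProfile("S", [_seg(1, 1)])
        with pytest.raises(ValueError, match="truncal"):
            refine_purity(recs, 0, prof, 0.5)


class TestSegmentQc:
    def _setup(self, break_segment=False, n_truncal=150, seed=0):
        truth, records, profiles, purities = ct.simulate_cohort(
            K=3, S=2, n_snv_per_clone=n_truncal, depth=100, purity=0.7,
            seed=seed)
        truncal_ids = [r.locus_id for r, c in
                       zip(records, truth.snv_assignment) if c == 0]
        if break_segment:
            # miscall one populous diploid segment as 1+0: CCFs computed
            # against the lost copy come out far below the genome level
            for s in truth.samples:
                segs = list(profiles[s].segments)
                target = max(
                    range(len(segs)),
                    key=lambda i: sum(1 for r in records
                                      if segs[i].contains(r.chrom, r.pos)))
                old = segs[target]
                segs[target] = Segment(old.chrom, old.start, old.end,
                                       CnState(1, 0, 1.0))
                profiles[s] = SegmentProfile(s, segs)
        rho = {p.sample_id: p.purity for p in purities}
        mat = ct.compute_ccf_matrix(records, truth.samples, profiles, rho)
        return mat, records, profiles, truncal_ids

    def test_clean_profile_unflagged(self):
        mat, records, profiles, truncal = self._setup()
        assert segment_qc(mat, records, profiles, truncal) == []

    def test_doubled_cn_flagged_overcorrected(self):
        mat, records, profiles, truncal = self._setup(break_segment=True)
        flags = segment_qc(mat, records, profiles, truncal)
        assert flags and all(f.kind == "overcorrected" for f in flags)

    def test_insufficient_support_unflagged(self):
        mat, records, profiles, truncal = self._setup(break_segment=True)
        cfg = ct.AnalysisConfig(qc_min_support=10**6)
        assert segment_qc(mat, records, profiles, truncal, cfg) == []


class TestImputeCnProfile:
    def _prof(self, sid, states):
        segs = [_seg(nm, mn, chrom="1", start=a, end=b)
                for (a, b), (nm, mn) in states.items()]
        return SegmentProfile(sid, segs)

    def test_unanimous(self):
        donors = [self._prof(f"d{i}", {(1, 100): (1, 1)}) for i in range(3)]
        out = impute_cn_profile(donors, [0.5, 0.5, 0.5], "t")
        assert out.segments[0].state1 == CnState(1, 1, 1.0)

    def test_modal_state_wins(self):
        donors = [self._prof("d1", {(1, 100): (2, 1)}),
                  self._prof("d2", {(1, 100): (2, 1)}),
                  self._prof("d3", {(1, 100): (1, 1)})]
        out = impute_cn_profile(donors, [0.3, 0.3, 0.9], "t")
        assert (out.segments[0].state1.n_major,
                out.segments[0].state1.n_minor) == (2, 1)

    def test_tie_broken_by_purity(self):
        donors = [self._prof("d1", {(1, 100): (2, 1)}),
                  self._prof("d2", {(1, 100): (1, 1)})]
        out = impute_cn_profile(donors, [0.3, 0.7], "t")
        assert (out.segments[0].state1.n_major,
                out.segments[0].state1.n_minor) == (1, 1)

    def test_resegmented_to_union_of_breakpoints(self):
        donors = [self._prof("d1", {(1, 100): (1, 1)}),
                  self._prof("d2", {(1, 50): (2, 1), (51, 100): (1, 1)})]
        out = impute_cn_profile(donors, [0.4, 0.8], "t")
        # breakpoint at 50 splits the grid; ties fall to the purer donor,
        # so the halves end up with different states and stay split
        assert [(s.start, s.end) for s in out.segments] == [(1, 50),
                                                            (51, 100)]
        assert out.segments[0].state1.n_major == 2
        assert out.segments[1].state1.n_major == 1

    def test_adjacent_same_state_segments_merged_back(self):
        donors = [self._prof("d1", {(1, 100): (1, 1)}),
                  self._prof("d2", {(1, 50): (2, 1), (51, 100): (2, 2)})]
        out = impute_cn_profile(donors, [0.9, 0.3], "t")
        assert [(s.start, s.end) for s in out.segments] == [(1, 100)]

    def test_no_donors_rejected(self):
        with pytest.raises(ValueError):
            impute_cn_profile([self._prof("d", {(1, 10): (1, 1)})], [0.5],
                              "t")
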
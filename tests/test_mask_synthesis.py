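import numpy as np
import pytest

from histocurate import (
    SlideRecord,
    SynthesisParams,
    Window,
    WindowScore,
    accept,
    assemble_cohort,
    foreground_mask,
    make_engineered_slide,
    scan_windows,
    score_window,
    synthesize_slide,
)
from oracles import bf_accept, bf_counts, bf_windows

SMALL = SynthesisParams(window_edge=100, retain_k=20)  # 50-px scan windows


class TestForegroundMask:
    def test_uniform_white_image_is_all_background(self):
        img = np.full((60, 60, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            fg = foreground_mask(img, 2)
        assert not fg.any()

    def test_dark_disk_foreground_matches_disk_area(self):
        img = np.full((200, 200, 3), 250, dtype=np.uint8)
        yy, xx = np.ogrid[:200, :200]
        disk = (yy - 100) ** 2 + (xx - 100) ** 2 <= 60**2
        img[disk] = 90
        fg = foreground_mask(img, 2)
        disk_fraction = disk.mean()
        assert abs(fg.mean() - disk_fraction) < 0.1 * disk_fraction

    def test_output_shape_is_ceil_of_half(self):
        img = np.zeros((101, 99, 3), dtype=np.uint8)
        img[0, 0] = 255
        assert foreground_mask(img, 2).shape == (51, 50)


class TestScanWindows:
    def test_exact_fit_gives_single_window(self):
        assert scan_windows((400, 400), 400, 0.5) == [Window(0, 0, 400, 400)]

    def test_wide_mask_strides_and_flushes(self):
        ws = scan_windows((400, 800), 400, 0.5)
        assert sorted({w.x0 for w in ws}) == [0, 200, 400]
        assert {w.y0 for w in ws} == {0}
        assert len(ws) == 3

    def test_mask_smaller_than_window_yields_nothing(self):
        assert scan_windows((399, 400), 400, 0.5) == []

    @pytest.mark.parametrize("shape,edge", [((57, 91), 20), ((64, 64), 16)])
    def test_more_overlap_never_loses_windows(self, shape, edge):
        counts = [len(scan_windows(shape, edge, p)) for p in (0.0, 0.3, 0.5, 0.7, 0.8, 0.9)]
        assert counts == sorted(counts)
        for ws in (scan_windows(shape, edge, p) for p in (0.5, 0.8)):
            for w in ws:
                assert w.x0 + w.width <= shape[1] and w.y0 + w.height <= shape[0]


class TestScoreAndAccept:
    def test_all_stroma_window_scores_zero(self):
        mask = np.ones((10, 10), dtype=np.uint8)
        s = score_window(mask, Window(0, 0, 10, 10), 3, SynthesisParams())
        assert (s.M, s.T, s.coverage, s.purity) == (0, 0, 0.0, 0.0)

    def test_half_target_window_counts(self):
        mask = np.ones((10, 10), dtype=np.uint8)
        mask[:5] = 3
        s = score_window(mask, Window(0, 0, 10, 10), 3, SynthesisParams())
        assert (s.N, s.M, s.T) == (100, 50, 50)
        assert s.coverage == 0.5 and s.purity == 1.0
        s_all = score_window(mask, Window(0, 0, 10, 10), 3, SynthesisParams(purity_denominator="all"))
        assert s_all.purity == 0.5

    def test_boundary_coverage_and_purity_are_accepted_inclusively(self):
        # N=400, M=40 -> coverage exactly 0.1; T=38 -> purity exactly 0.95
        s = WindowScore(N=400, M=40, T=38)
        assert accept(s, SynthesisParams())
        assert not accept(WindowScore(N=400, M=36, T=36), SynthesisParams())  # coverage 0.09

    def test_matches_bruteforce_on_random_mask(self):
        rng = np.random.default_rng(77)
        mask = rng.integers(0, 6, size=(40, 40)).astype(np.uint8)
        params = SynthesisParams(window_edge=20, downsample_factor=2)  # scan edge 10
        for w in scan_windows(mask.shape, 10, 0.5):
            s = score_window(mask, w, 4, params)
            N, M, T = bf_counts(mask, w.y0, w.x0, 10, 4)
            assert (s.N, s.M, s.T) == (N, M, T)
            assert accept(s, params) == bf_accept(N, M, T, 0.1, 0.95, "epithelial")


class TestAcceptanceMonotonicity:
    def test_tightening_thresholds_never_accepts_more(self):
        rng = np.random.default_rng(5)
        mask = rng.integers(0, 6, size=(50, 50)).astype(np.uint8)
        windows = scan_windows(mask.shape, 10, 0.5)

        def n_accepted(p_alpha, p_beta):
            params = SynthesisParams(window_edge=20, p_alpha=p_alpha, p_beta=p_beta)
            return sum(accept(score_window(mask, w, 3, params), params) for w in windows)

        for lo, hi in [(0.05, 0.2), (0.2, 0.5)]:
            assert n_accepted(hi, 0.3) <= n_accepted(lo, 0.3)
            assert n_accepted(0.05, hi) <= n_accepted(0.05, lo)


class TestSynthesizeSlide:
    def test_engineered_slide_yields_retain_k_without_escalation(self):
        record, img, mask = make_engineered_slide("GS3", "s1", rng=0)
        res = synthesize_slide(record, img, mask, 3)
        assert not res.excluded
        assert len(res.patches) == 20
        assert res.p_omega_used == 0.5
        coverages = [p.coverage for p in res.patches]
        assert coverages == sorted(coverages, reverse=True)

    def test_all_stroma_slide_is_excluded(self):
        record = SlideRecord("s2", "cohortA", "3+3")
        img = np.full((400, 400, 3), 240, dtype=np.uint8)
        img[50:350, 50:350] = 200
        mask = np.ones((400, 400), dtype=np.uint8)
        res = synthesize_slide(record, img, mask, 3, SMALL)
        assert res.excluded and "s2" in res.reason

    def test_misaligned_mask_shape_raises(self):
        record, img, mask = make_engineered_slide("GS3", "s3", rng=1)
        with pytest.raises(ValueError, match="mask shape"):
            synthesize_slide(record, img, mask[:-7], 3)

    def test_downsampled_mask_is_accepted_directly(self):
        record, img, mask = make_engineered_slide("GS3", "s4", rng=2)
        res_full = synthesize_slide(record, img, mask, 3)
        res_down = synthesize_slide(record, img, mask[::2, ::2], 3)
        assert [p.window for p in res_down.patches] == [p.window for p in res_full.patches]


class TestAssembleCohort:
    def _slides(self, grades, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        from histocurate.fixtures import _DIAGNOSIS_FOR_CLASS

        for i, g in enumerate(grades):
            yield make_engineered_slide(g, f"{g}-{i}", diagnosis=_DIAGNOSIS_FOR_CLASS[g], rng=rng)

    def test_gs3_slide_contributes_only_gs3(self):
        cohort = assemble_cohort(self._slides(["GS3"]))
        assert {p.target_code for p in cohort.patches} == {3}
        assert cohort.counts.loc["patches", "GS3"] == 20
        assert cohort.counts.loc["patches", "benign"] == 0

    def test_small_multiclass_cohort_bookkeeping(self):
        grades = ["benign", "benign", "GS3", "GS3", "GS4", "GS4", "GS5", "GS5"]
        cohort = assemble_cohort(self._slides(grades))
        assert cohort.counts.loc["patches", "total"] == 8 * 20
        assert (cohort.counts.loc["patches", ["benign", "GS3", "GS4", "GS5"]] == 40).all()

    def test_ineligible_diagnosis_is_skipped(self):
        record, img, mask = make_engineered_slide("GS3", "odd", diagnosis="other", rng=3)
        cohort = assemble_cohort([(record, img, mask)])
        assert cohort.patches == [] and cohort.ineligible == ["odd"]

    def test_missing_class_raises_when_required(self):
        with pytest.raises(ValueError, match="no eligible"):
            assemble_cohort(self._slides(["GS3"]), require_all_classes=True)


def test_scan_windows_agree_with_bruteforce_enumeration():
    rng = np.random.default_rng(9)
    for _ in range(25):
        shape = tuple(rng.integers(20, 61, size=2))
        edge = int(rng.integers(8, 20))
        p = float(rng.choice([0.0, 0.3, 0.5, 0.6, 0.8]))
        got = [(w.y0, w.x0) for w in scan_windows(shape, edge, p)]
        assert got == bf_windows(shape, edge, p)
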
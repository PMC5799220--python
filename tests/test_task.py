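"""HRF, ideal responses and FAUPA-task association."""

import numpy as np
import pytest

from faupa.core_stats import pearson_r
from faupa.errors import ParameterError
from faupa.task import (HrfParams, TaskParadigm, associate, default_paradigm,
                        group_mean_course, hrf, ideal_response,
                        load_bundled_paradigm)

RNG = np.random.default_rng(31)


class TestHrf:
    def test_peak_near_five_seconds_and_normalised(self):
        params = HrfParams()
        k = hrf(params)
        t_peak = np.argmax(k) * params.dt
        assert 4.0 <= t_peak <= 6.0
        assert k.max() == pytest.approx(1.0)

    def test_zero_at_onset(self):
        assert hrf(HrfParams())[0] == pytest.approx(0.0, abs=1e-12)

    def test_undershoot_present(self):
        k = hrf(HrfParams())
        assert k.min() < -0.01


class TestIdealResponse:
    def _single_trial(self):
        return TaskParadigm(trials=((0.0, 6.0, "FT"),), tr=2.5, n_timepoints=24)

    def test_single_trial_peak_window_and_decay(self):
        ideal = ideal_response(self._single_trial(), "FT")
        resp = ideal.course - 1.0
        t = np.arange(24) * 2.5
        t_peak = t[np.argmax(resp)]
        assert 5.0 <= t_peak <= 11.0
        late = resp[t >= 24.0]
        assert np.all(np.abs(late) < 0.1 * resp.max())

    def test_relative_course_zero_mean(self):
        ideal = ideal_response(self._single_trial(), "FT")
        assert abs(ideal.relative_course.mean()) < 1e-12

    def test_empty_condition_gives_zero_series(self):
        par = TaskParadigm(trials=(), tr=2.5, n_timepoints=24,
                           conditions=frozenset({"FT"}))
        ideal = ideal_response(par, "FT")
        assert np.allclose(ideal.relative_course, 0.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ParameterError):
            ideal_response(self._single_trial(), "PV")

    def test_amplitude_scaling_is_irrelevant_after_relative_conversion(self):
        # the published ideal course was "scaled by a factor of 2"; relative
        # conversion and correlation are invariant to that
        par = default_paradigm()
        a = ideal_response(par, "FT")
        doubled = 1.0 + 2.0 * (a.course - 1.0)
        rel = (doubled - doubled.mean()) / doubled.mean()
        assert pearson_r(rel, a.relative_course) == 1.0

    def test_matches_direct_convolution_oracle(self):
        par = self._single_trial()
        p = HrfParams()
        ideal = ideal_response(par, "FT")
        # independent oracle: trapezoid-free direct sum on the fine grid
        n_fine = int(round(24 * 2.5 / p.dt))
        tgrid = np.arange(n_fine) * p.dt
        box = ((tgrid >= 0) & (tgrid < 6.0)).astype(float)
        k = hrf(p)
        ref = np.zeros(n_fine)
        for i in range(n_fine):
            for j in range(max(0, i - k.size + 1), i + 1):
                ref[i] += box[j] * k[i - j] * p.dt
        sample = np.round(np.arange(24) * 2.5 / p.dt).astype(int)
        assert np.allclose(ideal.course, 1.0 + ref[sample], atol=1e-10)


class TestParadigm:
    def test_bundled_paradigm_matches_constructor(self):
        bundled = load_bundled_paradigm()
        built = default_paradigm()
        assert bundled.trials == built.trials
        assert bundled.conditions == {"WR", "PV", "FT"}
        labels = [t[2] for t in bundled.trials]
        assert len(bundled.trials) == 24
        assert all(labels.count(c) == 8 for c in ("WR", "PV", "FT"))
        last = bundled.trials[-1]
        assert last[0] + last[1] <= 2.5 * 288

    def test_tsv_round_trip(self, tmp_path):
        par = default_paradigm()
        par.to_tsv(tmp_path / "p.tsv")
        back = TaskParadigm.from_tsv(tmp_path / "p.tsv", tr=2.5, n_timepoints=288)
        assert back.trials == par.trials

    @pytest.mark.parametrize("trials", [
        ((-1.0, 6.0, "FT"),),                      # negative onset
        ((0.0, 6.0, "FT"), (0.0, 6.0, "PV")),      # not strictly increasing
        ((700.0, 30.0, "FT"),),                    # exceeds scan
    ])
    def test_invalid_timing_rejected(self, trials):
        with pytest.raises(ParameterError):
            TaskParadigm(trials=trials, tr=2.5, n_timepoints=288)


class TestAssociate:
    def test_self_association_is_perfect(self):
        ideal = ideal_response(default_paradigm(), "FT")
        r, p = associate(ideal.relative_course, ideal)
        assert r == 1.0 and p < 1e-300

    def test_task_locked_course_associates_strongly(self):
        ideal = ideal_response(default_paradigm(), "FT")
        sig = ideal.relative_course / ideal.relative_course.std()
        hits = 0
        for seed in range(40):
            noisy = sig + np.random.default_rng(seed).standard_normal(sig.size)
            r, _ = associate(noisy, ideal)
            hits += r > 0.5
        assert hits >= 38   # >= 95% at SNR 1

    def test_white_noise_does_not_associate(self):
        ideal = ideal_response(default_paradigm(), "FT")
        small = 0
        for seed in range(40):
            r, _ = associate(np.random.default_rng(100 + seed)
                             .standard_normal(288), ideal)
            small += abs(r) < 0.2
        assert small >= 38

    def test_affine_invariance(self):
        ideal = ideal_response(default_paradigm(), "FT")
        x = RNG.standard_normal(288) + ideal.relative_course
        r1, _ = associate(x, ideal)
        r2, _ = associate(3.0 * x - 7.0, ideal)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_group_averaging_improves_association(self):
        # averaging K task-locked noisy courses raises r with the ideal
        ideal = ideal_response(default_paradigm(), "FT")
        sig = ideal.relative_course / ideal.relative_course.std()
        rng = np.random.default_rng(77)
        courses = sig + rng.standard_normal((9, sig.size))
        r1 = np.mean([associate(c, ideal)[0] for c in courses])
        group, _sd = group_mean_course(list(courses))
        r9, _ = associate(group, ideal)
        assert r9 > r1


class TestGroupMeanCourse:
    def test_single_course_is_itself_with_zero_sd(self):
        x = RNG.standard_normal(50)
        mean, sd = group_mean_course([x])
        assert np.array_equal(mean, x)
        assert np.all(sd == 0)

    def test_opposite_courses_cancel(self):
        x = RNG.standard_normal(50)
        mean, _ = group_mean_course([x, -x])
        assert np.allclose(mean, 0.0)

    def test_matches_naive_loop(self):
        stack = RNG.standard_normal((5, 30))
        mean, sd = group_mean_course(list(stack))
        naive_mean = [sum(stack[:, t]) / 5 for t in range(30)]
        naive_sd = [np.sqrt(sum((stack[k, t] - naive_mean[t]) ** 2
                                for k in range(5)) / 4) for t in range(30)]
        assert np.allclose(mean, naive_mean, atol=1e-12)
        assert np.allclose(sd, naive_sd, atol=1e-12)
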
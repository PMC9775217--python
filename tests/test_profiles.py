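"""Binning, robustness criteria, Hill fitting, and the Bayesian bootstrap."""

import numpy as np
import pandas as pd
import pytest

from phremc.profiles import (
    HillCurve,
    HillFitError,
    apply_bin_criteria,
    bayesian_bootstrap_pka,
    bin_observations,
    hill_fit,
    pka_profile,
    property_profile,
)


def _obs(rows):
    return pd.DataFrame(
        rows, columns=["replicate", "pH", "frame", "insertion", "protonated"]
    )


def _uniform_obs(n_frames=100, reps=(0, 1, 2), phs=(5.0, 6.0), insertion=-5.5,
                 frac=0.5, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for rep in reps:
        for ph in phs:
            for f in range(n_frames):
                rows.append((rep, ph, f, insertion, int(rng.random() < frac)))
    return _obs(rows)


class TestBinning:
    def test_floor_rule(self):
        cells = bin_observations(_obs([(0, 6.0, 0, -5.3, 1)]))
        assert (cells.bin_low.iloc[0], cells.bin_high.iloc[0]) == (-6.0, -5.0)

    def test_boundary_is_half_open(self):
        cells = bin_observations(_obs([(0, 6.0, 0, -5.0, 1)]))
        assert (cells.bin_low.iloc[0], cells.bin_high.iloc[0]) == (-5.0, -4.0)

    def test_burn_in_drops_first_half_per_replicate(self):
        rows = [(0, 6.0, f, -5.5, 1) for f in range(100)]
        cells = bin_observations(_obs(rows), burn_in_fraction=0.5)
        assert cells.n_prot.sum() + cells.n_deprot.sum() == 50

    def test_count_conservation(self):
        obs = _uniform_obs()
        cells = bin_observations(obs, burn_in_fraction=0.0)
        assert cells.n_prot.sum() + cells.n_deprot.sum() == len(obs)


class TestCriteria:
    def _cells(self, n_prot, n_deprot, reps=(0, 1, 2), phs=(5.0, 6.0)):
        rows = []
        for rep in reps:
            for ph in phs:
                rows.append((-6.0, -5.0, ph, rep, n_prot, n_deprot))
        return pd.DataFrame(
            rows,
            columns=["bin_low", "bin_high", "pH", "replicate", "n_prot", "n_deprot"],
        )

    def test_nine_of_one_state_rejected_ten_accepted(self):
        cells9, _ = apply_bin_criteria(self._cells(9, 200))
        assert not cells9.cell_valid.any()
        cells10, bins10 = apply_bin_criteria(self._cells(10, 200))
        assert cells10.cell_valid.all()
        assert bins10.pka_valid.all()

    def test_two_replicates_rejected_three_accepted(self):
        _, bins2 = apply_bin_criteria(self._cells(50, 50, reps=(0, 1)))
        assert not bins2.pH_valid.any() if len(bins2) else True
        _, bins3 = apply_bin_criteria(self._cells(50, 50, reps=(0, 1, 2)))
        assert bins3.pH_valid.all()

    def test_single_ph_not_fittable(self):
        _, bins = apply_bin_criteria(self._cells(50, 50, phs=(6.0,)))
        assert not bins.pka_valid.any()
        assert bins.profile_valid.all()  # protonation profile still allowed

    def test_monotonicity_tolerance_boundary(self):
        # avg 0.30 at pH 5; rise to 0.36 (fails, > 0.05) vs 0.34 (passes)
        def make(avg_high):
            n_p = int(avg_high * 100)
            rows = []
            for rep in range(3):
                rows.append((-6.0, -5.0, 5.0, rep, 30, 70))
                rows.append((-6.0, -5.0, 6.0, rep, n_p, 100 - n_p))
            return pd.DataFrame(
                rows,
                columns=["bin_low", "bin_high", "pH", "replicate", "n_prot", "n_deprot"],
            )

        _, bad = apply_bin_criteria(make(0.36))
        assert not bad.pka_valid.any()
        assert not bad.monotonic.any()
        _, good = apply_bin_criteria(make(0.34))
        assert good.pka_valid.all()


class TestHillFit:
    def test_exact_three_point_recovery(self):
        c = hill_fit([(5.0, 10 / 11), (6.0, 0.5), (7.0, 1 / 11)])
        assert c.pKa == pytest.approx(6.0, abs=1e-9)
        assert c.n == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recovery_is_exact(self):
        truth = HillCurve(6.4, 1.0)
        pts = [(ph, float(truth.predict(ph))) for ph in (4.0, 5.0, 6.0, 7.0)]
        c = hill_fit(pts)
        assert c.pKa == pytest.approx(6.4, abs=1e-9)

    def test_cooperative_curve_recovered(self):
        truth = HillCurve(5.8, 2.5)
        pts = [(ph, float(truth.predict(ph))) for ph in (4.5, 5.5, 6.0, 6.5, 7.0)]
        c = hill_fit(pts)
        assert c.pKa == pytest.approx(5.8, abs=1e-6)
        assert c.n == pytest.approx(2.5, abs=1e-4)

    def test_matches_scipy_on_noisy_data(self):
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(3)
        ph = np.array([4.0, 5.0, 6.0, 7.0])
        p = np.clip(HillCurve(6.1, 1.0).predict(ph) + rng.normal(0, 0.04, 4), 0, 1)
        mine = hill_fit(list(zip(ph, p)))

        def f(x, pka, n):
            return 1.0 / (1.0 + 10.0 ** (n * (x - pka)))

        popt, _ = curve_fit(f, ph, p, p0=[6.0, 1.0], bounds=([-np.inf, 1e-3], [np.inf, 10.0]))
        assert mine.pKa == pytest.approx(popt[0], abs=1e-4)
        assert mine.n == pytest.approx(popt[1], abs=1e-4)

    def test_single_ph_rejected(self):
        with pytest.raises(HillFitError, match="two distinct pH"):
            hill_fit([(6.0, 0.5), (6.0, 0.52)])

    def test_flat_curve_rejected(self):
        with pytest.raises(HillFitError, match="flat"):
            hill_fit([(4.0, 0.0), (5.0, 0.0), (6.0, 0.0)])


class TestBayesianBootstrap:
    def test_identical_samples_zero_error(self):
        samples = {
            5.0: np.full(5, 10 / 11),
            6.0: np.full(5, 0.5),
            7.0: np.full(5, 1 / 11),
        }
        res = bayesian_bootstrap_pka(samples, B=200, seed=1)
        assert res.pKa == pytest.approx(6.0, abs=1e-9)
        assert res.error == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        samples = {
            ph: np.clip(HillCurve(6.0, 1.0).predict(ph) + rng.normal(0, 0.03, 8), 0, 1)
            for ph in (4.0, 5.0, 6.0, 7.0)
        }
        a = bayesian_bootstrap_pka(samples, B=300, seed=9)
        b = bayesian_bootstrap_pka(samples, B=300, seed=9)
        assert (a.pKa, a.error) == (b.pKa, b.error)

    def test_error_scales_with_replicates(self):
        def run(R, seed):
            rng = np.random.default_rng(seed)
            samples = {
                ph: np.clip(
                    HillCurve(6.0, 1.0).predict(ph) + rng.normal(0, 0.05, R), 0, 1
                )
                for ph in (4.0, 5.0, 6.0, 7.0)
            }
            return bayesian_bootstrap_pka(samples, B=400, seed=seed).error

        small = np.mean([run(5, s) for s in range(30)])
        large = np.mean([run(20, s) for s in range(30)])
        assert large < small / 1.5  # ~1/2 expected for 4x replicates

    def test_unreliable_bin_rejected(self):
        # grossly non-monotonic samples: most bootstraps fail criterion 3
        samples = {5.0: np.array([0.1, 0.12, 0.11]), 6.0: np.array([0.8, 0.82, 0.81])}
        with pytest.raises(HillFitError, match="unreliable|flat|criteria"):
            bayesian_bootstrap_pka(samples, B=100, seed=0)


class TestPropertyProfile:
    def _scalar_obs(self, value, reps=(0, 1, 2), n=30):
        rows = []
        for rep in reps:
            for f in range(n):
                rows.append((rep, 6.0, f, -5.5, value))
        return pd.DataFrame(
            rows, columns=["replicate", "pH", "frame", "insertion", "distance"]
        )

    def test_constant_scalar(self):
        prof = property_profile(self._scalar_obs(3.0), "distance")
        assert len(prof) == 1
        assert prof["mean"].iloc[0] == pytest.approx(3.0)
        assert prof["sem"].iloc[0] == pytest.approx(0.0)

    def test_two_replicates_filtered(self):
        prof = property_profile(self._scalar_obs(3.0, reps=(0, 1)), "distance")
        assert len(prof) == 0


class TestPkaProfileEndToEnd:
    def test_known_curve_recovered_per_bin(self):
        # synthesise observations whose per-bin titration follows a known
        # Hill curve; the pipeline must recover pKa per bin
        rng = np.random.default_rng(7)
        rows = []
        for b, pka in ((-6.0, 6.8), (-3.0, 6.2), (0.0, 5.6)):
            for rep in range(5):
                for ph in (4.0, 5.0, 6.0, 7.0):
                    frac = float(HillCurve(pka, 1.0).predict(ph))
                    for f in range(250):
                        rows.append(
                            (rep, ph, f, b + rng.uniform(0, 1), int(rng.random() < frac))
                        )
        prof = pka_profile(_obs(rows), B=300, seed=3)
        got = dict(zip(prof.bin_low, prof.pKa))
        for b, pka in ((-6.0, 6.8), (-3.0, 6.2), (0.0, 5.6)):
            assert got[b] == pytest.approx(pka, abs=0.12)
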
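import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import dimerslide as ds
from dimerslide.simulator import (
    FOOTPRINT_BP,
    NucleosomeSubstrate,
    SimParams,
    band_pattern_from_offsets,
    make_dimer,
    parse_substrate,
)


class TestSubstrateParsing:
    @pytest.mark.parametrize("name,left,right,length", [
        ("0N100", 0, 100, 247),
        ("50N50", 50, 50, 247),
        ("18N18", 18, 18, 183),
    ])
    def test_parse_and_length(self, name, left, right, length):
        sub = parse_substrate(name)
        assert (sub.left_flank, sub.right_flank) == (left, right)
        assert sub.dna_length == length
        assert sub.name == name

    @pytest.mark.parametrize("bad", ["N100", "100N", "50x50", "", "5N5N5"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_substrate(bad)

    @given(st.integers(0, 300), st.integers(0, 300))
    def test_round_trip(self, a, b):
        assert parse_substrate(f"{a}N{b}").name == f"{a}N{b}"


class TestSimulationBasics:
    def test_reproducible_under_seed(self):
        e1 = ds.simulate("0N100", "WT", n_molecules=20, t_end=50.0, seed=5)
        e2 = ds.simulate("0N100", "WT", n_molecules=20, t_end=50.0, seed=5)
        for a, b in zip(e1.trajectories, e2.trajectories):
            assert np.array_equal(a.dyad, b.dyad)
            assert np.array_equal(a.atp, b.atp)

    def test_dead_homodimer_inert(self):
        ens = ds.simulate("0N100", "EA", n_molecules=30, t_end=100.0, seed=6)
        assert np.all(ens.displacement == 0)
        assert np.all(ens.final_atp == 0)

    def test_zero_step_rate_keeps_position_and_burns_atp(self):
        params = SimParams(k_step0=0.0, k_atp=2.0)
        ens = ds.simulate("0N100", "WT", params, n_molecules=40, t_end=100.0,
                          seed=7)
        assert np.all(ens.displacement == 0)
        # two active motors at 2 /s for 100 s
        assert ens.final_atp.mean() == pytest.approx(400.0, rel=0.1)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            NucleosomeSubstrate(-1, 10)


class TestFlankConservation:
    def test_flank_sum_and_bounds_every_event(self, wt_0n140):
        sub = wt_0n140.substrate
        half = (sub.footprint - 1) // 2
        for tr in wt_0n140.trajectories:
            left = tr.dyad - half
            right = (sub.dna_length - 1) - tr.dyad - (sub.footprint - 1 - half)
            assert np.all(left >= 0) and np.all(right >= 0)
            assert np.all(left + right == sub.total_flank)

    def test_atp_ledger_dominates_coupled_steps(self, wt_0n140):
        assert np.all(wt_0n140.final_atp >= wt_0n140.coupled_steps)

    def test_atp_count_nondecreasing(self, wt_0n100):
        for tr in wt_0n100.trajectories:
            assert np.all(np.diff(tr.atp) >= 0)


class TestEndPositioning:
    def test_centred_50n50_stays_put(self):
        ens = ds.simulate("50N50", "WT", n_molecules=200, t_end=3600.0, seed=4)
        assert ens.mean_abs_displacement() < 2.0

    def test_0n100_centres_single_band(self, wt_0n100):
        pat = ds.band_pattern(
            ds.simulate("0N100", "WT", n_molecules=300, t_end=3600.0, seed=8))
        assert pat.n_bands == 1
        assert pat.positions[0] == 0.0

    def test_band_ladder_grows_per_20bp_of_overhang(self):
        expected = {"0N100": 1, "0N120": 2, "0N140": 3}
        for name, n in expected.items():
            ens = ds.simulate(name, "WT", n_molecules=400, t_end=3600.0,
                              seed=13)
            assert ds.band_pattern(ens).n_bands == n, name

    def test_0n140_band_positions(self, wt_0n140):
        pat = ds.band_pattern(wt_0n140)
        assert list(pat.positions) == [0.0, 10.0, 20.0]

    def test_no_overshoot_beyond_one_well(self):
        # long run so every molecule has settled; the dyad of an
        # end-positioned nucleosome never ends more than one well past
        # the DNA centre
        for name in ("0N100", "0N140"):
            ens = ds.simulate(name, "WT", n_molecules=300, t_end=7200.0,
                              seed=17)
            period = ens.params.well_period
            assert ens.offsets_from_centre.max() <= period + 1e-9, name

    def test_mirror_symmetry(self):
        e1 = ds.simulate("0N140", "WT", n_molecules=1000, t_end=3600.0,
                         seed=100)
        e2 = ds.simulate("140N0", "WT", n_molecules=1000, t_end=3600.0,
                         seed=200)
        ks = stats.ks_2samp(e1.offsets_from_centre, -e2.offsets_from_centre)
        assert ks.pvalue > 0.01

    def test_initial_rate_monotone_in_overhang_then_saturates(self):
        rates = []
        for b in (20, 40, 60, 80, 100):
            ens = ds.simulate(f"0N{b}", "WT", n_molecules=300, t_end=10.0,
                              seed=31)
            rates.append(ens.dyad_at(10.0).mean() - ens.start_dyad)
        rates = np.array(rates) / 10.0
        assert np.all(np.diff(rates) > -0.02)          # nondecreasing
        # short-flank regime is strongly length-dependent ...
        assert rates[1] - rates[0] > 0.15
        # ... while beyond the sensing midpoint the rate has saturated
        assert rates[-1] == pytest.approx(rates[-2], abs=0.1)


class TestHeterodimers:
    def test_single_motor_orientation_splits_productivity(self):
        ens = ds.simulate("0N100", make_dimer("WT", "EA"), n_molecules=400,
                          t_end=200.0, seed=7)
        productive = np.array([tr.productive for tr in ens.trajectories])
        assert productive.mean() == pytest.approx(0.5, abs=0.08)
        # productive molecules slide fully, unproductive not at all
        assert np.all(ens.displacement[~productive] == 0)
        assert ens.displacement[productive].mean() == pytest.approx(50, abs=2)
        # a single motor still hydrolyses in both orientations
        assert ens.final_atp[~productive].mean() > 0

    def test_forced_orientation(self):
        ens = ds.simulate("0N100", make_dimer("WT", "EA", "unproductive"),
                          n_molecules=20, t_end=100.0, seed=9)
        assert np.all(ens.displacement == 0)

    def test_orientation_rejected_for_two_motor_dimer(self):
        with pytest.raises(ValueError):
            make_dimer("WT", "WT", "productive")


class TestSensingRange:
    def test_wt_limit_is_50bp(self):
        assert ds.sensing_range(preset="WT", seed=11) == 50

    def test_ctd_deletion_shortens_sensing_below_40bp(self):
        assert ds.sensing_range(preset="dCTD", seed=11) < 40

    def test_round_trip_with_arbitrary_midpoint(self):
        params = SimParams.from_preset("WT", s_sense=40.0)
        assert ds.sensing_range(params=params, seed=5) == 40

    def test_ctd_deletion_moves_50n50_off_centre(self):
        ens = ds.simulate("50N50", "WT", SimParams.from_preset("dCTD"),
                          n_molecules=200, t_end=3600.0, seed=5)
        assert ens.mean_abs_displacement() > 2.0


class TestBandReduction:
    def test_point_mass_single_band(self):
        pat = band_pattern_from_offsets(np.zeros(50))
        assert pat.n_bands == 1 and pat.occupancies[0] == 1.0

    @given(st.lists(st.integers(-40, 40), min_size=1, max_size=200))
    def test_matches_brute_force_histogram(self, offsets):
        from collections import Counter
        pat = band_pattern_from_offsets(np.array(offsets, float),
                                        well_period=10,
                                        occupancy_threshold=0.05)
        counts = Counter(int(round(abs(o) / 10)) * 10 for o in offsets)
        expected = sorted(p for p, c in counts.items()
                          if c / len(offsets) >= 0.05)
        assert list(pat.positions) == [float(p) for p in expected]
        for p, occ in zip(pat.positions, pat.occupancies):
            assert occ == pytest.approx(counts[int(p)] / len(offsets))

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            band_pattern_from_offsets(np.array([]))


class TestFretProxy:
    def test_stationary_ensemble_flat_trace(self):
        ens = ds.simulate("50N50", "EA", n_molecules=10, t_end=100.0, seed=3)
        tr = ds.fret_proxy(ens)
        assert np.allclose(tr.signal, 1.0)

    def test_two_point_ensemble_matches_hand_mean(self):
        ens = ds.simulate("50N50", "EA", n_molecules=2, t_end=50.0, seed=1)
        tr = ds.fret_proxy(ens, decay_bp=14.0)
        # both molecules stationary at 50 bp left flank
        assert tr.signal[0] == pytest.approx(1.0)
        raw = np.exp(-50.0 / 14.0)
        # normalisation divides the (equal) per-molecule signals out
        assert np.allclose(tr.signal, (raw + raw) / 2 / raw)

    def test_0n100_decays_to_plateau_before_200s(self, wt_0n100):
        tr = ds.fret_proxy(wt_0n100)
        assert np.all(np.diff(tr.signal) <= 1e-9)
        from dimerslide.kinetics import completion_fraction
        assert completion_fraction(tr, 190.0) > 0.99


class TestMixtureRateReciprocity:
    def test_half_rate_doubles_completion_time(self):
        """Halving the ensemble stepping rate doubles time to completion."""
        def t90(k):
            params = SimParams.from_preset("WT", k_step0=k)
            ens = ds.simulate("0N100", "WT", params, n_molecules=200,
                              t_end=1200.0, seed=23)
            tr = ds.fret_proxy(ens, times=np.linspace(0, 1200, 1201))
            from dimerslide.kinetics import completion_fraction
            fr = [completion_fraction(tr, t) for t in tr.time]
            return tr.time[int(np.searchsorted(fr, 0.9))]
        ratio = t90(0.5) / t90(1.0)
        assert ratio == pytest.approx(2.0, rel=0.2)
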
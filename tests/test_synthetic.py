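"""Ground-truth generators: builder, conformers, mixtures, frames, traces."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from absaxs import (AntibodySpec, GlycanSite, MixtureTruth, make_toy_antibody,
                    make_conformer, simulate_experiment, simulate_secsaxs_frames,
                    simulate_spr_trace, simulate_melt_curve, debye_profile,
                    chi2, compute_tm)
from absaxs.profiles import ScatteringProfile
from absaxs.synthetic import CONFORMER_MODES, write_truth_sidecar


def glycan_labels(model):
    return sorted({lab for lab in model.labels if lab.startswith("glycan_")})


class TestBuilder:
    def test_full_occupancy_attaches_every_site(self):
        sites = tuple(GlycanSite(f"S{i}", r, 9, 1.0)
                      for i, r in enumerate((150, 200, 260, 330, 455)))
        model = make_toy_antibody(AntibodySpec(glycan_sites=sites))
        # five sites on each of the two heavy chains
        assert len(glycan_labels(model)) == 10

    def test_zero_length_glycans_leave_protein_only(self):
        sites = (GlycanSite("S", 260, 0, 1.0),)
        spec = AntibodySpec(glycan_sites=sites)
        model = make_toy_antibody(spec)
        expected = 2 * spec.n_res_fab + spec.n_res_fc + 2 * spec.n_hinge + 2 * spec.n_tail
        assert model.n_beads == expected
        assert not glycan_labels(model)

    def test_zero_occupancy_attaches_nothing(self):
        sites = (GlycanSite("S", 260, 9, 0.0),)
        model = make_toy_antibody(AntibodySpec(glycan_sites=sites))
        assert not glycan_labels(model)

    def test_closed_rg_in_printed_window(self, closed_model):
        """Compact IgA2-like monomers sit at Rg 43-46 A."""
        assert 43.0 <= closed_model.rg() <= 46.0

    def test_domain_rg_within_ig_fold_range(self, closed_model):
        # individual Fab/Fc domains sit near the upper end of the ~20-27 A
        # immunoglobulin range (the Fab long axis is generous so the whole
        # particle matches compact-antibody scattering features)
        for lab in ("Fab1", "Fab2", "Fc"):
            idx = closed_model.indices(lab)
            sub = closed_model.coords[idx]
            ctr = sub.mean(axis=0)
            rg = np.sqrt(np.mean(np.sum((sub - ctr) ** 2, axis=1)))
            assert 20.0 <= rg <= 28.0

    def test_builder_is_reproducible(self):
        a = make_toy_antibody(AntibodySpec(seed=5))
        b = make_toy_antibody(AntibodySpec(seed=5))
        assert np.array_equal(a.coords, b.coords)

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            AntibodySpec(glycan_sites=(GlycanSite("S", 260, 9, 1.4),))

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            AntibodySpec(hinge_range=(450, 460), tail_range=(449, 466))


class TestConformers:
    def test_seeded_determinism(self, closed_model):
        a = make_conformer(closed_model, "closed", seed=9)
        b = make_conformer(closed_model, "closed", seed=9)
        assert np.array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("mode,lo,hi", [
        ("closed", 43.0, 47.0),
        ("open", 52.0, 54.0),
        ("extended", 63.0, 66.0),
    ])
    def test_mode_rg_windows(self, closed_model, mode, lo, hi):
        conf = make_conformer(closed_model, mode, seed=1)
        assert lo <= conf.rg() <= hi

    @pytest.mark.parametrize("mode", CONFORMER_MODES)
    def test_rigid_bodies_keep_internal_distances(self, closed_model, mode):
        conf = make_conformer(closed_model, mode, seed=2)
        for lab in ("Fab1", "Fab2", "Fc"):
            idx = closed_model.indices(lab)
            assert np.max(np.abs(pdist(conf.coords[idx]) -
                                 pdist(closed_model.coords[idx]))) < 1e-6

    def test_unknown_mode_rejected(self, closed_model):
        with pytest.raises(ValueError):
            make_conformer(closed_model, "sideways")


class TestMixture:
    def test_zero_noise_reproduces_weighted_sum(self, closed_profile, open_profile):
        truth = MixtureTruth(weights=(0.3, 0.7), noise=0.0)
        mix = simulate_experiment(truth, [closed_profile, open_profile], seed=4)
        expected = 0.3 * closed_profile.I + 0.7 * open_profile.I
        assert np.array_equal(mix.I, expected)

    def test_degenerate_weight_selects_one_component(self, closed_profile,
                                                     open_profile):
        truth = MixtureTruth(weights=(1.0, 0.0), noise=0.0)
        mix = simulate_experiment(truth, [closed_profile, open_profile], seed=4)
        assert np.array_equal(mix.I, closed_profile.I)

    def test_noise_level_is_consistent_with_sigma(self, closed_profile,
                                                  open_profile):
        """Mean chi2 of the true mixture over replicates is ~1."""
        truth = MixtureTruth(weights=(0.6, 0.4), noise=0.02)
        ideal = ScatteringProfile(
            closed_profile.q, 0.6 * closed_profile.I + 0.4 * open_profile.I)
        vals = [chi2(simulate_experiment(truth, [closed_profile, open_profile],
                                         seed=s), ideal)[0]
                for s in range(100)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureTruth(weights=(0.6, 0.6))

    def test_sidecar_round_trips_key_values(self, tmp_path):
        truth = MixtureTruth()
        write_truth_sidecar(tmp_path / "truth.txt", truth, note="x")
        text = (tmp_path / "truth.txt").read_text()
        assert "weights=0.45,0.55" in text and "note=x" in text


class TestSecSaxsFrames:
    def test_zero_concentration_matches_buffer_statistics(self, closed_profile,
                                                          open_profile):
        truth = MixtureTruth(noise=0.0)
        frames, info = simulate_secsaxs_frames(
            truth, [closed_profile, open_profile], peak_concentration=0.0, seed=1)
        ref = frames[0].I
        assert all(np.array_equal(f.I, ref) for f in frames[1:])

    def test_apex_frame_has_maximal_intensity(self, closed_profile, open_profile):
        truth = MixtureTruth(noise=0.0)
        frames, info = simulate_secsaxs_frames(truth,
                                               [closed_profile, open_profile],
                                               n_buffer=5, n_peak=21, seed=1)
        integrals = [float(np.trapezoid(f.I, f.q)) for f in frames]
        apex = int(np.argmax(integrals))
        assert apex == int(np.argmax(info["concentration"]))
        assert integrals[apex] > integrals[0]

    def test_buffer_frame_minimum(self, closed_profile, open_profile):
        with pytest.raises(ValueError):
            simulate_secsaxs_frames(MixtureTruth(), [closed_profile, open_profile],
                                    n_buffer=1)


class TestSprTrace:
    def test_zero_concentration_gives_zero_response(self):
        tr = simulate_spr_trace(1e5, 0.01, 50.0, concentrations=[0.0], noise=0.0)
        assert np.allclose(tr.response, 0.0)

    def test_plateau_reaches_langmuir_equilibrium(self):
        ka, kd, rmax, c = 2e5, 0.06, 100.0, 300e-9
        tr = simulate_spr_trace(ka, kd, rmax, concentrations=[c],
                                t_assoc=600.0, t_dissoc=0.0, noise=0.0)
        expected = rmax * c / (c + kd / ka)
        assert tr.response[-1] == pytest.approx(expected, rel=1e-4)

    def test_printed_kd_regime(self):
        # ka = 2e5, kd = 0.06 puts K_D at 300 nM, inside 200-400 nM
        assert 200e-9 <= 0.06 / 2e5 <= 400e-9

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_spr_trace(-1.0, 0.06, 100.0)


class TestMeltCurve:
    def test_noiseless_tm_recovered_on_grid(self):
        curve = simulate_melt_curve(67.0, noise=0.0)
        assert compute_tm(curve) == pytest.approx(67.0, abs=0.5)

    def test_two_degree_offset_resolved(self):
        a = simulate_melt_curve(69.0, noise=0.0)
        b = simulate_melt_curve(67.0, noise=0.0)
        assert compute_tm(a) - compute_tm(b) == pytest.approx(2.0, abs=0.2)

    def test_flat_curve_flagged(self):
        curve = simulate_melt_curve(67.0, noise=0.0)
        curve.signal[:] = 1.0
        with pytest.raises(ValueError):
            compute_tm(curve)

    def test_tm_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt_curve(5.0)
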
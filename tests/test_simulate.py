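"""Forward generator: determinism, construction identities, phantoms."""

import numpy as np
import pytest

from indentmap.curves import extract_equilibrium_force, extract_peak_force
from indentmap.hayes import hayes_force
from indentmap.simulate import (
    GroundTruth,
    StudyConfig,
    make_study,
    read_study,
    simulate_needle_curve,
    simulate_relaxation_curve,
    voxelize_condyle,
    write_study,
)
from indentmap.volume import local_thickness, mean_thickness, segment_cartilage, split_condyles


class TestRelaxationCurve:
    def test_peak_is_hayes_force_at_full_depth(self):
        E, h = 15.0, 60.0
        c = simulate_relaxation_curve(E, h)
        assert c.F.max() == pytest.approx(float(hayes_force(E, 20.0, h)), rel=1e-12)

    def test_equilibrium_tail_is_ginf_fraction(self):
        c = simulate_relaxation_curve(10.0, 50.0)
        assert extract_equilibrium_force(c) == pytest.approx(
            0.3 * extract_peak_force(c), rel=0.02)

    def test_displacement_profile(self):
        c = simulate_relaxation_curve(10.0, 50.0)
        ramp = c.t <= 1.0
        assert np.allclose(c.w[ramp], 20.0 * c.t[ramp])
        assert np.all(c.w[~ramp] == 20.0)


class TestNeedleCurve:
    def test_stop_criterion_terminates_curve(self):
        c = simulate_needle_curve(60.0, 0.0)
        assert c.F[-1] >= 0.5
        assert np.all(c.F[:-1] < 0.5)

    def test_cartilage_span_scales_with_angle(self):
        c0 = simulate_needle_curve(60.0, 0.0)
        c45 = simulate_needle_curve(60.0, 45.0)
        # tilted site: longer vertical path to the interface, longer record
        assert c45.z[-1] > c0.z[-1]

    def test_failed_record_never_reaches_stop(self):
        c = simulate_needle_curve(60.0, 0.0, fail=True)
        assert c.F.max() < 0.5


class TestDeterminism:
    def test_same_seed_identical_study(self):
        a = make_study(StudyConfig(n_control=2, n_knockout=1, seed=7))
        b = make_study(StudyConfig(n_control=2, n_knockout=1, seed=7))
        assert a.truth_table.equals(b.truth_table)
        ka = sorted(a.indentation)
        assert ka == sorted(b.indentation)
        for k in ka[:20]:
            assert np.array_equal(a.indentation[k].F, b.indentation[k].F)

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = StudyConfig(n_control=1, n_knockout=1, seed=3)
        d1 = write_study(make_study(cfg), tmp_path / "one")
        d2 = write_study(make_study(cfg), tmp_path / "two")
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seed_differs(self):
        a = make_study(StudyConfig(n_control=1, n_knockout=0, seed=1))
        b = make_study(StudyConfig(n_control=1, n_knockout=0, seed=2))
        assert not a.truth_table.equals(b.truth_table)


class TestRoundTrip:
    def test_zero_noise_pipeline_recovers_truth(self, noiseless_truth):
        """End to end at zero noise: thickness within 1 um, modulus within
        2% of the generator's ground truth at every site."""
        from indentmap.study import IndentationStudy

        study = make_study(StudyConfig(n_control=2, n_knockout=1, seed=5),
                           truth=noiseless_truth)
        res = IndentationStudy.from_simulation(study).fit()
        m = res.site_table.merge(study.truth_table, on=["specimen", "site_id"],
                                 suffixes=("", "_true"))
        dh = (m.thickness_np_um - m.h_um).abs()
        assert dh.max() < 1.0
        rel = ((m.E_MPa - m.E_MPa_true) / m.E_MPa_true).abs()
        assert rel.max() < 0.02

    def test_write_read_roundtrip_preserves_analysis(self, tmp_path, noiseless_truth):
        from indentmap.study import IndentationStudy

        study = make_study(StudyConfig(n_control=1, n_knockout=0, seed=9),
                           truth=noiseless_truth)
        out = write_study(study, tmp_path / "study")
        res_mem = IndentationStudy.from_simulation(study).fit()
        res_disk = IndentationStudy.from_directory(out).fit()
        a = res_mem.site_table.set_index("site_id")["thickness_np_um"]
        b = res_disk.site_table.set_index("site_id")["thickness_np_um"]
        assert np.allclose(a, b, atol=1e-6, equal_nan=True)


class TestCondylePhantom:
    def test_uniform_shell_thickness(self):
        vol, _ = voxelize_condyle(50.0, voxel_um=4.39, bone_radius_um=150.0,
                                  length_um=300.0)
        cm = segment_cartilage(vol, method="fixed", threshold=60.0)
        assert mean_thickness(local_thickness(cm.mask, 4.39)) == pytest.approx(
            50.0, abs=4.39)

    def test_two_shells_split(self):
        vol, _ = voxelize_condyle(40.0, voxel_um=4.39, bone_radius_um=100.0,
                                  length_um=200.0, two_condyles=True)
        cm = segment_cartilage(vol, method="fixed", threshold=60.0)
        out = split_condyles(cm)
        assert set(np.unique(out.labels)) == {0, 1, 2}

    def test_landmarks_inside_cartilage(self, grid):
        sites = grid.site_ids
        vol, lms = voxelize_condyle({s: 50.0 for s in sites}, voxel_um=4.39,
                                    sites=sites, two_condyles=True)
        assert set(lms) == set(sites)
        cm = segment_cartilage(vol, method="fixed", threshold=60.0)
        for sid, (z, y, x) in lms.items():
            iz, iy, ix = (int(round(v / 4.39)) for v in (z, y, x))
            assert cm.mask[iz, iy, ix], sid

    def test_voxel_size_roundtrips_through_io(self, tmp_path):
        from indentmap.volume import load_volume, save_volume

        vol, _ = voxelize_condyle(40.0, voxel_um=4.39, bone_radius_um=80.0,
                                  length_um=100.0)
        save_volume(vol, tmp_path / "p.nii")
        assert load_volume(tmp_path / "p.nii").voxel_um == pytest.approx(4.39)


class TestStudyStructure:
    def test_record_counts(self, small_study):
        cfg = small_study.config
        n_spec = cfg.n_control + cfg.n_knockout
        assert len(small_study.indentation) == 31 * n_spec * 3
        assert len(small_study.needle) == 31 * n_spec
        assert len(small_study.truth_table) == 31 * n_spec

    def test_lateral_thicker_than_medial_in_controls(self, small_study):
        tt = small_study.truth_table
        ctrl = tt[tt.genotype == "control"]
        lat = ctrl[ctrl.site_id.str.startswith("L")].h_um.mean()
        med = ctrl[ctrl.site_id.str.startswith("M")].h_um.mean()
        assert lat > med

    def test_knockout_effect_directions_in_truth(self, small_study):
        tt = small_study.truth_table
        med = tt[tt.site_id.str.startswith("M")]
        ko = med[med.genotype == "knockout"]
        ct = med[med.genotype == "control"]
        assert ko.h_um.mean() > ct.h_um.mean()
        assert ko.E_MPa.mean() < ct.E_MPa.mean()
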
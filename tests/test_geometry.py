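"""Membrane geometry: surfaces, insertion signs, annulus profiles, PBC."""

import numpy as np
import pytest

from phremc.geometry import (
    LOWER,
    UPPER,
    MembraneFrame,
    annulus_half_thickness,
    insertion_series,
    local_deformation,
    local_surface_z,
    membrane_center,
)
from phremc.surrogate import (
    SyntheticFrameSpec,
    expected_half_thickness,
    generate_membrane_frames,
)


def _simple_frame(upper_z=19.5, lower_z=-19.5, n_side=8, spacing=5.0, probe=None):
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    xy = np.stack([xs.ravel(), ys.ravel()], axis=1) * spacing + spacing / 2
    n = len(xy)
    xyz = np.concatenate(
        [
            np.column_stack([xy, np.full(n, upper_z)]),
            np.column_stack([xy, np.full(n, lower_z)]),
        ]
    )
    return MembraneFrame(
        phosphate_xyz=xyz,
        phosphate_element=np.array(["P"] * n + ["P"] * n),
        phosphate_monolayer=np.array([UPPER] * n + [LOWER] * n),
        probes=probe or {},
        box=(n_side * spacing, n_side * spacing, 100.0),
    )


class TestMembraneCenter:
    def test_symmetric_sheets_center_zero(self):
        assert membrane_center(_simple_frame()) == pytest.approx(0.0)

    def test_translation_equivariance(self):
        f = _simple_frame()
        g = MembraneFrame(
            f.phosphate_xyz + np.array([0.0, 0.0, 3.0]),
            f.phosphate_element,
            f.phosphate_monolayer,
            box=f.box,
        )
        assert membrane_center(g) == pytest.approx(membrane_center(f) + 3.0)

    def test_requires_p_atoms(self):
        f = _simple_frame()
        g = MembraneFrame(
            f.phosphate_xyz,
            np.array(["O"] * len(f.phosphate_xyz)),
            f.phosphate_monolayer,
            box=f.box,
        )
        with pytest.raises(ValueError, match="no P atoms"):
            membrane_center(g)


class TestLocalSurface:
    def test_constant_field_all_within_radius(self):
        xy = np.column_stack([np.linspace(-2, 2, 12), np.zeros(12)]) + 20.0
        frame = MembraneFrame(
            np.column_stack([xy, np.full(12, 19.0)]),
            np.array(["P"] * 12),
            np.array([UPPER] * 12),
            box=(40.0, 40.0, 100.0),
        )
        z, n = local_surface_z(frame, (20.0, 20.0), UPPER)
        assert (z, n) == (pytest.approx(19.0), 12)

    def test_fallback_uses_ten_nearest(self):
        # 4 atoms inside the 6 A radius at z=20, next 6 nearest at z=18
        near = np.column_stack([np.full(4, 2.0), np.zeros(4), np.full(4, 20.0)])
        far = np.column_stack([np.full(6, 9.0), np.zeros(6), np.full(6, 18.0)])
        rest = np.column_stack([np.full(5, 15.0), np.zeros(5), np.full(5, 10.0)])
        frame = MembraneFrame(
            np.concatenate([near, far, rest]) + np.array([20.0, 20.0, 0.0]),
            np.array(["P"] * 15),
            np.array([UPPER] * 15),
            box=(60.0, 60.0, 100.0),
        )
        z, n = local_surface_z(frame, (20.0, 20.0), UPPER)
        assert n == 10
        assert z == pytest.approx((4 * 20.0 + 6 * 18.0) / 10)

    def test_periodic_wrap_matches_unwrapped(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 30, (40, 2))
        z = rng.normal(19.5, 0.3, 40)
        frame = MembraneFrame(
            np.column_stack([xy, z]),
            np.array(["P"] * 40),
            np.array([UPPER] * 40),
            box=(30.0, 30.0, 100.0),
        )
        # probe at the box edge; shifting all atoms by half a box and
        # rewrapping must give the identical surface
        shifted_xy = (xy + 15.0) % 30.0
        frame2 = MembraneFrame(
            np.column_stack([shifted_xy, z]),
            np.array(["P"] * 40),
            np.array([UPPER] * 40),
            box=(30.0, 30.0, 100.0),
        )
        z1, n1 = local_surface_z(frame, (0.5, 0.5), UPPER)
        z2, n2 = local_surface_z(frame2, (15.5, 15.5), UPPER)
        assert n1 == n2
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_too_few_atoms_in_monolayer_fails(self):
        frame = MembraneFrame(
            np.array([[0.0, 0.0, 19.0]] * 5),
            np.array(["P"] * 5),
            np.array([UPPER] * 5),
        )
        with pytest.raises(ValueError, match="only 5"):
            local_surface_z(frame, (0.0, 0.0), UPPER)


class TestInsertionSeries:
    @pytest.mark.parametrize(
        "probe_z, upper_z, lower_z, expected",
        [
            (13.0, 19.0, -19.0, -6.0),  # below the outer surface: interior
            (22.0, 19.0, -19.0, 3.0),  # water side
            (-13.0, 19.0, -19.0, -6.0),  # lower monolayer, sign flipped
        ],
    )
    def test_sign_convention(self, probe_z, upper_z, lower_z, expected):
        frame = _simple_frame(
            upper_z=upper_z, lower_z=lower_z,
            probe={"PRB": np.array([[20.0, 20.0, probe_z]])},
        )
        (rec,) = insertion_series([frame], "PRB")
        assert rec.insertion == pytest.approx(expected)
        assert rec.monolayer == (UPPER if probe_z > 0 else LOWER)

    def test_missing_residue_skipped_with_warning(self, caplog):
        frames = [
            _simple_frame(probe={"PRB": np.array([[20.0, 20.0, 13.0]])}),
            _simple_frame(),
        ]
        frames[1].frame_index = 1
        with caplog.at_level("WARNING"):
            recs = insertion_series(frames, "PRB")
        assert len(recs) == 1
        assert "absent" in caplog.text


class TestAnnulusProfiles:
    def test_flat_membrane_every_bin_at_bulk(self):
        frame = _simple_frame(probe={"PEP": np.array([[20.0, 20.0, 0.0]])})
        prof = annulus_half_thickness([frame], "PEP")
        for m in (UPPER, LOWER):
            mu = prof.mean[m]
            assert np.allclose(mu[np.isfinite(mu)], 19.5)

    def test_dimple_recovered_within_sampling_error(self):
        spec = SyntheticFrameSpec(
            n_lipids=256, amplitude=-3.0, sigma=3.0, noise_sd=0.5, seed=4
        )
        frames = generate_membrane_frames(spec, 60)
        prof = annulus_half_thickness(frames, "PRB", bin_width=1.0)
        truth = expected_half_thickness(spec, prof.bin_edges)
        for m in (UPPER, LOWER):
            mu, sem = prof.mean[m], prof.sem[m]
            ok = np.isfinite(mu) & np.isfinite(sem) & (sem > 0)
            assert ok.sum() > 20
            # 4 SEM: simultaneous bound over ~90 bins
            assert np.all(np.abs(mu[ok] - truth[ok]) <= 4.0 * sem[ok])

    def test_deformation_of_flat_membrane_is_zero(self):
        spec = SyntheticFrameSpec(n_lipids=256, amplitude=0.0, noise_sd=0.4, seed=8)
        frames = generate_membrane_frames(spec, 40)
        prof = annulus_half_thickness(frames, "PRB")
        deform = local_deformation(prof, bulk_cutoff=15.0)
        for m in (UPPER, LOWER):
            d, sem = deform.deformation[m], deform.sem[m]
            ok = np.isfinite(d) & np.isfinite(sem) & (sem > 0)
            assert np.all(np.abs(d[ok]) <= 4.0 * sem[ok])

    def test_z_translation_leaves_deformation_unchanged(self):
        spec = SyntheticFrameSpec(n_lipids=144, amplitude=-2.0, noise_sd=0.3, seed=5)
        frames = generate_membrane_frames(spec, 10)
        shifted = [
            MembraneFrame(
                f.phosphate_xyz + np.array([0.0, 0.0, 7.0]),
                f.phosphate_element,
                f.phosphate_monolayer,
                {k: v + np.array([0.0, 0.0, 7.0]) for k, v in f.probes.items()},
                f.frame_index,
                f.box,
            )
            for f in frames
        ]
        d1 = local_deformation(annulus_half_thickness(frames, "PRB"), 15.0)
        d2 = local_deformation(annulus_half_thickness(shifted, "PRB"), 15.0)
        for m in (UPPER, LOWER):
            a, b = d1.deformation[m], d2.deformation[m]
            ok = np.isfinite(a)
            assert np.allclose(a[ok], b[ok], atol=1e-9)

    def test_sem_shrinks_with_frames(self):
        spec = SyntheticFrameSpec(n_lipids=144, amplitude=0.0, noise_sd=0.5, seed=6)
        few = annulus_half_thickness(generate_membrane_frames(spec, 10), "PRB")
        spec2 = SyntheticFrameSpec(n_lipids=144, amplitude=0.0, noise_sd=0.5, seed=7)
        many = annulus_half_thickness(generate_membrane_frames(spec2, 40), "PRB")
        m_few = np.nanmedian(few.sem[UPPER])
        m_many = np.nanmedian(many.sem[UPPER])
        assert m_many < m_few / 1.5  # ~1/sqrt(4) expected

    def test_bulk_cutoff_beyond_profile_fails(self):
        frame = _simple_frame(n_side=2, probe={"PEP": np.array([[5.0, 5.0, 0.0]])})
        prof = annulus_half_thickness([frame], "PEP")
        with pytest.raises(ValueError):
            local_deformation(prof, bulk_cutoff=1000.0)
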
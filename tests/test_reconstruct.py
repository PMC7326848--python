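import numpy as np
import pandas as pd
import pytest

from ops_imaging.detector import DetectorResponseConfig, simulate_triples, smear_triples
from ops_imaging.generator import SourceSpec, generate_events
from ops_imaging.physics import CONSTANTS
from ops_imaging.reconstruct import (
    ImageGrid,
    VolumeImage,
    direct_image,
    estimate_psf,
    reconstruct_annihilation,
    reconstruct_records,
    tof_fbp,
)

C = CONSTANTS.c


def make_triple(r1, t1, r2, t2, rp=(0.0, 43.0, 10.0), tp=0.0):
    return pd.DataFrame({
        "a1_x": [r1[0]], "a1_y": [r1[1]], "a1_z": [r1[2]], "a1_t_ps": [t1],
        "a2_x": [r2[0]], "a2_y": [r2[1]], "a2_z": [r2[2]], "a2_t_ps": [t2],
        "p_x": [rp[0]], "p_y": [rp[1]], "p_z": [rp[2]], "p_t_ps": [tp],
    })


@pytest.fixture(scope="module")
def noiseless_records():
    rng = np.random.default_rng(20)
    events = generate_events([SourceSpec(1, (15.0, -3.0, 40.0), 2.5)],
                             300_000, rng)
    cfg = DetectorResponseConfig(crt_ps=0.0, spatial_fwhm_cm=0.0)
    triples, _ = simulate_triples(events, config=cfg, rng=rng)
    return reconstruct_records(triples)


class TestAnnihilationReconstruction:
    def test_noiseless_identity(self, noiseless_records):
        rec = noiseless_records
        pos_err = np.abs(rec[["rec_x", "rec_y", "rec_z"]].to_numpy()
                         - rec[["x", "y", "z"]].to_numpy()).max()
        dt_err = np.abs(rec["lifetime_rec_ps"] - rec["lifetime_ps"]).max()
        assert pos_err < 1e-9
        assert dt_err < 1e-8
        assert np.abs(rec["annih_t_rec_ps"] - rec["lifetime_ps"]).max() < 1e-8

    @pytest.mark.parametrize("dt_ps, shift_mm", [(30.0, 4.5), (10.0, 1.5)])
    def test_time_shift_moves_point_along_lor(self, dt_ps, shift_mm):
        # symmetric transverse LOR through the origin
        base = make_triple((-44.0, 0.0, 0.0), 44.0 / C, (44.0, 0.0, 0.0), 44.0 / C)
        pos0, _ = reconstruct_annihilation(base)
        pert = make_triple((-44.0, 0.0, 0.0), 44.0 / C,
                           (44.0, 0.0, 0.0), 44.0 / C + dt_ps)
        pos1, _ = reconstruct_annihilation(pert)
        delta = (pos1 - pos0)[0]
        # a later arrival at hit 2 pulls the point towards hit 1 (negative x)
        assert delta[0] == pytest.approx(-C * dt_ps / 2.0, rel=1e-12)
        assert delta[0] == pytest.approx(-shift_mm / 10.0, abs=5e-3)
        assert abs(delta[1]) < 1e-12 and abs(delta[2]) < 1e-12

    def test_offset_clamped_to_chord(self):
        tr = make_triple((-44.0, 0.0, 0.0), 0.0, (44.0, 0.0, 0.0), 1e6)
        pos, _ = reconstruct_annihilation(tr)
        assert pos[0, 0] == pytest.approx(-44.0)

    def test_degenerate_lor_raises(self):
        tr = make_triple((44.0, 0.0, 0.0), 0.0, (44.0, 0.0, 0.0), 0.0)
        with pytest.raises(ValueError):
            reconstruct_annihilation(tr)


class TestDirectImage:
    def test_count_conservation(self, noiseless_records):
        grid = ImageGrid.centered((15.0, -3.0, 40.0), (5.0, 5.0, 5.0),
                                  (0.5, 0.5, 0.5))
        img = direct_image(noiseless_records, grid)
        assert img.values.sum() == len(noiseless_records)
        assert (img.values >= 0).all()

    def test_point_source_lands_in_source_voxel(self, noiseless_records):
        grid = ImageGrid.centered((15.0, -3.0, 40.0), (5.0, 5.0, 5.0),
                                  (0.5, 0.5, 0.5))
        img = direct_image(noiseless_records, grid)
        np.testing.assert_allclose(img.argmax_position(), (15.0, -3.0, 40.0),
                                   atol=0.26)

    def test_radial_psf_grows_with_crt(self, source6_raw):
        rng = np.random.default_rng(21)
        grid = ImageGrid.centered((20.0, 0.0, 75.0), (6.5, 10.0, 6.5),
                                  (0.5, 0.5, 0.5))
        widths = []
        for crt in (10.0, 140.0, 500.0):
            cfg = DetectorResponseConfig(crt_ps=crt)
            rec = reconstruct_records(smear_triples(source6_raw, cfg, rng))
            widths.append(estimate_psf(direct_image(rec, grid),
                                       (20.0, 0.0, 75.0)).radial_fwhm_mm)
        assert widths[0] < widths[1] < widths[2]


class TestTofFbp:
    def test_peak_at_source_across_crt(self, source6_raw):
        rng = np.random.default_rng(22)
        grid = ImageGrid.centered((20.0, 0.0, 75.0), (3.0, 3.0, 3.0),
                                  (0.18, 0.18, 0.29))
        for crt in (10.0, 500.0):
            cfg = DetectorResponseConfig(crt_ps=crt)
            sm = smear_triples(source6_raw, cfg, rng)
            img = tof_fbp(sm, grid, crt)
            np.testing.assert_allclose(img.argmax_position(), (20.0, 0.0, 75.0),
                                       atol=0.3)

    def test_psf_stable_across_crt(self, source6_raw):
        # TOF-FBP resolution is set by the detector, not the TOF kernel:
        # every CRT's PSF stays within 25% of the across-CRT mean
        rng = np.random.default_rng(23)
        grid = ImageGrid.centered((20.0, 0.0, 75.0), (3.0, 3.0, 3.0),
                                  (0.18, 0.18, 0.29))
        widths = []
        for crt in (10.0, 50.0, 140.0, 500.0):
            cfg = DetectorResponseConfig(crt_ps=crt)
            sm = smear_triples(source6_raw, cfg, rng)
            img = tof_fbp(sm, grid, crt)
            psf = estimate_psf(img, (20.0, 0.0, 75.0), window_cm=6.0)
            widths.append(psf.radial_fwhm_mm)
        mean = np.mean(widths)
        assert np.all(np.abs(np.array(widths) - mean) < 0.25 * mean)

    def test_empty_records_rejected(self):
        grid = ImageGrid.centered((0, 0, 0), (2, 2, 2), (0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            tof_fbp(pd.DataFrame(columns=["a1_x"]), grid, 100.0)


class TestPsfEstimation:
    def test_recovers_known_gaussian_blob(self):
        rng = np.random.default_rng(24)
        sigma = 0.8  # cm
        pts = rng.normal(0.0, sigma, (400_000, 3))
        rec = pd.DataFrame({"rec_x": pts[:, 0], "rec_y": pts[:, 1],
                            "rec_z": pts[:, 2]})
        grid = ImageGrid.centered((0.0, 0.0, 0.0), (5.0, 5.0, 5.0),
                                  (0.25, 0.25, 0.25))
        img = direct_image(rec, grid)
        psf = estimate_psf(img, (0.0, 0.0, 0.0), window_cm=9.0)
        expected = 2.3548 * sigma * 10.0
        assert psf.radial_fwhm_mm == pytest.approx(expected, rel=0.02)
        assert psf.axial_fwhm_mm == pytest.approx(expected, rel=0.02)

    def test_empty_window_raises(self):
        grid = ImageGrid.centered((0, 0, 0), (2, 2, 2), (0.5, 0.5, 0.5))
        img = VolumeImage(grid, np.full(grid.shape, np.nan))
        with pytest.raises(ValueError):
            estimate_psf(img, (0.0, 0.0, 0.0))


class TestNiftiExport:
    def test_round_trip_header(self, tmp_path):
        import nibabel as nib

        grid = ImageGrid.centered((1.0, 2.0, 3.0), (2.0, 2.0, 2.0),
                                  (0.5, 0.5, 0.5))
        img = VolumeImage(grid, np.random.default_rng(0).random(grid.shape),
                          {"crt_ps": 50.0})
        path = tmp_path / "img.nii"
        img.to_nifti(str(path))
        loaded = nib.load(str(path))
        np.testing.assert_allclose(loaded.header.get_zooms(), (5.0, 5.0, 5.0))
        np.testing.assert_allclose(np.asarray(loaded.dataobj), img.values,
                                   rtol=1e-6)
        assert (tmp_path / "img.nii.json").exists()
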
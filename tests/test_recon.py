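"""Pixel realignment, cLFM upsampling, DAO and iterative tomography."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from cslfm import (ConfocalConfig, MultiViewStack, RawScanSequence,
                   SpatialAngularPSF, VolumeGrid, airy_unit, apply_confocal,
                   clfm_upsample, dao_estimate, forward_views,
                   iterative_tomography, pixel_realign, reconstruct_pipeline,
                   scan_offsets_um, simulate_raw_scan)
from cslfm.metrics import fwhm, snr


def make_sequence(config, frames):
    return RawScanSequence(data=frames,
                           phase_offsets_um=scan_offsets_um(config),
                           pixel_um=config.pixel_mla_um, config=config,
                           mode="slfm")


class TestPixelRealign:
    def test_energy_conserved_and_matches_loop_oracle(self, small_config):
        rng = np.random.default_rng(0)
        s, nv, nl = small_config.scan_s, small_config.n_views, 4
        frames = rng.random((s, s, nl * nv, nl * nv))
        views = pixel_realign(make_sequence(small_config, frames),
                              small_config)
        assert views.data.sum() == pytest.approx(frames.sum(), rel=1e-9)
        oracle = np.zeros_like(views.data)
        for my in range(s):
            for mx in range(s):
                for iy in range(nl):
                    for a in range(nv):
                        for ix in range(nl):
                            for b in range(nv):
                                oracle[a, b, iy * s + (s - 1 - my),
                                       ix * s + (s - 1 - mx)] = \
                                    frames[my, mx, iy * nv + a, ix * nv + b]
        assert np.array_equal(oracle, views.data)

    def test_scanned_lattice_refines_sampling(self, small_config):
        s, nv, nl = small_config.scan_s, small_config.n_views, 4
        frames = np.ones((s, s, nl * nv, nl * nv))
        views = pixel_realign(make_sequence(small_config, frames),
                              small_config)
        assert views.data.shape[-1] == nl * s
        assert views.step_um == pytest.approx(small_config.mla_pitch_um / s)

    def test_incomplete_lattice_refused(self, small_config):
        seq = make_sequence(small_config, np.ones((3, 3, 20, 20)))
        seq.phase_offsets_um = seq.phase_offsets_um + 1.0
        with pytest.raises(ValueError, match="lattice"):
            pixel_realign(seq, small_config)


class TestClfmUpsample:
    def _views(self, config, data):
        return MultiViewStack(data=data, step_um=config.mla_pitch_um,
                              config=config, mode="clfm",
                              meta={"unscanned": True})

    def test_constant_maps_to_constant(self, small_config):
        v = self._views(small_config, np.full((5, 5, 12, 12), 3.5))
        out = clfm_upsample(v, 3)
        assert np.allclose(out.data, 3.5, rtol=1e-12)
        assert out.data.shape[-2:] == (36, 36)
        assert out.step_um == pytest.approx(small_config.mla_pitch_um / 3)

    def test_reproduces_cubic_polynomials_interior(self, small_config):
        # independent oracle: evaluate the cubic on the fine grid directly
        # the spline boundary condition error decays ~0.27^d with the
        # distance d in coarse cells, so compare deep in the interior
        n, s = 40, 3
        i = np.arange(n) - (n - 1) / 2
        poly = lambda t: 2.0 + 0.05 * t + 0.01 * t ** 2 - 0.0008 * t ** 3
        img = poly(i)[:, None] * poly(i)[None, :]
        v = self._views(small_config,
                        np.broadcast_to(img, (5, 5, n, n)).copy())
        out = clfm_upsample(v, s)
        nf = n * s
        jf = (np.arange(nf) - (nf - 1) / 2) / s
        expected = poly(jf)[:, None] * poly(jf)[None, :]
        inner = slice(45, -45)
        assert np.allclose(out.data[2, 2][inner, inner],
                           expected[inner, inner], rtol=1e-6)

    def test_rejects_bad_inputs(self, small_config):
        v = self._views(small_config, np.ones((5, 5, 8, 8)))
        with pytest.raises(ValueError, match=">= 1"):
            clfm_upsample(v, 0)
        scanned = MultiViewStack(np.ones((5, 5, 8, 8)), step_um=10.0,
                                 config=small_config, mode="slfm")
        with pytest.raises(ValueError, match="unscanned"):
            clfm_upsample(scanned, 3)


@pytest.fixture(scope="module")
def textured_views(recon_psf, recon_config):
    rng = np.random.default_rng(5)
    nz = len(recon_psf.z_um)
    n = recon_psf.data.shape[-1]
    vol = np.zeros((nz, n, n))
    iz0 = nz // 2
    for _ in range(30):
        vol[iz0, rng.integers(6, n - 6), rng.integers(6, n - 6)] += \
            rng.uniform(0.5, 1.5)
    vg = VolumeGrid(vol, recon_psf.z_um, recon_psf.step_obj_um)
    return forward_views(vg, recon_psf)


class TestDAO:
    def test_aberration_free_views_give_zero_shifts(self, textured_views,
                                                    recon_psf):
        sm = dao_estimate(textured_views, recon_psf)
        assert np.all(sm.magnitude_um() <= 0.1 * recon_psf.step_obj_um)

    def test_recovers_imposed_pupil_tilt(self, textured_views, recon_psf):
        tilt = 0.5  # µm of disparity per view index
        nv = textured_views.n_views
        idx = np.arange(nv) - nv // 2
        step = textured_views.step_obj_um
        data = np.empty_like(textured_views.data)
        for v in range(nv):
            for u in range(nv):
                data[v, u] = ndimage.shift(
                    textured_views.data[v, u],
                    (tilt * idx[v] / step, tilt * idx[u] / step), order=1)
        shifted = MultiViewStack(np.maximum(data, 0),
                                 step_um=textured_views.step_um,
                                 config=textured_views.config, mode="slfm")
        sm = dao_estimate(shifted, recon_psf)
        for v in range(nv):
            for u in range(nv):
                if v == nv // 2 and u == nv // 2:
                    continue
                expect = np.hypot(tilt * idx[v], tilt * idx[u])
                got = sm.magnitude_um()[v, u]
                assert got == pytest.approx(expect, rel=0.10)

    def test_equivariant_under_global_translation(self, textured_views,
                                                  recon_psf):
        rolled = MultiViewStack(np.roll(textured_views.data, (3, 2),
                                        axis=(2, 3)),
                                step_um=textured_views.step_um,
                                config=textured_views.config, mode="slfm")
        a = dao_estimate(textured_views, recon_psf)
        b = dao_estimate(rolled, recon_psf)
        assert np.allclose(a.dy_um, b.dy_um, atol=1e-6)
        assert np.allclose(a.dx_um, b.dx_um, atol=1e-6)

    def test_featureless_views_warn_and_return_zero(self, recon_config,
                                                    recon_psf):
        flat = MultiViewStack(np.zeros((5, 5, 31, 31)), step_um=recon_psf.
                              step_um, config=recon_config, mode="slfm")
        with pytest.warns(UserWarning, match="featureless"):
            sm = dao_estimate(flat, recon_psf)
        assert not sm.magnitude_um().any()


class TestIterativeTomography:
    def test_delta_psf_converges_to_measurement(self, small_config):
        # single-view identity system: the RL fixed point is the data
        rng = np.random.default_rng(2)
        img = rng.random((21, 21)) + 0.1
        kern = np.zeros((1, 1, 1, 5, 5))
        kern[0, 0, 0, 2, 2] = 1.0
        psf = SpatialAngularPSF(data=kern, z_um=np.array([0.0]),
                                step_um=small_config.mla_pitch_um / 3,
                                config=small_config)
        views = MultiViewStack(img[None, None], step_um=psf.step_um,
                               config=small_config, mode="slfm")
        res = iterative_tomography(views, psf, n_iter=10)
        assert np.allclose(res.volume.data[0], img, rtol=1e-3)

    def test_bead_localized_within_one_voxel(self, recon_psf):
        nz = len(recon_psf.z_um)
        n = recon_psf.data.shape[-1]
        vol = np.zeros((nz, n, n))
        true = (nz // 2 + 1, n // 2 + 5, n // 2 - 7)
        vol[true] = 1.0
        vg = VolumeGrid(vol, recon_psf.z_um, recon_psf.step_obj_um)
        res = iterative_tomography(forward_views(vg, recon_psf), recon_psf,
                                   n_iter=30)
        got = np.unravel_index(res.volume.data.argmax(),
                               res.volume.data.shape)
        assert max(abs(g - t) for g, t in zip(got, true)) <= 1
        fid = np.array(res.fidelity)
        assert np.all(np.diff(fid) <= np.abs(fid[:-1]) * 1e-3 + 1e-9)
        assert res.volume.data.min() >= 0

    def test_reconstructed_bead_near_diffraction_limited(self, recon_psf,
                                                         recon_config):
        nz = len(recon_psf.z_um)
        n = recon_psf.data.shape[-1]
        vol = np.zeros((nz, n, n))
        vol[nz // 2, n // 2, n // 2] = 1.0
        vg = VolumeGrid(vol, recon_psf.z_um, recon_psf.step_obj_um)
        res = iterative_tomography(forward_views(vg, recon_psf), recon_psf,
                                   n_iter=30)
        w = fwhm(res.volume.data[nz // 2][n // 2],
                 step_um=recon_psf.step_obj_um)
        limit = 0.51 * recon_config.wavelength_um / recon_config.na
        assert w == pytest.approx(limit, rel=0.25)

    def test_zero_iterations_return_initialization(self, textured_views,
                                                   recon_psf):
        res = iterative_tomography(textured_views, recon_psf, n_iter=0)
        assert len(res.fidelity) == 0
        flat = res.volume.data
        assert np.allclose(flat, flat.flat[0])
        res_b = iterative_tomography(textured_views, recon_psf, n_iter=0,
                                     init="backproject")
        assert not np.allclose(res_b.volume.data, res_b.volume.data.flat[0])

    def test_matched_confocal_psf_avoids_out_of_focus_artifacts(
            self, small_psf, small_config):
        # reconstructing confocal data with the unmodulated PSF misplaces
        # energy into object-empty planes adjacent to the focus
        conf = ConfocalConfig(slit_width_um=2 * airy_unit(small_config))
        mod = apply_confocal(small_psf, conf)
        nz = len(small_psf.z_um)
        n = small_psf.data.shape[-1]
        c = n // 2
        vol = np.zeros((nz, n, n))
        vol[nz // 2, c - 4, c - 4] = 1.0
        vol[0, c - 8, c + 8] = 1.0
        vol[-1, c + 6, c + 6] = 1.0
        vg = VolumeGrid(vol, small_psf.z_um, small_psf.step_obj_um)
        views = forward_views(vg, mod)
        matched = iterative_tomography(views, mod, n_iter=20)
        with pytest.warns(UserWarning, match="unmodulated"):
            mismatched = iterative_tomography(views, small_psf, n_iter=20)
        truth = vol / vol.max()
        snr_m = snr(truth, matched.volume.data / matched.volume.data.max())
        snr_u = snr(truth,
                    mismatched.volume.data / mismatched.volume.data.max())
        assert snr_m > snr_u + 3.0
        empty = [iz for iz in range(nz) if iz not in (0, nz // 2, nz - 1)]
        e_m = matched.volume.data[empty].sum() / matched.volume.data.sum()
        e_u = mismatched.volume.data[empty].sum() / \
            mismatched.volume.data.sum()
        assert e_m < e_u


class TestPipeline:
    def test_both_modes_localize_same_voxel(self, small_chain, small_config,
                                            small_psf):
        hs = small_chain[1]
        n = small_psf.data.shape[-1]
        vol = np.zeros((7, n, n))
        true = (3, n // 2 + 3, n // 2 - 2)
        vol[true] = 1.0
        vg = VolumeGrid(vol, small_psf.z_um, small_psf.step_obj_um)
        conf = ConfocalConfig.from_au(small_config, 11.0)
        seq_s = simulate_raw_scan(vg, hs, small_config, mode="slfm")
        seq_c = simulate_raw_scan(vg, hs, small_config, conf, mode="cslfm")
        mod = apply_confocal(small_psf, conf, exact_offset=True)
        res_s = reconstruct_pipeline(seq_s, small_psf, n_iter=15)
        res_c = reconstruct_pipeline(seq_c, mod, n_iter=15)
        loc_s = np.unravel_index(res_s.volume.data.argmax(), vol.shape)
        loc_c = np.unravel_index(res_c.volume.data.argmax(), vol.shape)
        assert loc_s == loc_c == true
        assert "ws_um" in res_c.log
        assert res_c.log["ws_um"] == pytest.approx(conf.slit_width_um)
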
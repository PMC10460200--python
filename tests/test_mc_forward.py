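import numpy as np
import pytest

from fdot import mc
from fdot.geometry import OptodeLayout, VoxelHeadModel
from fdot.measurement import FDMeasurement
from fdot.optical import OpticalTable, Tissue, TissueOpticalProperties

from conftest import homogeneous_table


def make_records(paths, tofs, det_ids, n_voxels=4, n_launched=1):
    """Hand-built records: paths is a list of {voxel: length} dicts."""
    indptr = [0]
    vox, plen = [], []
    for p in paths:
        for v, l in p.items():
            vox.append(v)
            plen.append(l)
        indptr.append(len(vox))
    return mc.PhotonRecords(
        det_id=np.array(det_ids, np.int32), tof=np.array(tofs, float),
        launch_idx=np.arange(len(paths)), indptr=np.array(indptr, np.int64),
        voxel_idx=np.array(vox, np.int64), path_len=np.array(plen, float),
        n_launched=n_launched, grid_shape=(n_voxels, 1, 1), spacing=1.0,
        seed=0)


class TestDetectedWeight:
    def test_zero_absorption_gives_unit_weight(self):
        rec = make_records([{0: 5.0, 1: 3.0}], [0.1], [0])
        assert mc.detected_weight(rec, np.zeros(4))[0] == 1.0

    def test_single_tissue_hand_value(self):
        """mu_a = 0.01 /mm over 10 mm: w = e^-0.1 = 0.904837..."""
        rec = make_records([{2: 10.0}], [0.1], [0])
        mu = np.zeros(4)
        mu[2] = 0.01
        assert mc.detected_weight(rec, mu)[0] == pytest.approx(
            np.exp(-0.1), rel=1e-12)

    def test_weight_decreases_with_absorption(self):
        rec = make_records([{0: 2.0, 1: 7.0}], [0.1], [0])
        mu = np.array([0.01, 0.02, 0.0, 0.0])
        w0 = mc.detected_weight(rec, mu)[0]
        mu2 = mu.copy()
        mu2[1] += 0.005
        assert mc.detected_weight(rec, mu2)[0] < w0

    def test_negative_absorption_rejected(self):
        rec = make_records([{0: 2.0}], [0.1], [0])
        with pytest.raises(ValueError):
            mc.detected_weight(rec, np.array([-0.01, 0, 0, 0]))


class TestFDMeasurement:
    def test_two_photon_hand_example(self):
        """(w, t) = (0.9, 0.1 ns), (0.5, 0.2 ns) at f = 0.1 GHz."""
        rec = make_records([{0: 1.0}, {1: 1.0}], [0.1, 0.2], [0, 0])
        mu = np.zeros(4)
        # weights via absorption: choose mu_a * l to give 0.9 and 0.5
        rec.path_len[:] = [-np.log(0.9), -np.log(0.5)]
        mu = np.array([1.0, 1.0, 0.0, 0.0])
        m = mc.fd_measurement(rec, mu, 0.1, n_d=1)[0]
        X = 0.9 * np.cos(0.02 * np.pi) + 0.5 * np.cos(0.04 * np.pi)
        Y = 0.9 * np.sin(0.02 * np.pi) + 0.5 * np.sin(0.04 * np.pi)
        assert m.X == pytest.approx(X, rel=1e-12)
        assert m.Y == pytest.approx(Y, rel=1e-12)
        assert m.phase == pytest.approx(np.arctan2(Y, X), rel=1e-12)
        assert m.phase == pytest.approx(0.08527, abs=5e-5)

    def test_cw_limit(self):
        rec = make_records([{0: 1.0}, {1: 2.0}], [0.3, 0.5], [0, 0])
        mu = np.full(4, 0.01)
        m = mc.fd_measurement(rec, mu, 0.0, n_d=1)[0]
        assert m.Y == 0.0
        assert m.phase == 0.0
        w = mc.detected_weight(rec, mu)
        assert m.X == pytest.approx(w.sum() / rec.n_launched)

    def test_zero_detection_flagged_invalid(self):
        rec = make_records([{0: 1.0}], [0.1], [0])
        ms = mc.fd_measurement(rec, np.zeros(4), 0.1, n_d=2)
        assert not ms[1].valid  # detector 1 saw nothing

    def test_phase_slope_at_zero_frequency(self):
        """dphi/df at f=0+ equals 2 pi <t>_w (weighted mean time)."""
        rec = make_records([{0: 1.0}, {1: 2.0}], [0.3, 0.7], [0, 0])
        mu = np.full(4, 0.05)
        w = mc.detected_weight(rec, mu)
        t_mean = (w * rec.tof).sum() / w.sum()
        eps = 1e-7
        m = mc.fd_measurement(rec, mu, eps, n_d=1)[0]
        assert m.phase / eps == pytest.approx(2 * np.pi * t_mean, rel=1e-6)


class TestTransport:
    def test_ballistic_nonscattering_slab(self):
        """mu_s = 0, matched index: every photon crosses the slab and is
        detected with path ~ thickness and t = l n / c."""
        labels = np.ones((40, 40, 20), np.int16)
        head = VoxelHeadModel(labels, 1.0)
        opt = homogeneous_table(mu_a=0.01, mu_s=0.0, g=0.0, n=1.0)
        lay = OptodeLayout(np.array([[20.0, 20.0, 20.0]]),
                           np.array([[20.0, 20.0, 0.0]]),
                           launch_target=np.array([20.0, 20.0, -1000.0]))
        rec = mc.transport(head, opt, lay, 0, 2000, seed=5)
        assert rec.n_detected == 2000
        paths = rec.total_paths()
        assert np.all(np.abs(paths - 20.0) < 0.01)
        assert np.allclose(rec.tof, paths * 1.0 / 299.792458)

    def test_energy_bookkeeping(self, slab_records):
        fates = slab_records.fate_counts
        assert fates.sum() == slab_records.n_launched
        assert fates[0] == slab_records.n_detected

    def test_partial_paths_sum_to_tissue_totals(self, slab, slab_records):
        head, _, _ = slab
        per_tissue = slab_records.per_tissue_paths(head.labels)
        total = sum(per_tissue.values())
        assert np.allclose(total, slab_records.total_paths(), rtol=1e-12)

    def test_determinism_and_strict_replay(self, slab, slab_records):
        head, optics, layout = slab
        rec2 = mc.transport(head, optics, layout, 0, 300_000, seed=3)
        assert np.array_equal(rec2.path_len, slab_records.path_len)
        rep = mc.replay_transport(slab_records, head, optics, layout)
        assert np.array_equal(rep.det_id, slab_records.det_id)
        assert np.array_equal(rep.tof, slab_records.tof)
        assert np.array_equal(rep.voxel_idx, slab_records.voxel_idx)
        assert np.array_equal(rep.path_len, slab_records.path_len)

    def test_semi_infinite_cw_slope_matches_diffusion_theory(self):
        """CW reflectance vs SDS on a homogeneous half-space: the
        ln(R) slope over SDS 15-30 mm agrees with the extrapolated-
        boundary diffusion solution within 5%."""
        labels = np.ones((100, 100, 45), np.int16)
        head = VoxelHeadModel(labels, 1.0)
        mu_a, mu_sp, n_med = 0.01, 1.0, 1.4
        opt = homogeneous_table(mu_a=mu_a, mu_s=mu_sp, g=0.0, n=n_med)
        sds = np.array([15.0, 18.0, 21.0, 24.0, 27.0, 30.0])
        c = np.array([50.0, 50.0, 45.0])
        src = c[None, :]
        # four-fold symmetric detector rings for statistics
        det = []
        for dx, dy in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
            det += [[c[0] + dx * s, c[1] + dy * s, c[2]] for s in sds]
        lay = OptodeLayout(src, np.array(det),
                           launch_target=np.array([50.0, 50.0, -1e3]))
        rec = mc.transport(head, opt, lay, 0, 2_000_000, seed=17)
        mu = mc.mu_a_volume(head, opt)
        ms = mc.fd_measurement(rec, mu, 0.0, lay.n_d)
        X = np.array([m.X for m in ms]).reshape(4, len(sds)).sum(axis=0)
        lnR = np.log(X)
        slope_mc = np.polyfit(sds, lnR, 1)[0]

        # extrapolated-boundary point-source solution
        from fdot.optical import effective_reflection
        rho = effective_reflection(n_med, 1.0)
        D = 1.0 / (3.0 * (mu_a + mu_sp))
        mu_eff = np.sqrt(mu_a / D)
        z0 = 1.0 / (mu_a + mu_sp)
        zb = 2.0 * D * (1.0 + rho) / (1.0 - rho)
        r1 = np.sqrt(sds ** 2 + z0 ** 2)
        r2 = np.sqrt(sds ** 2 + (z0 + 2 * zb) ** 2)
        R_th = (z0 * (mu_eff + 1 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
                + (z0 + 2 * zb) * (mu_eff + 1 / r2) * np.exp(-mu_eff * r2) / r2 ** 2)
        slope_th = np.polyfit(sds, np.log(R_th), 1)[0]
        assert slope_mc == pytest.approx(slope_th, rel=0.05)

    def test_source_off_surface_rejected(self, slab):
        head, optics, _ = slab
        lay = OptodeLayout(np.array([[20.0, 20.0, 40.0]]),
                           np.array([[28.0, 20.0, 20.0]]),
                           launch_target=np.array([20.0, 20.0, 0.0]))
        with pytest.raises(ValueError):
            mc.transport(head, optics, lay, 0, 100, seed=1)


def test_records_roundtrip_through_container(tmp_path, slab_records):
    p = tmp_path / "records.npz"
    slab_records.save(p)
    back = mc.PhotonRecords.load(p)
    assert np.array_equal(back.det_id, slab_records.det_id)
    assert np.array_equal(back.path_len, slab_records.path_len)
    assert back.n_launched == slab_records.n_launched
    assert back.grid_shape == slab_records.grid_shape


class TestMeasurementVector:
    def test_vector_length_and_mask(self, slab):
        head, optics, layout = slab
        vec = mc.assemble_measurement_vector(head, optics, layout, 20_000,
                                             seed=2, f=0.1)
        assert vec.n_pairs == layout.n_s * layout.n_d
        assert vec.mask.sum() <= vec.n_pairs
        df = vec.to_dataframe()
        assert list(df.columns[:3]) == ["source", "detector", "sds"]

    def test_sds_mask_applied(self):
        """Pairs beyond the SDS cutoff are masked out consistently."""
        labels = np.ones((80, 40, 20), np.int16)
        head = VoxelHeadModel(labels, 1.0)
        opt = homogeneous_table()
        src = np.array([[10.0, 20.0, 20.0]])
        det = np.array([[30.0, 20.0, 20.0], [70.0, 20.0, 20.0]])
        lay = OptodeLayout(src, det, launch_target=np.array([10.0, 20.0, 0.0]))
        vec = mc.assemble_measurement_vector(head, opt, lay, 50_000, seed=4,
                                             f=0.1, sds_max=55.0)
        assert not vec.mask[1]  # SDS 60 mm pair excluded

    def test_mbll_reweighting_consistency(self, slab, slab_records):
        """Transporting once and reweighting with a different absorption
        equals the direct measurement with that absorption (trajectories
        are absorption-independent)."""
        head, optics, layout = slab
        mu1 = mc.mu_a_volume(head, optics)
        m1 = mc.fd_measurement(slab_records, mu1, 0.1, 1)[0]
        mu2 = mu1 * 1.7
        m2 = mc.fd_measurement(slab_records, mu2, 0.1, 1)[0]
        w1 = mc.detected_weight(slab_records, mu1)
        w2 = mc.detected_weight(slab_records, mu2)
        assert np.all(w2 <= w1)
        assert m2.X < m1.X

    def test_sampling_noise_scales_with_photon_count(self, slab):
        """Doubling the photon count shrinks the ln A standard error by
        about sqrt(2) (within 20% over 10 replicates)."""
        head, optics, layout = slab
        mu = mc.mu_a_volume(head, optics)

        def lnA_replicates(n, seeds):
            out = []
            for s in seeds:
                rec = mc.transport(head, optics, layout, 0, n, seed=s)
                out.append(mc.fd_measurement(rec, mu, 0.0, 1)[0].log_amplitude)
            return np.std(out, ddof=1)

        seeds = np.arange(100, 110)
        se1 = lnA_replicates(40_000, seeds)
        se2 = lnA_replicates(80_000, seeds + 50)
        assert se1 / se2 == pytest.approx(np.sqrt(2.0), rel=0.35)
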
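"""Reaction-diffusion sheet: Laplacian closure, integration, wave behavior."""

import numpy as np
import pytest

from ectopy.cell import CellParams, find_equilibria
from ectopy.heterogeneity import build_annulus, default_annulus
from ectopy.medium import (
    FieldState,
    MediumConfig,
    StimulusProtocol,
    detect_failures,
    integrate,
    laplacian,
    resting_field,
)


@pytest.fixture(scope="module")
def annulus_cfg():
    geo = build_annulus((40, 40), default_annulus(), bc="periodic")
    return MediumConfig(b_field=np.ones((40, 40)), c=0.7, bc="periodic", annulus=geo)


class TestLaplacian:
    @pytest.mark.parametrize("bc", ["neumann", "periodic"])
    def test_constant_field_vanishes(self, bc):
        cfg = MediumConfig.homogeneous((7, 9), bc=bc)
        assert np.abs(laplacian(np.full((7, 9), 2.5), cfg)).max() == 0.0

    def test_point_source_stencil(self):
        cfg = MediumConfig.homogeneous((5, 5))
        V = np.zeros((5, 5))
        V[2, 2] = 1.0
        L = laplacian(V, cfg)
        assert L[2, 2] == -4.0
        for i, j in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert L[i, j] == 1.0
        assert L[0, 0] == 0.0

    def test_fully_masked_cell_sees_zero(self, rng):
        mask = np.ones((4, 6, 6), dtype=bool)
        mask[:, 3, 3] = False  # cell receives nothing
        # symmetric closure on its neighbors
        mask[1, 2, 3] = False  # (2,3) does not receive from south (= cell (3,3))
        mask[0, 4, 3] = False
        mask[3, 3, 4] = False
        mask[2, 3, 2] = False
        cfg = MediumConfig(b_field=np.ones((6, 6)), flux_mask=mask, bc="neumann")
        V = rng.normal(size=(6, 6))
        assert laplacian(V, cfg)[3, 3] == 0.0

    def test_shape_mismatch_rejected(self):
        cfg = MediumConfig.homogeneous((5, 5))
        with pytest.raises(ValueError):
            laplacian(np.zeros((4, 5)), cfg)

    def test_asymmetric_mask_rejected(self):
        mask = np.ones((4, 6, 6), dtype=bool)
        mask[0, 3, 3] = False  # one-way masking
        with pytest.raises(ValueError):
            MediumConfig(b_field=np.ones((6, 6)), flux_mask=mask)

    @pytest.mark.parametrize("bc", ["neumann", "periodic"])
    def test_flux_antisymmetry(self, bc, rng, annulus_cfg):
        """No-flux closures conserve: the Laplacian sums to zero over the grid."""
        cfg = MediumConfig.homogeneous((12, 17), c=0.8, bc=bc)
        V = rng.normal(size=(12, 17))
        assert abs(cfg.c**2 * laplacian(V, cfg).sum()) < 1e-10
        V2 = np.random.default_rng(5).normal(size=annulus_cfg.shape)
        assert abs(annulus_cfg.c**2 * laplacian(V2, annulus_cfg).sum()) < 1e-10


class TestIntegration:
    def test_rest_is_equilibrium_of_coupled_system(self):
        cfg = MediumConfig.homogeneous((10, 10), b=1.0, c=1.0)
        state = resting_field(cfg)
        final, _ = integrate(state, cfg, None, 1000.0, dt=0.1)
        assert np.abs(final.V - state.V).max() < 1e-6
        assert np.abs(final.W - state.W).max() < 1e-6

    def test_annulus_interior_untouched(self, annulus_cfg):
        """Fully masked cells never change from their initial value."""
        state = resting_field(annulus_cfg)
        state.V[annulus_cfg.absent] = 0.42  # sentinel inside the hole
        stim = StimulusProtocol(2.0, 0.0, 15.0, "uniform")
        final, _ = integrate(state, annulus_cfg, stim, 100.0, dt=0.1)
        assert np.allclose(final.V[annulus_cfg.absent], 0.42)

    def test_monostable_wave_propagates_and_repolarizes(self):
        """A left-edge pulse produces a rightward planar pulse that fully repolarizes."""
        cfg = MediumConfig.homogeneous((30, 100), b=1.0, c=1.0)
        stim = StimulusProtocol(2.0, 0.0, 15.0, "left")
        state = resting_field(cfg)
        final, snaps = integrate(state, cfg, stim, 1800.0, dt=0.1,
                                 snapshot_times=[400.0, 800.0])
        # front advances monotonically to the right
        fronts = [np.where(s.V[15] > 0)[0].max() for s in snaps]
        assert fronts[0] < fronts[1]
        assert np.all(final.V < -1.0)

    def test_bistable_front_recruits_medium(self):
        cfg = MediumConfig.homogeneous((30, 60), b=2.0, c=1.0)
        stim = StimulusProtocol(2.0, 0.0, 15.0, "left")
        final, _ = integrate(resting_field(cfg), cfg, stim, 1200.0, dt=0.1)
        assert np.all(final.V > 1.0)
        assert final.V.mean() == pytest.approx(1.2, abs=0.05)

    def test_wave_speed_increases_with_coupling(self):
        arrivals = {}
        for c in (0.6, 0.8, 1.0):
            cfg = MediumConfig.homogeneous((10, 90), b=1.0, c=c)
            stim = StimulusProtocol(2.0, 0.0, 15.0, "left")
            _, snaps = integrate(resting_field(cfg), cfg, stim, 1800.0, dt=0.1,
                                 snapshot_times=np.arange(10, 1801, 10.0))
            arrivals[c] = next(s.t for s in snaps if s.V[5, 80] > 0)
        assert arrivals[0.6] > arrivals[0.8] > arrivals[1.0]

    def test_step_halving_convergence(self):
        """Halving dt moves the wave arrival time at column 80 by < 1%."""
        times = {}
        for dt in (0.1, 0.05):
            cfg = MediumConfig.homogeneous((10, 90), b=1.0, c=1.0)
            stim = StimulusProtocol(2.0, 0.0, 15.0, "left")
            _, snaps = integrate(resting_field(cfg), cfg, stim, 1400.0, dt=dt,
                                 snapshot_times=np.arange(2, 1400.1, 2.0))
            times[dt] = next(s.t for s in snaps if s.V[5, 80] > 0)
        assert abs(times[0.1] - times[0.05]) / times[0.05] < 0.01

    def test_fixed_step_matches_adaptive_reference(self):
        cfg = MediumConfig.homogeneous((8, 20), b=1.0, c=0.8)
        stim = StimulusProtocol(2.0, 0.0, 15.0, "left")
        f_rk4, _ = integrate(resting_field(cfg), cfg, stim, 120.0, dt=0.1)
        f_ref, _ = integrate(resting_field(cfg), cfg, stim, 120.0, method="adaptive")
        assert np.abs(f_rk4.V - f_ref.V).max() < 5e-3


class TestFailureDetection:
    def test_rest_and_upstate_snapshots(self, annulus_cfg):
        rest = resting_field(annulus_cfg)
        assert not detect_failures(rest, annulus_cfg).any()
        up = FieldState(np.full(annulus_cfg.shape, 1.2), np.zeros(annulus_cfg.shape), 0.0)
        fails = detect_failures(up, annulus_cfg)
        assert np.array_equal(fails, annulus_cfg.tissue)

    def test_threshold_is_respected(self):
        cfg = MediumConfig.homogeneous((5, 5))
        state = FieldState(np.full((5, 5), 0.5), np.zeros((5, 5)), 0.0)
        assert detect_failures(state, cfg, threshold=0.6).sum() == 0
        assert detect_failures(state, cfg, threshold=0.4).sum() == 25
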
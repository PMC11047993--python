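"""Flow-solver validation against analytic oracles, plus geometry and
census unit checks.  The array-scale droplet behaviour is exercised in
the acceptance suite; here every case runs on tiny grids in seconds."""

import numpy as np
import pytest

from synthchip.flow import (DomainRaster, FluidPair, SDAGeometry,
                            TwoPhaseSolver, build_geometry, droplet_census,
                            init_circle, make_box_domain, make_channel_domain)
from synthchip.flow.solver import PhaseState
import synthchip.flow._kernels as K


class TestGeometry:
    def test_default_raster_shape_and_density(self):
        geom, raster = build_geometry(SDAGeometry())
        assert geom.cells_per_pitch == 32
        assert geom.cell_um == pytest.approx(3.16 / 32)
        # 4x4 tiles plus injection/collection channels plus solid ring
        ny, nx = raster.shape
        assert ny == 4 * 32 + 2
        assert nx > 4 * 32
        assert len(raster.chamber_slices) == 16
        assert raster.valve_cells.sum() > 0
        assert raster.fluid.sum() > 0.2 * ny * nx

    def test_refining_preserves_topology(self):
        """Halving the cell size must reproduce the same geometry, just
        finer: fluid fraction and chamber area nearly unchanged."""
        g32, r32 = build_geometry(SDAGeometry(n_units_x=1, n_units_y=1))
        g64, r64 = build_geometry(
            SDAGeometry(n_units_x=1, n_units_y=1, cells_per_pitch=64)
        )
        assert g64.chamber_area_um2 == pytest.approx(g32.chamber_area_um2,
                                                     rel=0.02)

    def test_mirrored_rows_are_flipped(self):
        _, raster = build_geometry(SDAGeometry(n_units_x=1, n_units_y=2))
        (sy0, _), (sy1, _) = (raster.chamber_slices[(0, 0)],
                              raster.chamber_slices[(1, 0)])
        ny = raster.shape[0]
        # chamber of the flipped row sits mirrored within the row block
        # (tiles span rows 1 .. ny-2 inside the solid ring)
        assert sy0.start - 1 == (ny - 1) - sy1.stop

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            SDAGeometry(neck_width=0.7)   # neck wider than channel
        with pytest.raises(ValueError):
            SDAGeometry(valve_width=0.35)  # valve wider than neck
        with pytest.raises(ValueError):
            SDAGeometry(chamber_width=3.5)  # does not fit the pitch
        with pytest.raises(ValueError):
            SDAGeometry(unit_pitch=-1.0)

    def test_fluid_properties_validated(self):
        with pytest.raises(ValueError):
            FluidPair(sigma=-1.0)
        with pytest.raises(ValueError):
            FluidPair(theta_wall_deg=200.0)
        fl = FluidPair()
        assert fl.capillary_number() == pytest.approx(1.02375e-4)
        assert fl.reynolds_number() == pytest.approx(4e-3, rel=0.01)


@pytest.fixture(scope="module")
def poiseuille_solver():
    raster = make_channel_domain(64, 16, 0.1)
    solver = TwoPhaseSolver(raster)
    for _ in range(400):
        solver.step()
    return solver


class TestAnalyticOracles:
    def test_poiseuille_profile_within_2_percent(self, poiseuille_solver):
        """Single-phase pressure-driven channel flow must develop the
        parabolic profile (creeping-flow momentum balance oracle)."""
        s = poiseuille_solver
        u = s.state.u
        prof = u[1:-1, int(u.shape[1] * 0.75)]
        W = 1.6
        y = (np.arange(16) + 0.5) * 0.1
        exact = 6.0 * (y / W) * (1 - y / W)   # mean inflow = 1
        assert np.abs(prof - exact).max() / exact.max() < 0.02

    def test_divergence_free_to_solver_tolerance(self, poiseuille_solver):
        assert poiseuille_solver.divergence_max() < 1e-10

    def test_young_laplace_jump_within_10_percent(self):
        """Static droplet: pressure jump vs the 2D Young-Laplace closed
        form sigma/R."""
        raster = make_box_domain(32, 32, 0.1)
        solver = TwoPhaseSolver(raster)
        init_circle(solver, 1.6, 1.6, 0.8)
        for _ in range(5000):
            solver.step()
        st = solver.state
        area = st.dispersed_area(solver.h, raster.fluid)
        r_eff = np.sqrt(area / np.pi)
        expected = solver.inv_ca / r_eff
        dp = st.p[16, 16] - st.p[2:5, 2:5].mean()
        assert dp == pytest.approx(expected, rel=0.10)

    def test_advected_blob_conserves_area(self):
        """Rigid translation through one channel traverse: the
        conservative transport must keep the dispersed area to <1%."""
        raster = make_channel_domain(128, 40, 0.1)
        solver = TwoPhaseSolver(raster)
        init_circle(solver, 2.0, 2.0, 0.9)
        a0 = solver.state.dispersed_area(solver.h, raster.fluid)
        phi = solver.state.phi
        u = np.ones_like(solver.state.u)
        v = np.zeros_like(solver.state.v)
        out = np.zeros_like(phi)
        ct = raster.cell_type
        dt = 0.025
        for _ in range(int(6.4 / dt)):
            K.set_wall_ghost_phi(phi, ct, solver.costh, solver.h,
                                 solver._phig)
            phi, solver._phig = solver._phig, phi
            K.box_smooth(phi, solver._tmp)
            K.box_smooth(solver._tmp, solver._phis)
            K.normals_curvature(solver._phis, solver.h, solver._nxc,
                                solver._nyc, solver._gmag, solver._kappa)
            K.advect_phi(phi, u, v, dt, solver.h, solver.uft, solver.vft,
                         ct, solver._ubar_dyn, solver._vbar_dyn, out)
            phi, out = out, phi
            for _ in range(2):
                K.reinit_step(phi, solver._nxc, solver._nyc, 0.7, 0.25,
                              ct, solver._ubar_dyn, solver._vbar_dyn, out)
                phi, out = out, phi
        a1 = float(phi[raster.fluid].sum()) * solver.h**2
        assert abs(a1 - a0) / a0 < 0.01
        assert phi.min() > -1e-3 and phi.max() < 1 + 1e-3

    def test_phase_fraction_bounded_at_init(self):
        _, raster = build_geometry(SDAGeometry(n_units_x=1, n_units_y=1))
        solver = TwoPhaseSolver(raster)
        phi = solver.state.phi
        assert phi.min() >= 0.0 and phi.max() <= 1.0
        # dispersed fraction equals plug area over fluid area
        x0, x1 = raster.plug_x
        plug_cells = raster.fluid[:, x0:x1].sum()
        assert solver.initial_area == pytest.approx(
            plug_cells * solver.h**2
        )


class TestCensus:
    def _state(self, raster, phi):
        return PhaseState(phi=phi, u=np.zeros((raster.shape[0],
                                               raster.shape[1] + 1)),
                          v=np.zeros((raster.shape[0] + 1,
                                      raster.shape[1])),
                          p=np.zeros(raster.shape))

    def test_full_chamber_reports_chamber_area(self):
        geom, raster = build_geometry(SDAGeometry(n_units_x=1, n_units_y=1))
        phi = np.zeros(raster.shape)
        sy, sx = raster.chamber_slices[(0, 0)]
        phi[sy, sx] = 1.0
        census = droplet_census(self._state(raster, phi), raster)
        assert census.chamber_areas_um2[0, 0] == pytest.approx(
            geom.chamber_area_um2
        )
        assert census.n_droplets == 1
        assert census.chamber_confined.all()

    def test_half_filled_chamber_reports_half(self):
        geom, raster = build_geometry(SDAGeometry(n_units_x=1, n_units_y=1))
        phi = np.zeros(raster.shape)
        sy, sx = raster.chamber_slices[(0, 0)]
        phi[sy, sx] = 0.5
        census = droplet_census(self._state(raster, phi), raster)
        assert census.chamber_areas_um2[0, 0] == pytest.approx(
            geom.chamber_area_um2 / 2
        )

    def test_two_disjoint_blobs_counted(self):
        _, raster = build_geometry(SDAGeometry(n_units_x=2, n_units_y=1))
        phi = np.zeros(raster.shape)
        for key in ((0, 0), (0, 1)):
            sy, sx = raster.chamber_slices[key]
            phi[sy, sx] = 1.0
        census = droplet_census(self._state(raster, phi), raster)
        assert census.n_droplets == 2
        assert census.droplet_confined.all()

    def test_blob_spanning_outside_chamber_not_confined(self):
        _, raster = build_geometry(SDAGeometry(n_units_x=1, n_units_y=1))
        phi = np.zeros(raster.shape)
        phi[raster.fluid] = 1.0   # water everywhere: one huge component
        census = droplet_census(self._state(raster, phi), raster)
        assert census.n_droplets == 1
        assert not census.droplet_confined.any()
        assert not census.chamber_confined.any()
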
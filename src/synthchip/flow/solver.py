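"""Two-phase incompressible flow solver for the SDA unit array.

Model
-----
Creeping-flow (unsteady Stokes) momentum on a MAC grid — at the device
scale Re ~ 4e-3, so the convective term is dropped and density enters
only through the (negligible) transient term.  The interface is a
conservative level-set volume fraction ``phi`` (water = 1) with
continuum-surface-force surface tension, a static 135 degree contact
angle imposed through ghost values in the walls, and a Hysing-type
semi-implicit interfacial viscosity that removes the explicit capillary
time-step restriction (essential here: Ca ~ 1e-4 makes surface tension
four orders of magnitude stiffer than viscosity).

Everything is nondimensionalised with the cell problem's natural
scales: length 1 µm, velocity = injection speed (3 mm/s), so one time
unit is 1/3 ms and pressures are in units of mu_c U / L.

The solver is deterministic: identical inputs give identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import _kernels as K
from .fluids import FluidPair
from .geometry import DomainRaster, SDAGeometry, build_geometry

__all__ = ["PhaseState", "TwoPhaseSolver", "SolverDivergedError", "init_phases",
           "run_to_steady", "SteadyResult"]

U_REF_M_S = 3e-3   # injection speed: the velocity unit
L_REF_M = 1e-6     # 1 µm: the length unit


class SolverDivergedError(RuntimeError):
    """The time integration produced non-finite fields."""


@dataclass
class PhaseState:
    """Fields of the two-phase simulation (nondimensional units)."""

    phi: np.ndarray   # volume fraction of the dispersed phase, cells
    u: np.ndarray     # x-velocity at vertical faces (ny, nx+1)
    v: np.ndarray     # y-velocity at horizontal faces (ny+1, nx)
    p: np.ndarray     # pressure, cells
    t: float = 0.0
    n_steps: int = 0

    def dispersed_area(self, h: float, fluid: np.ndarray | None = None) -> float:
        """Dispersed-phase area in µm^2 (``fluid`` mask excludes the
        contact-angle ghost values stored in wall cells)."""
        phi = self.phi if fluid is None else self.phi[fluid]
        return float(phi.sum()) * h * h


class TwoPhaseSolver:
    """Time integrator bound to one rasterized domain and fluid pair."""

    def __init__(
        self,
        raster: DomainRaster,
        fluids: FluidPair | None = None,
        *,
        u_inlet: float = 1.0,
        cfl: float = 0.3,
        dt_max_cells: float = 0.25,
        beta_coeff: float = 1.0,
        eps_reinit: float = 0.7,
        n_reinit: int = 2,
        cg_tol: float = 1e-7,
        cg_maxit: int = 500,
        n_kappa_smooth: int = 3,
        kappa_max_cells: float = 0.5,
        debris_interval: int = 25,
        debris_min_cells: int = 5,
    ) -> None:
        self.raster = raster
        self.fluids = fluids or FluidPair()
        self.h = raster.h
        self.u_inlet = u_inlet
        self.cfl = cfl
        self.dt_max = dt_max_cells * self.h / max(u_inlet, 1e-12)
        self.beta_coeff = beta_coeff
        self.eps_reinit = eps_reinit
        self.n_reinit = n_reinit
        self.cg_tol = cg_tol
        self.cg_maxit = cg_maxit
        self.n_kappa_smooth = n_kappa_smooth
        self.kappa_max_cells = kappa_max_cells
        # tiny detached fragments (interface debris) carry grid-scale
        # curvature and inject force noise; they are removed periodically
        # and booked against the mass audit
        self.debris_interval = debris_interval
        self.debris_min_cells = debris_min_cells

        fl = self.fluids
        self.inv_ca = fl.sigma / (fl.mu_c * U_REF_M_S)
        self.re = fl.rho_c * U_REF_M_S * L_REF_M / fl.mu_c
        self.mu_ratio = fl.viscosity_ratio
        self.costh = math.cos(math.radians(fl.theta_wall_deg))

        self._setup_faces()
        self._setup_passages()
        self._setup_poisson(self._ublock, self._vblock)
        self._alloc_work()
        self.state = init_phases(raster, plug=raster.plug_x is not None)
        self._apply_inlet_bc(self.state.u)
        self.outflux_total = 0.0
        self.clipped_total = 0.0
        self.max_overshoot = 0.0
        self.initial_area = self.state.dispersed_area(self.h, raster.fluid)
        self.cg_iters_last = (0, 0)

    # ------------------------------------------------------------ setup

    def _setup_faces(self) -> None:
        ct = self.raster.cell_type
        ny, nx = ct.shape
        fluid = ct == 1
        uft = np.zeros((ny, nx + 1), dtype=np.int8)
        vft = np.zeros((ny + 1, nx), dtype=np.int8)
        uft[:, 1:nx][fluid[:, :-1] & fluid[:, 1:]] = K.F_UNKNOWN
        vft[1:ny, :][fluid[:-1, :] & fluid[1:, :]] = K.F_UNKNOWN
        # inlet: left faces of inlet cells whose west neighbour is solid
        inj = self.raster.inlet_cells
        for j, i in zip(*np.nonzero(inj)):
            if i == 0 or ct[j, i - 1] == 0:
                uft[j, i] = K.F_INLET
        out = self.raster.outlet_cells
        for j, i in zip(*np.nonzero(out)):
            if i == nx - 1 or ct[j, i + 1] == 0:
                uft[j, i + 1] = K.F_OUTLET
        self.uft, self.vft = uft, vft

        def unknown_index(ft):
            idx = np.argwhere(ft == K.F_UNKNOWN)
            uid = np.full(ft.shape, -1, dtype=np.int64)
            uid[ft == K.F_UNKNOWN] = np.arange(idx.shape[0])
            jf = idx[:, 0].astype(np.int64).copy()
            if_ = idx[:, 1].astype(np.int64).copy()
            nbr = np.empty((idx.shape[0], 4), dtype=np.int64)
            nbr[:, 0] = uid[jf, if_ - 1]
            nbr[:, 1] = uid[jf, if_ + 1]
            nbr[:, 2] = uid[jf - 1, if_]
            nbr[:, 3] = uid[jf + 1, if_]
            return jf, if_, nbr

        self._ujf, self._uif, self._unbr = unknown_index(uft)
        self._vjf, self._vif, self._vnbr = unknown_index(vft)

        # phase barrier at the capillary valve: no dispersed-phase flux
        # (advective or compressive) crosses a valve-cell face -- the
        # sub-grid capillary stop admits only the continuous phase
        vc = self.raster.valve_cells
        ubar = np.zeros_like(uft, dtype=np.int8)
        vbar = np.zeros_like(vft, dtype=np.int8)
        if vc is not None:
            ubar[:, 1:][vc] = 1
            ubar[:, :-1][vc] = 1
            vbar[1:, :][vc] = 1
            vbar[:-1, :][vc] = 1
        self._ubar, self._vbar = ubar, vbar

    def _setup_passages(self) -> None:
        """Identify sub-grid capillary passages (valves and necks).

        Both are features near or below the grid's meniscus resolution,
        so their capillary behaviour is modelled as state logic instead
        of being resolved:

        * a *valve* (0.2 µm) never admits the aqueous phase — its entry
          pressure exceeds anything the device generates.  It shuts
          hydrodynamically (faces become walls, also in the pressure
          projection) as soon as water reaches its one-cell collar, and
          reopens when the water retreats.
        * a *neck* admits the aqueous phase only once the upstream
          pressure reaches its entry pressure.  While the aqueous front
          is pinned at a neck, the interface carries no flux — but that
          state can only persist while the unit still has an open oil
          path (its valve): the moment the valve shuts, the imposed
          injection flux drives the pressure up to the neck's yield
          point, so the neck opens.  Operationally: a neck is blocked
          iff water presses on it AND its unit's valve is still open.

        Dispersed-phase fluxes never cross a valve face; neck faces are
        equally phi-barred while the neck is blocked.
        """
        from scipy import ndimage

        ny, nx = self.raster.shape
        fluid = self.raster.fluid
        self._ublock = np.zeros((ny, nx + 1), dtype=np.int8)
        self._vblock = np.zeros((ny + 1, nx), dtype=np.int8)
        self._passages = []   # dicts: kind, unit, collar, cells, faces
        # Necks are hydrodynamically free: the resolved interface
        # physics provides their entry resistance.  Only the oil drain
        # (valve + slot), far below meniscus resolution, gets the
        # explicit check-valve treatment.
        for kind, mask, collar_r in (
            ("valve", self.raster.valve_cells, 1),
        ):
            if mask is None or not mask.any():
                continue
            chamber_mask = np.zeros((ny, nx), dtype=bool)
            for sy, sx in self.raster.chamber_slices.values():
                chamber_mask[sy, sx] = True
            labels, n = ndimage.label(mask)
            for k in range(1, n + 1):
                cells = labels == k
                collar = (ndimage.binary_dilation(cells, iterations=collar_r)
                          & fluid & ~cells)
                if kind == "valve" and chamber_mask.any():
                    # the drain shuts only when the *chamber-side* front
                    # reaches it; seam-side water passing the slot mouth
                    # must not close it
                    collar &= chamber_mask
                ju, iu = np.nonzero(
                    np.logical_or(np.pad(cells, ((0, 0), (0, 1))),
                                  np.pad(cells, ((0, 0), (1, 0))))
                )
                jv, iv = np.nonzero(
                    np.logical_or(np.pad(cells, ((0, 1), (0, 0))),
                                  np.pad(cells, ((1, 0), (0, 0))))
                )
                unit = -1
                if self.raster.unit_of_cell is not None:
                    jj, ii = np.nonzero(cells)
                    unit = int(self.raster.unit_of_cell[jj[0], ii[0]])
                chamber = None
                if unit >= 0:
                    for (rr, cc), sl in self.raster.chamber_slices.items():
                        n_x = 1 + max(c2 for _, c2 in
                                      self.raster.chamber_slices)
                        if rr * n_x + cc == unit:
                            chamber = sl
                            break
                self._passages.append({
                    "kind": kind, "unit": unit, "chamber": chamber,
                    "collar": np.nonzero(collar), "cells": np.nonzero(cells),
                    "ufaces": (ju, iu), "vfaces": (jv, iv),
                    "blocked": False,
                })
        # permanent phi barriers on valve faces; dynamic ones for necks
        self._ubar_dyn = self._ubar.copy()
        self._vbar_dyn = self._vbar.copy()
        self._n_rebuilds = 0
        # a blocked neck yields once the adjacent water reaches its
        # theoretical capillary entry pressure 2 sigma |cos theta| / w
        th = math.radians(self.fluids.theta_wall_deg)
        w_neck = self.raster.h
        if self.raster.neck_cells is not None and self.raster.neck_cells.any():
            from scipy import ndimage as _ndi
            lbl, _ = _ndi.label(self.raster.neck_cells)
            sl = _ndi.find_objects(lbl)[0]
            w_neck = max(sl[0].stop - sl[0].start,
                         sl[1].stop - sl[1].start) * self.raster.h
        self._neck_yield = self.inv_ca * 2.0 * abs(math.cos(th)) / w_neck

    def _update_gates(self, phic, pressure) -> None:
        """Advance the passage state machine; rebuild the projection
        operator when any passage opens or closes."""
        valve_open_of_unit = {
            p["unit"]: not p["blocked"]
            for p in self._passages if p["kind"] == "valve"
        }
        changed = False
        for p in self._passages:
            level = float(phic[p["collar"]].max(initial=0.0))
            if p["kind"] == "valve":
                # the drain shuts the moment the aqueous front seals its
                # chamber-side mouth; the unit's neck then has to yield
                want = p["blocked"]
                if not p["blocked"] and level > 0.3:
                    want = True
                elif p["blocked"] and level < 0.05:
                    want = False
            else:
                valve_open = valve_open_of_unit.get(p["unit"], False)
                if p.get("yielded") and level < 0.05:
                    p["yielded"] = False   # re-arm once the water retreats
                if p["blocked"]:
                    wet = phic[p["collar"]] > 0.6
                    p_water = (float(pressure[p["collar"]][wet].max())
                               if wet.any() else -np.inf)
                    if p_water > self._neck_yield:
                        p["yielded"] = True
                if not valve_open or p.get("yielded"):
                    want = False
                elif not p["blocked"]:
                    want = level > 0.3
                else:
                    want = level > 0.05
            if want != p["blocked"]:
                p["blocked"] = want
                changed = True
        if changed:
            self._ublock[:] = 0
            self._vblock[:] = 0
            np.copyto(self._ubar_dyn, self._ubar)
            np.copyto(self._vbar_dyn, self._vbar)
            for p in self._passages:
                if p["blocked"]:
                    self._ublock[p["ufaces"]] = 1
                    self._vblock[p["vfaces"]] = 1
                    self._ubar_dyn[p["ufaces"]] = 1
                    self._vbar_dyn[p["vfaces"]] = 1
            self._setup_poisson(self._ublock, self._vblock)
            self._n_rebuilds += 1

    def _sealed_cells(self):
        ny, nx = self.raster.shape
        m = np.zeros((ny, nx), dtype=bool)
        for p in self._passages:
            if p["blocked"]:
                m[p["cells"]] = True
        return m

    def _setup_poisson(self, ublock=None, vblock=None) -> None:
        """(Re)assemble and factorize the pressure Poisson operator.

        ``ublock``/``vblock`` mark faces closed by gated capillary
        valves; no pressure coupling crosses them (they behave as
        walls), so the projection reroutes the flux instead of pushing
        it through a choked valve.  Reassembly happens only when a
        valve opens or closes.
        """
        ct = self.raster.cell_type
        ny, nx = ct.shape
        fluid = ct == 1
        if ublock is None:
            ublock = np.zeros((ny, nx + 1), dtype=np.int8)
        if vblock is None:
            vblock = np.zeros((ny + 1, nx), dtype=np.int8)
        pid = np.full((ny, nx), -1, dtype=np.int64)
        cells = np.argwhere(fluid)
        pid[fluid] = np.arange(cells.shape[0])
        n = cells.shape[0]
        h2 = self.h * self.h
        diag = np.zeros(n)

        rows_l, cols_l = [], []
        # horizontal couplings across open interior u-faces
        m = fluid[:, :-1] & fluid[:, 1:] & (ublock[:, 1:-1] == 0)
        a, b = pid[:, :-1][m], pid[:, 1:][m]
        rows_l += [a, b]
        cols_l += [b, a]
        np.add.at(diag, a, 1.0 / h2)
        np.add.at(diag, b, 1.0 / h2)
        # vertical couplings
        m = fluid[:-1, :] & fluid[1:, :] & (vblock[1:-1, :] == 0)
        a, b = pid[:-1, :][m], pid[1:, :][m]
        rows_l += [a, b]
        cols_l += [b, a]
        np.add.at(diag, a, 1.0 / h2)
        np.add.at(diag, b, 1.0 / h2)
        # outlet faces: Dirichlet p = 0 at the face
        jo, io = np.nonzero(self.uft == K.F_OUTLET)
        has_outlet = jo.size > 0
        if has_outlet:
            np.add.at(diag, pid[jo, io - 1], 2.0 / h2)
        else:
            diag[0] += 1.0  # pin the pressure level in closed domains
        if getattr(self, "_passages", None):
            # cells sealed inside blocked passages: pin their (irrelevant)
            # pressure so the factorization stays non-singular
            sealed = self._sealed_cells() & fluid
            if sealed.any():
                diag[pid[sealed]] += 1.0
        rows = np.concatenate(rows_l + [np.arange(n)])
        cols = np.concatenate(cols_l + [np.arange(n)])
        vals = np.concatenate(
            [np.full(rows.shape[0] - n, -1.0 / h2), diag]
        )
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        self._psolve = splu(A)
        self._pid = pid
        self._pcells = cells

    def _alloc_work(self) -> None:
        ny, nx = self.raster.shape
        z = lambda *s: np.zeros(s)
        self._phis = z(ny, nx)
        self._tmp = z(ny, nx)
        self._nxc = z(ny, nx)
        self._nyc = z(ny, nx)
        self._gmag = z(ny, nx)
        self._kappa = z(ny, nx)
        self._fx = z(ny, nx + 1)
        self._fy = z(ny + 1, nx)
        self._div = z(ny, nx)
        self._phin = z(ny, nx)
        self._phig = z(ny, nx)
        nU, nV = self._ujf.shape[0], self._vjf.shape[0]
        self._diagU, self._rhsU = z(nU), z(nU)
        self._coefU = z(nU, 4)
        self._diagV, self._rhsV = z(nV), z(nV)
        self._coefV = z(nV, 4)

    # -------------------------------------------------------------- BCs

    def _apply_inlet_bc(self, u: np.ndarray) -> None:
        u[self.uft == K.F_INLET] = self.u_inlet

    # ------------------------------------------------------------- step

    def step(self, dt: float | None = None) -> float:
        """Advance one time step; returns the dt used."""
        st = self.state
        h = self.h
        ct = self.raster.cell_type

        K.set_wall_ghost_phi(st.phi, ct, self.costh, h, self._phig)
        st.phi, self._phig = self._phig, st.phi
        K.box_smooth(st.phi, self._tmp)
        K.box_smooth(self._tmp, self._phis)
        K.normals_curvature(self._phis, h, self._nxc, self._nyc,
                            self._gmag, self._kappa, self.kappa_max_cells)
        for _ in range(self.n_kappa_smooth):
            K.kappa_smooth(self._kappa, self._gmag, h, self._tmp)
            self._kappa, self._tmp = self._tmp, self._kappa

        if dt is None:
            umax = K.max_face_speed(st.u, st.v, self.uft, self.vft)
            dt = min(self.dt_max, self.cfl * h / max(umax, 1e-9))

        # variable viscosity + semi-implicit interface stabilisation
        phic = np.clip(st.phi, 0.0, 1.0)
        self._update_gates(phic, st.p)
        mu_eff = 1.0 + (self.mu_ratio - 1.0) * phic
        mu_eff += self.beta_coeff * self.inv_ca * dt * self._gmag
        mu_eff[ct == 0] = 1.0

        K.csf_forces(st.phi, self._kappa, h, self.inv_ca,
                     self.uft, self.vft, self._ubar_dyn, self._vbar_dyn,
                     self._fx, self._fy)

        # incremental pressure-correction: the momentum solve sees the
        # current pressure gradient, so the steady limit is exact Stokes
        # even though dt/Re is large, and a static droplet admits the
        # exact discrete balance grad p = CSF force (no parasitic
        # currents from the splitting).
        ny, nx = ct.shape
        fx_tot = self._fx.copy()
        fx_tot[:, 1:nx] -= np.diff(st.p, axis=1) / h
        fy_tot = self._fy.copy()
        fy_tot[1:ny, :] -= np.diff(st.p, axis=0) / h

        re_dt = self.re / dt
        itu = self._solve_component(0, st.u, fx_tot, mu_eff, re_dt)
        itv = self._solve_component(1, st.v, fy_tot, mu_eff, re_dt)
        self.cg_iters_last = (itu, itv)
        # gated valve faces are walls this step
        st.u[self._ublock == 1] = 0.0
        st.v[self._vblock == 1] = 0.0

        # outlet: zero-gradient provisional velocity
        outlet_u = self.uft == K.F_OUTLET
        jo, io = np.nonzero(outlet_u)
        st.u[jo, io] = st.u[jo, io - 1]

        # projection (on the pressure increment; outlet keeps total p = 0)
        dtp = dt / self.re
        K.divergence(st.u, st.v, h, ct, self._div)
        rhs = -self._div[self.raster.fluid] / dtp
        psi = self._psolve.solve(rhs)
        p2d = np.zeros_like(self._div)
        p2d[self.raster.fluid] = psi
        K.correct_velocity(st.u, st.v, p2d, dtp, h, self.uft, self.vft,
                           self._ublock, self._vblock)
        st.p = st.p + p2d
        # stability guard: transient gate toggles can briefly drive
        # grid-scale velocity spikes; physical speeds stay below ~20
        np.clip(st.u, -60.0, 60.0, out=st.u)
        np.clip(st.v, -60.0, 60.0, out=st.v)

        # interface transport and re-sharpening
        outflux = K.advect_phi(st.phi, st.u, st.v, dt, h,
                               self.uft, self.vft, ct,
                               self._ubar_dyn, self._vbar_dyn, self._phin)
        st.phi, self._phin = self._phin, st.phi
        for _ in range(self.n_reinit):
            K.reinit_step(st.phi, self._nxc, self._nyc,
                          self.eps_reinit, 0.25, ct,
                          self._ubar_dyn, self._vbar_dyn, self._phin)
            st.phi, self._phin = self._phin, st.phi
        fl = self.raster.fluid
        over = max(float(st.phi[fl].max(initial=0.0)) - 1.0,
                   -float(st.phi[fl].min(initial=0.0)))
        self.max_overshoot = max(self.max_overshoot, over)
        K.redistribute_phi(st.phi, ct, self._ubar_dyn, self._vbar_dyn, 30)
        self.clipped_total += K.clip_phi(st.phi, ct, 0.0, 1.0) * h * h
        self.outflux_total += outflux  # already an area (u * h * dt)

        st.t += dt
        st.n_steps += 1
        if self.debris_interval and st.n_steps % self.debris_interval == 0:
            self._remove_debris()
        if st.n_steps % 50 == 0 and not np.isfinite(st.phi[fl]).all():
            raise SolverDivergedError(
                f"non-finite phi at t={st.t:.4f}, step {st.n_steps}"
            )
        return dt

    def _remove_debris(self) -> None:
        from scipy import ndimage

        blob = self.state.phi > 0.05
        labels, n = ndimage.label(blob)
        if n == 0:
            return
        sizes = ndimage.sum_labels(blob, labels, index=np.arange(1, n + 1))
        small = np.nonzero(sizes < self.debris_min_cells)[0] + 1
        if small.size:
            kill = np.isin(labels, small)
            self.clipped_total += float(self.state.phi[kill].sum()) * self.h**2
            self.state.phi[kill] = 0.0

    def _solve_component(self, comp, field2d, force, mu_eff, re_dt) -> int:
        if comp == 0:
            jf, if_, nbr = self._ujf, self._uif, self._unbr
            diag, coef, rhs = self._diagU, self._coefU, self._rhsU
        else:
            jf, if_, nbr = self._vjf, self._vif, self._vnbr
            diag, coef, rhs = self._diagV, self._coefV, self._rhsV
        if jf.shape[0] == 0:
            return 0
        K.build_velocity_system(
            jf, if_, nbr, comp, self.uft, self.vft, self.raster.cell_type,
            mu_eff, self.h, re_dt, self.u_inlet, field2d, force,
            diag, coef, rhs,
        )
        x = field2d[jf, if_].copy()
        iters = K.cg_solve(diag, coef, nbr, rhs, x, self.cg_tol, self.cg_maxit)
        field2d[jf, if_] = x
        return int(iters)

    # ------------------------------------------------------- diagnostics

    def divergence_max(self) -> float:
        K.divergence(self.state.u, self.state.v, self.h,
                     self.raster.cell_type, self._div)
        return float(np.abs(self._div[self.raster.fluid]).max(initial=0.0))

    def mass_error(self) -> float:
        """Relative dispersed-mass drift after accounting for outflow."""
        now = self.state.dispersed_area(self.h, self.raster.fluid)
        ref = max(self.initial_area, 1e-12)
        return (now + self.outflux_total - self.initial_area) / ref

    def run(self, t_end: float, max_steps: int = 10**7) -> PhaseState:
        while self.state.t < t_end and self.state.n_steps < max_steps:
            self.step()
        return self.state


# ---------------------------------------------------------------- helpers

def init_phases(raster: DomainRaster, plug: bool = True) -> PhaseState:
    """Initial condition: everything continuous phase except the
    dispersed plug in the injection channel (sharp; the first reinit
    steps relax it to the equilibrium profile)."""
    ny, nx = raster.shape
    phi = np.zeros((ny, nx))
    if plug and raster.plug_x is not None:
        x0, x1 = raster.plug_x
        phi[:, x0:x1][raster.fluid[:, x0:x1]] = 1.0
    u = np.zeros((ny, nx + 1))
    v = np.zeros((ny + 1, nx))
    p = np.zeros((ny, nx))
    return PhaseState(phi=phi, u=u, v=v, p=p)


def init_circle(solver: TwoPhaseSolver, cx: float, cy: float, r: float) -> None:
    """Seed a circular dispersed droplet (centre/radius in µm) with the
    equilibrium tanh profile of the conservative level set."""
    h = solver.h
    ny, nx = solver.raster.shape
    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    x = (x + 0.5) * h
    y = (y + 0.5) * h
    d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2) - r
    eps = solver.eps_reinit * h
    solver.state.phi = 1.0 / (1.0 + np.exp(np.clip(d / eps, -60, 60)))
    solver.state.phi[~solver.raster.fluid] = 0.0
    solver.initial_area = solver.state.dispersed_area(h)


@dataclass
class SteadyResult:
    """Outcome of :func:`run_to_steady`."""

    state: PhaseState
    history: list = field(default_factory=list)  # (t, per-chamber areas µm²)
    steady: bool = False
    solver: TwoPhaseSolver | None = None

    @property
    def final_areas(self) -> np.ndarray:
        return self.history[-1][1]


def run_to_steady(
    geom: SDAGeometry | None = None,
    fluids: FluidPair | None = None,
    *,
    raster: DomainRaster | None = None,
    t_max: float = 30.0,
    census_interval: float = 0.25,
    steady_window: float = 2.5,
    steady_rel_tol: float = 0.005,
    verbose: bool = False,
    **solver_kw,
) -> SteadyResult:
    """Advance the SDA array until the per-chamber droplet areas settle.

    Steady state requires (a) the dispersed plug to have left the
    injection channel and (b) every chamber area to change by less than
    ``steady_rel_tol`` of the chamber area over a trailing window of one
    flush-through time (default 2.5 time units ~ 0.8 ms).
    """
    from .census import droplet_census

    if raster is None:
        geom, raster = build_geometry(geom)
    solver = TwoPhaseSolver(raster, fluids, **solver_kw)
    n_ch = len(raster.chamber_slices)
    chamber_area = (geom.chamber_area_um2 if geom is not None
                    else raster.fluid_area_um2())
    history: list[tuple[float, np.ndarray]] = []
    next_census = 0.0
    steady = False
    while solver.state.t < t_max:
        solver.step()
        if solver.state.t >= next_census:
            census = droplet_census(solver.state, raster)
            history.append((solver.state.t, census.chamber_areas_um2.copy()))
            next_census = solver.state.t + census_interval
            if verbose:
                print(
                    f"t={solver.state.t:7.3f} step={solver.state.n_steps:6d} "
                    f"areas={census.chamber_areas_um2.ravel().round(2)} "
                    f"mass_err={solver.mass_error():+.3e}"
                )
            if n_ch and _is_steady(history, solver, raster, chamber_area,
                                   steady_window, steady_rel_tol):
                steady = True
                break
    return SteadyResult(state=solver.state, history=history, steady=steady,
                        solver=solver)


def _is_steady(history, solver, raster, chamber_area, window, rel_tol) -> bool:
    t_now = history[-1][0]
    if raster.inj_x is not None:
        x0, x1 = raster.inj_x
        inj_mass = float(solver.state.phi[:, x0:x1].sum()) * solver.h**2
        if inj_mass > 0.02 * chamber_area:
            return False   # plug tail still in the injection channel
    in_window = [(t, a) for t, a in history if t >= t_now - window]
    if len(in_window) < 3 or t_now - in_window[0][0] < 0.9 * window:
        return False   # not enough trailing history yet
    stack = np.stack([a for _, a in in_window])
    drift = np.abs(stack.max(axis=0) - stack.min(axis=0))
    return bool((drift <= rel_tol * chamber_area).all())
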
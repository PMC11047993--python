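"""Numba kernels for the two-phase flow solver.

Discretization summary (all nondimensional: lengths in µm, velocities
in units of the 3 mm/s injection speed):

* MAC staggered grid; u on vertical faces (ny, nx+1), v on horizontal
  faces (ny+1, nx), scalars at cell centres.
* Interface: conservative level-set field phi in [0, 1] (dispersed
  phase = 1), advected with minmod-limited upwind fluxes in
  conservative form and re-sharpened by Olsson-Kreiss
  compression-diffusion pseudo-steps.
* Surface tension: continuum-surface-force at faces,
  f = (1/Ca) kappa grad(phi), with curvature from a box-smoothed phi;
  stabilised semi-implicitly by an interface viscosity
  beta = (1/Ca) dt |grad(phi_smooth)| added to the implicit viscous
  operator (the Hysing-type treatment that removes the explicit
  capillary time-step limit).
* Momentum: unsteady Stokes (creeping flow, convection dropped at
  Re ~ 4e-3), backward-Euler implicit viscosity solved with
  Jacobi-preconditioned CG; Chorin projection with a direct sparse
  factorization of the pressure Poisson operator.

Face type codes: 0 = solid/Dirichlet-0, 1 = interior unknown,
2 = velocity inlet, 3 = pressure outlet (zero gradient).
"""

from __future__ import annotations

import numpy as np
from numba import njit

F_SOLID, F_UNKNOWN, F_INLET, F_OUTLET = 0, 1, 2, 3


# ------------------------------------------------------------------ phi BCs

@njit(cache=True)
def set_wall_ghost_phi(phi, ctype, costh, h, out):
    """Compute contact-angle ghost values of phi for solid cells.

    For a wall whose normal points into the fluid, the interface must
    meet it at the prescribed angle:  d(phi)/dn_solid = cos(theta)
    |grad_t phi|.  theta > 90 deg (non-wetting water) makes the ghost
    fraction smaller than the fluid-side value.  Reads ``phi`` only and
    writes ``out`` (a sweep updating in place would bias the ghosts
    toward the scan direction).
    """
    ny, nx = ctype.shape
    for j in range(ny):
        for i in range(nx):
            out[j, i] = phi[j, i]
    for j in range(ny):
        for i in range(nx):
            if ctype[j, i] != 0:
                continue
            acc = 0.0
            n = 0
            # fluid neighbour in each direction; tangential gradient taken
            # along the wall at the fluid cell
            for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                jf = j + dj
                if jf < 0 or jf >= ny:
                    continue
                if_ = i + di
                if if_ < 0 or if_ >= nx:
                    continue
                if ctype[jf, if_] != 1:
                    continue
                if di != 0:  # vertical wall: tangential = y
                    lo = phi[jf - 1, if_] if jf > 0 else phi[jf, if_]
                    hi = phi[jf + 1, if_] if jf < ny - 1 else phi[jf, if_]
                    gt = abs(hi - lo) / (2.0 * h)
                else:        # horizontal wall: tangential = x
                    lo = phi[jf, if_ - 1] if if_ > 0 else phi[jf, if_]
                    hi = phi[jf, if_ + 1] if if_ < nx - 1 else phi[jf, if_]
                    gt = abs(hi - lo) / (2.0 * h)
                val = phi[jf, if_] + costh * gt * h
                if val < 0.0:
                    val = 0.0
                elif val > 1.0:
                    val = 1.0
                acc += val
                n += 1
            if n > 0:
                out[j, i] = acc / n


@njit(cache=True)
def box_smooth(src, out):
    """3x3 box average with edge clamping (used twice to build phi_smooth)."""
    ny, nx = src.shape
    for j in range(ny):
        for i in range(nx):
            s = 0.0
            n = 0
            for dj in range(-1, 2):
                jj = j + dj
                if jj < 0 or jj >= ny:
                    continue
                for di in range(-1, 2):
                    ii = i + di
                    if ii < 0 or ii >= nx:
                        continue
                    s += src[jj, ii]
                    n += 1
            out[j, i] = s / n


# --------------------------------------------------- normals and curvature

@njit(cache=True)
def normals_curvature(phis, h, nxc, nyc, gmag, kappa, kmax_cells=0.5):
    """Cell normals/|grad| from smoothed phi and CSF curvature.

    Curvature is the negative divergence of face-normalised gradients
    (positive kappa for a convex dispersed droplet), clipped to the
    grid-resolvable 1/h.
    """
    ny, nx = phis.shape
    # cell-centred gradient
    for j in range(ny):
        for i in range(nx):
            ip = i + 1 if i < nx - 1 else i
            im = i - 1 if i > 0 else i
            jp = j + 1 if j < ny - 1 else j
            jm = j - 1 if j > 0 else j
            gx = (phis[j, ip] - phis[j, im]) / ((ip - im) * h)
            gy = (phis[jp, i] - phis[jm, i]) / ((jp - jm) * h)
            g = np.sqrt(gx * gx + gy * gy)
            gmag[j, i] = g
            if g > 1e-12:
                nxc[j, i] = gx / g
                nyc[j, i] = gy / g
            else:
                nxc[j, i] = 0.0
                nyc[j, i] = 0.0
    gmin = 0.02 / h
    kmax = kmax_cells / h  # curvature below the resolvable radius is noise
    for j in range(1, ny - 1):
        for i in range(1, nx - 1):
            if gmag[j, i] < gmin:
                kappa[j, i] = 0.0
                continue
            # face-normalised gradients of phis
            k = 0.0
            # east/west x-faces
            for s in (1, -1):
                il = i if s == 1 else i - 1
                gx = (phis[j, il + 1] - phis[j, il]) / h
                gy = 0.25 * (
                    phis[j + 1, il + 1] + phis[j + 1, il]
                    - phis[j - 1, il + 1] - phis[j - 1, il]
                ) / h
                g = np.sqrt(gx * gx + gy * gy)
                if g > 1e-12:
                    k += s * gx / g
            for s in (1, -1):
                jl = j if s == 1 else j - 1
                gy = (phis[jl + 1, i] - phis[jl, i]) / h
                gx = 0.25 * (
                    phis[jl + 1, i + 1] + phis[jl, i + 1]
                    - phis[jl + 1, i - 1] - phis[jl, i - 1]
                ) / h
                g = np.sqrt(gx * gx + gy * gy)
                if g > 1e-12:
                    k += s * gy / g
            k = -k / h
            if k > kmax:
                k = kmax
            elif k < -kmax:
                k = -kmax
            kappa[j, i] = k


@njit(cache=True)
def kappa_smooth(kappa, gmag, h, out):
    """Average curvature along the interface band, weighted by |grad phi|.

    Reduces cell-to-cell curvature noise (the driver of parasitic
    currents at Ca ~ 1e-4) and extends the centreline value into the
    profile tails where the raw estimate is unreliable.
    """
    ny, nx = kappa.shape
    gmin = 0.02 / h
    for j in range(ny):
        for i in range(nx):
            if gmag[j, i] < gmin:
                out[j, i] = 0.0
                continue
            s = 0.0
            w = 0.0
            for dj in range(-2, 3):
                jj = j + dj
                if jj < 0 or jj >= ny:
                    continue
                for di in range(-2, 3):
                    ii = i + di
                    if ii < 0 or ii >= nx:
                        continue
                    g = gmag[jj, ii]
                    if g > gmin:
                        ww = g * g
                        s += ww * kappa[jj, ii]
                        w += ww
            out[j, i] = s / w if w > 0.0 else kappa[j, i]


@njit(cache=True)
def csf_forces(phi, kappa, h, inv_ca, uft, vft, ubar, vbar, fx, fy):
    """Balanced CSF force at velocity faces: (1/Ca) kappa_face dphi/dn."""
    ny, nx = phi.shape
    for j in range(ny):
        for i in range(nx + 1):
            if uft[j, i] != F_UNKNOWN or ubar[j, i] == 1:
                fx[j, i] = 0.0
                continue
            dphi = phi[j, i] - phi[j, i - 1]
            if dphi != 0.0:
                kf = 0.5 * (kappa[j, i] + kappa[j, i - 1])
                fx[j, i] = inv_ca * kf * dphi / h
            else:
                fx[j, i] = 0.0
    for j in range(ny + 1):
        for i in range(nx):
            if vft[j, i] != F_UNKNOWN or vbar[j, i] == 1:
                fy[j, i] = 0.0
                continue
            dphi = phi[j, i] - phi[j - 1, i]
            if dphi != 0.0:
                kf = 0.5 * (kappa[j, i] + kappa[j - 1, i])
                fy[j, i] = inv_ca * kf * dphi / h
            else:
                fy[j, i] = 0.0


# ----------------------------------------------------- implicit viscous CG

@njit(cache=True)
def build_velocity_system(
    jf, if_, nbr_id, comp, uft, vft, ctype, mu_eff, h, re_dt, u_in,
    uvold, force, diag, coef, rhs,
):
    """Assemble diag/off-diagonal/rhs for one velocity component.

    ``comp`` = 0 for u (faces normal to x), 1 for v.  Walls seen in the
    face-normal direction impose the Dirichlet value at distance h
    (no-penetration holds exactly at that face); walls in the
    tangential direction use the ghost reflection (factor 2), putting
    no-slip second-order at the wall plane.
    """
    n = jf.shape[0]
    h2 = h * h
    for m in range(n):
        j = jf[m]
        i = if_[m]
        d = re_dt
        r = re_dt * uvold[j, i] + force[j, i]
        for k in range(4):
            # k: 0=W, 1=E, 2=S, 3=N (in the face grid)
            if comp == 0:
                if k == 0:
                    jn, in_ = j, i - 1
                elif k == 1:
                    jn, in_ = j, i + 1
                elif k == 2:
                    jn, in_ = j - 1, i
                else:
                    jn, in_ = j + 1, i
                ft = uft[jn, in_]
                normal_dir = k < 2
                if normal_dir:
                    ci = i - 1 if k == 0 else i
                    a = mu_eff[j, ci]
                else:
                    jlo = jn if k == 2 else j
                    a = _corner_mu(mu_eff, ctype, jlo, i - 1, jlo + 1, i)
            else:
                if k == 0:
                    jn, in_ = j, i - 1
                elif k == 1:
                    jn, in_ = j, i + 1
                elif k == 2:
                    jn, in_ = j - 1, i
                else:
                    jn, in_ = j + 1, i
                ft = vft[jn, in_]
                normal_dir = k >= 2
                if normal_dir:
                    cj = j - 1 if k == 2 else j
                    a = mu_eff[cj, i]
                else:
                    ilo = in_ if k == 0 else i
                    a = _corner_mu(mu_eff, ctype, j - 1, ilo, j, ilo + 1)
            c = a / h2
            if ft == F_UNKNOWN:
                d += c
                coef[m, k] = c
            elif ft == F_SOLID:
                coef[m, k] = 0.0
                if normal_dir:
                    d += c          # Dirichlet 0 at distance h
                else:
                    d += 2.0 * c    # no-slip wall at the half-distance plane
            elif ft == F_INLET:
                coef[m, k] = 0.0
                d += c
                r += c * u_in
            else:  # outlet: zero gradient, drop the link
                coef[m, k] = 0.0
        diag[m] = d
        rhs[m] = r


@njit(cache=True)
def _corner_mu(mu_eff, ctype, j0, i0, j1, i1):
    """Effective viscosity at a grid corner: fluid-cell average of the 2x2
    neighbourhood (rows j0..j1-? explicit four cells)."""
    s = 0.0
    n = 0
    ny, nx = mu_eff.shape
    for j in (j0, j1):
        for i in (i0, i1):
            if 0 <= j < ny and 0 <= i < nx and ctype[j, i] == 1:
                s += mu_eff[j, i]
                n += 1
    if n == 0:
        return 1.0
    return s / n


@njit(cache=True)
def cg_solve(diag, coef, nbr, rhs, x, tol, maxit):
    """Jacobi-preconditioned CG for the SPD velocity system.

    y = A x with A[m] = diag[m] x[m] - sum_k coef[m,k] x[nbr[m,k]].
    Returns the iteration count (maxit+1 signals non-convergence).
    """
    n = diag.shape[0]
    r = np.empty(n)
    z = np.empty(n)
    p = np.empty(n)
    ap = np.empty(n)
    # r = b - A x
    for m in range(n):
        s = diag[m] * x[m]
        for k in range(4):
            nb = nbr[m, k]
            if nb >= 0:
                s -= coef[m, k] * x[nb]
        r[m] = rhs[m] - s
    bnorm = 0.0
    for m in range(n):
        bnorm += rhs[m] * rhs[m]
    bnorm = np.sqrt(bnorm)
    if bnorm < 1e-300:
        bnorm = 1.0
    rz = 0.0
    for m in range(n):
        z[m] = r[m] / diag[m]
        p[m] = z[m]
        rz += r[m] * z[m]
    it = 0
    while it < maxit:
        rnorm = 0.0
        for m in range(n):
            rnorm += r[m] * r[m]
        if np.sqrt(rnorm) <= tol * bnorm:
            break
        # ap = A p
        for m in range(n):
            s = diag[m] * p[m]
            for k in range(4):
                nb = nbr[m, k]
                if nb >= 0:
                    s -= coef[m, k] * p[nb]
            ap[m] = s
        pap = 0.0
        for m in range(n):
            pap += p[m] * ap[m]
        if pap <= 0.0:
            break
        alpha = rz / pap
        for m in range(n):
            x[m] += alpha * p[m]
            r[m] -= alpha * ap[m]
        rz_new = 0.0
        for m in range(n):
            z[m] = r[m] / diag[m]
            rz_new += r[m] * z[m]
        beta = rz_new / rz
        rz = rz_new
        for m in range(n):
            p[m] = z[m] + beta * p[m]
        it += 1
    return it


# ------------------------------------------------------------- projection

@njit(cache=True)
def divergence(u, v, h, ctype, out):
    ny, nx = ctype.shape
    for j in range(ny):
        for i in range(nx):
            if ctype[j, i] == 1:
                out[j, i] = (u[j, i + 1] - u[j, i] + v[j + 1, i] - v[j, i]) / h
            else:
                out[j, i] = 0.0


@njit(cache=True)
def correct_velocity(u, v, psi, dtp, h, uft, vft, ublock, vblock):
    ny, nx = psi.shape
    for j in range(ny):
        for i in range(nx + 1):
            ft = uft[j, i]
            if ublock[j, i] == 1:
                u[j, i] = 0.0
            elif ft == F_UNKNOWN:
                u[j, i] -= dtp * (psi[j, i] - psi[j, i - 1]) / h
            elif ft == F_OUTLET:
                # Dirichlet psi = 0 at the face: ghost = -psi_interior
                u[j, i] -= dtp * (-2.0 * psi[j, i - 1]) / h
    for j in range(ny + 1):
        for i in range(nx):
            if vblock[j, i] == 1:
                v[j, i] = 0.0
            elif vft[j, i] == F_UNKNOWN:
                v[j, i] -= dtp * (psi[j, i] - psi[j - 1, i]) / h


# -------------------------------------------------------------- advection

@njit(cache=True, inline="always")
def _minmod(a, b):
    if a * b <= 0.0:
        return 0.0
    if abs(a) < abs(b):
        return a
    return b


@njit(cache=True)
def advect_phi(phi, u, v, dt, h, uft, vft, ctype, ubar, vbar, out):
    """Conservative MUSCL (minmod) transport of phi.

    Fluxes vanish at solid faces and at the inlet (pure continuous
    phase flows in); the outlet flux is upwinded from the interior.
    Returns the dispersed-phase volume leaving through the outlet.
    """
    ny, nx = phi.shape
    fxf = np.zeros((ny, nx + 1))
    fyf = np.zeros((ny + 1, nx))
    outflux = 0.0
    for j in range(ny):
        for i in range(nx + 1):
            ft = uft[j, i]
            if ft == F_SOLID or ft == F_INLET or ubar[j, i]:
                continue
            uf = u[j, i]
            if uf == 0.0:
                continue
            if uf > 0.0:
                cu = i - 1
                sgn = 1.0
            else:
                cu = i
                sgn = -1.0
            im = cu - 1 if cu > 0 else cu
            ip = cu + 1 if cu < nx - 1 else cu
            s = _minmod(phi[j, cu] - phi[j, im], phi[j, ip] - phi[j, cu])
            pf = phi[j, cu] + 0.5 * sgn * s
            fxf[j, i] = uf * pf
            if ft == F_OUTLET:
                outflux += uf * pf * h * dt
    for j in range(ny + 1):
        for i in range(nx):
            if vft[j, i] != F_UNKNOWN or vbar[j, i]:
                continue
            vf = v[j, i]
            if vf == 0.0:
                continue
            if vf > 0.0:
                cu = j - 1
                sgn = 1.0
            else:
                cu = j
                sgn = -1.0
            jm = cu - 1 if cu > 0 else cu
            jp = cu + 1 if cu < ny - 1 else cu
            s = _minmod(phi[cu, i] - phi[jm, i], phi[jp, i] - phi[cu, i])
            pf = phi[cu, i] + 0.5 * sgn * s
            fyf[j, i] = vf * pf
    for j in range(ny):
        for i in range(nx):
            if ctype[j, i] == 1:
                out[j, i] = phi[j, i] - dt / h * (
                    fxf[j, i + 1] - fxf[j, i] + fyf[j + 1, i] - fyf[j, i]
                )
            else:
                out[j, i] = phi[j, i]
    return outflux


# --------------------------------------------------------- reinitialization

@njit(cache=True)
def reinit_step(phi, nxc, nyc, eps, dtau, ctype, ubar, vbar, out):
    """One Olsson-Kreiss compression-diffusion pseudo-step (flux form,
    zero flux through solid faces, hence conservative)."""
    ny, nx = phi.shape
    fxf = np.zeros((ny, nx + 1))
    fyf = np.zeros((ny + 1, nx))
    for j in range(ny):
        for i in range(1, nx):
            if ctype[j, i - 1] != 1 or ctype[j, i] != 1 or ubar[j, i]:
                continue
            nfx = 0.5 * (nxc[j, i - 1] + nxc[j, i])
            nfy = 0.5 * (nyc[j, i - 1] + nyc[j, i])
            nn = np.sqrt(nfx * nfx + nfy * nfy)
            if nn < 1e-8:
                continue
            nfx /= nn
            nfy /= nn
            pf = 0.5 * (phi[j, i - 1] + phi[j, i])
            if pf < 0.0:
                pf = 0.0
            elif pf > 1.0:
                pf = 1.0
            comp = pf * (1.0 - pf) * nfx
            # normal diffusion eps (grad phi . n) n_x; eps is in cell units
            # (eps_phys = eps * h), so raw phi differences stand in for h*grad
            jp = j + 1 if j < ny - 1 else j
            jm = j - 1 if j > 0 else j
            dpy = 0.25 * (
                phi[jp, i] + phi[jp, i - 1] - phi[jm, i] - phi[jm, i - 1]
            )
            fxf[j, i] = comp - ((phi[j, i] - phi[j, i - 1]) * nfx + dpy * nfy) * nfx * eps
    for j in range(1, ny):
        for i in range(nx):
            if ctype[j - 1, i] != 1 or ctype[j, i] != 1 or vbar[j, i]:
                continue
            nfx = 0.5 * (nxc[j - 1, i] + nxc[j, i])
            nfy = 0.5 * (nyc[j - 1, i] + nyc[j, i])
            nn = np.sqrt(nfx * nfx + nfy * nfy)
            if nn < 1e-8:
                continue
            nfx /= nn
            nfy /= nn
            pf = 0.5 * (phi[j - 1, i] + phi[j, i])
            if pf < 0.0:
                pf = 0.0
            elif pf > 1.0:
                pf = 1.0
            comp = pf * (1.0 - pf) * nfy
            ip = i + 1 if i < nx - 1 else i
            im = i - 1 if i > 0 else i
            dpx = 0.25 * (
                phi[j, ip] + phi[j - 1, ip] - phi[j, im] - phi[j - 1, im]
            )
            fyf[j, i] = comp - (dpx * nfx + (phi[j, i] - phi[j - 1, i]) * nfy) * nfy * eps
    for j in range(ny):
        for i in range(nx):
            if ctype[j, i] == 1:
                out[j, i] = phi[j, i] - dtau * (
                    fxf[j, i + 1] - fxf[j, i] + fyf[j + 1, i] - fyf[j, i]
                )
            else:
                out[j, i] = phi[j, i]


@njit(cache=True, inline="always")
def _barred(ubar, vbar, j, i, dj, di):
    if di == 1:
        return ubar[j, i + 1] == 1
    if di == -1:
        return ubar[j, i] == 1
    if dj == 1:
        return vbar[j + 1, i] == 1
    return vbar[j, i] == 1


@njit(cache=True)
def redistribute_phi(phi, ctype, ubar, vbar, npass):
    """Fold phi overshoot/undershoot back into neighbouring cells.

    Pile-ups against walls (e.g. at the choked valve entrance) and
    advection undershoots would otherwise be truncated, destroying
    dispersed mass; instead the excess (deficit) is shifted to the
    least- (most-) filled fluid neighbour, conserving mass locally.
    """
    ny, nx = phi.shape
    for _ in range(npass):
        moved = 0.0
        for j in range(1, ny - 1):
            for i in range(1, nx - 1):
                if ctype[j, i] != 1:
                    continue
                p = phi[j, i]
                if p > 1.0:
                    excess = p - 1.0
                    best = -1
                    bj = bi = 0
                    room = 0.0
                    for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                        jj, ii = j + dj, i + di
                        if _barred(ubar, vbar, j, i, dj, di):
                            continue
                        if ctype[jj, ii] == 1 and 1.0 - phi[jj, ii] > room:
                            room = 1.0 - phi[jj, ii]
                            bj, bi = jj, ii
                            best = 1
                    if best > 0:
                        take = excess if excess < room else room
                        phi[j, i] -= take
                        phi[bj, bi] += take
                        moved += take
                elif p < 0.0:
                    deficit = -p
                    best = -1
                    bj = bi = 0
                    avail = 0.0
                    for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                        jj, ii = j + dj, i + di
                        if _barred(ubar, vbar, j, i, dj, di):
                            continue
                        if ctype[jj, ii] == 1 and phi[jj, ii] > avail:
                            avail = phi[jj, ii]
                            bj, bi = jj, ii
                            best = 1
                    if best > 0:
                        take = deficit if deficit < avail else avail
                        phi[j, i] += take
                        phi[bj, bi] -= take
                        moved += take
        if moved == 0.0:
            break


@njit(cache=True)
def clip_phi(phi, ctype, lo, hi):
    """Clip phi into [lo, hi]; returns the net dispersed volume (in cells)
    removed by clipping, for the mass audit."""
    ny, nx = phi.shape
    removed = 0.0
    for j in range(ny):
        for i in range(nx):
            if ctype[j, i] != 1:
                continue
            p = phi[j, i]
            if p < lo:
                removed += p - lo
                phi[j, i] = lo
            elif p > hi:
                removed += p - hi
                phi[j, i] = hi
    return removed


@njit(cache=True)
def max_face_speed(u, v, uft, vft):
    um = 0.0
    ny, nx1 = u.shape
    for j in range(ny):
        for i in range(nx1):
            if uft[j, i] != F_SOLID:
                a = abs(u[j, i])
                if a > um:
                    um = a
    ny1, nx = v.shape
    for j in range(ny1):
        for i in range(nx):
            if vft[j, i] != F_SOLID:
                a = abs(v[j, i])
                if a > um:
                    um = a
    return um
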
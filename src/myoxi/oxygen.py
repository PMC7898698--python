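"""Steady-state tissue PO₂ modelling on muscle-section geometry.

The model is a Krogh-type reaction–diffusion equation over the section
cross-section, with myoglobin-facilitated transport inside fibres and
Michaelis–Menten oxygen consumption:

    ∇·( (D_O2·α + D_Mb·C_Mb·S'(P)) ∇P ) = q·M0 · P/(P + P_crit)   in fibres
    ∇·(  D_O2·α               ∇P ) = 0                            elsewhere

with S(P) = P/(P + P50_Mb) the myoglobin saturation, Dirichlet P = P_cap
on capillary discs of radius r_cap, and zero flux on the ROI boundary.
q ∈ (0, 1] scales maximal consumption M0 between rest and maximal work.

Discretisation: uniform finite differences (5-point stencil) on a
raster of spacing ``grid_h`` with harmonic face conductivities, which
preserves the discrete maximum principle.  The nonlinear consumption
and facilitation terms are handled by damped Picard iteration; each
linearised consumption term q·M0·P/(P_prev + P_crit) keeps the system
an M-matrix, so iterates remain within [0, P_cap].

``OxygenTransportModel(section, params).solve(demand=...)`` returns a
:class:`PO2Field`; ``summarize_po2`` reduces a field to per-fibre-type
means and a hypoxic area fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .section import MuscleSection

CM_PER_UM = 1e-4


class TransportError(RuntimeError):
    pass


@dataclass(frozen=True)
class TransportParams:
    """Physical and numerical parameters of the PO₂ model.

    Units: pressures mmHg; lengths cm except ``grid_h`` (µm);
    concentrations/consumption in ml O₂ per ml tissue (per second).

    Defaults follow the capillary-supply modelling literature for rat
    muscle: maximal consumption 15.7e-5 ml O₂·ml⁻¹·s⁻¹, myoglobin
    concentration 10.2e-3 ml O₂·ml⁻¹, O₂ solubility 3.89e-5
    ml O₂·ml⁻¹·mmHg⁻¹, myoglobin diffusivity 1.73e-7 cm²·s⁻¹, free-O₂
    diffusivity 2.41e-5 cm²·s⁻¹, capillary radius 1.8–2.5e-4 cm.
    """

    p_cap: float = 30.0            # capillary-wall PO₂, mmHg
    r_cap: float = 2.5e-4          # capillary radius, cm
    m0: float = 15.7e-5            # maximal consumption, ml O₂ ml⁻¹ s⁻¹
    demand_scale: float = 1.0      # fraction of m0 (rest ≈ 0.1, max = 1)
    c_mb: float = 10.2e-3          # myoglobin O₂ capacity, ml O₂ ml⁻¹
    alpha: float = 3.89e-5         # O₂ solubility, ml O₂ ml⁻¹ mmHg⁻¹
    d_o2: float = 2.41e-5          # free O₂ diffusivity, cm² s⁻¹
    d_mb: float = 1.73e-7          # myoglobin diffusivity, cm² s⁻¹
    p50_mb: float = 5.3            # myoglobin half-saturation, mmHg
    p_crit: float = 0.5            # Michaelis constant of consumption, mmHg
    grid_h: float = 1.0            # grid spacing, µm
    tol: float = 1e-8              # Picard relative-change tolerance
    max_iter: int = 60
    damping: float = 1.0           # Picard damping factor in (0, 1]
    consumption_order: str = "michaelis"  # or "zero"

    def validate(self) -> None:
        for name in ("p_cap", "r_cap", "m0", "c_mb", "alpha", "d_o2", "d_mb",
                     "p50_mb", "p_crit", "grid_h", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.demand_scale <= 1.0:
            raise ValueError("demand_scale must be in [0, 1]")
        if not 1.8e-4 <= self.r_cap <= 2.5e-4:
            raise ValueError("r_cap outside the physiological range "
                             "1.8e-4–2.5e-4 cm; use replace() to override "
                             "after constructing with a valid value")
        if self.consumption_order not in ("michaelis", "zero"):
            raise ValueError("consumption_order must be 'michaelis' or 'zero'")


@dataclass
class PO2Field:
    """Raster PO₂ solution plus the masks used to compute it.

    ``grid`` holds PO₂ in mmHg (NaN outside the ROI); ``fibre_id`` is
    -2 outside the ROI, -1 in extracellular space, otherwise the fibre
    index; ``capillary_mask`` flags Dirichlet nodes.
    """

    grid: np.ndarray
    fibre_id: np.ndarray
    capillary_mask: np.ndarray
    fibre_types: list
    grid_h: float                  # µm
    origin: tuple                  # (x, y) of node (0, 0) centre, µm
    params: TransportParams
    n_iterations: int = 0
    residual: float = np.nan
    conservation: Optional[tuple] = None

    @property
    def in_roi(self) -> np.ndarray:
        return self.fibre_id > -2

    def flux_balance(self) -> tuple[float, float]:
        """(total consumption, net capillary influx), ml O₂ s⁻¹ cm⁻¹ depth.

        Both integrals are per unit section depth; at convergence they
        agree (discrete conservation).
        """
        if self.conservation is None:
            raise TransportError("field was not produced by solve()")
        return self.conservation

    def to_tiff(self, path, sidecar: bool = True) -> None:
        """Write the PO₂ raster as 32-bit float TIFF (+ parameter sidecar)."""
        import tifffile

        tifffile.imwrite(str(path), self.grid.astype(np.float32))
        if sidecar:
            with open(str(path) + ".params.txt", "w") as fh:
                for k, v in vars(self.params).items():
                    fh.write(f"{k} = {v}\n")
                fh.write(f"grid_h_um = {self.grid_h}\n")
                fh.write(f"n_iterations = {self.n_iterations}\n")
                fh.write(f"residual = {self.residual:.3e}\n")


@dataclass
class PO2Summary:
    """Per-type mean PO₂ (area-weighted over fibre pixels) and hypoxia."""

    mean_po2: dict                 # {"I": .., "IIa": .., ..., "all": ..} mmHg
    hypoxic_fraction: float        # fibre-area fraction with P < threshold
    threshold: float = 0.5


class OxygenTransportModel:
    """Finite-difference PO₂ model bound to one muscle section.

    Parameters
    ----------
    section : MuscleSection
        Geometry in µm; must contain at least one capillary.
    params : TransportParams
        Physical constants and solver controls.
    """

    def __init__(self, section: MuscleSection, params: TransportParams
                 = TransportParams()):
        params.validate()
        if section.n_capillaries == 0:
            raise TransportError("section has no capillaries: the PO₂ "
                                 "problem has no oxygen source")
        if params.grid_h > params.r_cap / CM_PER_UM:
            raise TransportError(
                f"grid_h = {params.grid_h} µm does not resolve the capillary "
                f"radius ({params.r_cap / CM_PER_UM:.2f} µm)")
        self.section = section
        self.params = params
        self._rasterise()

    # -- geometry rasterisation ---------------------------------------
    def _rasterise(self) -> None:
        roi = self.section.roi
        h = self.params.grid_h
        minx, miny, maxx, maxy = roi.bounds
        nx = int(np.ceil((maxx - minx) / h))
        ny = int(np.ceil((maxy - miny) / h))
        xs = minx + (np.arange(nx) + 0.5) * h
        ys = miny + (np.arange(ny) + 0.5) * h
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        flatx, flaty = X.ravel(), Y.ravel()

        in_roi = shapely.contains_xy(roi, flatx, flaty).reshape(nx, ny)
        fibre_id = np.full((nx, ny), -2, dtype=np.int32)
        fibre_id[in_roi] = -1
        for i, f in enumerate(self.section.fibres):
            m = shapely.contains_xy(f.polygon, flatx, flaty).reshape(nx, ny)
            fibre_id[m & in_roi] = i

        cap_mask = np.zeros((nx, ny), dtype=bool)
        cap_owner = np.full((nx, ny), -1, dtype=np.int32)
        r_um = self.params.r_cap / CM_PER_UM
        for ci, (cx, cy) in enumerate(self.section.capillaries):
            if not roi.buffer(1e-6).covers(shapely.Point(cx, cy)):
                raise TransportError(f"capillary ({cx:.2f}, {cy:.2f}) outside ROI")
            i0 = max(int((cx - r_um - minx) / h) - 1, 0)
            i1 = min(int((cx + r_um - minx) / h) + 2, nx)
            j0 = max(int((cy - r_um - miny) / h) - 1, 0)
            j1 = min(int((cy + r_um - miny) / h) + 2, ny)
            sub = (X[i0:i1, j0:j1] - cx) ** 2 + (Y[i0:i1, j0:j1] - cy) ** 2 \
                <= r_um ** 2
            cap_mask[i0:i1, j0:j1] |= sub
            cap_owner[i0:i1, j0:j1][sub] = ci
            if not (sub & in_roi[i0:i1, j0:j1]).any():
                # tiny capillary between nodes: pin the nearest in-ROI node
                d2 = (flatx - cx) ** 2 + (flaty - cy) ** 2
                d2[~in_roi.ravel()] = np.inf
                flat = np.argmin(d2)
                cap_mask.ravel()[flat] = True
                cap_owner.ravel()[flat] = ci
        cap_mask &= in_roi

        # angular extent of each capillary circle lying inside the ROI
        # (capillaries on the ROI boundary expose only part of their wall)
        n_cap = len(self.section.capillaries)
        theta = np.linspace(0.0, 2 * np.pi, 128, endpoint=False)
        cap_theta = np.empty(n_cap)
        for ci, (cx, cy) in enumerate(self.section.capillaries):
            px = cx + 1.3 * r_um * np.cos(theta)
            py = cy + 1.3 * r_um * np.sin(theta)
            cap_theta[ci] = 2 * np.pi * shapely.contains_xy(roi, px, py).mean()
        self._cap_theta = np.maximum(cap_theta, 0.25 * np.pi)

        self._nx, self._ny = nx, ny
        self._origin = (xs[0], ys[0])
        self._in_roi = in_roi
        self._fibre_id = fibre_id
        self._cap_mask = cap_mask
        self._cap_owner = cap_owner
        self._X, self._Y = X, Y
        GI, GJ = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        self._GI, self._GJ = GI, GJ
        idx = np.full((nx, ny), -1, dtype=np.int64)
        idx[in_roi] = np.arange(in_roi.sum())
        self._idx = idx

    # -- assembly -------------------------------------------------------
    def _conductivity(self, P: np.ndarray) -> np.ndarray:
        """Effective conductivity k(P) per node (ml O₂ cm⁻¹ s⁻¹ mmHg⁻¹)."""
        p = self.params
        k = np.full((self._nx, self._ny), p.d_o2 * p.alpha)
        fib = self._fibre_id >= 0
        k[fib] += p.d_mb * p.c_mb * p.p50_mb / (P[fib] + p.p50_mb) ** 2
        k[~self._in_roi] = 0.0
        return k

    def _assemble(self, P_prev: np.ndarray):
        p = self.params
        nx, ny = self._nx, self._ny
        h_cm = p.grid_h * CM_PER_UM
        k = self._conductivity(P_prev)
        idx = self._idx
        n_unknown = int(self._in_roi.sum())
        fib = self._fibre_id >= 0
        q = p.demand_scale * p.m0

        rows, cols, vals = [], [], []
        rhs = np.zeros(n_unknown)
        diag = np.zeros(n_unknown)

        dirichlet = self._cap_mask
        free = self._in_roi & ~dirichlet

        # consumption (linearised Michaelis–Menten or zero-order)
        if p.consumption_order == "michaelis":
            c_lin = np.where(fib, q / (P_prev + p.p_crit), 0.0)
            diag[idx[free]] += c_lin[free]
        else:
            rhs[idx[free]] -= np.where(fib, q, 0.0)[free]

        # interior diffusion faces (free–free): symmetric 5-point stencil
        # with harmonic face conductivities
        h_um = p.grid_h
        r_um = p.r_cap / CM_PER_UM
        caps = self.section.capillaries
        bdry_recs = []  # (free_idx, opp_gi, opp_gj, delta_um, k_free) per face
        for di, dj in ((1, 0), (0, 1)):
            si = np.s_[:nx - di, :ny - dj]
            sj = np.s_[di:, dj:]
            both = self._in_roi[si] & self._in_roi[sj]
            ki, kj = k[si], k[sj]
            kf = np.where(both, 2.0 * ki * kj / np.where(ki + kj > 0,
                                                         ki + kj, 1.0), 0.0)
            w = kf[both] / h_cm ** 2
            a, b = idx[si][both], idx[sj][both]
            da, db = dirichlet[si][both], dirichlet[sj][both]
            ff = ~da & ~db
            for m, other in ((a, b), (b, a)):
                diag_add = np.zeros(n_unknown)
                np.add.at(diag_add, m[ff], w[ff])
                diag += diag_add
                rows.append(m[ff]); cols.append(other[ff]); vals.append(-w[ff])
            # record capillary-boundary faces (free node, owning capillary)
            xa, ya = self._X[si][both], self._Y[si][both]
            xb, yb = self._X[sj][both], self._Y[sj][both]
            gia, gja = self._GI[si][both], self._GJ[si][both]
            gib, gjb = self._GI[sj][both], self._GJ[sj][both]
            oa, ob = self._cap_owner[si][both], self._cap_owner[sj][both]
            for (m, is_dir_m, is_dir_o, xm, ym, gi, gj, own_o, ux, uy) in (
                    (a, da, db, xa, ya, gia, gja, ob, di, dj),
                    (b, db, da, xb, yb, gib, gjb, oa, -di, -dj)):
                sel = ~is_dir_m & is_dir_o
                if sel.any():
                    bdry_recs.append((m[sel], xm[sel], ym[sel],
                                      k[gi[sel], gj[sel]], own_o[sel],
                                      float(ux), float(uy)))

        # Capillary-boundary coupling with the radial (Peaceman-type) log
        # correction: the exact steady resistance between the capillary
        # circle (radius r_cap) and a node at radius r is ln(r/r_cap)/k
        # per subtended radian, so the face coefficient uses r·ln(r/r_cap)
        # in place of the linear node–circle distance.  Per capillary, the
        # angular coverage of the staircase of faces is normalised to the
        # circle arc actually inside the ROI, so the wall flux is neither
        # under- nor over-counted.  The coupling stays in the matrix, so
        # the discrete consumption/influx balance is exact.
        if bdry_recs:
            m_all = np.concatenate([r[0] for r in bdry_recs])
            xm = np.concatenate([r[1] for r in bdry_recs])
            ym = np.concatenate([r[2] for r in bdry_recs])
            kf = np.concatenate([r[3] for r in bdry_recs])
            own = np.concatenate([r[4] for r in bdry_recs])
            ux = np.concatenate([np.full(len(r[0]), r[5]) for r in bdry_recs])
            uy = np.concatenate([np.full(len(r[0]), r[6]) for r in bdry_recs])
            rx, ry = xm - caps[own, 0], ym - caps[own, 1]
            r = np.maximum(np.hypot(rx, ry), r_um * 1.02)
            g = np.abs(rx * ux + ry * uy) / r      # |cos| of face vs radial
            dtheta = g * h_um / r                  # angle subtended per face
            coverage = np.zeros(len(caps))
            np.add.at(coverage, own, dtheta)
            scale = self._cap_theta[own] / np.maximum(coverage[own], 1e-12)
            w_b = kf * scale * dtheta / (h_cm ** 2 * np.log(r / r_um))
            dd = np.zeros(n_unknown)
            np.add.at(dd, m_all, w_b)
            diag += dd
            rr = np.zeros(n_unknown)
            np.add.at(rr, m_all, w_b * p.p_cap)
            rhs += rr
            self._bflux = [(m_all, w_b)]
        else:
            self._bflux = []

        # Dirichlet rows: identity
        dmask = idx[dirichlet]
        diag[dmask] = 1.0
        rhs[dmask] = p.p_cap

        rows.append(np.arange(n_unknown)); cols.append(np.arange(n_unknown))
        vals.append(diag)
        A = csr_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n_unknown, n_unknown))
        return A, rhs

    # -- solve ----------------------------------------------------------
    def solve(self, demand: Optional[float | str] = None) -> PO2Field:
        """Solve to steady state; ``demand`` overrides the params'
        demand_scale ("rest" = 0.1, "max" = 1.0, or a fraction)."""
        p = self.params
        if demand is not None:
            scale = {"rest": 0.1, "max": 1.0}.get(demand, demand)
            p = replace(p, demand_scale=float(scale))
        P = np.full((self._nx, self._ny), p.p_cap)
        P[~self._in_roi] = np.nan
        self_params, self.params = self.params, p
        try:
            last_change = np.inf
            for it in range(1, p.max_iter + 1):
                Pwork = np.where(self._in_roi, np.nan_to_num(P, nan=p.p_cap), p.p_cap)
                A, rhs = self._assemble(Pwork)
                sol = spsolve(A.tocsc(), rhs)
                P_new = np.full_like(P, np.nan)
                P_new[self._in_roi] = sol
                if p.damping < 1.0 and it > 1:
                    P_new[self._in_roi] = (p.damping * P_new[self._in_roi]
                                           + (1 - p.damping) * P[self._in_roi])
                change = np.nanmax(np.abs(P_new - P)) / p.p_cap
                P = P_new
                last_change = change
                linear = (p.consumption_order == "zero" and p.c_mb == 0.0)
                if change <= p.tol or linear:
                    break
            else:
                raise TransportError(
                    f"Picard iteration did not converge in {p.max_iter} "
                    f"iterations (relative change {last_change:.3e})")
            # conservation at the converged state: re-assemble with the
            # final iterate and integrate consumption vs capillary influx
            Pfin = np.where(self._in_roi, np.nan_to_num(P, nan=p.p_cap), p.p_cap)
            self._assemble(Pfin)
            h_cm = p.grid_h * CM_PER_UM
            fib = self._fibre_id >= 0
            free = self._in_roi & ~self._cap_mask
            q = p.demand_scale * p.m0
            if p.consumption_order == "michaelis":
                M = np.where(fib & free, q * Pfin / (Pfin + p.p_crit), 0.0)
            else:
                M = np.where(fib & free, q, 0.0)
            consumption = float(M.sum() * h_cm ** 2)
            # capillary influx through the discrete boundary couplings;
            # matrix-consistent, so it balances consumption exactly
            Pu = Pfin[self._in_roi]
            influx = 0.0
            for i_idx, w_b in self._bflux:
                influx += float(np.sum(w_b * (p.p_cap - Pu[i_idx])) * h_cm ** 2)
        finally:
            self.params = self_params
        return PO2Field(grid=P, fibre_id=self._fibre_id,
                        capillary_mask=self._cap_mask,
                        fibre_types=self.section.fibre_types(),
                        grid_h=p.grid_h, origin=self._origin, params=p,
                        n_iterations=it, residual=last_change,
                        conservation=(consumption, influx))

    fit = solve  # statsmodels-style alias


# ----------------------------------------------------------------------
# Analytic reference and summaries
# ----------------------------------------------------------------------

def krogh_reference(params: TransportParams, tissue_radius: float,
                    r: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Krogh-cylinder PO₂ profile (zero-order consumption,
    no myoglobin).

    For K = d_o2·α and M = demand_scale·m0,

        P(r) = P_cap + (M/4K)(r² − r_cap²) − (M·R_t²/2K)·ln(r/r_cap),

    which satisfies ∇·(K∇P) = M, P(r_cap) = P_cap and P'(R_t) = 0, and
    the flux balance 2π·r_cap·K·P'(r_cap) = −M·π(R_t² − r_cap²).

    Returns ``(r, P)`` with radii in cm and PO₂ in mmHg.
    """
    if tissue_radius <= params.r_cap:
        raise ValueError("tissue_radius must exceed r_cap")
    if r is None:
        r = np.linspace(params.r_cap, tissue_radius, 200)
    r = np.asarray(r, dtype=float)
    if np.any(r < params.r_cap - 1e-15):
        raise ValueError("radii below r_cap are inside the capillary")
    K = params.d_o2 * params.alpha
    M = params.demand_scale * params.m0
    P = (params.p_cap + M / (4 * K) * (r ** 2 - params.r_cap ** 2)
         - M * tissue_radius ** 2 / (2 * K) * np.log(r / params.r_cap))
    return r, P


def summarize_po2(field: PO2Field, threshold: float = 0.5) -> PO2Summary:
    """Area-weighted per-type mean PO₂ over fibre pixels and the hypoxic
    fibre-area fraction (P below ``threshold`` mmHg)."""
    fib = field.fibre_id >= 0
    if not fib.any():
        raise TransportError("field has an empty fibre mask")
    P = field.grid
    types = np.array(field.fibre_types + [""], dtype=object)
    node_type = np.where(fib, types[np.clip(field.fibre_id, 0, None)], "")
    means: dict = {}
    for t in sorted({ft for ft in field.fibre_types}):
        m = node_type == t
        if m.any():
            means[t] = float(np.nanmean(P[m]))
    means["all"] = float(np.nanmean(P[fib]))
    hyp = float(np.mean(P[fib] < threshold))
    return PO2Summary(mean_po2=means, hypoxic_fraction=hyp, threshold=threshold)
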
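"""Implicit-membrane linearized Poisson–Boltzmann solver and valence extraction.

The membrane potential V enters the linearized PB equation as an extra
source term restricted to the intracellular electrolyte (the Roux
formulation for implicit-membrane systems):

    -div(eps(r) grad(u)) + kbar2(r) u = 4*pi*l_B * rho(r) + kbar2(r) * u_V * f(r)

with u the potential in thermal units (kT/e), eps(r) the dielectric map,
kbar2(r) = eps_s * kappa^2 the modified screening coefficient (nonzero only
in ion-accessible solvent), l_B the vacuum Bjerrum length, rho the point
charges of the atomic model (trilinearly spread onto the grid), u_V the
applied intracellular potential in kT/e, and f(r) the Heaviside indicator
of the intracellular solution (1 in the connected intracellular solvent, 0
in membrane, protein, and extracellular solution).

The total electrostatic energy is the plain charge-potential sum
E = sum_i q_i * phi(r_i) (no 1/2 charging factor; absolute values are
convention-dependent but the V-linear part, and hence the valence, is not).
The valence of a transition is the slope of Delta_E between the bound and
free configurations versus V, divided by Faraday's constant: the effective
fraction of an elementary charge displaced across the transmembrane field,
positive when positive charge moves toward the cytoplasm.

Discretization: 7-point finite differences on a uniform grid, harmonic-mean
dielectric on cell faces, Dirichlet boundaries from a screened-Coulomb
superposition plus the 1D bare-membrane voltage profile. The resulting
symmetric positive-definite system is solved by Jacobi-preconditioned
conjugate gradients.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import label as ndi_label
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .constants import (
    AVOGADRO,
    FARADAY_KCAL_PER_MOL_V,
    R_KCAL_PER_MOL_K,
    bjerrum_length_vacuum_A,
    thermal_voltage_mV,
)
from .model_io import AtomicModel, StatePair

__all__ = [
    "Grid3D",
    "MembraneSlab",
    "SolverSettings",
    "FieldMaps",
    "PBSolution",
    "ValenceResult",
    "build_region_maps",
    "solve_lpb",
    "electrostatic_energy",
    "compute_valence",
    "membrane_voltage_profile",
    "write_dx",
]

#: Faraday constant expressed in kcal/(mol·mV·e): the slope-to-valence divisor.
F_KCAL_PER_MOL_MV = FARADAY_KCAL_PER_MOL_V / 1000.0


@dataclass(frozen=True)
class Grid3D:
    """Uniform rectilinear grid: node n = origin + spacing * index."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if any(d < 9 for d in self.dims):
            raise ValueError(f"dims must be >= 9 per axis (stencil room), got {self.dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)
        )

    @property
    def upper_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)

    @classmethod
    def centered(cls, center: tuple[float, float, float], spacing: float,
                 dims: tuple[int, int, int]) -> "Grid3D":
        half = spacing * (np.asarray(dims) - 1) / 2.0
        return cls(origin=tuple(np.asarray(center) - half), spacing=spacing, dims=tuple(dims))


@dataclass(frozen=True)
class MembraneSlab:
    """Implicit membrane: low-dielectric slab z_lower <= z <= z_upper."""

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError(f"need z_lower < z_upper, got [{self.z_lower}, {self.z_upper}]")

    @property
    def thickness(self) -> float:
        return self.z_upper - self.z_lower


@dataclass(frozen=True)
class SolverSettings:
    """Dielectric, electrolyte, and numerical parameters of a PB solve.

    Defaults follow common implicit-membrane PB practice: protein and
    membrane interior at eps 2, water at 80, 150 mM 1:1 salt, a 2 Å
    ion-exclusion (Stern) shell and a 1.4 Å solvent probe.
    """

    eps_protein: float = 2.0
    eps_membrane: float = 2.0
    eps_solvent: float = 80.0
    ionic_strength_M: float = 0.150
    temperature_K: float = 298.15
    stern_layer_A: float = 2.0
    solvent_probe_A: float = 1.4
    membrane_potential_mV: float = 0.0
    tolerance: float = 1e-6
    max_iterations: int = 5000
    enforce_padding: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if min(self.eps_protein, self.eps_membrane, self.eps_solvent) < 1:
            raise ValueError("dielectric constants must be >= 1")

    @property
    def kappa2_bulk(self) -> float:
        """Modified screening coefficient kbar2 = 8*pi*l_B*n_ion in 1/A^2."""
        n_ion = self.ionic_strength_M * AVOGADRO / 1e27  # ions per A^3
        return 8.0 * np.pi * bjerrum_length_vacuum_A(self.temperature_K) * n_ion

    @property
    def debye_length_A(self) -> float:
        """Debye screening length in the bulk solvent, Å."""
        k2 = self.kappa2_bulk / self.eps_solvent
        return float(1.0 / np.sqrt(k2)) if k2 > 0 else np.inf

    @property
    def thermal_mV(self) -> float:
        return thermal_voltage_mV(self.temperature_K)


@dataclass
class FieldMaps:
    """Co-registered eps(r), kbar2(r) and f(r) coefficient maps."""

    grid: Grid3D
    epsilon: np.ndarray
    kappa2: np.ndarray
    f_intracellular: np.ndarray
    slab: MembraneSlab | None = None

    def __post_init__(self) -> None:
        for name in ("epsilon", "kappa2", "f_intracellular"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid dims {self.grid.shape}")
        if np.any((self.f_intracellular > 0) & (self.kappa2 <= 0)):
            raise ValueError("f may be nonzero only where kappa2 > 0")


@dataclass
class PBSolution:
    """Grid potential in kT/e plus convergence diagnostics."""

    phi: np.ndarray  # kT/e
    grid: Grid3D
    settings: SolverSettings
    converged: bool
    iterations: int
    residual: float

    @property
    def phi_mV(self) -> np.ndarray:
        return self.phi * self.settings.thermal_mV


@dataclass
class ValenceResult:
    """Valence (slope of Delta_E vs V over F) and the per-voltage table."""

    valence: float
    intercept_kcal_mol: float
    voltages_mV: list[float]
    delta_E_kcal_mol: list[float]
    fit_r2: float
    description: str = ""

    def to_dict(self) -> dict:
        return {
            "valence": self.valence,
            "intercept_kcal_mol": self.intercept_kcal_mol,
            "per_voltage": [
                {"V_mV": v, "delta_E_kcal_mol": e}
                for v, e in zip(self.voltages_mV, self.delta_E_kcal_mol)
            ],
            "fit_r2": self.fit_r2,
            "description": self.description,
        }


# --- region map construction ------------------------------------------------


def _sphere_union_mask(grid: Grid3D, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean node mask of the union of spheres (vectorized per atom)."""
    mask = np.zeros(grid.shape, dtype=bool)
    if centers.shape[0] == 0:
        return mask
    ax, ay, az = grid.axes()
    h = grid.spacing
    for (cx, cy, cz), r in zip(centers, radii):
        if r <= 0:
            continue
        # clip to the local bounding box of the sphere
        i0, i1 = np.searchsorted(ax, [cx - r - h, cx + r + h])
        j0, j1 = np.searchsorted(ay, [cy - r - h, cy + r + h])
        k0, k1 = np.searchsorted(az, [cz - r - h, cz + r + h])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx2 = (ax[i0:i1] - cx) ** 2
        dy2 = (ay[j0:j1] - cy) ** 2
        dz2 = (az[k0:k1] - cz) ** 2
        local = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) <= r * r
        mask[i0:i1, j0:j1, k0:k1] |= local
    return mask


def build_region_maps(
    model: AtomicModel,
    slab: MembraneSlab | None,
    grid: Grid3D,
    settings: SolverSettings,
) -> FieldMaps:
    """Construct the eps / kbar2 / f coefficient maps for one configuration.

    Dielectric: eps_protein inside the probe-inflated atomic envelope,
    eps_membrane inside the slab outside the protein, eps_solvent
    elsewhere. Ions (kbar2 > 0) live in solvent beyond the Stern shell and
    outside the membrane. f = 1 on ion-accessible solvent nodes 6-connected
    to the lower grid face (the intracellular bath); solvent pockets not
    connected to that bath get f = 0.

    The grid must pad the model's bounding box by at least three Debye
    lengths on every axis (checked unless ``settings.enforce_padding`` is
    off), and the slab must lie inside the grid.
    """
    if len(model) > 0 and settings.enforce_padding and np.isfinite(settings.debye_length_A):
        lo, hi = model.bounding_box
        pad = 3.0 * settings.debye_length_A
        glo = np.asarray(grid.origin)
        ghi = grid.upper_corner
        if np.any(lo - glo < pad - 1e-9) or np.any(ghi - hi < pad - 1e-9):
            raise ValueError(
                f"grid too small: need >= {pad:.1f} A (3 Debye lengths) of padding "
                f"around the model bounding box [{lo}, {hi}]"
            )
    az = grid.axes()[2]
    if slab is not None and not (az[0] < slab.z_lower and slab.z_upper < az[-1]):
        raise ValueError(
            f"membrane slab [{slab.z_lower}, {slab.z_upper}] not inside grid z range "
            f"[{az[0]}, {az[-1]}]"
        )

    pos = model.positions
    radii = model.radii
    protein = _sphere_union_mask(grid, pos, radii + settings.solvent_probe_A)
    ion_excluded = _sphere_union_mask(
        grid, pos, radii + settings.solvent_probe_A + settings.stern_layer_A
    )

    eps = np.full(grid.shape, settings.eps_solvent)
    kappa2 = np.full(grid.shape, settings.kappa2_bulk)
    z = az[None, None, :]
    if slab is not None:
        in_slab = np.broadcast_to((z >= slab.z_lower) & (z <= slab.z_upper), grid.shape)
        eps[in_slab] = settings.eps_membrane
        kappa2[in_slab.copy()] = 0.0
    eps[protein] = settings.eps_protein
    kappa2[protein | ion_excluded] = 0.0

    f = np.zeros(grid.shape)
    if slab is not None:
        accessible = kappa2 > 0
        labels, _ = ndi_label(accessible)  # 6-connectivity by default
        bottom = labels[:, :, 0]
        bath_ids = np.unique(bottom[bottom > 0])
        if bath_ids.size:
            f = np.isin(labels, bath_ids).astype(float)
    return FieldMaps(grid=grid, epsilon=eps, kappa2=kappa2, f_intracellular=f, slab=slab)


# --- boundary values and initial guess -------------------------------------


def membrane_voltage_profile(z: np.ndarray, slab: MembraneSlab,
                             settings: SolverSettings) -> np.ndarray:
    """Bare-membrane (no protein, no charges) potential profile g(z).

    Closed-form 1D solution of the membrane-potential problem for two
    electrolyte baths separated by the dielectric slab, normalized so the
    deep intracellular bath sits at 1 and the extracellular bath at 0:
    exponential relaxation (Debye length) in each bath, linear across the
    slab. This doubles as the far-field Dirichlet profile for 3D solves.
    """
    kappa = 1.0 / settings.debye_length_A
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError("membrane potential requires nonzero ionic strength")
    d = slab.thickness
    s = settings.eps_membrane / (d * kappa * settings.eps_solvent)
    a = -s / (1.0 + 2.0 * s)      # g(z_lower) = 1 + a
    b = s / (1.0 + 2.0 * s)       # g(z_upper) = b
    g_l, g_u = 1.0 + a, b
    z = np.asarray(z, dtype=float)
    g = np.empty_like(z)
    below = z <= slab.z_lower
    above = z >= slab.z_upper
    inside = ~(below | above)
    g[below] = 1.0 + a * np.exp(kappa * (z[below] - slab.z_lower))
    g[above] = b * np.exp(-kappa * (z[above] - slab.z_upper))
    g[inside] = g_l + (g_u - g_l) * (z[inside] - slab.z_lower) / d
    return g


def _debye_superposition(grid: Grid3D, model: AtomicModel,
                         settings: SolverSettings,
                         faces_only: bool) -> np.ndarray:
    """Screened-Coulomb superposition of all charges, in kT/e.

    u(r) = sum_i q_i * (l_B / eps_s) * exp(-kappa |r - r_i|) / |r - r_i|
    evaluated on the full grid (small models) or only the 6 boundary faces.
    """
    lB = bjerrum_length_vacuum_A(settings.temperature_K)
    kappa = 1.0 / settings.debye_length_A if np.isfinite(settings.debye_length_A) else 0.0
    out = np.zeros(grid.shape)
    q = model.charges
    pos = model.positions
    if pos.shape[0] == 0:
        return out
    ax, ay, az = grid.axes()

    def add_block(ix, iy, iz):
        X = ax[ix][:, None, None, None]
        Y = ay[iy][None, :, None, None]
        Z = az[iz][None, None, :, None]
        r = np.sqrt(
            (X - pos[:, 0]) ** 2 + (Y - pos[:, 1]) ** 2 + (Z - pos[:, 2]) ** 2
        )
        r = np.maximum(r, grid.spacing / 2.0)
        contrib = (lB / settings.eps_solvent) * np.sum(
            q * np.exp(-kappa * r) / r, axis=-1
        )
        out[np.ix_(ix, iy, iz)] += contrib

    nx, ny, nz = grid.dims
    allx, ally, allz = np.arange(nx), np.arange(ny), np.arange(nz)
    if not faces_only:
        # chunk along x to bound memory
        step = max(1, int(2e7 / (ny * nz * max(1, len(q)))))
        for i0 in range(0, nx, step):
            add_block(allx[i0:i0 + step], ally, allz)
        return out
    add_block(np.array([0, nx - 1]), ally, allz)
    add_block(allx[1:-1], np.array([0, ny - 1]), allz)
    # avoid double-counting corners/edges: evaluate z faces on interior x,y only
    add_block(allx[1:-1], ally[1:-1], np.array([0, nz - 1]))
    return out


# --- the finite-difference solve -------------------------------------------


def _spread_charges(grid: Grid3D, model: AtomicModel) -> np.ndarray:
    """Trilinear (cloud-in-cell) assignment of point charges to grid nodes."""
    rho = np.zeros(grid.shape)
    if len(model) == 0:
        return rho
    frac = (model.positions - np.asarray(grid.origin)) / grid.spacing
    if np.any(frac < 0) or np.any(frac > np.asarray(grid.dims) - 1):
        raise ValueError("atom outside grid; enlarge the grid")
    base = np.floor(frac).astype(int)
    base = np.minimum(base, np.asarray(grid.dims) - 2)
    t = frac - base
    q = model.charges
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          q * wx * wy * wz)
    return rho


def _boundary_field(maps: FieldMaps, model: AtomicModel, settings: SolverSettings,
                    u_V: float) -> np.ndarray:
    """Dirichlet values (and initial guess) on the full grid, kT/e."""
    grid = maps.grid
    faces_only = len(model) > 64
    u = _debye_superposition(grid, model, settings, faces_only=faces_only)
    if u_V != 0.0:
        if maps.slab is None:
            raise ValueError("membrane potential requires a membrane slab")
        g = membrane_voltage_profile(grid.axes()[2], maps.slab, settings)
        u += u_V * g[None, None, :]
    return u


def solve_lpb(maps: FieldMaps, model: AtomicModel, settings: SolverSettings) -> PBSolution:
    """Solve the membrane-potential-modified linearized PB equation.

    7-point stencil, harmonic-mean face dielectrics, trilinear charge
    spreading; Dirichlet boundary = screened-Coulomb superposition plus
    the applied potential times the bare-membrane far-field profile.
    Returns the potential in kT/e; ``converged`` reports whether the
    relative residual met ``settings.tolerance``.
    """
    grid = maps.grid
    eps = maps.epsilon
    if np.any(eps <= 0):
        raise ValueError("dielectric map contains non-positive values")
    h = grid.spacing
    nx, ny, nz = grid.dims
    u_V = settings.membrane_potential_mV / settings.thermal_mV

    lB = bjerrum_length_vacuum_A(settings.temperature_K)
    rho = _spread_charges(grid, model)
    source = 4.0 * np.pi * lB * rho / h**3 + maps.kappa2 * u_V * maps.f_intracellular

    u_bc = _boundary_field(maps, model, settings, u_V)

    # interior numbering
    Ni = (nx - 2) * (ny - 2) * (nz - 2)
    num = -np.ones(grid.shape, dtype=np.int64)
    num[1:-1, 1:-1, 1:-1] = np.arange(Ni).reshape(nx - 2, ny - 2, nz - 2)

    interior = (slice(1, -1),) * 3
    diag = maps.kappa2[interior].ravel().astype(float)
    rhs = source[interior].ravel().astype(float)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    center = num[interior].ravel()

    shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    e_int = eps[interior]
    for sx, sy, sz in shifts:
        nb = (slice(1 + sx, (nx - 1 + sx) or None),
              slice(1 + sy, (ny - 1 + sy) or None),
              slice(1 + sz, (nz - 1 + sz) or None))
        e_nb = eps[nb]
        e_face = 2.0 * e_int * e_nb / (e_int + e_nb) / h**2
        diag += e_face.ravel()
        nb_num = num[nb].ravel()
        is_int = nb_num >= 0
        rows.append(center[is_int])
        cols.append(nb_num[is_int])
        vals.append(-e_face.ravel()[is_int])
        # boundary neighbours move to the RHS
        bmask = ~is_int
        if np.any(bmask):
            rhs[bmask] += e_face.ravel()[bmask] * u_bc[nb].ravel()[bmask]

    rows.append(center)
    cols.append(center)
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(Ni, Ni),
    ).tocsr()

    inv_diag = 1.0 / diag
    M = LinearOperator((Ni, Ni), matvec=lambda x: inv_diag * x)
    x0 = u_bc[interior].ravel()

    b_norm = np.linalg.norm(rhs)
    if b_norm == 0:
        phi = np.zeros(grid.shape)
        return PBSolution(phi=phi, grid=grid, settings=settings,
                          converged=True, iterations=0, residual=0.0)

    it_count = 0

    def _cb(_xk):
        nonlocal it_count
        it_count += 1

    x, info = cg(A, rhs, x0=x0, rtol=settings.tolerance, atol=0.0,
                 maxiter=settings.max_iterations, M=M, callback=_cb)
    residual = float(np.linalg.norm(rhs - A @ x) / b_norm)
    converged = info == 0 and residual <= settings.tolerance * 1.001
    if not converged:
        warnings.warn(
            f"PB solve did not converge: residual {residual:.2e} after {it_count} iterations",
            RuntimeWarning,
        )
    phi = u_bc.copy()
    phi[interior] = x.reshape(nx - 2, ny - 2, nz - 2)
    return PBSolution(phi=phi, grid=grid, settings=settings,
                      converged=converged, iterations=it_count, residual=residual)


# --- energies and valence ---------------------------------------------------


def _trilinear_sample(field: np.ndarray, grid: Grid3D, points: np.ndarray) -> np.ndarray:
    frac = (points - np.asarray(grid.origin)) / grid.spacing
    dims = np.asarray(grid.dims)
    if np.any(frac < 1.0 - 1e-9) or np.any(frac > dims - 2 + 1e-9):
        raise ValueError("atom outside the grid interior; enlarge the grid")
    base = np.floor(frac).astype(int)
    base = np.minimum(base, dims - 2)
    t = frac - base
    out = np.zeros(points.shape[0])
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                out += field[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz] * wx * wy * wz
    return out


def electrostatic_energy(solution: PBSolution, model: AtomicModel) -> float:
    """Charge-potential sum E = sum_i q_i phi(r_i) in kcal/mol.

    phi is interpolated trilinearly at atom positions. The grid
    self-energy of each charge is included; it is voltage-independent and
    cancels in the energy differences and slopes this package reports.
    """
    if not solution.converged:
        raise ValueError("PB solution did not converge; energy would be unreliable")
    if len(model) == 0:
        return 0.0
    u_at_atoms = _trilinear_sample(solution.phi, solution.grid, model.positions)
    kT = R_KCAL_PER_MOL_K * solution.settings.temperature_K
    return float(kT * np.sum(model.charges * u_at_atoms))


def compute_valence(
    pair: StatePair,
    slab: MembraneSlab,
    grid: Grid3D,
    settings: SolverSettings,
    voltages_mV: list[float] | None = None,
) -> ValenceResult:
    """Apparent valence of the bound<->free transition from Delta_E vs V.

    For each applied intracellular potential V the coefficient maps are
    rebuilt per state (same grid), the modified LPB is solved, and
    Delta_E(V) = E_bound(V) - E_free(V) is recorded. The valence is the
    least-squares slope of Delta_E versus V divided by F
    (0.0230609 kcal/(mol*mV*e)); z > 0 means net positive charge displaced
    toward the intracellular side upon binding.
    """
    if voltages_mV is None:
        voltages_mV = [-100.0, -50.0, 0.0, 50.0, 100.0]
    voltages = [float(v) for v in voltages_mV]
    if len(set(voltages)) < 3:
        raise ValueError("need at least 3 distinct voltages")
    if min(voltages) >= 0 or max(voltages) <= 0:
        raise ValueError("voltages must span zero")

    delta_E: list[float] = []
    maps_bound = build_region_maps(pair.state_bound, slab, grid, settings)
    maps_free = build_region_maps(pair.state_free, slab, grid, settings)
    for V in voltages:
        s = dataclasses.replace(settings, membrane_potential_mV=V)
        sol_b = solve_lpb(maps_bound, pair.state_bound, s)
        if not sol_b.converged:
            raise RuntimeError(f"bound-state solve failed to converge at V = {V} mV")
        sol_f = solve_lpb(maps_free, pair.state_free, s)
        if not sol_f.converged:
            raise RuntimeError(f"free-state solve failed to converge at V = {V} mV")
        delta_E.append(
            electrostatic_energy(sol_b, pair.state_bound)
            - electrostatic_energy(sol_f, pair.state_free)
        )

    v_arr = np.asarray(voltages)
    e_arr = np.asarray(delta_E)
    slope, intercept = np.polyfit(v_arr, e_arr, 1)
    pred = slope * v_arr + intercept
    ss_res = float(np.sum((e_arr - pred) ** 2))
    ss_tot = float(np.sum((e_arr - e_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ValenceResult(
        valence=float(slope / F_KCAL_PER_MOL_MV),
        intercept_kcal_mol=float(intercept),
        voltages_mV=voltages,
        delta_E_kcal_mol=[float(e) for e in delta_E],
        fit_r2=r2,
        description=pair.description,
    )


# --- OpenDX export ----------------------------------------------------------


def write_dx(field: np.ndarray, grid: Grid3D, path: str | Path,
             comment: str = "scalar field") -> None:
    """Write a scalar grid in OpenDX format (APBS-compatible)."""
    nx, ny, nz = grid.dims
    if field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    h = grid.spacing
    with Path(path).open("w") as out:
        out.write(f"# {comment}\n")
        out.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        out.write(f"origin {grid.origin[0]:.6e} {grid.origin[1]:.6e} {grid.origin[2]:.6e}\n")
        out.write(f"delta {h:.6e} 0.0 0.0\ndelta 0.0 {h:.6e} 0.0\ndelta 0.0 0.0 {h:.6e}\n")
        out.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        out.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = field.ravel(order="C")
        for i in range(0, flat.size, 3):
            out.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        out.write('attribute "dep" string "positions"\n')
        out.write('object "field" class field\n')
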
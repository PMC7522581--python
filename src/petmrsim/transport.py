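"""Condensed-history positron transport in tissue, with an optional uniform
axial magnetic field.

Scheme
------
Positrons lose energy continuously at the Berger-Seltzer collision stopping
power (Bethe theory with the positron correction term), taking fixed
fractional-energy steps (default dE/E = 5%) capped by a maximum geometric
step.  After each step the direction receives a multiple-scattering
deflection: the polar angle is Rayleigh-distributed with width
theta_0 = (13.6 MeV / beta c p) * sqrt(x / X0) * (1 + 0.038 ln(L / X0)),
azimuth uniform.  The logarithmic Highland correction is evaluated at the
particle's residual CSDA path L rather than the substep thickness x --
applied per substep it would destroy the additivity of the accumulated
variance and overestimate the detour; anchoring it at the physical path
keeps the step subdivision consistent.  Between scattering nodes the trajectory in a
magnetic field is the exact analytic helix segment for the step's path
length, so the gyroradius is reproduced to machine precision for loss-free
motion.  Radiative (bremsstrahlung) loss is neglected: it is below 2% of the
stopping power for these energies in tissue.  At the energy cutoff (default
10 keV, residual range well under 10 um in unit-density tissue) the positron
annihilates at rest.

Positrons cross low-density regions (air gaps) with negligible loss and
re-enter denser shapes; a positron is recorded as escaped once it leaves
the bounding box of all placed shapes, since its residual range in air
exceeds any phantom in this package.  Escaped positrons contribute no
annihilation photons — the mechanism behind the depressed thin-sleeve
sensitivity of high-endpoint emitters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .isotopes import IsotopeSpec, sample_decays
from .materials import Material, World

MEC2_KEV = 511.0
#: 2*pi*r_e^2*m_e*c^2 in MeV cm^2 (per electron), Bethe prefactor
_BETHE_PREF_MEV_CM2 = 2.549553e-25
#: momentum (MeV/c) = _PB * B (T) * r (mm) for unit charge
_PB = 0.299792458e-3
_ESCAPE_DENSITY = 0.01  # g/cm^3; lighter backgrounds do not stop positrons


@dataclass(frozen=True)
class TransportConfig:
    """Knobs of the condensed-history scheme.

    magnetic_field : uniform field vector in tesla (axial = z).
    max_step : geometric cap on one step, mm.
    energy_cutoff : annihilate at rest below this kinetic energy, keV.
    energy_fraction : fractional energy loss per step.
    scattering / energy_loss : disable switches for closed-form validation.
    """

    magnetic_field: tuple[float, float, float] = (0.0, 0.0, 0.0)
    max_step: float = 1.0
    energy_cutoff: float = 10.0
    energy_fraction: float = 0.05
    scattering: bool = True
    energy_loss: bool = True
    seed: int = 0
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.energy_cutoff < 0:
            raise ValueError("energy_cutoff must be non-negative")


def momentum_kev(kinetic_kev) -> np.ndarray:
    """Relativistic momentum p*c in keV: sqrt(T^2 + 2 T mc^2)."""
    t = np.asarray(kinetic_kev, dtype=float)
    return np.sqrt(t * (t + 2.0 * MEC2_KEV))


def gyroradius_mm(kinetic_kev, b_tesla: float) -> np.ndarray:
    """Gyroradius for motion perpendicular to a field of b_tesla."""
    return momentum_kev(kinetic_kev) / 1000.0 / (_PB * 1000.0 * b_tesla)


@dataclass
class PositronState:
    """Position (mm), unit direction, kinetic energy (keV)."""

    position: np.ndarray
    direction: np.ndarray
    kinetic_energy: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        self.direction = d / n
        if self.kinetic_energy < 0:
            raise ValueError("kinetic energy must be non-negative")

    @property
    def momentum(self) -> float:
        """p*c in MeV."""
        return float(momentum_kev(self.kinetic_energy)) / 1000.0


@dataclass(frozen=True)
class AnnihilationRecord:
    """Emission and annihilation points (mm) of one positron."""

    emission_point: np.ndarray
    annihilation_point: np.ndarray
    path_length: float
    escaped: bool = False

    @property
    def displacement(self) -> np.ndarray:
        return np.asarray(self.annihilation_point) - np.asarray(self.emission_point)


@dataclass
class AnnihilationCloud:
    """Columnar container of annihilation records (one row per positron)."""

    emission: np.ndarray  # (n, 3) mm
    annihilation: np.ndarray  # (n, 3) mm; NaN where escaped
    path_length: np.ndarray  # (n,) mm
    escaped: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.path_length)

    def __getitem__(self, i: int) -> AnnihilationRecord:
        return AnnihilationRecord(
            emission_point=self.emission[i],
            annihilation_point=self.annihilation[i],
            path_length=float(self.path_length[i]),
            escaped=bool(self.escaped[i]),
        )

    @property
    def displacement(self) -> np.ndarray:
        return self.annihilation - self.emission

    def annihilated(self) -> "AnnihilationCloud":
        keep = ~self.escaped
        return AnnihilationCloud(
            self.emission[keep], self.annihilation[keep],
            self.path_length[keep], self.escaped[keep],
        )

    def escape_fraction(self) -> float:
        return float(np.mean(self.escaped))


# ---------------------------------------------------------------------------
# Physics kernels (vectorized over particles)
# ---------------------------------------------------------------------------

def collision_stopping_power_kev_mm(kinetic_kev, material: Material) -> np.ndarray:
    """Berger-Seltzer collision stopping power for positrons, keV/mm."""
    return _stopping_kev_mm(
        np.asarray(kinetic_kev, dtype=float),
        np.full(np.shape(np.asarray(kinetic_kev)), material.electron_density_cm3),
        np.full(np.shape(np.asarray(kinetic_kev)), material.mean_excitation_energy),
    )


def _stopping_kev_mm(t_kev: np.ndarray, ne_cm3: np.ndarray, i_ev: np.ndarray) -> np.ndarray:
    tau = t_kev / MEC2_KEV
    gamma = 1.0 + tau
    beta2 = np.clip(1.0 - 1.0 / gamma**2, 1e-12, None)
    i_ratio = (i_ev * 1e-3) / MEC2_KEV  # I in keV over mc^2
    tp2 = tau + 2.0
    f_pos = 2.0 * np.log(2.0) - (beta2 / 12.0) * (
        23.0 + 14.0 / tp2 + 10.0 / tp2**2 + 4.0 / tp2**3
    )
    bracket = np.log(np.clip(tau**2 * tp2 / 2.0, 1e-300, None) / i_ratio**2) + f_pos
    bracket = np.clip(bracket, 0.5, None)  # keep positive far below validity
    s_mev_cm = _BETHE_PREF_MEV_CM2 * ne_cm3 / beta2 * bracket
    return s_mev_cm * 100.0  # MeV/cm -> keV/mm


def csda_range_mm(kinetic_kev: float, material: Material, n_grid: int = 4000) -> float:
    """Continuous-slowing-down path length from 1 keV up, by quadrature."""
    e = np.linspace(1.0, kinetic_kev, n_grid)
    return float(np.trapezoid(1.0 / collision_stopping_power_kev_mm(e, material), e))


class _CsdaTable:
    """Residual CSDA path vs energy for each material of a world (interp)."""

    def __init__(self, materials: list[Material], e_max_kev: float = 6000.0):
        self.e_grid = np.linspace(1.0, e_max_kev, 600)
        rows = []
        for m in materials:
            if m.density < _ESCAPE_DENSITY:
                rows.append(np.full_like(self.e_grid, np.inf))
            else:
                inv_s = 1.0 / _stopping_kev_mm(
                    self.e_grid,
                    np.full_like(self.e_grid, m.electron_density_cm3),
                    np.full_like(self.e_grid, m.mean_excitation_energy),
                )
                rows.append(
                    np.concatenate(
                        ([0.0], np.cumsum(np.diff(self.e_grid) * (inv_s[1:] + inv_s[:-1]) / 2))
                    )
                )
        self.table = np.array(rows)

    def lookup(self, t_kev: np.ndarray, mat_idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(t_kev))
        for m in range(len(self.table)):
            sel = mat_idx == m
            if sel.any():
                out[sel] = np.interp(t_kev[sel], self.e_grid, self.table[m])
        return out


def _highland_log_factor(residual_path_mm: np.ndarray, x0_mm: np.ndarray) -> np.ndarray:
    """1 + 0.038 ln(L/X0) evaluated at the residual CSDA path, clamped."""
    ratio = np.clip(residual_path_mm / x0_mm, 1e-12, None)
    return np.clip(1.0 + 0.038 * np.log(ratio), 0.25, 1.0)


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2) perpendicular to each unit vector in d (n,3).

    e1 = d x a with a = x-hat (or y-hat where d is nearly axial), written
    out component-wise: np.cross is a hot spot at this call frequency.
    """
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    use_x = np.abs(dx) < 0.9
    e1x = np.where(use_x, 0.0, -dz)
    e1y = np.where(use_x, dz, 0.0)
    e1z = np.where(use_x, -dy, dx)
    inv = 1.0 / np.sqrt(e1x**2 + e1y**2 + e1z**2)
    e1x, e1y, e1z = e1x * inv, e1y * inv, e1z * inv
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    return np.stack((e1x, e1y, e1z), axis=1), np.stack((e2x, e2y, e2z), axis=1)


def _advance_helix(
    pos: np.ndarray,
    dirs: np.ndarray,
    step_mm: np.ndarray,
    p_kev: np.ndarray,
    bvec: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance along exact helix segments of given path length.

    Positive charge assumed; the rotation sense follows d' proportional to
    d x B.  With |B| = 0 this reduces to a straight step.
    """
    bmag = float(np.linalg.norm(bvec))
    if bmag == 0.0:
        return pos + dirs * step_mm[:, None], dirs
    bhat = np.asarray(bvec, dtype=float) / bmag
    d_par = dirs @ bhat
    perp = dirs - d_par[:, None] * bhat
    sin_a = np.linalg.norm(perp, axis=1)
    phi = _PB * 1000.0 * bmag * step_mm / (p_kev / 1000.0)  # rad, pitch-free
    straight = sin_a < 1e-12
    u = np.where(straight[:, None], 0.0, perp / np.where(sin_a[:, None] == 0, 1.0, sin_a[:, None]))
    w = np.cross(bhat[None, :], u)
    r_g = (p_kev / 1000.0) * sin_a / (_PB * 1000.0 * bmag)  # mm, uses p_perp
    sin_p, cos_p = np.sin(phi), np.cos(phi)
    # d(dir)/ds ~ d x B: with d = u initially, d x bhat = -w, so rotate u -> -w
    new_pos = (
        pos
        + (step_mm * d_par)[:, None] * bhat
        + (r_g * sin_p)[:, None] * u
        - (r_g * (1.0 - cos_p))[:, None] * w
    )
    new_dir = d_par[:, None] * bhat + (sin_a * cos_p)[:, None] * u - (sin_a * sin_p)[:, None] * w
    new_pos = np.where(straight[:, None], pos + dirs * step_mm[:, None], new_pos)
    new_dir = np.where(straight[:, None], dirs, new_dir)
    return new_pos, new_dir


def _scatter(
    dirs: np.ndarray,
    theta0: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply a Rayleigh(theta0) polar deflection with uniform azimuth."""
    n = len(dirs)
    theta = theta0 * np.sqrt(-2.0 * np.log(np.clip(rng.random(n), 1e-300, None)))
    theta = np.minimum(theta, np.pi)
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    e1, e2 = _perp_frame(dirs)
    st, ct = np.sin(theta), np.cos(theta)
    a = st * np.cos(psi)
    b = st * np.sin(psi)
    out = ct[:, None] * dirs + a[:, None] * e1 + b[:, None] * e2
    inv = 1.0 / np.sqrt(np.einsum("ij,ij->i", out, out))
    return out * inv[:, None]


# ---------------------------------------------------------------------------
# Batch transport
# ---------------------------------------------------------------------------

def transport_batch(
    energies_kev: np.ndarray,
    origins: np.ndarray,
    directions: np.ndarray,
    world: World,
    config: TransportConfig,
    rng: np.random.Generator,
) -> AnnihilationCloud:
    """Transport a batch of positrons to annihilation (or escape)."""
    n = len(energies_kev)
    pos = np.array(origins, dtype=float).reshape(n, 3).copy()
    dirs = np.array(directions, dtype=float).reshape(n, 3).copy()
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    t_kev = np.asarray(energies_kev, dtype=float).copy()

    emission = pos.copy()
    annihilation = np.full((n, 3), np.nan)
    path = np.zeros(n)
    escaped = np.zeros(n, dtype=bool)

    mats = world.materials()
    ne = np.array([m.electron_density_cm3 for m in mats])
    i_ev = np.array([m.mean_excitation_energy for m in mats])
    x0_mm = np.array([m.radiation_length_mm for m in mats])
    bvec = np.asarray(config.magnetic_field, dtype=float)
    csda = _CsdaTable(mats) if config.scattering else None
    world_lo, world_hi = world.bounds()
    world_lo = world_lo - 0.5
    world_hi = world_hi + 0.5

    # immediately-at-rest positrons annihilate at the origin
    at_rest = t_kev <= config.energy_cutoff
    annihilation[at_rest] = pos[at_rest]
    idx = np.flatnonzero(~at_rest)
    pos, dirs, t_kev = pos[idx], dirs[idx], t_kev[idx]
    acc_path = np.zeros(len(idx))

    for _ in range(config.max_iterations):
        if len(idx) == 0:
            break
        mat_idx = world.material_index_at(pos)

        # escape: outside the bounding box of every placed shape
        lost = np.any((pos < world_lo) | (pos > world_hi), axis=1)
        if np.any(lost):
            gi = idx[lost]
            escaped[gi] = True
            path[gi] = acc_path[lost]
            keep = ~lost
            idx, pos, dirs, t_kev, acc_path, mat_idx = (
                idx[keep], pos[keep], dirs[keep], t_kev[keep],
                acc_path[keep], mat_idx[keep],
            )
            if len(idx) == 0:
                break

        if config.energy_loss:
            s_kev_mm = _stopping_kev_mm(t_kev, ne[mat_idx], i_ev[mat_idx])
            de = config.energy_fraction * t_kev
            # near-vacuum media: free flight at the geometric step cap
            with np.errstate(divide="ignore"):
                step = np.where(s_kev_mm > 1e-9, de / s_kev_mm, np.inf)
            over = step > config.max_step
            step[over] = config.max_step
            de = np.where(s_kev_mm > 1e-9, step * s_kev_mm, 0.0)
            last = (t_kev - de <= config.energy_cutoff) & (s_kev_mm > 1e-9)
            de = np.where(last, t_kev - config.energy_cutoff, de)
            step = np.where(s_kev_mm > 1e-9, de / s_kev_mm, step)
        else:
            step = np.full(len(idx), config.max_step)
            de = np.zeros(len(idx))
            last = np.zeros(len(idx), dtype=bool)

        p_kev = momentum_kev(t_kev)
        new_pos, new_dirs = _advance_helix(pos, dirs, step, p_kev, bvec)

        # sub-step at material boundaries: bisect the helix parameter
        crossed = world.material_index_at(new_pos) != mat_idx
        if np.any(crossed):
            ci = np.flatnonzero(crossed)
            lo = np.zeros(len(ci))
            hi = np.ones(len(ci))
            for _ in range(12):
                mid = (lo + hi) / 2.0
                mp, _ = _advance_helix(pos[ci], dirs[ci], step[ci] * mid, p_kev[ci], bvec)
                inside = world.material_index_at(mp) == mat_idx[ci]
                lo = np.where(inside, mid, lo)
                hi = np.where(inside, hi, mid)
            frac = np.clip(hi, 1e-6, 1.0)  # just past the crossing
            sub_pos, sub_dir = _advance_helix(pos[ci], dirs[ci], step[ci] * frac, p_kev[ci], bvec)
            new_pos[ci] = sub_pos
            new_dirs[ci] = sub_dir
            step[ci] = step[ci] * frac
            de[ci] = de[ci] * frac
            last[ci] = t_kev[ci] - de[ci] <= config.energy_cutoff

        pos = new_pos
        dirs = new_dirs
        acc_path += step
        t_kev = np.maximum(t_kev - de, config.energy_cutoff)

        if config.scattering:
            gamma = 1.0 + t_kev / MEC2_KEV
            beta = np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 1e-12, None))
            residual = csda.lookup(t_kev, mat_idx)
            theta0 = (
                (13.6e3 / (beta * p_kev))
                * np.sqrt(np.clip(step / x0_mm[mat_idx], 0.0, None))
                * _highland_log_factor(residual, x0_mm[mat_idx])
            )
            dirs = _scatter(dirs, theta0, rng)

        done = last if config.energy_loss else np.zeros(len(idx), dtype=bool)
        if np.any(done):
            gi = idx[done]
            annihilation[gi] = pos[done]
            path[gi] = acc_path[done]
            keep = ~done
            idx, pos, dirs, t_kev, acc_path = (
                idx[keep], pos[keep], dirs[keep], t_kev[keep], acc_path[keep],
            )
    if len(idx):
        raise RuntimeError(
            f"{len(idx)} positrons did not terminate within "
            f"{config.max_iterations} steps"
        )

    return AnnihilationCloud(
        emission=emission, annihilation=annihilation, path_length=path, escaped=escaped
    )


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------

def step(
    state: PositronState,
    material: Material,
    config: TransportConfig,
    rng: np.random.Generator,
) -> PositronState:
    """One condensed-history step in a homogeneous material."""
    if state.kinetic_energy <= config.energy_cutoff:
        raise ValueError("kinetic energy must exceed the cutoff to step")
    t = np.array([state.kinetic_energy])
    if config.energy_loss:
        ne = np.array([material.electron_density_cm3])
        i_ev = np.array([material.mean_excitation_energy])
        s = _stopping_kev_mm(t, ne, i_ev)
        de = config.energy_fraction * t
        stp = np.minimum(de / s, config.max_step)
        de = stp * s
        de = np.minimum(de, t - config.energy_cutoff)
        stp = de / s
    else:
        stp = np.array([config.max_step])
        de = np.array([0.0])
    p = momentum_kev(t)
    pos, dirs = _advance_helix(
        state.position[None, :], state.direction[None, :], stp, p,
        np.asarray(config.magnetic_field, dtype=float),
    )
    if config.scattering:
        gamma = 1.0 + (t - de) / MEC2_KEV
        beta = np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 1e-12, None))
        residual = np.array([csda_range_mm(float(t[0] - de[0]), material)])
        theta0 = (
            (13.6e3 / (beta * momentum_kev(t - de)))
            * np.sqrt(stp / material.radiation_length_mm)
            * _highland_log_factor(residual, np.array([material.radiation_length_mm]))
        )
        dirs = _scatter(dirs, theta0, rng)
    return PositronState(
        position=pos[0], direction=dirs[0], kinetic_energy=float(t[0] - de[0])
    )


def transport(
    e0_kev: float,
    origin,
    world: World,
    config: TransportConfig,
    rng: np.random.Generator | None = None,
) -> AnnihilationRecord:
    """Transport a single positron of initial energy e0_kev."""
    if e0_kev < 0:
        raise ValueError("initial energy must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    d = rng.normal(size=(1, 3))
    cloud = transport_batch(
        np.array([e0_kev]), np.asarray(origin, dtype=float)[None, :], d, world, config, rng
    )
    return cloud[0]


def simulate_cloud(
    isotope: IsotopeSpec,
    world: World,
    config: TransportConfig,
    n: int,
    origin=(0.0, 0.0, 0.0),
) -> AnnihilationCloud:
    """Annihilation cloud of a point source: one record per beta-plus decay.

    Decays with no positron (electron capture) are skipped; the returned
    cloud has one row per positron-emitting decay.  Deterministic for a
    fixed ``config.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    decays = sample_decays(isotope, n, seed=config.seed)
    has_pos = decays.branch_index >= 0
    energies = decays.energy_kev[has_pos]
    m = len(energies)
    rng = np.random.default_rng((config.seed, 1))
    dirs = rng.normal(size=(m, 3))
    origins = np.tile(np.asarray(origin, dtype=float), (m, 1))
    return transport_batch(energies, origins, dirs, world, config, rng)


@dataclass(frozen=True)
class RangeStatistics:
    """Mean positron range statistics (mm)."""

    mean_3d: float
    mean_transversal: float
    mean_axial: float
    n: int

    def __post_init__(self) -> None:
        if min(self.mean_3d, self.mean_transversal, self.mean_axial) < 0:
            raise ValueError("range statistics must be non-negative")


def range_statistics(
    records: AnnihilationCloud | list[AnnihilationRecord],
    transversal_convention: str = "projection",
) -> RangeStatistics:
    """Mean 3D / transversal / axial range of an annihilation cloud.

    mean_3d is the mean Euclidean emission-to-annihilation distance.
    mean_axial is the mean absolute axial (z) projection.  The transversal
    mean follows the 1D-projection convention, (|dx| + |dy|)/2, under which
    transversal = axial = mean_3d/2 for isotropic clouds; pass
    ``transversal_convention="radial"`` for the in-plane radial norm
    sqrt(dx^2 + dy^2) instead.  Escaped positrons are excluded.
    """
    if isinstance(records, AnnihilationCloud):
        disp = records.annihilated().displacement
    else:
        disp = np.array([r.displacement for r in records if not r.escaped])
    if len(disp) == 0:
        raise ValueError("no annihilation records")
    if transversal_convention == "projection":
        trans = float(np.mean((np.abs(disp[:, 0]) + np.abs(disp[:, 1])) / 2.0))
    elif transversal_convention == "radial":
        trans = float(np.mean(np.hypot(disp[:, 0], disp[:, 1])))
    else:
        raise ValueError("transversal_convention must be 'projection' or 'radial'")
    return RangeStatistics(
        mean_3d=float(np.mean(np.linalg.norm(disp, axis=1))),
        mean_transversal=trans,
        mean_axial=float(np.mean(np.abs(disp[:, 2]))),
        n=len(disp),
    )
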
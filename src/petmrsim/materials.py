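"""Materials, phantoms and scanner geometry.

Materials carry the quantities the transport code needs: mass density, Z/A
(electron density), mean excitation energy (collision stopping power),
radiation length (multiple-scattering width) and a two-part photon
attenuation model: Compton attenuation computed from the Klein-Nishina total
cross-section per electron times the electron density, plus a small
photoelectric component scaling as (511/E)^3 anchored at 511 keV.  Tissue
materials (lung / soft tissue / bone) are modeled as water with the stated
mass densities, i.e. electron density scaled by the density ratio.

Worlds are ordered lists of placed shapes (axis-aligned boxes and z-axis
cylinders); point-in-material lookup is first-match, so nested structures
(line source inside a sleeve inside air) are built by listing the innermost
shape first.

The scanner is a cylindrical ring: 5 axial rings of 28 detector blocks,
crystals of 25 mm depth x 4.0 mm transaxial x 5.3 mm axial, covering a
250 mm axial and 600 mm transaxial field of view.  The ring radius is not a
published quantity; the default of 312 mm places the crystal faces just
outside the 300 mm FOV radius.  Absolute detection efficiency is therefore
calibrated (see the sensitivity pipeline), not asserted from geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

N_AVOGADRO = 6.02214076e23
R_E_CM = 2.8179403262e-13  # classical electron radius, cm
MEC2_KEV = 511.0


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

def klein_nishina_total_cm2(energy_kev: np.ndarray) -> np.ndarray:
    """Klein-Nishina total Compton cross-section per electron (cm^2)."""
    eps = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    one_p2 = 1.0 + 2.0 * eps
    log_term = np.log(one_p2)
    sigma = (
        (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / one_p2 - log_term / eps)
        + log_term / (2.0 * eps)
        - (1.0 + 3.0 * eps) / one_p2**2
    )
    return 2.0 * np.pi * R_E_CM**2 * sigma


@dataclass(frozen=True)
class Material:
    """Bulk material for positron and photon transport.

    density: g/cm^3; z_over_a: electrons per atomic mass unit;
    mean_excitation_energy: eV; radiation_length: g/cm^2;
    photoelectric_511: linear photoelectric attenuation at 511 keV, 1/cm.
    """

    name: str
    density: float
    z_over_a: float
    mean_excitation_energy: float
    radiation_length: float
    photoelectric_511: float = 0.0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")

    @property
    def electron_density_cm3(self) -> float:
        return self.density * N_AVOGADRO * self.z_over_a

    @property
    def radiation_length_mm(self) -> float:
        if self.density == 0:
            return np.inf
        return self.radiation_length / self.density * 10.0

    def compton_attenuation(self, energy_kev) -> np.ndarray:
        """Compton linear attenuation, 1/cm."""
        return self.electron_density_cm3 * klein_nishina_total_cm2(energy_kev)

    def photoelectric_attenuation(self, energy_kev) -> np.ndarray:
        """Photoelectric linear attenuation, 1/cm (E^-3 scaling from 511)."""
        e = np.asarray(energy_kev, dtype=float)
        return self.photoelectric_511 * (MEC2_KEV / e) ** 3

    def linear_attenuation(self, energy_kev) -> np.ndarray:
        """Total photon linear attenuation, 1/cm."""
        return self.compton_attenuation(energy_kev) + self.photoelectric_attenuation(
            energy_kev
        )


def _water_like(name: str, density: float) -> Material:
    return Material(
        name=name,
        density=density,
        z_over_a=0.55509,
        mean_excitation_energy=75.0,
        radiation_length=36.08,
        photoelectric_511=5.0e-6 * density,
    )


#: Registry of built-in materials.  Photoelectric anchors at 511 keV are small
#: for the low-Z materials and substantial only for the LYSO crystal.
MATERIALS: dict[str, Material] = {
    "vacuum": Material("vacuum", 0.0, 0.0, 1.0, np.inf, 0.0),
    "air": Material("air", 1.205e-3, 0.49919, 85.7, 36.62, 0.0),
    "water": _water_like("water", 1.0),
    "soft": _water_like("soft", 1.0),
    "lung": _water_like("lung", 0.3),
    "bone": _water_like("bone", 1.42),
    "aluminum": Material("aluminum", 2.699, 0.48181, 166.0, 24.01, 2.7e-4),
    "polyethylene": Material("polyethylene", 0.96, 0.57034, 57.4, 44.77, 2.0e-6),
    "lyso": Material("lyso", 7.1, 0.4207, 472.0, 7.22, 0.33),
}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown material {name!r}") from None


# ---------------------------------------------------------------------------
# Shapes and worlds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned box: center (mm) and half-extents (mm)."""

    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        c = np.asarray(self.center)
        h = np.asarray(self.half_extents)
        return np.all(np.abs(p - c) <= h, axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        h = np.asarray(self.half_extents)
        return c - h, c + h

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds()
        return rng.uniform(lo, hi, size=(n, 3))


@dataclass(frozen=True)
class ZCylinder:
    """Finite cylinder with axis parallel to z."""

    cx: float
    cy: float
    radius: float
    z_min: float
    z_max: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        r2 = (p[:, 0] - self.cx) ** 2 + (p[:, 1] - self.cy) ** 2
        return (r2 <= self.radius**2) & (p[:, 2] >= self.z_min) & (p[:, 2] <= self.z_max)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([self.cx - self.radius, self.cy - self.radius, self.z_min]),
            np.array([self.cx + self.radius, self.cy + self.radius, self.z_max]),
        )

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # uniform in the disc, uniform in z
        r = self.radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        z = rng.uniform(self.z_min, self.z_max, n)
        return np.column_stack((self.cx + r * np.cos(phi), self.cy + r * np.sin(phi), z))


@dataclass
class World:
    """Ordered list of (shape, material); lookup is first-match.

    ``source`` optionally marks the shape in which activity is distributed
    (used by the acquisition pipelines to sample emission points).
    """

    shapes: list[tuple[Box | ZCylinder, Material]]
    background: Material = field(default_factory=lambda: MATERIALS["air"])
    source: Box | ZCylinder | None = None

    def materials(self) -> list[Material]:
        return [self.background] + [m for _, m in self.shapes]

    def material_index_at(self, points: np.ndarray) -> np.ndarray:
        """Index into materials(): 0 = background, i+1 = shapes[i]."""
        p = np.atleast_2d(points)
        idx = np.zeros(len(p), dtype=np.int64)
        unresolved = np.ones(len(p), dtype=bool)
        for i, (shape, _) in enumerate(self.shapes):
            hit = unresolved & shape.contains(p)
            idx[hit] = i + 1
            unresolved &= ~hit
        return idx

    def material_at(self, point) -> Material:
        i = int(self.material_index_at(np.asarray(point, dtype=float))[0])
        return self.materials()[i]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.shapes:
            return np.zeros(3), np.zeros(3)
        los, his = zip(*(s.bounds() for s, _ in self.shapes))
        return np.min(los, axis=0), np.max(his, axis=0)

    def to_dict(self) -> dict:
        """JSON-serializable geometry dump for inspection."""
        def shape_dict(shape):
            d = {"type": type(shape).__name__}
            d.update({k: v for k, v in vars(shape).items()})
            return d

        return {
            "background": self.background.name,
            "shapes": [
                {"shape": shape_dict(s), "material": m.name} for s, m in self.shapes
            ],
        }


def material_at(world: World, point) -> Material:
    """Module-level convenience wrapper around World.material_at."""
    return world.material_at(point)


# ---------------------------------------------------------------------------
# Phantom builders
# ---------------------------------------------------------------------------

SLEEVE_STEP_MM = 2.5
SLEEVE_INNER_RADIUS_MM = 1.95
SOURCE_LENGTH_MM = 700.0
NECR_PHANTOM_RADIUS_MM = 101.5
NECR_SOURCE_INNER_RADIUS_MM = 1.6
NECR_SOURCE_OFFSET_MM = 45.0


def build_sensitivity_phantom(
    n_sleeves: int, position_offset: float = 0.0
) -> World:
    """Line source in 0..5 concentric 2.5 mm aluminum sleeves.

    A 700 mm water-equivalent line source of negligible diameter surrounded
    by an aluminum tube of total wall thickness 2.5 * n_sleeves mm, placed at
    ``position_offset`` mm radially off-center (0 or 100 in the protocol).
    """
    if not 0 <= n_sleeves <= 5:
        raise ValueError("n_sleeves must be in 0..5")
    x = float(position_offset)
    hz = SOURCE_LENGTH_MM / 2.0
    source = ZCylinder(x, 0.0, 0.5, -hz, hz)
    shapes: list[tuple[Box | ZCylinder, Material]] = [(source, MATERIALS["water"])]
    if n_sleeves > 0:
        # air annulus between source and sleeve, then the aluminum wall
        shapes.append((ZCylinder(x, 0.0, SLEEVE_INNER_RADIUS_MM, -hz, hz), MATERIALS["air"]))
        outer = SLEEVE_INNER_RADIUS_MM + SLEEVE_STEP_MM * n_sleeves
        shapes.append((ZCylinder(x, 0.0, outer, -hz, hz), MATERIALS["aluminum"]))
    return World(shapes=shapes, background=MATERIALS["air"], source=source)


def sleeve_thickness_mm(n_sleeves: int) -> float:
    return SLEEVE_STEP_MM * n_sleeves


def build_necr_phantom(source_offset_mm: float = NECR_SOURCE_OFFSET_MM) -> World:
    """NEMA NECR phantom: 203 mm x 700 mm polyethylene cylinder.

    Contains a 700 mm long, 3.2 mm inner-diameter water-filled line source
    placed ``source_offset_mm`` off-axis (45 mm per NEMA NU 2-2012; the
    protocol places it below the center).
    """
    hz = SOURCE_LENGTH_MM / 2.0
    source = ZCylinder(0.0, -source_offset_mm, NECR_SOURCE_INNER_RADIUS_MM, -hz, hz)
    body = ZCylinder(0.0, 0.0, NECR_PHANTOM_RADIUS_MM, -hz, hz)
    return World(
        shapes=[(source, MATERIALS["water"]), (body, MATERIALS["polyethylene"])],
        background=MATERIALS["air"],
        source=source,
    )


def necr_phantom_volume_ml() -> float:
    """Phantom volume from geometry (~22.65 L), used for kBq/ml."""
    return float(np.pi * NECR_PHANTOM_RADIUS_MM**2 * SOURCE_LENGTH_MM / 1000.0)


def build_tissue_cube(material: str | Material, side_mm: float = 200.0) -> World:
    """Homogeneous tissue cube (default 20 cm) centered at the origin."""
    mat = get_material(material) if isinstance(material, str) else material
    h = side_mm / 2.0
    cube = Box((0.0, 0.0, 0.0), (h, h, h))
    return World(shapes=[(cube, mat)], background=MATERIALS["air"], source=cube)


def build_two_cube_world(
    material_neg_x: str | Material = "lung",
    material_pos_x: str | Material = "soft",
    side_mm: float = 200.0,
) -> World:
    """Two adjacent 20 cm cubes meeting at the x = 0 plane.

    Points exactly on the interface resolve to the first-listed (negative-x)
    cube.
    """
    m1 = get_material(material_neg_x) if isinstance(material_neg_x, str) else material_neg_x
    m2 = get_material(material_pos_x) if isinstance(material_pos_x, str) else material_pos_x
    h = side_mm / 2.0
    c1 = Box((-h, 0.0, 0.0), (h, h, h))
    c2 = Box((h, 0.0, 0.0), (h, h, h))
    return World(shapes=[(c1, m1), (c2, m2)], background=MATERIALS["air"])


# ---------------------------------------------------------------------------
# Scanner geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScannerGeometry:
    """Cylindrical block-detector ring.

    Crystals tile each block at the transaxial pitch; the remainder of the
    block arc is dead space.  Axially the five rings tile the 250 mm FOV at a
    50 mm ring pitch with the crystal array centered in each ring.
    """

    ring_radius: float = 312.0
    n_rings: int = 5
    blocks_per_ring: int = 28
    crystal_depth: float = 25.0
    crystal_pitch_transaxial: float = 4.0
    crystal_pitch_axial: float = 5.3
    axial_fov: float = 250.0
    transaxial_fov: float = 600.0

    def __post_init__(self) -> None:
        if self.ring_radius < self.transaxial_fov / 2.0:
            raise ValueError(
                "ring radius must be at least half the transaxial FOV "
                f"({self.ring_radius} < {self.transaxial_fov / 2.0})"
            )

    # -- derived tiling ----------------------------------------------------
    @property
    def block_arc_mm(self) -> float:
        return 2.0 * np.pi * self.ring_radius / self.blocks_per_ring

    @property
    def crystals_per_block_transaxial(self) -> int:
        return int(self.block_arc_mm // self.crystal_pitch_transaxial)

    @property
    def ring_pitch_mm(self) -> float:
        return self.axial_fov / self.n_rings

    @property
    def crystals_per_ring_axial(self) -> int:
        return int(self.ring_pitch_mm // self.crystal_pitch_axial)

    @property
    def n_transaxial(self) -> int:
        return self.blocks_per_ring * self.crystals_per_block_transaxial

    @property
    def n_axial(self) -> int:
        return self.n_rings * self.crystals_per_ring_axial

    @property
    def n_crystals(self) -> int:
        return self.n_transaxial * self.n_axial

    @property
    def n_slices(self) -> int:
        """Single-slice-rebinned slice count (2 * n_axial - 1)."""
        return 2 * self.n_axial - 1

    def axial_extent(self) -> float:
        """Axial span covered by crystal centers plus outer half-pitches."""
        return (
            self.n_rings * self.ring_pitch_mm
            - (self.ring_pitch_mm - self.crystals_per_ring_axial * self.crystal_pitch_axial)
        )

    def to_dict(self) -> dict:
        """JSON-serializable geometry dump for inspection."""
        from dataclasses import asdict

        d = asdict(self)
        d.update(
            n_crystals=self.n_crystals,
            crystals_per_block_transaxial=self.crystals_per_block_transaxial,
            crystals_per_ring_axial=self.crystals_per_ring_axial,
            n_slices=self.n_slices,
        )
        return d

    # -- index mapping -----------------------------------------------------
    def crystal_index(self, ring, block, axial_in_block, trans_in_block) -> np.ndarray:
        """(ring, block, axial, transaxial) -> flat crystal index."""
        a = np.asarray(ring) * self.crystals_per_ring_axial + np.asarray(axial_in_block)
        t = np.asarray(block) * self.crystals_per_block_transaxial + np.asarray(
            trans_in_block
        )
        return a * self.n_transaxial + t

    def crystal_components(self, index) -> tuple[np.ndarray, ...]:
        """Flat crystal index -> (ring, block, axial_in_block, trans_in_block)."""
        idx = np.asarray(index)
        if np.any((idx < 0) | (idx >= self.n_crystals)):
            raise ValueError("crystal index out of range")
        a, t = np.divmod(idx, self.n_transaxial)
        ring, axial = np.divmod(a, self.crystals_per_ring_axial)
        block, trans = np.divmod(t, self.crystals_per_block_transaxial)
        return ring, block, axial, trans

    def crystal_angle_z(self, index) -> tuple[np.ndarray, np.ndarray]:
        """Crystal-face center as (azimuthal angle rad, axial z mm)."""
        ring, block, axial, trans = self.crystal_components(index)
        nt = self.crystals_per_block_transaxial
        na = self.crystals_per_ring_axial
        dtheta = self.crystal_pitch_transaxial / self.ring_radius
        theta = (
            block * (2.0 * np.pi / self.blocks_per_ring)
            + (trans - (nt - 1) / 2.0) * dtheta
        )
        z = (
            -self.axial_fov / 2.0
            + (ring + 0.5) * self.ring_pitch_mm
            + (axial - (na - 1) / 2.0) * self.crystal_pitch_axial
        )
        return theta, z

    def crystal_position(self, index) -> np.ndarray:
        """Crystal-face center in mm, shape (..., 3)."""
        theta, z = self.crystal_angle_z(index)
        return np.stack(
            (
                self.ring_radius * np.cos(theta),
                self.ring_radius * np.sin(theta),
                np.broadcast_to(z, np.shape(theta)),
            ),
            axis=-1,
        )

    def crystal_from_angle_z(self, theta, z) -> np.ndarray:
        """Map a hit at (angle, z) on the ring surface to a crystal index.

        Returns -1 for hits in inter-crystal dead space or outside the axial
        coverage.
        """
        theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
        z = np.asarray(z, dtype=float)
        block_angle = 2.0 * np.pi / self.blocks_per_ring
        # offset so block 0 is centered on angle 0
        rel = np.mod(theta + block_angle / 2.0, 2.0 * np.pi)
        block = np.floor(rel / block_angle).astype(np.int64) % self.blocks_per_ring
        u = (rel - block * block_angle - block_angle / 2.0) * self.ring_radius
        nt = self.crystals_per_block_transaxial
        half_arc = nt * self.crystal_pitch_transaxial / 2.0
        trans = np.floor((u + half_arc) / self.crystal_pitch_transaxial).astype(np.int64)
        ok_t = (np.abs(u) <= half_arc) & (trans >= 0) & (trans < nt)

        zz = z + self.axial_fov / 2.0
        ring = np.floor(zz / self.ring_pitch_mm).astype(np.int64)
        ok_r = (ring >= 0) & (ring < self.n_rings)
        ring = np.clip(ring, 0, self.n_rings - 1)
        w = zz - (ring + 0.5) * self.ring_pitch_mm
        na = self.crystals_per_ring_axial
        half_ax = na * self.crystal_pitch_axial / 2.0
        axial = np.floor((w + half_ax) / self.crystal_pitch_axial).astype(np.int64)
        ok_a = (np.abs(w) <= half_ax) & (axial >= 0) & (axial < na)

        idx = self.crystal_index(ring, block, np.clip(axial, 0, na - 1), np.clip(trans, 0, nt - 1))
        return np.where(ok_t & ok_r & ok_a, idx, -1)


_SCANNER_FIELDS = {
    "ring_radius",
    "n_rings",
    "blocks_per_ring",
    "crystal_depth",
    "crystal_pitch_transaxial",
    "crystal_pitch_axial",
    "axial_fov",
    "transaxial_fov",
}


def build_scanner(overrides: dict | None = None) -> ScannerGeometry:
    """Default scanner geometry, optionally with documented field overrides."""
    overrides = dict(overrides or {})
    unknown = set(overrides) - _SCANNER_FIELDS
    if unknown:
        raise ValueError(f"unknown scanner overrides: {sorted(unknown)}")
    return replace(ScannerGeometry(), **overrides)


# ---------------------------------------------------------------------------
# Digitizer configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigitizerConfig:
    """Energy window, resolution, coincidence window and dead time.

    ``dead_time_tau_ns`` defaults to the value calibrated once against the
    18F peak-NECR operating point and then frozen for all isotopes (see
    config.py); energy resolution defaults to 10.5% FWHM at 511 keV.
    """

    energy_window_kev: tuple[float, float] = (425.0, 650.0)
    energy_resolution_fwhm: float = 0.105
    coincidence_window_ns: float = 4.57
    dead_time_tau_ns: float = 0.0
    dead_time_model: str = "paralyzable"

    def __post_init__(self) -> None:
        lo, hi = self.energy_window_kev
        if not lo < hi:
            raise ValueError("energy window lower bound must be below upper")
        if self.dead_time_tau_ns < 0:
            raise ValueError("dead time must be non-negative")
        if self.dead_time_model not in ("paralyzable", "non-paralyzable"):
            raise ValueError("dead_time_model must be paralyzable or non-paralyzable")
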
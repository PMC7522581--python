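"""NEMA NU 2-2012 count-rate (NECR) pipeline.

The list-mode coincidences of one acquisition are histogrammed per axial
slice into a sinogram of 320 projection angles (0..pi) by 640 radial bins
(-300..+300 mm, 0.9375 mm bins).  The analysis then follows the protocol
steps: zero all bins more than 120 mm from the center, circularly shift
each angle row so its maximum sits in the center bin, sum the rows into a
summed projection profile, and estimate the background (scattered plus
random) counts inside a 40 mm strip around the center from the average of
the interpolated profile values at the two strip edges times the
(fractional) number of bins in the strip.  Counts inside the strip above
that background are true events; everything else is background.  From the
per-slice trues/background totals the count rates, scatter fraction and

    NECR = T^2 / (T + S + R)

follow (no factor-2 randoms variant, since randoms are never separately
estimated: the background splits into S and R only through the scatter
fraction measured at low activity where randoms vanish).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detection import Acquisition, simulate_acquisition, ssrb_slice
from .isotopes import IsotopeSpec
from .materials import (
    DigitizerConfig,
    ScannerGeometry,
    World,
    build_necr_phantom,
    necr_phantom_volume_ml,
)
from .transport import TransportConfig

N_ANGLE_BINS = 320
N_RADIAL_BINS = 640
RADIAL_HALF_SPAN_MM = 300.0
RADIAL_BIN_MM = 2.0 * RADIAL_HALF_SPAN_MM / N_RADIAL_BINS  # 0.9375
MASK_RADIUS_MM = 120.0
STRIP_WIDTH_MM = 40.0


@dataclass
class Sinogram:
    """Per-slice LOR histogram: (n_slices, angle, radial) counts."""

    data: np.ndarray
    radial_bin_mm: float = RADIAL_BIN_MM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.shape[1:] != (N_ANGLE_BINS, N_RADIAL_BINS):
            raise ValueError(
                f"sinogram must be (slices, {N_ANGLE_BINS}, {N_RADIAL_BINS})"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def total(self) -> int:
        return int(self.data.sum())

    def radial_centers(self) -> np.ndarray:
        return -RADIAL_HALF_SPAN_MM + (np.arange(N_RADIAL_BINS) + 0.5) * self.radial_bin_mm

    def save(self, path: str | Path) -> None:
        """Portable array file (.npy) with a JSON sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {
            "shape": list(self.data.shape),
            "axes": ["slice", "angle", "radial"],
            "angle_range_rad": [0.0, float(np.pi)],
            "radial_range_mm": [-RADIAL_HALF_SPAN_MM, RADIAL_HALF_SPAN_MM],
            "radial_bin_mm": self.radial_bin_mm,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Sinogram":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(np.load(path.with_suffix(".npy")), radial_bin_mm=meta["radial_bin_mm"])


def bin_sinogram(
    coincidences,
    scanner: ScannerGeometry,
    n_slices: int | None = None,
    face_sampling_seed: int | None = 0,
) -> Sinogram:
    """Histogram list-mode coincidences into per-slice sinograms.

    Each LOR maps to a projection angle in [0, pi) and a signed radial
    distance from the scanner axis; LORs beyond +-300 mm are dropped.
    Oblique LORs collapse to the slice at the mean axial crystal position
    (single-slice rebinning).

    The list-mode record localizes a photon only to a crystal; the
    interaction point is uniform across the 4 mm crystal face, so each
    endpoint is drawn uniformly over its face arc (deterministically, from
    ``face_sampling_seed``).  Binning crystal centers instead
    (face_sampling_seed=None) phase-locks the ~2 mm LOR comb with the
    aligned peak and biases the strip-edge background estimate.
    """
    c1 = np.asarray(coincidences["crystal1"], dtype=np.int64)
    c2 = np.asarray(coincidences["crystal2"], dtype=np.int64)
    if len(c1) and (
        c1.min() < 0 or c2.min() < 0
        or c1.max() >= scanner.n_crystals or c2.max() >= scanner.n_crystals
    ):
        raise ValueError("unknown crystal index in list-mode input")
    n_slices = n_slices or scanner.n_slices
    data = np.zeros((n_slices, N_ANGLE_BINS, N_RADIAL_BINS), dtype=np.int64)
    if len(c1) == 0:
        return Sinogram(data)

    th1, _ = scanner.crystal_angle_z(c1)
    th2, _ = scanner.crystal_angle_z(c2)
    if face_sampling_seed is not None:
        rng = np.random.default_rng(face_sampling_seed)
        half = scanner.crystal_pitch_transaxial / 2.0 / scanner.ring_radius
        th1 = th1 + rng.uniform(-half, half, len(th1))
        th2 = th2 + rng.uniform(-half, half, len(th2))
    r = scanner.ring_radius
    x1, y1 = r * np.cos(th1), r * np.sin(th1)
    dx = r * np.cos(th2) - x1
    dy = r * np.sin(th2) - y1
    alpha = np.arctan2(dy, dx)
    theta = np.mod(alpha - np.pi / 2.0, np.pi)  # normal angle in [0, pi)
    s = x1 * np.cos(theta) + y1 * np.sin(theta)
    # purely axial LORs (both crystals at one transaxial position) have no
    # projection direction; their offset is the ring radius, beyond the span
    degenerate = np.hypot(dx, dy) < 1e-9
    s = np.where(degenerate, np.hypot(x1, y1), s)

    sl = ssrb_slice(scanner, c1, c2)
    ia = np.clip((theta / np.pi * N_ANGLE_BINS).astype(np.int64), 0, N_ANGLE_BINS - 1)
    ir = np.floor((s + RADIAL_HALF_SPAN_MM) / RADIAL_BIN_MM).astype(np.int64)
    ok = (ir >= 0) & (ir < N_RADIAL_BINS) & (sl >= 0) & (sl < n_slices)
    np.add.at(data, (sl[ok], ia[ok], ir[ok]), 1)
    return Sinogram(data)


def mask_radius(sino: Sinogram, r_max_mm: float = MASK_RADIUS_MM) -> Sinogram:
    """Zero all radial bins whose centers lie beyond r_max from the axis."""
    keep = np.abs(sino.radial_centers()) <= r_max_mm
    data = sino.data.copy()
    data[:, :, ~keep] = 0
    return Sinogram(data, radial_bin_mm=sino.radial_bin_mm)


def alignment_shifts(plane: np.ndarray) -> np.ndarray:
    """Per-angle-row circular shifts that center each row's maximum.

    The shift of each projection angle is a property of the (static) source
    position — a sinusoid of its offset — so shifts measured once on a
    high-statistics plane can be reused on sparse planes of the same
    geometry.  Ties break to the lower-index bin (argmax convention);
    all-zero rows get shift 0.
    """
    plane = np.asarray(plane)
    center = N_RADIAL_BINS // 2
    peaks = np.argmax(plane, axis=1)
    shifts = peaks - center
    shifts[plane.max(axis=1) == 0] = 0
    return shifts


def _align_rows(plane: np.ndarray, shifts: np.ndarray | None = None) -> np.ndarray:
    if shifts is None:
        shifts = alignment_shifts(plane)
    cols = np.arange(plane.shape[1])
    idx = (cols[None, :] + shifts[:, None]) % plane.shape[1]
    return np.take_along_axis(plane, idx, axis=1)


def align_and_sum(sino_or_plane, shifts: np.ndarray | None = None) -> np.ndarray:
    """Align every angle row on its maximum and sum rows into a profile.

    Accepts a single (angle, radial) plane -> (radial,) profile, or a
    Sinogram -> (n_slices, radial) array of per-slice profiles.  Optional
    precomputed ``shifts`` (from :func:`alignment_shifts`) replace the
    per-row maxima — used when individual rows are too sparse to carry
    their own alignment.
    """
    if isinstance(sino_or_plane, Sinogram):
        return np.stack(
            [_align_rows(p, shifts).sum(axis=0) for p in sino_or_plane.data]
        )
    plane = np.asarray(sino_or_plane)
    return _align_rows(plane, shifts).sum(axis=0)


def strip_background(
    profile: np.ndarray,
    strip_width_mm: float = STRIP_WIDTH_MM,
    bin_width_mm: float = RADIAL_BIN_MM,
) -> tuple[float, float]:
    """Split a summed profile into (background, trues) counts.

    The strip spans +-strip_width/2 about the profile center; the edge
    values are linearly interpolated at the fractional-bin strip borders,
    averaged, and multiplied by the fractional number of bins in the strip
    to estimate the background under the peak.  Counts above background
    inside the strip are trues; all remaining counts are background-type.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if strip_width_mm >= n * bin_width_mm:
        raise ValueError("strip wider than the profile")
    center_mm = (n // 2 + 0.5) * bin_width_mm  # center-bin center position
    half = strip_width_mm / 2.0
    lo_mm, hi_mm = center_mm - half, center_mm + half
    centers = (np.arange(n) + 0.5) * bin_width_mm

    left_val = float(np.interp(lo_mm, centers, profile))
    right_val = float(np.interp(hi_mm, centers, profile))
    n_bins_strip = strip_width_mm / bin_width_mm
    background_in_strip = 0.5 * (left_val + right_val) * n_bins_strip

    # integrate the profile over the strip with fractional edge bins
    edges = np.arange(n + 1) * bin_width_mm
    lo_idx = np.searchsorted(edges, lo_mm, side="right") - 1
    hi_idx = np.searchsorted(edges, hi_mm, side="right") - 1
    if lo_idx == hi_idx:
        inside = profile[lo_idx] * (hi_mm - lo_mm) / bin_width_mm
    else:
        inside = profile[lo_idx] * (edges[lo_idx + 1] - lo_mm) / bin_width_mm
        inside += profile[lo_idx + 1:hi_idx].sum()
        inside += profile[hi_idx] * (hi_mm - edges[hi_idx]) / bin_width_mm

    trues = max(float(inside) - background_in_strip, 0.0)
    background = float(profile.sum()) - trues
    return background, trues


@dataclass(frozen=True)
class CountRatePoint:
    """Rates at one activity level (kcps), NEMA strip analysis."""

    activity_concentration_kbq_ml: float
    trues_kcps: float
    scatter_kcps: float
    randoms_kcps: float
    total_kcps: float
    necr_kcps: float
    scatter_fraction_pct: float


@dataclass
class NECRCurve:
    points: list[CountRatePoint] = field(default_factory=list)

    @property
    def peak(self) -> CountRatePoint:
        return max(self.points, key=lambda p: p.necr_kcps)


def analyze_sinogram(
    sino: Sinogram,
    collapse_slices: bool = True,
    shifts: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mask, align, strip-analyze; return total (trues, background) counts.

    With ``collapse_slices`` (the desk-scale default) all slices are summed
    into one plane before alignment, so each angle row carries enough
    counts for its maximum to mark the source; at full NEMA statistics the
    per-slice analysis (collapse_slices=False) applies.
    """
    masked = mask_radius(sino)
    if collapse_slices:
        planes = [masked.data.sum(axis=0)]
    else:
        planes = list(masked.data)
    trues = 0.0
    background = 0.0
    for plane in planes:
        if plane.sum() == 0:
            continue
        b, t = strip_background(align_and_sum(plane, shifts))
        trues += t
        background += b
    return trues, background


def count_rates(
    acq: Acquisition,
    scanner: ScannerGeometry,
    low_activity_scatter_fraction_pct: float | None = None,
    phantom_volume_ml: float | None = None,
    randoms_negligible_threshold: float = 0.01,
    collapse_slices: bool = True,
    shifts: np.ndarray | None = None,
) -> CountRatePoint:
    """NEMA strip-method count rates for one acquisition.

    At low activity (predicted randoms-to-trues ratio below the threshold)
    the whole background is scatter and the scatter fraction is measured
    directly; otherwise the supplied low-activity scatter fraction splits
    the background into scatter and randoms via S = T * SF / (1 - SF).
    """
    volume = phantom_volume_ml or necr_phantom_volume_ml()
    sino = bin_sinogram(acq.coincidences, scanner)
    trues, background = analyze_sinogram(sino, collapse_slices, shifts)
    t_rate = trues / acq.duration_s / 1000.0  # kcps
    b_rate = background / acq.duration_s / 1000.0
    total = t_rate + b_rate

    # predicted randoms rate from the singles rate and coincidence window
    window_s = acq.coincidence_window_ns * 1e-9
    r_pred_kcps = acq.singles_rate_cps**2 * window_s / 1000.0
    randoms_small = t_rate == 0 or (r_pred_kcps / max(t_rate, 1e-12)) < randoms_negligible_threshold

    if low_activity_scatter_fraction_pct is not None:
        sf = low_activity_scatter_fraction_pct
        s_rate = t_rate * sf / (100.0 - sf)
        r_rate = max(b_rate - s_rate, 0.0)
    elif randoms_small:
        s_rate, r_rate = b_rate, 0.0
        sf = 100.0 * s_rate / (s_rate + t_rate) if (s_rate + t_rate) > 0 else 0.0
    else:
        raise ValueError(
            "randoms are not negligible at this activity; supply the "
            "low-activity scatter fraction"
        )

    necr = t_rate**2 / total if total > 0 else 0.0
    activity_kbq = acq.activity_bq / 1000.0
    return CountRatePoint(
        activity_concentration_kbq_ml=activity_kbq / volume,
        trues_kcps=t_rate,
        scatter_kcps=s_rate,
        randoms_kcps=r_rate,
        total_kcps=total,
        necr_kcps=necr,
        scatter_fraction_pct=sf,
    )


def default_activity_levels_bq(n_levels: int = 11) -> np.ndarray:
    """Log-spaced activity levels over 1..800 MBq."""
    return np.geomspace(1e6, 800e6, n_levels)


def necr_curve(
    isotope: IsotopeSpec,
    activity_levels_bq,
    scanner: ScannerGeometry,
    digitizer: DigitizerConfig,
    seed: int,
    n_decays_per_level: int = 500_000,
    efficiency: float = 1.0,
    world: World | None = None,
    transport_config: TransportConfig | None = None,
    sf_activity_bq: float = 2.0e5,
) -> NECRCurve:
    """Count-rate curve over activity levels; peak is the grid maximum.

    The scatter fraction is first measured in a dedicated acquisition at
    ``sf_activity_bq`` (low enough for randoms to vanish) and then held
    fixed across the curve to split background into scatter and randoms,
    per the protocol.
    """
    levels = np.sort(np.asarray(activity_levels_bq, dtype=float))
    if len(levels) < 3:
        raise ValueError("need at least 3 activity levels")
    world = world or build_necr_phantom()
    sf_low, shifts = _sf_and_shifts(
        isotope, scanner, digitizer, seed=seed,
        activity_bq=sf_activity_bq,
        n_decays=n_decays_per_level,
        world=world,
        transport_config=transport_config,
    )
    curve = NECRCurve()
    for i, act in enumerate(levels):
        acq = simulate_acquisition(
            isotope, world, scanner, digitizer,
            activity_bq=float(act),
            n_decays=n_decays_per_level,
            seed=seed + 7919 * (i + 1),
            transport_config=transport_config,
            efficiency=efficiency,
        )
        curve.points.append(
            count_rates(
                acq, scanner,
                low_activity_scatter_fraction_pct=sf_low,
                shifts=shifts,
            )
        )
    return curve


def _sf_and_shifts(
    isotope: IsotopeSpec,
    scanner: ScannerGeometry,
    digitizer: DigitizerConfig,
    seed: int,
    activity_bq: float,
    n_decays: int,
    world: World,
    transport_config: TransportConfig | None,
) -> tuple[float, np.ndarray]:
    """Low-activity scatter fraction plus the reference alignment shifts.

    Run at unit detection efficiency: the scatter fraction is a ratio of
    pair rates, all scaling with the efficiency squared, so thinning only
    costs statistics here.
    """
    acq = simulate_acquisition(
        isotope, world, scanner, digitizer,
        activity_bq=activity_bq,
        n_decays=n_decays,
        seed=seed,
        transport_config=transport_config,
        efficiency=1.0,
    )
    sino = mask_radius(bin_sinogram(acq.coincidences, scanner))
    shifts = alignment_shifts(sino.data.sum(axis=0))
    point = count_rates(acq, scanner, shifts=shifts)
    return point.scatter_fraction_pct, shifts


def measure_scatter_fraction(
    isotope: IsotopeSpec,
    scanner: ScannerGeometry,
    digitizer: DigitizerConfig,
    seed: int,
    activity_bq: float = 2.0e5,
    n_decays: int = 300_000,
    world: World | None = None,
    transport_config: TransportConfig | None = None,
) -> float:
    """Strip-method scatter fraction (%) at randoms-free low activity."""
    world = world or build_necr_phantom()
    sf, _ = _sf_and_shifts(
        isotope, scanner, digitizer, seed, activity_bq, n_decays, world,
        transport_config,
    )
    return sf
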
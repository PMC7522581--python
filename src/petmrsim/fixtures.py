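"""Synthetic list-mode and sensitivity-series generators with known truth.

These generators exercise the NEMA analysis pipelines against streams whose
true/scatter/random composition is known exactly:

* trues lie on LORs through an off-center line source (small transverse
  jitter),
* scattered events lie on LORs whose radial offset is smeared by a broad
  flat kernel around the source (the smooth scatter background of a real
  sinogram),
* randoms are uniform in (projection angle, radial offset),

all with Poisson counts at the configured rates and uniform timestamps.
The scatter kernel and the randoms' radial span default to widths that keep
every generated event inside the 120 mm analysis mask, so the configured
rates are exactly the ground truth the strip method should recover.
The sensitivity-series generator evaluates S_i = S_0 exp(-2 mu X_i)
exactly, optionally Poisson-perturbed at a stated count level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import ScannerGeometry
from .sensitivity import SensitivityEntry, SensitivitySeries


@dataclass(frozen=True)
class FixtureSpec:
    """Composition of a synthetic list-mode stream."""

    trues_kcps: float = 6.0
    scatter_kcps: float = 2.0
    randoms_kcps: float = 2.0
    source_offset_mm: tuple[float, float] = (0.0, -45.0)
    true_jitter_mm: float = 1.0
    scatter_width_mm: float = 140.0
    randoms_half_span_mm: float = 115.0
    duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.trues_kcps, self.scatter_kcps, self.randoms_kcps) < 0:
            raise ValueError("rates must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


def _lor_to_crystals(
    theta: np.ndarray,
    s: np.ndarray,
    z: np.ndarray,
    scanner: ScannerGeometry,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map (normal angle, radial offset, axial z) LORs to crystal pairs.

    Returns (crystal1, crystal2, valid); invalid rows hit inter-crystal
    dead space or leave the ring.
    """
    r = scanner.ring_radius
    s = np.clip(s, -r + 1e-6, r - 1e-6)
    half_chord = np.sqrt(r**2 - s**2)
    nx, ny = np.cos(theta), np.sin(theta)
    dx, dy = -ny, nx
    e1x, e1y = s * nx + half_chord * dx, s * ny + half_chord * dy
    e2x, e2y = s * nx - half_chord * dx, s * ny - half_chord * dy
    c1 = scanner.crystal_from_angle_z(np.arctan2(e1y, e1x), z)
    c2 = scanner.crystal_from_angle_z(np.arctan2(e2y, e2x), z)
    valid = (c1 >= 0) & (c2 >= 0) & (c1 != c2)
    return c1, c2, valid


def _sample_valid(
    n: int,
    draw,
    scanner: ScannerGeometry,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw LORs until n of them land on crystals on both ends."""
    out1 = np.empty(n, dtype=np.int64)
    out2 = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(max_tries):
        if filled >= n:
            break
        m = max(n - filled, 16)
        theta, s, z = draw(int(m * 1.5), rng)
        c1, c2, valid = _lor_to_crystals(theta, s, z, scanner)
        take = min(int(valid.sum()), n - filled)
        out1[filled:filled + take] = c1[valid][:take]
        out2[filled:filled + take] = c2[valid][:take]
        filled += take
    if filled < n:
        raise RuntimeError("could not place fixture LORs on crystals")
    return out1, out2


def generate_listmode(spec: FixtureSpec, scanner: ScannerGeometry) -> pd.DataFrame:
    """Synthetic coincidence table with ground-truth labels.

    Columns match the acquisition list-mode output plus the exact label;
    event counts are Poisson with mean rate x duration; deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    x0, y0 = spec.source_offset_mm
    z_extent = scanner.axial_extent() / 2.0 - scanner.crystal_pitch_axial

    def draw_z(m, rng):
        return rng.uniform(-z_extent, z_extent, m)

    def draw_true(m, rng):
        theta = rng.uniform(0.0, np.pi, m)
        s = x0 * np.cos(theta) + y0 * np.sin(theta)
        s = s + rng.normal(0.0, spec.true_jitter_mm, m)
        return theta, s, draw_z(m, rng)

    def draw_scatter(m, rng):
        theta = rng.uniform(0.0, np.pi, m)
        s = x0 * np.cos(theta) + y0 * np.sin(theta)
        s = s + rng.uniform(-spec.scatter_width_mm / 2.0, spec.scatter_width_mm / 2.0, m)
        return theta, s, draw_z(m, rng)

    parts = []
    for label, rate, draw in (
        ("true", spec.trues_kcps, draw_true),
        ("scattered", spec.scatter_kcps, draw_scatter),
    ):
        n = int(rng.poisson(rate * 1000.0 * spec.duration_s))
        if n == 0:
            continue
        c1, c2 = _sample_valid(n, draw, scanner, rng)
        parts.append(_frame(c1, c2, label, n, spec, rng))

    def draw_random(m, rng):
        theta = rng.uniform(0.0, np.pi, m)
        s = rng.uniform(-spec.randoms_half_span_mm, spec.randoms_half_span_mm, m)
        return theta, s, draw_z(m, rng)

    n_rand = int(rng.poisson(spec.randoms_kcps * 1000.0 * spec.duration_s))
    if n_rand:
        c1, c2 = _sample_valid(n_rand, draw_random, scanner, rng)
        parts.append(_frame(c1, c2, "random", n_rand, spec, rng))

    if not parts:
        return _frame(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), "true", 0, spec, rng
        )
    df = pd.concat(parts, ignore_index=True)
    return df.sort_values("time", kind="stable").reset_index(drop=True)


def _frame(c1, c2, label, n, spec, rng) -> pd.DataFrame:
    ids1 = np.arange(n, dtype=np.int64)
    # randoms join photons of distinct decays; scattered carry a history
    ids2 = ids1 + n if label == "random" else ids1
    scat = np.ones(n, dtype=np.int64) if label == "scattered" else np.zeros(n, dtype=np.int64)
    return pd.DataFrame(
        {
            "crystal1": c1,
            "crystal2": c2,
            "time": rng.uniform(0.0, spec.duration_s * 1e9, n),
            "energy1": np.full(n, 511.0),
            "energy2": np.full(n, 511.0),
            "event_id1": ids1,
            "event_id2": ids2,
            "scatter1": scat,
            "scatter2": np.zeros(n, dtype=np.int64),
            "label": label,
        }
    )


def generate_sensitivity_series(
    s0: float,
    mu_al_per_mm: float,
    thicknesses_mm,
    noise_counts: float | None = None,
    position_offset: float = 0.0,
    seed: int = 0,
) -> SensitivitySeries:
    """Exact (or Poisson-noisy) S_i = S_0 exp(-2 mu X_i) series.

    With ``noise_counts`` set, each S_i is replaced by a Poisson draw at
    that expected count, rescaled — emulating a counting measurement with
    noise_counts expected trues per sleeve setting.
    """
    thicknesses = np.asarray(thicknesses_mm, dtype=float)
    if len(thicknesses) == 0:
        raise ValueError("need at least one thickness")
    rng = np.random.default_rng(seed)
    series = SensitivitySeries(position_offset=position_offset)
    for x in thicknesses:
        s_true = s0 * np.exp(-2.0 * mu_al_per_mm * x)
        if noise_counts is not None:
            counts = rng.poisson(noise_counts)
            s_val = s_true * counts / noise_counts
        else:
            s_val = s_true
        series.entries.append(
            SensitivityEntry(
                thickness_mm=float(x),
                rate_cps_per_kbq=float(s_val),
                min_trues_per_slice=int(noise_counts or 0),
                total_trues=int(noise_counts or 0),
            )
        )
    return series
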
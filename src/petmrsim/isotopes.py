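"""Beta-plus decay schemes and positron energy-spectrum sampling.

Supported isotopes: 18F, 15O, 13N, 11C, 68Ga and 82Rb.  Each is described by
its total beta-plus branching ratio and one or two beta branches (endpoint
kinetic energy, intensity, optional coincident prompt gamma).  The branch
spectrum uses the allowed-transition Fermi shape

    N(T) dT  ∝  F(Z, T) · p · (T + m_e c²) · (Q − T)² dT

with the nonrelativistic point-charge Coulomb correction for positrons,
F = 2πη / (1 − exp(−2πη)) with η = −Z α / β (the daughter's nuclear charge
repels the outgoing positron, suppressing the low-energy end).  Screening is
neglected.  Sampling is by inverse transform on a tabulated CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

MEC2_KEV = 511.0  # electron rest energy, keV
ALPHA = 7.2973525693e-3  # fine-structure constant


class UnsupportedIsotopeError(ValueError):
    """Raised for isotopes outside the supported beta-plus set."""


@dataclass(frozen=True)
class BetaBranch:
    """One beta-plus decay branch.

    endpoint_energy : maximum positron kinetic energy (keV).
    intensity       : fraction of ALL decays taking this branch.
    prompt_gamma_energy : keV of a gamma emitted in coincidence, or None.
    """

    endpoint_energy: float
    intensity: float
    prompt_gamma_energy: float | None = None

    def __post_init__(self) -> None:
        if self.endpoint_energy <= 0:
            raise ValueError("branch endpoint energy must be positive")
        if not 0 < self.intensity <= 1:
            raise ValueError("branch intensity must be in (0, 1]")


@dataclass(frozen=True)
class IsotopeSpec:
    """Decay scheme of a beta-plus emitter."""

    name: str
    branches: tuple[BetaBranch, ...]
    branching_ratio: float  # total beta-plus fraction, percent
    atomic_number_daughter: int

    def __post_init__(self) -> None:
        if not 0 < self.branching_ratio <= 100:
            raise ValueError("branching ratio must be in (0, 100] percent")
        total = sum(b.intensity for b in self.branches)
        if abs(total - self.branching_ratio / 100.0) > 1e-6:
            raise ValueError(
                f"branch intensities sum to {total}, expected "
                f"{self.branching_ratio / 100.0}"
            )

    @property
    def main_branch(self) -> BetaBranch:
        return max(self.branches, key=lambda b: b.intensity)

    @property
    def max_endpoint(self) -> float:
        return max(b.endpoint_energy for b in self.branches)


@dataclass(frozen=True)
class SpectrumTable:
    """Tabulated beta spectrum: normalized density and CDF on an energy grid."""

    energies: np.ndarray  # keV, ascending from 0 to the endpoint
    density: np.ndarray  # probability density per keV, trapezoid-normalized
    cumulative: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("spectrum density must be non-negative")
        if self.cumulative is None:
            cdf = _trapezoid_cdf(self.energies, self.density)
            object.__setattr__(self, "cumulative", cdf)

    def mean_energy(self) -> float:
        return float(np.trapezoid(self.energies * self.density, self.energies))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform sample of n kinetic energies (keV)."""
        u = rng.random(n)
        return np.interp(u, self.cumulative, self.energies)


def _trapezoid_cdf(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    cdf = np.concatenate(([0.0], np.cumsum(np.diff(x) * (f[1:] + f[:-1]) / 2.0)))
    cdf /= cdf[-1]
    return np.maximum.accumulate(cdf)  # guard monotonicity against round-off


_SPEC_CACHE: dict[str, IsotopeSpec] = {}


def _load_table() -> dict:
    with resources.files("petmrsim.data").joinpath("isotopes.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_isotopes() -> list[str]:
    return sorted(_load_table().keys())


def get_isotope(name: str) -> IsotopeSpec:
    """Look up an isotope by symbol (case-insensitive, e.g. 'F18', 'rb82')."""
    table = _load_table()
    match = {k.lower(): k for k in table}.get(name.strip().lower())
    if match is None:
        raise UnsupportedIsotopeError(
            f"{name!r} is not a supported beta-plus emitter; "
            f"supported: {', '.join(sorted(table))}"
        )
    if match in _SPEC_CACHE:
        return _SPEC_CACHE[match]
    rec = table[match]
    branches = tuple(
        BetaBranch(
            endpoint_energy=float(b["endpoint_kev"]),
            intensity=float(b["intensity"]),
            prompt_gamma_energy=(
                float(b["prompt_gamma_kev"]) if "prompt_gamma_kev" in b else None
            ),
        )
        for b in rec["branches"]
    )
    spec = IsotopeSpec(
        name=match,
        branches=branches,
        branching_ratio=float(rec["branching_ratio"]),
        atomic_number_daughter=int(rec["daughter_z"]),
    )
    _SPEC_CACHE[match] = spec
    return spec


# ---------------------------------------------------------------------------
# Beta spectrum
# ---------------------------------------------------------------------------

def fermi_function(z_daughter: int, kinetic_kev: np.ndarray) -> np.ndarray:
    """Nonrelativistic point-charge Coulomb correction for positrons.

    F = 2πη / (1 − e^{−2πη}), η = −Z α / β.  F < 1 everywhere for positrons
    and F → 0 as β → 0, driving the density to zero at zero kinetic energy.
    """
    t = np.asarray(kinetic_kev, dtype=float)
    gamma = 1.0 + t / MEC2_KEV
    beta = np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 1e-30, None))
    eta = -z_daughter * ALPHA / beta
    x = 2.0 * np.pi * eta
    # x is negative; 1 - exp(-x) can overflow for very small beta: clamp.
    with np.errstate(over="ignore"):
        denom = 1.0 - np.exp(-x)
    out = np.where(np.isfinite(denom) & (denom != 0.0), x / np.where(denom == 0, 1, denom), 0.0)
    return np.clip(out, 0.0, None)


def _allowed_shape(z_daughter: int, q_kev: float, t_kev: np.ndarray) -> np.ndarray:
    t = np.asarray(t_kev, dtype=float)
    total_e = t + MEC2_KEV
    p = np.sqrt(np.clip(total_e**2 - MEC2_KEV**2, 0.0, None))  # keV/c
    shape = fermi_function(z_daughter, t) * p * total_e * (q_kev - t) ** 2
    return np.where((t <= 0) | (t >= q_kev), 0.0, shape)


def beta_spectrum(
    spec: IsotopeSpec, branch: BetaBranch, grid_size: int = 1024
) -> SpectrumTable:
    """Tabulate the normalized allowed-shape spectrum of one branch."""
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    q = branch.endpoint_energy
    if q <= 0:
        raise ValueError("endpoint must be positive")
    e = np.linspace(0.0, q, grid_size)
    dens = _allowed_shape(spec.atomic_number_daughter, q, e)
    norm = np.trapezoid(dens, e)
    return SpectrumTable(energies=e, density=dens / norm)


@dataclass(frozen=True)
class DecaySample:
    """Vectorized sample of n decays.

    branch_index == -1 marks decays with no positron (electron capture).
    prompt_gamma_kev is 0.0 where the branch emits no gamma.
    """

    branch_index: np.ndarray
    energy_kev: np.ndarray  # 0 where no positron
    prompt_gamma_kev: np.ndarray


def sample_decays(spec: IsotopeSpec, n: int, seed: int) -> DecaySample:
    """Sample n decays: branch choice, positron kinetic energy, prompt gammas."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array([b.intensity for b in spec.branches])
    p_none = 1.0 - probs.sum()
    choice = rng.choice(
        len(probs) + 1, size=n, p=np.concatenate((probs, [max(p_none, 0.0)]))
    )
    branch_index = np.where(choice == len(probs), -1, choice)
    energy = np.zeros(n)
    gamma = np.zeros(n)
    for i, branch in enumerate(spec.branches):
        mask = branch_index == i
        m = int(mask.sum())
        if m:
            table = beta_spectrum(spec, branch)
            energy[mask] = table.sample(m, rng)
            if branch.prompt_gamma_energy is not None:
                gamma[mask] = branch.prompt_gamma_energy
    return DecaySample(branch_index=branch_index, energy_kev=energy, prompt_gamma_kev=gamma)


def theoretical_sensitivity(
    branching_ratio_pct: float,
    ref_sensitivity: float = 21.5,
    ref_branching_ratio_pct: float = 96.76,
) -> float:
    """Branching-ratio-scaled sensitivity prediction (cps/kBq).

    Scales a reference NEMA sensitivity (default: the 18F value of
    21.5 cps/kBq) by the ratio of beta-plus branching ratios.
    """
    if min(branching_ratio_pct, ref_sensitivity, ref_branching_ratio_pct) <= 0:
        raise ValueError("all arguments must be positive")
    return ref_sensitivity * branching_ratio_pct / ref_branching_ratio_pct
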
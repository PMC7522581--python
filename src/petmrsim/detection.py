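"""Annihilation-photon and prompt-gamma tracking, digitization and
coincidence sorting.

Photons are tracked through the phantom with Woodcock (delta) tracking
against a majorant attenuation, so no per-shape boundary distances are ever
computed: virtual collisions are rejected with probability mu_local/mu_max.
Real interactions split into photoelectric absorption and Compton
scattering; Compton energies and angles are sampled from the Klein-Nishina
differential cross-section with Kahn's rejection method, and each Compton
interaction increments the photon's scatter count (the history used for the
true/scattered classification).  A photon leaving the phantom flies
ballistically to the detector ring; crystal interception uses the block/
crystal tiling of the scanner and the photon is absorbed with probability
1 - exp(-mu_LYSO(E) * depth), thinned further by a global efficiency factor
that absorbs everything the desk-scale chain does not model (crystal
packing, optical losses, inter-crystal scatter).

The digitizer applies a Gaussian energy blur (FWHM fraction at 511 keV with
sqrt(E) scaling), the 425-650 keV acceptance window, and per-block dead
time (paralyzable by default).  Coincidence sorting pairs time-ordered
singles within the coincidence window (take-all-goods policy, self-pairs on
one crystal excluded).  Classification follows the event-ID rule: different
originating decays -> random; same decay with any Compton history on either
photon -> scattered; otherwise true.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isotopes import IsotopeSpec, sample_decays
from .materials import (
    MEC2_KEV,
    DigitizerConfig,
    Material,
    ScannerGeometry,
    World,
    get_material,
    klein_nishina_total_cm2,
)
from .transport import TransportConfig, _perp_frame, transport_batch

#: photons below this energy can never blur into the acceptance window
MIN_TRACKED_KEV = 300.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def emit_annihilation_pair(
    record,
    event_id: int,
    time_ns: float,
    rng: np.random.Generator,
    noncollinearity_fwhm_rad: float = 0.0,
):
    """Two back-to-back 511 keV photons from one annihilation record.

    Returns two PhotonState-like dicts.  With the default zero
    non-collinearity the directions are exactly antiparallel.
    """
    d = isotropic_directions(1, rng)[0]
    d2 = -d
    if noncollinearity_fwhm_rad > 0.0:
        sigma = noncollinearity_fwhm_rad * _FWHM_TO_SIGMA
        theta = abs(rng.normal(0.0, sigma))
        psi = rng.uniform(0.0, 2.0 * np.pi)
        e1, e2 = _perp_frame(d2[None, :])
        d2 = (
            np.cos(theta) * d2
            + np.sin(theta) * (np.cos(psi) * e1[0] + np.sin(psi) * e2[0])
        )
        d2 /= np.linalg.norm(d2)
    point = np.asarray(record.annihilation_point, dtype=float)
    mk = lambda direction: {
        "position": point.copy(),
        "direction": direction,
        "energy": MEC2_KEV,
        "scatter_count": 0,
        "event_id": event_id,
        "emission_time": time_ns,
    }
    return mk(d), mk(d2)


# ---------------------------------------------------------------------------
# Klein-Nishina sampling (Kahn's method, vectorized rejection)
# ---------------------------------------------------------------------------

def sample_compton(
    energy_kev: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample scattered energy and polar angle cosine from Klein-Nishina."""
    alpha = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    n = len(alpha)
    eta = np.empty(n)
    cos_t = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while np.any(todo):
        m = int(todo.sum())
        a = alpha[todo]
        r1, r2, r3 = rng.random(m), rng.random(m), rng.random(m)
        branch1 = r1 <= (2.0 * a + 1.0) / (2.0 * a + 9.0)
        e = np.where(branch1, 1.0 + 2.0 * a * r2, (2.0 * a + 1.0) / (1.0 + 2.0 * a * r2))
        ct = 1.0 - (e - 1.0) / a
        acc1 = r3 <= 4.0 * (1.0 / e - 1.0 / e**2)
        acc2 = r3 <= 0.5 * (ct**2 + 1.0 / e)
        accept = np.where(branch1, acc1, acc2)
        idx = np.flatnonzero(todo)[accept]
        eta[idx] = e[accept]
        cos_t[idx] = ct[accept]
        todo[idx] = False
    return np.asarray(energy_kev, dtype=float) / eta, cos_t


def compton_scattered_energy(energy_kev: float, cos_theta: float) -> float:
    """Closed-form Compton energy at a given scattering angle."""
    return energy_kev / (1.0 + (energy_kev / MEC2_KEV) * (1.0 - cos_theta))


def _rotate(dirs: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    psi = rng.uniform(0.0, 2.0 * np.pi, len(dirs))
    e1, e2 = _perp_frame(dirs)
    st = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    out = (
        cos_t[:, None] * dirs
        + (st * np.cos(psi))[:, None] * e1
        + (st * np.sin(psi))[:, None] * e2
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Woodcock tracking through the phantom
# ---------------------------------------------------------------------------

def _attenuation_arrays(world: World):
    mats = world.materials()
    ne = np.array([m.electron_density_cm3 for m in mats])
    pe511 = np.array([m.photoelectric_511 for m in mats])
    return ne, pe511


def _mu_mm(ne, pe511, energy_kev):
    """Linear attenuation (1/mm): Compton + photoelectric parts."""
    sigma = klein_nishina_total_cm2(energy_kev)
    mu_c = ne * sigma / 10.0
    mu_pe = pe511 * (MEC2_KEV / energy_kev) ** 3 / 10.0
    return mu_c, mu_pe


def track_photons_batch(
    positions: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    world: World,
    rng: np.random.Generator,
    max_scatters: int = 30,
):
    """Track photons until escape or absorption.

    Returns (positions, directions, energies, scatter_counts, alive) where
    ``alive`` marks photons that escaped the phantom (not absorbed) with
    energy above MIN_TRACKED_KEV.
    """
    pos = np.array(positions, dtype=float)
    dirs = np.array(directions, dtype=float)
    en = np.array(energies, dtype=float)
    n = len(en)
    scat = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    done = np.zeros(n, dtype=bool)

    if not world.shapes:
        return pos, dirs, en, scat, alive

    lo, hi = world.bounds()
    ne, pe511 = _attenuation_arrays(world)
    ne_max = ne.max()
    pe_max = pe511.max()

    idx = np.flatnonzero(alive)
    for _ in range(max_scatters * 20):
        if len(idx) == 0:
            break
        e = en[idx]
        mu_c_maj, mu_pe_maj = _mu_mm(ne_max, pe_max, e)
        mu_maj = mu_c_maj + mu_pe_maj
        step = -np.log(np.clip(rng.random(len(idx)), 1e-300, None)) / mu_maj
        pos[idx] += dirs[idx] * step[:, None]

        outside = np.any((pos[idx] < lo) | (pos[idx] > hi), axis=1)
        # escaped photons keep their state; drop from the working set
        keep = ~outside
        idx = idx[keep]
        if len(idx) == 0:
            break

        mat_idx = world.material_index_at(pos[idx])
        e = en[idx]
        mu_c, mu_pe = _mu_mm(ne[mat_idx], pe511[mat_idx], e)
        mu_t = mu_c + mu_pe
        mu_c_maj, mu_pe_maj = _mu_mm(ne_max, pe_max, e)
        u = rng.random(len(idx)) * (mu_c_maj + mu_pe_maj)
        real = u < mu_t
        photo = u < mu_pe  # photoelectric share of the real interactions

        absorbed = np.flatnonzero(real & photo)
        if len(absorbed):
            gi = idx[absorbed]
            alive[gi] = False
            done[gi] = True

        compton = np.flatnonzero(real & ~photo)
        if len(compton):
            gi = idx[compton]
            new_e, cos_t = sample_compton(en[gi], rng)
            dirs[gi] = _rotate(dirs[gi], cos_t, rng)
            en[gi] = new_e
            scat[gi] += 1
            low = new_e < MIN_TRACKED_KEV
            if np.any(low):
                kill = gi[low]
                alive[kill] = False
                done[kill] = True
        idx = idx[~done[idx]]
        over = scat[idx] >= max_scatters
        if np.any(over):
            alive[idx[over]] = False
            idx = idx[~over]
    return pos, dirs, en, scat, alive


def track_photon(photon: dict, world: World, scanner: ScannerGeometry, rng):
    """Track a single photon; returns a detector-hit dict or None on escape.

    Scalar convenience wrapper over the batch tracker plus ring projection.
    """
    pos, dirs, en, scat, alive = track_photons_batch(
        photon["position"][None, :],
        photon["direction"][None, :],
        np.array([photon["energy"]]),
        world,
        rng,
    )
    if not alive[0]:
        return None
    crystal, t_extra = project_to_ring(pos, dirs, scanner)
    if crystal[0] < 0:
        return None
    return {
        "crystal": int(crystal[0]),
        "energy": float(en[0]),
        "scatter_count": int(scat[0]),
        "event_id": photon["event_id"],
        "time": photon["emission_time"],
    }


def project_to_ring(
    positions: np.ndarray, directions: np.ndarray, scanner: ScannerGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect rays with the detector cylinder; map to crystal indices.

    Returns (crystal_index, path_to_ring_mm); index -1 where the ray misses
    the crystal coverage (dead space, axial overrun, or axial rays).
    """
    p = np.atleast_2d(positions)
    d = np.atleast_2d(directions)
    r2 = scanner.ring_radius**2
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2.0 * (p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1])
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - r2
    disc = b**2 - 4.0 * a * c
    ok = (a > 1e-12) & (disc > 0.0)
    safe_a = np.where(ok, a, 1.0)
    t = (-b + np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * safe_a)
    ok &= t > 0.0
    hit = p + t[:, None] * d
    theta = np.arctan2(hit[:, 1], hit[:, 0])
    crystal = scanner.crystal_from_angle_z(theta, hit[:, 2])
    crystal = np.where(ok, crystal, -1)
    return crystal, t


# ---------------------------------------------------------------------------
# Digitizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleEvent:
    """One accepted detector single."""

    crystal: int
    detection_time: float  # ns
    recorded_energy: float  # keV
    event_id: int
    scatter_count: int


@dataclass
class CoincidenceEvent:
    """A pair of singles within the coincidence window."""

    event1: SingleEvent
    event2: SingleEvent
    label: str | None = None


def digitize(
    hits: pd.DataFrame, config: DigitizerConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Energy blur + window + per-block dead time on a time-sorted hit table.

    ``hits`` columns: crystal, block, time, energy, event_id, scatter_count.
    """
    t = hits["time"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("hits must be time-sorted")
    e = hits["energy"].to_numpy(dtype=float)
    sigma511 = config.energy_resolution_fwhm * MEC2_KEV * _FWHM_TO_SIGMA
    sigma = sigma511 * np.sqrt(np.clip(e, 0.0, None) / MEC2_KEV)
    e_rec = e + rng.normal(size=len(e)) * sigma
    lo, hi = config.energy_window_kev
    keep = (e_rec >= lo) & (e_rec <= hi)

    out = hits.loc[keep].copy()
    out["energy"] = e_rec[keep]

    tau = config.dead_time_tau_ns
    if tau > 0.0 and len(out):
        times = out["time"].to_numpy()
        blocks = out["block"].to_numpy()
        order = np.lexsort((times, blocks))
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        tb = times[order]
        bb = blocks[order]
        if config.dead_time_model == "paralyzable":
            ok_sorted = np.ones(len(tb), dtype=bool)
            same = bb[1:] == bb[:-1]
            ok_sorted[1:] = ~(same & (np.diff(tb) <= tau))
        else:
            ok_sorted = np.ones(len(tb), dtype=bool)
            last_t = -np.inf
            last_b = -1
            for i in range(len(tb)):
                if bb[i] != last_b:
                    last_b = bb[i]
                    last_t = tb[i]
                elif tb[i] - last_t <= tau:
                    ok_sorted[i] = False
                else:
                    last_t = tb[i]
        out = out.loc[ok_sorted[inv]]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Coincidence sorting and classification
# ---------------------------------------------------------------------------

def sort_coincidences(singles: pd.DataFrame, window_ns: float) -> pd.DataFrame:
    """Pair time-sorted singles within the coincidence window.

    Take-all-goods: within a cluster of k singles inside the window every
    pair is emitted, except self-pairs on a single crystal.
    """
    t = singles["time"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("singles must be time-sorted")
    n = len(t)
    i_list, j_list = [], []
    k = 1
    while True:
        if k >= n:
            break
        close = t[k:] - t[:-k] <= window_ns
        idx = np.flatnonzero(close)
        if len(idx) == 0:
            break
        i_list.append(idx)
        j_list.append(idx + k)
        k += 1
    if not i_list:
        return _empty_coincidences()
    i = np.concatenate(i_list)
    j = np.concatenate(j_list)
    c1 = singles["crystal"].to_numpy()
    keep = c1[i] != c1[j]
    i, j = i[keep], j[keep]
    order = np.argsort(t[i], kind="stable")
    i, j = i[order], j[order]

    df = pd.DataFrame(
        {
            "crystal1": c1[i],
            "crystal2": c1[j],
            "time": t[i],
            "energy1": singles["energy"].to_numpy()[i],
            "energy2": singles["energy"].to_numpy()[j],
            "event_id1": singles["event_id"].to_numpy()[i],
            "event_id2": singles["event_id"].to_numpy()[j],
            "scatter1": singles["scatter_count"].to_numpy()[i],
            "scatter2": singles["scatter_count"].to_numpy()[j],
        }
    )
    df["label"] = classify_coincidences(df)
    return df


def _empty_coincidences() -> pd.DataFrame:
    cols = [
        "crystal1", "crystal2", "time", "energy1", "energy2",
        "event_id1", "event_id2", "scatter1", "scatter2", "label",
    ]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})


def classify_coincidences(df: pd.DataFrame) -> np.ndarray:
    """Vectorized true/scattered/random labels by the event-ID rule."""
    same = df["event_id1"].to_numpy() == df["event_id2"].to_numpy()
    unscattered = (df["scatter1"].to_numpy() == 0) & (df["scatter2"].to_numpy() == 0)
    return np.where(~same, "random", np.where(unscattered, "true", "scattered"))


def classify_coincidence(c: CoincidenceEvent) -> str:
    """Label one coincidence: random / true / scattered."""
    if c.event1.event_id != c.event2.event_id:
        label = "random"
    elif c.event1.scatter_count == 0 and c.event2.scatter_count == 0:
        label = "true"
    else:
        label = "scattered"
    c.label = label
    return label


# ---------------------------------------------------------------------------
# Acquisition pipeline
# ---------------------------------------------------------------------------

@dataclass
class Acquisition:
    """List-mode output of one simulated acquisition."""

    coincidences: pd.DataFrame
    singles_rate_cps: float
    duration_s: float
    n_decays: int
    activity_bq: float
    coincidence_window_ns: float = 4.57


def simulate_acquisition(
    isotope: IsotopeSpec,
    world: World,
    scanner: ScannerGeometry,
    digitizer: DigitizerConfig,
    activity_bq: float,
    n_decays: int,
    seed: int,
    transport_config: TransportConfig | None = None,
    efficiency: float = 1.0,
    prompt_gammas: bool = True,
    chunk_size: int = 400_000,
) -> Acquisition:
    """Simulate ``n_decays`` decays at a fixed activity.

    The acquisition duration follows from n_decays / activity; decay times
    are uniform on it, which conditionally on the decay count is the Poisson
    process the randoms and dead-time models need.  Positrons are
    transported to annihilation in the world (escapees contribute nothing),
    back-to-back 511 keV photon pairs and any prompt gammas are tracked to
    the ring, digitized and sorted into coincidences.
    """
    if world.source is None:
        raise ValueError("world has no source region")
    tcfg = transport_config or TransportConfig(seed=seed)
    duration_ns = n_decays / activity_bq * 1e9
    crystal_mu_mm = _lyso_mu_mm
    depth = scanner.crystal_depth

    frames = []
    n_singles_raw = 0
    start = 0
    chunk_i = 0
    while start < n_decays:
        m = min(chunk_size, n_decays - start)
        rng = np.random.default_rng((seed, 17, chunk_i))
        decays = sample_decays(
            isotope, m, seed=(seed * 1_000_003 + chunk_i * 97 + 13) % (2**31)
        )
        times = rng.uniform(0.0, duration_ns, m)
        event_ids = np.arange(start, start + m, dtype=np.int64)
        origins = world.source.sample_points(m, rng)

        has_pos = decays.branch_index >= 0
        k = int(has_pos.sum())
        cloud = transport_batch(
            decays.energy_kev[has_pos],
            origins[has_pos],
            isotropic_directions(k, rng),
            world,
            tcfg,
            rng,
        )
        ann_ok = ~cloud.escaped
        ann_pts = cloud.annihilation[ann_ok]
        ann_ids = event_ids[has_pos][ann_ok]
        ann_times = times[has_pos][ann_ok]

        # photon source list: two 511s per annihilation + prompt gammas
        d1 = isotropic_directions(len(ann_pts), rng)
        p_pos = [ann_pts, ann_pts]
        p_dir = [d1, -d1]
        p_en = [np.full(len(ann_pts), MEC2_KEV)] * 2
        p_id = [ann_ids, ann_ids]
        p_t = [ann_times, ann_times]
        if prompt_gammas:
            has_g = decays.prompt_gamma_kev > 0.0
            g = int(has_g.sum())
            if g:
                p_pos.append(origins[has_g])
                p_dir.append(isotropic_directions(g, rng))
                p_en.append(decays.prompt_gamma_kev[has_g])
                p_id.append(event_ids[has_g])
                p_t.append(times[has_g])
        pos = np.concatenate(p_pos)
        dirs = np.concatenate(p_dir)
        en = np.concatenate(p_en)
        ids = np.concatenate(p_id)
        tt = np.concatenate(p_t)

        pos, dirs, en, scat, alive = track_photons_batch(pos, dirs, en, world, rng)
        crystal, _ = project_to_ring(pos[alive], dirs[alive], scanner)
        det_ok = crystal >= 0
        e_hit = en[alive][det_ok]
        p_abs = 1.0 - np.exp(-crystal_mu_mm(e_hit) * depth)
        accept = rng.random(len(e_hit)) < p_abs * efficiency
        frames.append(
            pd.DataFrame(
                {
                    "crystal": crystal[det_ok][accept],
                    "time": tt[alive][det_ok][accept],
                    "energy": e_hit[accept],
                    "event_id": ids[alive][det_ok][accept],
                    "scatter_count": scat[alive][det_ok][accept],
                }
            )
        )
        start += m
        chunk_i += 1

    hits = pd.concat(frames, ignore_index=True)
    n_singles_raw = len(hits)
    ring, block, _, _ = _components_safe(scanner, hits["crystal"].to_numpy())
    hits["block"] = ring * scanner.blocks_per_ring + block
    hits = hits.sort_values("time", kind="stable").reset_index(drop=True)

    rng_d = np.random.default_rng((seed, 23))
    singles = digitize(hits, digitizer, rng_d)
    coinc = sort_coincidences(singles, digitizer.coincidence_window_ns)
    duration_s = duration_ns * 1e-9
    return Acquisition(
        coincidences=coinc,
        singles_rate_cps=len(singles) / duration_s,
        duration_s=duration_s,
        n_decays=n_decays,
        activity_bq=activity_bq,
        coincidence_window_ns=digitizer.coincidence_window_ns,
    )


def _components_safe(scanner: ScannerGeometry, crystal: np.ndarray):
    return scanner.crystal_components(np.clip(crystal, 0, scanner.n_crystals - 1))


_LYSO: Material = get_material("lyso")


def _lyso_mu_mm(energy_kev: np.ndarray) -> np.ndarray:
    return _LYSO.linear_attenuation(energy_kev) / 10.0


def ssrb_slice(scanner: ScannerGeometry, crystal1, crystal2) -> np.ndarray:
    """Single-slice-rebinned slice index (0 .. 2*n_axial-2) of a LOR."""
    r1, _, a1, _ = scanner.crystal_components(crystal1)
    r2, _, a2, _ = scanner.crystal_components(crystal2)
    na = scanner.crystals_per_ring_axial
    return (r1 * na + a1) + (r2 * na + a2)
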
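"""Idealised plastic-scintillator total-body scanner response.

Photon transport is single-interaction: a photon emitted inside the bore is
traced to the cylindrical plastic shell (four contiguous annular layers,
43..49 cm radius by default), the interaction depth is sampled from the
exponential attenuation law along the in-plastic slant path, and the deposited
energy is drawn from the Klein-Nishina Compton electron spectrum.  Hit
positions are smeared with a 5 mm FWHM Gaussian (axially and tangentially;
the radial coordinate is kept at the interaction radius, as for a strip
readout), and hit times with a Gaussian whose width is tied to the
coincidence resolving time: CRT is the FWHM of the *difference* of two
independent single-hit times, so sigma_single = CRT / (2 sqrt(2 ln 2)) / sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .generator import generate_events, SourceSpec
from .physics import CONSTANTS, Material, compton_edge, material

__all__ = [
    "DetectorGeometry",
    "DetectorResponseConfig",
    "SelectionCounters",
    "FWHM_TO_SIGMA",
    "crt_to_sigma_single",
    "propagate_photons",
    "sample_compton_deposits",
    "smear_hits",
    "smear_triples",
    "simulate_triples",
    "select_triples",
    "efficiency_curves",
    "line_source",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def crt_to_sigma_single(crt_ps: float) -> float:
    """Single-hit Gaussian sigma such that a two-hit time difference has FWHM = CRT."""
    if crt_ps < 0:
        raise ValueError("CRT must be non-negative")
    return crt_ps * FWHM_TO_SIGMA / np.sqrt(2.0)


@dataclass(frozen=True)
class DetectorGeometry:
    """Cylindrical shell of contiguous plastic layers.

    Four 1.5-cm annuli starting at the 43 cm inner radius give the default
    6 cm total plastic; layers touch, so transport treats them as one annulus.
    """

    inner_radius: float = 43.0
    afov: float = 200.0
    n_layers: int = 4
    layer_thickness: float = 1.5
    strip_cross_section_cm: tuple[float, float] = (0.7, 1.9)  # metadata only

    def __post_init__(self) -> None:
        if self.inner_radius <= 0 or self.afov <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.n_layers < 1 or self.layer_thickness <= 0:
            raise ValueError("invalid layer structure")

    @property
    def total_thickness(self) -> float:
        return self.n_layers * self.layer_thickness

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.total_thickness

    @property
    def half_length(self) -> float:
        return self.afov / 2.0

    @property
    def layer_inner_radii(self) -> tuple[float, ...]:
        return tuple(self.inner_radius + i * self.layer_thickness
                     for i in range(self.n_layers))


@dataclass(frozen=True)
class DetectorResponseConfig:
    """Resolution and selection settings of the idealised scanner."""

    crt_ps: float = 140.0
    spatial_fwhm_cm: float = 0.5
    threshold_annih_kev: float = 200.0
    threshold_prompt_kev: float = 400.0

    def __post_init__(self) -> None:
        if self.crt_ps < 0 or self.spatial_fwhm_cm < 0:
            raise ValueError("resolutions must be non-negative")
        if self.threshold_annih_kev < 0 or self.threshold_prompt_kev < 0:
            raise ValueError("thresholds must be non-negative")
        if self.threshold_prompt_kev <= compton_edge(511.0):
            raise ValueError(
                "prompt threshold must exceed the 511 keV Compton edge "
                "(340.7 keV) for unambiguous prompt tagging"
            )

    @property
    def sigma_single_ps(self) -> float:
        return crt_to_sigma_single(self.crt_ps)

    @property
    def sigma_pos_cm(self) -> float:
        return self.spatial_fwhm_cm * FWHM_TO_SIGMA


@dataclass
class SelectionCounters:
    """Per-cut bookkeeping of the triple-coincidence selection."""

    generated: int = 0
    all_three_interact: int = 0
    pass_annih_threshold: int = 0
    pass_prompt_threshold: int = 0

    @property
    def selected(self) -> int:
        return self.pass_prompt_threshold

    def merge(self, other: "SelectionCounters") -> "SelectionCounters":
        return SelectionCounters(
            self.generated + other.generated,
            self.all_three_interact + other.all_three_interact,
            self.pass_annih_threshold + other.pass_annih_threshold,
            self.pass_prompt_threshold + other.pass_prompt_threshold,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "generated": self.generated,
            "all_three_interact": self.all_three_interact,
            "pass_annih_threshold": self.pass_annih_threshold,
            "pass_prompt_threshold": self.pass_prompt_threshold,
        }


def propagate_photons(
    origins: np.ndarray,
    directions: np.ndarray,
    energy_kev: float,
    geometry: DetectorGeometry,
    mat: Material,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Trace photons from in-bore origins to the plastic shell.

    Returns arrays: ``hit`` (bool mask), ``pos`` (N, 3) interaction points,
    ``tof_ps`` flight times, and ``path_cm`` available in-plastic path (for
    diagnostics).  A photon interacts if an exponential depth draw with the
    material's attenuation coefficient falls inside its in-plastic chord,
    clipped by the axial extent of the scanner.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(origins)
    rho2 = origins[:, 0] ** 2 + origins[:, 1] ** 2
    if np.any(rho2 >= geometry.inner_radius**2):
        raise ValueError("photon origin lies outside the scanner bore")
    mu = mat.mu(energy_kev)

    ux, uy, uz = directions[:, 0], directions[:, 1], directions[:, 2]
    px, py, pz = origins[:, 0], origins[:, 1], origins[:, 2]
    a = ux**2 + uy**2
    b = px * ux + py * uy

    with np.errstate(divide="ignore", invalid="ignore"):
        # outward crossings of the inner and outer cylinder (positive roots)
        disc_in = b**2 - a * (rho2 - geometry.inner_radius**2)
        disc_out = b**2 - a * (rho2 - geometry.outer_radius**2)
        t_in = (-b + np.sqrt(np.maximum(disc_in, 0.0))) / a
        t_out = (-b + np.sqrt(np.maximum(disc_out, 0.0))) / a
        # axial clipping: plastic only exists for |z| <= half_length
        t_cap = (np.sign(uz) * geometry.half_length - pz) / uz
    t_cap = np.where(uz == 0.0, np.inf, t_cap)
    axial_only = a == 0.0  # parallel to the axis: never crosses the shell

    t_lo = t_in
    t_hi = np.minimum(t_out, t_cap)
    path = np.maximum(t_hi - t_lo, 0.0)
    path[axial_only] = 0.0

    depth = rng.exponential(1.0 / mu, n)
    hit = depth < path
    t_int = t_lo + depth
    pos = origins + directions * t_int[:, None]
    tof_ps = t_int / CONSTANTS.c
    pos[~hit] = np.nan
    tof_ps[~hit] = np.nan
    return {"hit": hit, "pos": pos, "tof_ps": tof_ps, "path_cm": path}


def _klein_nishina_weight(cos_t: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / (1.0 + alpha * (1.0 - cos_t))  # E'/E
    return r**2 * (r + 1.0 / r - (1.0 - cos_t**2))


def sample_compton_deposits(
    energy_kev: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Electron energies from the Klein-Nishina spectrum, by rejection sampling.

    The scattering angle is drawn against a flat envelope bounded by the
    forward-scattering maximum of the differential cross-section; the deposit
    is E - E' with E' = E / (1 + (E/m_e c^2)(1 - cos theta)), bounded by the
    Compton edge.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    alpha = energy_kev / CONSTANTS.m_e_c2_kev
    w_max = _klein_nishina_weight(np.array([1.0]), alpha)[0]
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.0), 1024)
        cos_t = rng.uniform(-1.0, 1.0, m)
        keep = rng.random(m) * w_max < _klein_nishina_weight(cos_t, alpha)
        accepted = cos_t[keep]
        take = min(len(accepted), n - filled)
        e_scattered = energy_kev / (1.0 + alpha * (1.0 - accepted[:take]))
        out[filled:filled + take] = energy_kev - e_scattered
        filled += take
    return out


def smear_hits(
    pos: np.ndarray,
    time_ps: np.ndarray,
    config: DetectorResponseConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply position (axial + tangential) and time smearing to hits.

    The radial coordinate is left at the true interaction radius; axial (z)
    and tangential (azimuthal) components receive independent Gaussians of
    ``spatial_fwhm_cm``.  With zero CRT / zero FWHM the input is returned
    unchanged, which the reconstruction tests rely on.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float)).copy()
    time_ps = np.asarray(time_ps, dtype=float).copy()
    n = len(pos)
    sig_p = config.sigma_pos_cm
    if sig_p > 0:
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        tangential = np.column_stack((-np.sin(phi), np.cos(phi)))
        pos[:, :2] += tangential * rng.normal(0.0, sig_p, n)[:, None]
        pos[:, 2] += rng.normal(0.0, sig_p, n)
    sig_t = config.sigma_single_ps
    if sig_t > 0:
        time_ps = time_ps + rng.normal(0.0, sig_t, n)
    return pos, time_ps


def select_triples(
    edep_a1: np.ndarray,
    edep_a2: np.ndarray,
    edep_p: np.ndarray,
    interact_mask: np.ndarray,
    config: DetectorResponseConfig,
) -> tuple[np.ndarray, SelectionCounters]:
    """Energy selection of triple coincidences with per-cut counters.

    ``interact_mask`` flags events whose three photons all interacted; the
    annihilation deposits must exceed ``threshold_annih_kev`` and the prompt
    deposit ``threshold_prompt_kev`` (strict inequalities, so a 399 keV
    prompt deposit fails a 400 keV threshold).
    """
    counters = SelectionCounters(generated=len(interact_mask))
    counters.all_three_interact = int(interact_mask.sum())
    annih_ok = interact_mask & (edep_a1 > config.threshold_annih_kev) \
        & (edep_a2 > config.threshold_annih_kev)
    counters.pass_annih_threshold = int(annih_ok.sum())
    selected = annih_ok & (edep_p > config.threshold_prompt_kev)
    counters.pass_prompt_threshold = int(selected.sum())
    return selected, counters


TRIPLE_COLUMNS = [
    "event_id", "source_id", "tau_gen_ps", "lifetime_ps",
    "x", "y", "z",
    "a1_x", "a1_y", "a1_z", "a1_t_ps", "a1_edep_kev",
    "a2_x", "a2_y", "a2_z", "a2_t_ps", "a2_edep_kev",
    "p_x", "p_y", "p_z", "p_t_ps", "p_edep_kev",
]


def simulate_triples(
    events: pd.DataFrame,
    geometry: DetectorGeometry | None = None,
    mat: Material | None = None,
    config: DetectorResponseConfig | None = None,
    *,
    rng: np.random.Generator | int = 0,
    smear: bool = True,
) -> tuple[pd.DataFrame, SelectionCounters]:
    """Full detector response for a table of generated decay events.

    Propagates the two annihilation photons (opposite directions, 511 keV)
    and the prompt photon (1160 keV), samples Compton deposits, applies the
    energy selection, and -- when ``smear`` is set -- Gaussian position/time
    smearing.  Returns the registered-triple table (true quantities kept
    alongside the registered ones) and the selection counters.
    """
    geometry = geometry or DetectorGeometry()
    mat = mat or material("plastic")
    config = config or DetectorResponseConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    origins = events[["x", "y", "z"]].to_numpy()
    a_dir = events[["adx", "ady", "adz"]].to_numpy()
    p_dir = events[["pdx", "pdy", "pdz"]].to_numpy()

    h1 = propagate_photons(origins, a_dir, 511.0, geometry, mat, rng)
    h2 = propagate_photons(origins, -a_dir, 511.0, geometry, mat, rng)
    hp = propagate_photons(origins, p_dir, 1160.0, geometry, mat, rng)

    n = len(events)
    edep1 = np.where(h1["hit"], sample_compton_deposits(511.0, n, rng), 0.0)
    edep2 = np.where(h2["hit"], sample_compton_deposits(511.0, n, rng), 0.0)
    edepp = np.where(hp["hit"], sample_compton_deposits(1160.0, n, rng), 0.0)

    interact = h1["hit"] & h2["hit"] & hp["hit"]
    selected, counters = select_triples(edep1, edep2, edepp, interact, config)

    annih_t = events["annih_t_ps"].to_numpy()
    t0 = events["t0_ps"].to_numpy()
    sel = selected
    pos1, t1 = h1["pos"][sel], annih_t[sel] + h1["tof_ps"][sel]
    pos2, t2 = h2["pos"][sel], annih_t[sel] + h2["tof_ps"][sel]
    posp, tp = hp["pos"][sel], t0[sel] + hp["tof_ps"][sel]
    if smear:
        pos1, t1 = smear_hits(pos1, t1, config, rng)
        pos2, t2 = smear_hits(pos2, t2, config, rng)
        posp, tp = smear_hits(posp, tp, config, rng)

    triples = pd.DataFrame({
        "event_id": events["event_id"].to_numpy()[sel],
        "source_id": events["source_id"].to_numpy()[sel],
        "tau_gen_ps": events["tau_gen_ps"].to_numpy()[sel],
        "lifetime_ps": events["lifetime_ps"].to_numpy()[sel],
        "x": origins[sel, 0], "y": origins[sel, 1], "z": origins[sel, 2],
        "a1_x": pos1[:, 0], "a1_y": pos1[:, 1], "a1_z": pos1[:, 2],
        "a1_t_ps": t1, "a1_edep_kev": edep1[sel],
        "a2_x": pos2[:, 0], "a2_y": pos2[:, 1], "a2_z": pos2[:, 2],
        "a2_t_ps": t2, "a2_edep_kev": edep2[sel],
        "p_x": posp[:, 0], "p_y": posp[:, 1], "p_z": posp[:, 2],
        "p_t_ps": tp, "p_edep_kev": edepp[sel],
    })
    return triples, counters


def smear_triples(
    triples: pd.DataFrame,
    config: DetectorResponseConfig,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Apply position/time smearing to an *unsmeared* triple table.

    Detection does not depend on the CRT, so one detected sample (from
    ``simulate_triples(..., smear=False)``) can be re-smeared at several CRT
    settings; this is how the CRT scan re-uses common random numbers for the
    transport stage.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = triples.copy()
    for tag in ("a1", "a2", "p"):
        pos = out[[f"{tag}_x", f"{tag}_y", f"{tag}_z"]].to_numpy()
        t = out[f"{tag}_t_ps"].to_numpy()
        pos, t = smear_hits(pos, t, config, rng)
        out[f"{tag}_x"], out[f"{tag}_y"], out[f"{tag}_z"] = pos.T
        out[f"{tag}_t_ps"] = t
    return out


def line_source(length_cm: float = 200.0, tau_ops_ns: float = 2.0) -> SourceSpec:
    """Axial line source emulated as metadata; see ``generate_line_events``."""
    return SourceSpec(0, (0.0, 0.0, 0.0), tau_ops_ns, 1.0)


def generate_line_events(
    n_events: int,
    rng: np.random.Generator,
    *,
    length_cm: float = 200.0,
    tau_ops_ns: float = 2.0,
) -> pd.DataFrame:
    """Decays uniform along a ``length_cm`` line on the scanner axis."""
    events = generate_events([line_source(length_cm, tau_ops_ns)], n_events, rng,
                             source_radius_cm=0.0)
    events["z"] = rng.uniform(-length_cm / 2.0, length_cm / 2.0, n_events)
    return events


def efficiency_curves(
    thresholds_kev: Sequence[float],
    n_events: int,
    geometry: DetectorGeometry | None = None,
    mat: Material | None = None,
    *,
    prompt_threshold_kev: float = 400.0,
    seed: int | np.random.Generator = 0,
    source_length_cm: float = 200.0,
) -> pd.DataFrame:
    """Registration efficiency against energy threshold for a line source.

    Columns: ``threshold_kev``, ``prompt`` (prompt photon registered above
    threshold), ``pair`` (both annihilation photons above threshold) and
    ``triple`` (pair above threshold with the prompt above the *fixed*
    ``prompt_threshold_kev``).  One common event sample is reused across
    thresholds (common random numbers), so each curve is exactly monotone
    non-increasing.
    """
    thresholds = np.asarray(sorted(thresholds_kev), dtype=float)
    geometry = geometry or DetectorGeometry()
    mat = mat or material("plastic")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    events = generate_line_events(n_events, rng, length_cm=source_length_cm)
    origins = events[["x", "y", "z"]].to_numpy()
    a_dir = events[["adx", "ady", "adz"]].to_numpy()
    p_dir = events[["pdx", "pdy", "pdz"]].to_numpy()

    h1 = propagate_photons(origins, a_dir, 511.0, geometry, mat, rng)
    h2 = propagate_photons(origins, -a_dir, 511.0, geometry, mat, rng)
    hp = propagate_photons(origins, p_dir, 1160.0, geometry, mat, rng)
    e1 = np.where(h1["hit"], sample_compton_deposits(511.0, n_events, rng), -1.0)
    e2 = np.where(h2["hit"], sample_compton_deposits(511.0, n_events, rng), -1.0)
    ep = np.where(hp["hit"], sample_compton_deposits(1160.0, n_events, rng), -1.0)

    rows = []
    prompt_fixed = ep > prompt_threshold_kev
    for thr in thresholds:
        prompt = ep > thr
        pair = (e1 > thr) & (e2 > thr)
        rows.append((thr, prompt.mean(), pair.mean(), (pair & prompt_fixed).mean()))
    return pd.DataFrame(rows, columns=["threshold_kev", "prompt", "pair", "triple"])
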
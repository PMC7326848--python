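"""Synthetic decay-event generation for Sc-44 labelled point sources.

Each decay emits one positron (annihilating, after an exponentially
distributed ortho-positronium lifetime, into two exactly back-to-back 511 keV
photons at the source point) and one 1160 keV prompt photon from the Ca-44*
de-excitation.  Prompt and annihilation directions are isotropic and mutually
independent.  Event times use an event-local clock with the positron emission
at t0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SourceSpec",
    "nema_sources",
    "sample_exponential",
    "sample_isotropic",
    "generate_events",
    "EVENT_COLUMNS",
]

NS_TO_PS = 1000.0


@dataclass(frozen=True)
class SourceSpec:
    """A point-like source: position [cm], oPs mean lifetime [ns], activity weight."""

    id: int
    position: tuple[float, float, float]
    tau_ops_ns: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_ops_ns <= 0:
            raise ValueError("mean lifetime must be positive")
        if self.weight <= 0:
            raise ValueError("source weight must be positive")

    @property
    def tau_ops_ps(self) -> float:
        return self.tau_ops_ns * NS_TO_PS


# Six point sources arranged following the NEMA NU 2 resolution protocol:
# transaxial offsets x = 1, 10, 20 cm at the axial centre and at 3/4 of the
# axial half-length; each position carries a different oPs mean lifetime in
# the range expected for human tissue.
_NEMA_TABLE = [
    (1, (1.0, 0.0, 0.0), 2.0),
    (2, (10.0, 0.0, 0.0), 2.4),
    (3, (20.0, 0.0, 0.0), 2.8),
    (4, (1.0, 0.0, 75.0), 2.2),
    (5, (10.0, 0.0, 75.0), 2.6),
    (6, (20.0, 0.0, 75.0), 3.0),
]


def nema_sources() -> list[SourceSpec]:
    """The default six-source arrangement (equal activity weights)."""
    return [SourceSpec(i, pos, tau, weight=1.0 / len(_NEMA_TABLE))
            for i, pos, tau in _NEMA_TABLE]


def sample_exponential(tau_ps: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exponential lifetimes with mean ``tau_ps`` via inverse-CDF sampling."""
    if tau_ps <= 0:
        raise ValueError("tau must be positive")
    return -tau_ps * np.log1p(-rng.random(n))


def sample_isotropic(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) unit vectors uniform on the sphere (uniform cos(theta), azimuth)."""
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack((sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))


EVENT_COLUMNS = [
    "event_id", "source_id", "x", "y", "z", "t0_ps",
    "pdx", "pdy", "pdz", "lifetime_ps", "annih_t_ps", "adx", "ady", "adz",
    "tau_gen_ps",
]


def generate_events(
    sources: Sequence[SourceSpec],
    n_events: int,
    seed: int | np.random.Generator,
    *,
    source_radius_cm: float = 0.1,
    deexcitation_tau_ps: float = 0.0,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Generate ``n_events`` decays from a weighted mixture of point sources.

    Columns: origin (x, y, z) [cm]; prompt emission time t0_ps and direction
    (pdx, pdy, pdz); true oPs lifetime [ps]; annihilation time; annihilation
    photon A direction (adx, ady, adz) -- photon B is its exact antipode;
    tau_gen_ps records the generating mean lifetime of the parent source.

    ``source_radius_cm`` smears origins uniformly inside a sphere of that
    radius (0 for ideal point sources); ``deexcitation_tau_ps`` optionally
    delays the prompt emission by an exponential Ca-44* de-excitation time
    (a few ps, negligible at the tens-of-ps precision of interest, default
    off).  The event clock starts at the positron emission, so the
    annihilation occurs at the oPs lifetime and the prompt photon leaves at
    t0 (zero unless the de-excitation delay is enabled).
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if not sources:
        raise ValueError("at least one source is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    weights = np.array([s.weight for s in sources], dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(sources), size=n_events, p=weights)

    positions = np.array([s.position for s in sources], dtype=float)[idx]
    taus = np.array([s.tau_ops_ps for s in sources], dtype=float)[idx]
    source_ids = np.array([s.id for s in sources], dtype=np.int64)[idx]

    if source_radius_cm > 0:
        # uniform in a sphere: isotropic direction times radius ~ U^(1/3)
        r = source_radius_cm * rng.random(n_events) ** (1.0 / 3.0)
        positions = positions + sample_isotropic(n_events, rng) * r[:, None]

    t0 = np.zeros(n_events)
    if deexcitation_tau_ps > 0:
        t0 = sample_exponential(deexcitation_tau_ps, n_events, rng)

    lifetimes = -taus * np.log1p(-rng.random(n_events))
    prompt_dir = sample_isotropic(n_events, rng)
    annih_dir = sample_isotropic(n_events, rng)

    return pd.DataFrame({
        "event_id": np.arange(id_offset, id_offset + n_events, dtype=np.int64),
        "source_id": source_ids,
        "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2],
        "t0_ps": t0,
        "pdx": prompt_dir[:, 0], "pdy": prompt_dir[:, 1], "pdz": prompt_dir[:, 2],
        "lifetime_ps": lifetimes,
        "annih_t_ps": lifetimes,
        "adx": annih_dir[:, 0], "ady": annih_dir[:, 1], "adz": annih_dir[:, 2],
        "tau_gen_ps": taus,
    })
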
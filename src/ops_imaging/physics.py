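"""Physical constants, materials and closed-form efficiency/attenuation factors.

Unit conventions used throughout the package: lengths in cm, times in ps
(mean lifetimes may be passed in ns at documented API boundaries and are
converted exactly once), energies in keV, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhysicsConstants",
    "CONSTANTS",
    "Material",
    "PhantomModel",
    "MATERIALS",
    "material",
    "f_three_gamma",
    "ops_2g_to_3g_ratio",
    "detection_efficiency",
    "phantom_attenuation",
    "compton_edge",
]


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the positronium-imaging problem.

    c               speed of light [cm/ps]
    tau_vacuum_ns   ortho-positronium mean lifetime in vacuum [ns]
    m_e_c2_kev      electron rest energy [keV]
    tau_pps_ps      para-positronium vacuum mean lifetime [ps] (informational)
    """

    c: float = 0.0299792458
    tau_vacuum_ns: float = 142.0
    m_e_c2_kev: float = 511.0
    tau_pps_ps: float = 125.0

    def __post_init__(self) -> None:
        for name in ("c", "tau_vacuum_ns", "m_e_c2_kev", "tau_pps_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = PhysicsConstants()


@dataclass(frozen=True)
class Material:
    """Scintillator material description.

    mu_511, mu_1160   linear attenuation coefficients at 511/1160 keV [1/cm]
    thickness         radial scintillator thickness d [cm]
    eps_sel_annih     selection efficiency for 511 keV annihilation photons
    eps_sel_prompt    selection efficiency for the 1160 keV prompt photon
    """

    name: str
    mu_511: float
    mu_1160: float
    thickness: float
    eps_sel_annih: float
    eps_sel_prompt: float

    def __post_init__(self) -> None:
        if self.mu_511 <= 0 or self.mu_1160 <= 0:
            raise ValueError("attenuation coefficients must be positive")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        for eps in (self.eps_sel_annih, self.eps_sel_prompt):
            if not 0.0 <= eps <= 1.0:
                raise ValueError("selection efficiencies must lie in [0, 1]")

    def mu(self, energy_kev: float) -> float:
        """Attenuation coefficient for one of the two fixed photon energies."""
        if energy_kev == 511:
            return self.mu_511
        if energy_kev == 1160:
            return self.mu_1160
        raise ValueError("only the 511 and 1160 keV lines are modelled")

    def with_overrides(self, **kwargs) -> "Material":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhantomModel:
    """Water cylinder approximating the patient (radius 10 cm, 200 cm long)."""

    radius: float = 10.0
    mu_water_511: float = 0.096
    mu_water_1160: float = 0.066
    length: float = 200.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("phantom radius and length must be positive")
        if not self.mu_water_511 > self.mu_water_1160 > 0:
            raise ValueError("expected mu_water(511) > mu_water(1160) > 0")

    def mu(self, energy_kev: float) -> float:
        if energy_kev == 511:
            return self.mu_water_511
        if energy_kev == 1160:
            return self.mu_water_1160
        raise ValueError("only the 511 and 1160 keV lines are modelled")

    @property
    def volume_cm3(self) -> float:
        return float(np.pi * self.radius**2 * self.length)


# Attenuation coefficients and selection efficiencies for the two scanner
# technologies; the "water" entry mirrors the phantom medium so that all three
# media are loadable by name from a run config.
MATERIALS: dict[str, Material] = {
    "lyso": Material("lyso", mu_511=0.833, mu_1160=0.413, thickness=1.81,
                     eps_sel_annih=0.34, eps_sel_prompt=0.66),
    "plastic": Material("plastic", mu_511=0.098, mu_1160=0.068, thickness=6.0,
                        eps_sel_annih=0.44, eps_sel_prompt=0.66),
    "water": Material("water", mu_511=0.096, mu_1160=0.066, thickness=20.0,
                      eps_sel_annih=1.0, eps_sel_prompt=1.0),
}


def material(name: str, **overrides) -> Material:
    """Look up a built-in material preset by (case-insensitive) name."""
    try:
        base = MATERIALS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIALS)}"
        ) from None
    return base.with_overrides(**overrides) if overrides else base


def f_three_gamma(tau_tissue_ns, *, tau_vacuum_ns: float = CONSTANTS.tau_vacuum_ns):
    """Fraction of ortho-positronium decays proceeding to 3 photons.

    In a medium with mean lifetime ``tau_tissue`` the intrinsic 3-gamma decay
    rate (1/tau_vacuum) competes with pick-off and conversion; the branching
    fraction to 3 gamma is tau_tissue / tau_vacuum (unity in vacuum).
    """
    tau = np.asarray(tau_tissue_ns, dtype=float)
    if np.any(tau <= 0) or np.any(tau > tau_vacuum_ns):
        raise ValueError(
            f"tau_tissue must lie in (0, {tau_vacuum_ns}] ns"
        )
    out = tau / tau_vacuum_ns
    return out if out.ndim else float(out)


def ops_2g_to_3g_ratio(tau_tissue_ns, *, tau_vacuum_ns: float = CONSTANTS.tau_vacuum_ns):
    """Ratio of 2-gamma (pick-off/conversion) to 3-gamma oPs annihilation rates.

    For tau_tissue = 2 ns this is (1 - 2/142)/(2/142) = 70: in tissue the
    ortho-positronium annihilates to two photons seventy times more often
    than it decays to three.
    """
    f3 = f_three_gamma(tau_tissue_ns, tau_vacuum_ns=tau_vacuum_ns)
    f3 = np.asarray(f3, dtype=float)
    out = (1.0 - f3) / f3
    return out if out.ndim else float(out)


def _check_theta(theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0) or np.any(th >= np.pi):
        raise ValueError("polar angle must lie strictly inside (0, pi)")
    return th


def detection_efficiency(theta, mat: Material, energy_kev: float = 511):
    """Interaction probability 1 - exp(-mu d / sin(theta)) in a cylindrical layer.

    ``theta`` is the polar angle between the photon direction and the scanner
    axis; d/sin(theta) is the slant path through a radial thickness d.
    """
    th = _check_theta(theta)
    out = 1.0 - np.exp(-mat.mu(energy_kev) * mat.thickness / np.sin(th))
    return out if out.ndim else float(out)


def phantom_attenuation(theta, phantom: PhantomModel, energy_kev: float = 511):
    """Survival probability exp(-mu_water R_phantom / sin(theta)) through the body."""
    th = _check_theta(theta)
    out = np.exp(-phantom.mu(energy_kev) * phantom.radius / np.sin(th))
    return out if out.ndim else float(out)


def compton_edge(energy_kev, *, m_e_c2_kev: float = CONSTANTS.m_e_c2_kev):
    """Maximum energy transferable to an electron in a single Compton scattering."""
    e = np.asarray(energy_kev, dtype=float)
    alpha = e / m_e_c2_kev
    out = e * 2 * alpha / (1 + 2 * alpha)
    return out if out.ndim else float(out)
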
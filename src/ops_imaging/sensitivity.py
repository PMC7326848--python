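"""Analytic sensitivity model for 2-gamma and 2-gamma + prompt coincidences.

The scanner is a cylindrical scintillator shell of radius R spanning axial
positions [-AFOV/2, +AFOV/2]; a line source of positronium decays lies on the
axis.  For a decay at axial position z, a photon emitted at polar angle theta
crosses the shell at axial coordinate z + R/tan(theta), so it is accepted when
that coordinate falls inside the scanner.  The relative sensitivity is the
double integral over z and theta of the per-photon interaction probabilities,
phantom survival factors and (optionally) energy-selection efficiencies:

    S = int_0^{AFOV/2} dz [ int (eps_a(th) Att_a(th))^2 sin th dth ]
                        x [ int  eps_p(th) Att_p(th)   sin th dth ]   (triple)

with the pair integral over the back-to-back acceptance and the prompt
integral over the single-photon acceptance.  Only sensitivity *ratios* (gains
relative to a 20-cm-AFOV LYSO scanner in plain 2-gamma mode) are physically
meaningful here; the overall prefactor is arbitrary and cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .physics import Material, PhantomModel, material

__all__ = [
    "ScannerSpec",
    "SensitivityResult",
    "AcceptanceBounds",
    "acceptance_bounds",
    "sensitivity",
    "reference_sensitivity",
    "gain",
    "gain_curve",
    "crossover_afov",
    "projected_counts",
    "DEFAULT_REFERENCE",
]

Mode = Literal["two_gamma", "triple"]
PromptBounds = Literal["single", "mirror"]


@dataclass(frozen=True)
class ScannerSpec:
    """Analytic scanner: cylinder of given inner diameter and axial length."""

    afov: float
    material: Material
    inner_diameter: float = 80.0

    def __post_init__(self) -> None:
        if not 10.0 <= self.afov <= 200.0:
            raise ValueError("supported AFOV range is 10..200 cm")
        if self.inner_diameter <= 0:
            raise ValueError("inner diameter must be positive")

    @property
    def radius(self) -> float:
        return self.inner_diameter / 2.0


@dataclass(frozen=True)
class SensitivityResult:
    afov: float
    mode: Mode
    value: float
    gain: float | None = None


class AcceptanceBounds(NamedTuple):
    """Polar-angle acceptance for a source on the axis at height z.

    theta_min         smallest accepted angle (near end cap)
    theta_max_pair    largest angle for which *both* back-to-back photons hit
    theta_max_single  largest angle for which a single photon hits (far cap)
    """

    theta_min: float
    theta_max_pair: float
    theta_max_single: float


def acceptance_bounds(z: float, scanner: ScannerSpec) -> AcceptanceBounds:
    """Geometric polar-angle bounds for a decay at axial position z >= 0.

    A photon at angle theta reaches the shell (radius R) at axial coordinate
    z + R/tan(theta).  Single-photon acceptance requires |z + R/tan(theta)|
    <= AFOV/2; the back-to-back pair additionally requires the mirrored photon
    (angle pi - theta) to be accepted, which symmetrises the bounds about
    pi/2.  Outside the scanner half-length the bounds collapse to zero
    measure.
    """
    half = scanner.afov / 2.0
    r = scanner.radius
    if z < 0:
        raise ValueError("z must be non-negative (model is mirror symmetric)")
    if z >= half:
        return AcceptanceBounds(np.pi / 2, np.pi / 2, np.pi / 2)
    theta_near = float(np.arctan2(r, half - z))
    theta_far = float(np.arctan2(r, half + z))
    return AcceptanceBounds(theta_near, np.pi - theta_near, np.pi - theta_far)


def _pair_integrand(theta: float, mat: Material, phantom: PhantomModel) -> float:
    s = np.sin(theta)
    eff = 1.0 - np.exp(-mat.mu_511 * mat.thickness / s)
    att = np.exp(-phantom.mu_water_511 * phantom.radius / s)
    return (eff * att) ** 2 * s


def _prompt_integrand(theta: float, mat: Material, phantom: PhantomModel) -> float:
    s = np.sin(theta)
    eff = 1.0 - np.exp(-mat.mu_1160 * mat.thickness / s)
    att = np.exp(-phantom.mu_water_1160 * phantom.radius / s)
    return eff * att * s


def sensitivity(
    scanner: ScannerSpec,
    phantom: PhantomModel | None = None,
    mode: Mode = "triple",
    *,
    include_selection: bool = True,
    prompt_bounds: PromptBounds = "single",
    rtol: float = 1e-8,
) -> SensitivityResult:
    """Evaluate the sensitivity integral for one scanner configuration.

    ``prompt_bounds`` selects the polar acceptance used for the prompt photon:
    "single" integrates it over the full single-photon acceptance (the
    literal reading of the model, used for the headline gains), "mirror"
    restricts it to the same symmetric bounds as the annihilation pair (the
    convention consistent with the quoted gain-curve crossover points); see
    docs/methods.md for the numerical consequences of the choice.
    """
    phantom = phantom or PhantomModel()
    mat = scanner.material

    def inner(z: float) -> float:
        b = acceptance_bounds(z, scanner)
        if b.theta_max_pair <= b.theta_min:
            return 0.0
        pair, _ = quad(_pair_integrand, b.theta_min, b.theta_max_pair,
                       args=(mat, phantom), epsrel=rtol)
        if mode == "two_gamma":
            return pair
        hi = b.theta_max_single if prompt_bounds == "single" else b.theta_max_pair
        prompt, _ = quad(_prompt_integrand, b.theta_min, hi,
                         args=(mat, phantom), epsrel=rtol)
        return pair * prompt

    value, err = quad(inner, 0.0, scanner.afov / 2.0, epsrel=rtol, limit=200)
    if value > 0 and err > 1e-3 * value:
        raise RuntimeError(
            f"sensitivity quadrature did not converge: value={value}, err={err}"
        )
    if include_selection:
        value *= mat.eps_sel_annih**2
        if mode == "triple":
            value *= mat.eps_sel_prompt
    return SensitivityResult(afov=scanner.afov, mode=mode, value=float(value))


# Standard 2-gamma imaging with a 20-cm LYSO scanner: the gain normalisation.
DEFAULT_REFERENCE = ScannerSpec(afov=20.0, material=material("lyso"))


def reference_sensitivity(
    phantom: PhantomModel | None = None,
    *,
    include_selection: bool = True,
    reference: ScannerSpec = DEFAULT_REFERENCE,
) -> float:
    return sensitivity(reference, phantom, "two_gamma",
                       include_selection=include_selection).value


def gain(
    scanner: ScannerSpec,
    phantom: PhantomModel | None = None,
    mode: Mode = "triple",
    *,
    include_selection: bool = True,
    prompt_bounds: PromptBounds = "single",
) -> SensitivityResult:
    """Sensitivity relative to 2-gamma imaging with a 20-cm-AFOV LYSO scanner."""
    res = sensitivity(scanner, phantom, mode, include_selection=include_selection,
                      prompt_bounds=prompt_bounds)
    ref = reference_sensitivity(phantom, include_selection=include_selection)
    return SensitivityResult(res.afov, res.mode, res.value, gain=res.value / ref)


def gain_curve(
    mat: Material,
    mode: Mode,
    afovs: Iterable[float],
    phantom: PhantomModel | None = None,
    *,
    include_selection: bool = True,
    prompt_bounds: PromptBounds = "single",
) -> pd.DataFrame:
    """Gain as a function of AFOV; columns afov_cm, value, gain."""
    phantom = phantom or PhantomModel()
    ref = reference_sensitivity(phantom, include_selection=include_selection)
    rows = []
    for afov in afovs:
        res = sensitivity(ScannerSpec(afov=afov, material=mat), phantom, mode,
                          include_selection=include_selection,
                          prompt_bounds=prompt_bounds)
        rows.append((afov, res.value, res.value / ref))
    return pd.DataFrame(rows, columns=["afov_cm", "value", "gain"])


def crossover_afov(
    mat: Material,
    phantom: PhantomModel | None = None,
    mode: Mode = "triple",
    *,
    include_selection: bool = True,
    prompt_bounds: PromptBounds = "single",
    bracket: tuple[float, float] = (11.0, 199.0),
    xtol: float = 0.1,
) -> float:
    """AFOV at which the gain curve crosses unity (sensitivity parity with the
    20-cm LYSO 2-gamma reference), found by root bisection to ``xtol`` cm."""
    phantom = phantom or PhantomModel()
    ref = reference_sensitivity(phantom, include_selection=include_selection)

    def f(afov: float) -> float:
        return sensitivity(ScannerSpec(afov=afov, material=mat), phantom, mode,
                           include_selection=include_selection,
                           prompt_bounds=prompt_bounds).value / ref - 1.0

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"gain-1 does not change sign on [{lo}, {hi}] "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g})"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def projected_counts(
    activity_bq: float,
    scan_time_s: float,
    efficiency: float,
    ops_fraction: float,
    phantom: PhantomModel | None = None,
) -> tuple[float, float]:
    """Projected number of image-forming triple coincidences and their density.

    total  = activity x scan time x detection/selection efficiency x
             ortho-positronium formation fraction
    per cm^3 divides by the phantom volume (pi R^2 L).
    """
    for name, v in [("activity_bq", activity_bq), ("scan_time_s", scan_time_s),
                    ("efficiency", efficiency), ("ops_fraction", ops_fraction)]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    phantom = phantom or PhantomModel()
    total = activity_bq * scan_time_s * efficiency * ops_fraction
    return float(total), float(total / phantom.volume_cm3)
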
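"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from ops_imaging.physics import PhantomModel, detection_efficiency, phantom_attenuation
from ops_imaging.sensitivity import ScannerSpec


def mc_sensitivity(afov, mat, mode, n_rays, rng, prompt_bounds="single"):
    """Brute-force ray-sampling estimator of the sensitivity integral.

    Samples axial decay positions uniformly on [0, AFOV/2] and isotropic
    directions; each ray carries the analytic interaction and phantom
    survival weight if it falls inside the acceptance.  Independent of the
    quadrature code path.  Returns (estimate, standard error).
    """
    phantom = PhantomModel()
    scanner = ScannerSpec(afov=afov, material=mat)
    half = afov / 2.0
    z = rng.uniform(0.0, half, n_rays)
    cos_t = rng.uniform(-1.0, 1.0, n_rays)
    theta = np.arccos(cos_t)

    b_near = np.arctan2(scanner.radius, half - z)
    b_far = np.arctan2(scanner.radius, half + z)
    in_pair = (theta >= b_near) & (theta <= np.pi - b_near)
    th = np.clip(theta, 1e-6, np.pi - 1e-6)
    w_pair = np.where(
        in_pair,
        (detection_efficiency(th, mat, 511)
         * phantom_attenuation(th, phantom, 511)) ** 2,
        0.0,
    )
    if mode == "two_gamma":
        w = w_pair
        # E[w] * 2 (direction measure) * half (z measure)
        scale = 2.0 * half
    else:
        cos_p = rng.uniform(-1.0, 1.0, n_rays)
        theta_p = np.arccos(cos_p)
        hi = np.pi - (b_far if prompt_bounds == "single" else b_near)
        in_p = (theta_p >= b_near) & (theta_p <= hi)
        th_p = np.clip(theta_p, 1e-6, np.pi - 1e-6)
        w_p = np.where(
            in_p,
            detection_efficiency(th_p, mat, 1160)
            * phantom_attenuation(th_p, phantom, 1160),
            0.0,
        )
        w = w_pair * w_p
        scale = 4.0 * half
    est = w.mean() * scale
    se = w.std(ddof=1) / np.sqrt(n_rays) * scale
    return est, se
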
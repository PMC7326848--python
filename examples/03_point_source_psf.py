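"""Point-spread function of the direct and TOF-FBP images vs timing resolution.

A point source at (20, 0, 75) cm is imaged through the full chain.  The
'direct' image is a plain histogram of per-event TOF-reconstructed
annihilation points (usable without tomographic reconstruction once CRT
reaches tens of ps); the TOF-FBP image applies list-mode Gaussian
backprojection with deconvolution.  Radial/axial FWHM are extracted from
Gaussian fits to profiles of the peak.
"""

import numpy as np

from ops_imaging.detector import DetectorResponseConfig, simulate_triples, smear_triples
from ops_imaging.generator import SourceSpec, generate_events
from ops_imaging.reconstruct import (
    ImageGrid, direct_image, estimate_psf, reconstruct_records, tof_fbp,
)

POS = (20.0, 0.0, 75.0)
rng = np.random.default_rng(3)
events = generate_events([SourceSpec(6, POS, 3.0)], 2_000_000, rng)
raw, _ = simulate_triples(events, rng=rng, smear=False)
print(f"{len(raw)} registered triples from {len(events)} decays\n")

grid_d = ImageGrid.centered(POS, (8.5, 12.0, 8.5), (0.5, 0.5, 0.5))
grid_f = ImageGrid.centered(POS, (3.0, 3.0, 3.0), (0.18, 0.18, 0.29))
print("CRT [ps]   direct radial/axial [mm]   TOF-FBP radial/axial [mm]")
for crt in (10.0, 50.0, 140.0, 500.0):
    cfg = DetectorResponseConfig(crt_ps=crt)
    rec = reconstruct_records(smear_triples(raw, cfg, rng))
    p_d = estimate_psf(direct_image(rec, grid_d), POS, window_cm=16.0)
    p_f = estimate_psf(tof_fbp(smear_triples(raw, cfg, rng), grid_f, crt),
                       POS, window_cm=6.0)
    print(f"{crt:7.0f}    {p_d.radial_fwhm_mm:5.1f} / {p_d.axial_fwhm_mm:4.1f}"
          f"              {p_f.radial_fwhm_mm:5.1f} / {p_f.axial_fwhm_mm:4.1f}")

print("\nThe direct image degrades radially as CRT grows (the TOF localisation")
print("error is c*dt/2 along the line of response), while TOF-FBP stays near")
print("the detector-limited resolution; at CRT = 50 ps the two are comparable.")
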
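"""Mean ortho-positronium lifetime imaging of the six-source arrangement.

Runs the full chain (generate -> detect -> reconstruct) for the six point
sources with tissue-like mean lifetimes of 2.0-3.0 ns, forms the per-voxel
mean-lifetime image and compares reconstructed with generated lifetimes
around each source peak.
"""

import numpy as np

from ops_imaging.detector import DetectorResponseConfig, simulate_triples, smear_triples
from ops_imaging.generator import generate_events, nema_sources
from ops_imaging.lifetime import compare_generated_vs_reconstructed, effective_time_sigma
from ops_imaging.reconstruct import reconstruct_records

rng = np.random.default_rng(4)
events = generate_events(nema_sources(), 3_000_000, rng)
raw, counters = simulate_triples(events, rng=rng, smear=False)
print(f"{counters.selected} registered triples from {counters.generated} decays")

for crt in (50.0, 500.0):
    cfg = DetectorResponseConfig(crt_ps=crt)
    rec = reconstruct_records(smear_triples(raw, cfg, rng))
    sigma = effective_time_sigma(rec)
    table = compare_generated_vs_reconstructed(rec, nema_sources(),
                                               neighborhood_cm=1.5)
    print(f"\nCRT = {crt:.0f} ps (chain timing resolution {sigma:.0f} ps):")
    cols = ["source_id", "tau_gen_ps", "tau_rec_ps", "bias_ps", "bias_se_ps", "n"]
    print(table[cols].to_string(index=False,
                                float_format=lambda v: f"{v:8.1f}"))

print("\n'bias_ps' compares the reconstructed mean lifetime with the generated")
print("image of the same events: it isolates the reconstruction-chain error,")
print("which stays at the few-ps level even at CRT = 500 ps because the")
print("timing noise is symmetric and far smaller than the ns-scale lifetimes.")
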
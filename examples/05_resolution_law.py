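"""Mean-lifetime resolution versus per-voxel statistics.

The statistical error of the per-voxel mean-lifetime estimate follows
sqrt(tau^2 + sigma_eff^2) / sqrt(N) ~ tau / sqrt(N), because the chain's
timing noise sigma_eff (tens of ps) is negligible against the ns-scale
ortho-positronium lifetime.  With the ~10^4 events per cm^3 expected from a
20-min total-body scan, the mean lifetime is resolved to about 20 ps RMS.
"""

from ops_imaging.lifetime import lifetime_resolution_study

for sigma_eff, label in ((0.0, "statistics only"),
                         (190.0, "CRT = 500 ps chain noise")):
    table = lifetime_resolution_study(2.0, sigma_eff,
                                      [100, 1_000, 10_000, 40_000],
                                      reps=400, seed=5)
    print(f"tau = 2 ns, sigma_eff = {sigma_eff:.0f} ps ({label}):")
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:8.2f}"))
    print()

print("Quadrupling the statistics halves the RMS; the sigma_eff=0 and")
print("sigma_eff=190 ps columns are nearly identical, which is why the")
print("achievable lifetime resolution is CRT-independent in this regime.")
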
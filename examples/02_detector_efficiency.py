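"""Registration efficiency of the plastic total-body scanner vs energy threshold.

Simulates decays uniformly along a 200-cm axial line source, transports the
two 511 keV photons and the 1160 keV prompt through the 6-cm plastic shell,
and tabulates the fraction of events registered as the energy threshold is
raised.  The 'triple' column applies the imaging selection: both annihilation
deposits above the threshold and the prompt deposit above 400 keV.
"""

from ops_imaging.detector import efficiency_curves

curves = efficiency_curves(
    thresholds_kev=[0, 50, 100, 150, 200, 250, 300],
    n_events=300_000,
    seed=1,
)
print(curves.to_string(index=False,
                       formatters={c: "{:.4f}".format
                                   for c in ("prompt", "pair", "triple")}))
sel = curves.loc[curves["threshold_kev"] == 200, "triple"].iloc[0]
print(f"\nAt the working point (200 keV pair / 400 keV prompt) about "
      f"{100 * sel:.2f}% of all decays yield an image-forming triple "
      f"coincidence; scaled to a 370 MBq 20-min scan this is what makes "
      f"whole-body positronium imaging statistically feasible.")
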
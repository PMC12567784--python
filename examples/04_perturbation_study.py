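"""Twofold amplification / halving of the alveolar-interstitium transfer rate.

Re-simulates the calibration scenario with K_alv_inter scaled by 0.5 and 2
and prints the fold change of the alveolar and lung observables relative to
baseline: faster transfer empties the alveolar surface into the lung
interstitium.
"""
import nanopbtk as npk

params = npk.default_parameters()
preset = npk.kreyling_preset()
study = npk.perturbation_study(params, preset.scenario, "K_alv_inter",
                               factors=(0.5, 2.0),
                               outputs=("alveolar", "lung"), t_end=674.0)

print("fold change vs baseline (alveolar | lung):")
for t in (24.0, 168.0, 674.0):
    row = [f"x{f:g}: {study.fold_change[f]['alveolar'].loc[t]:6.2f} | "
           f"{study.fold_change[f]['lung'].loc[t]:5.2f}"
           for f in (0.5, 2.0)]
    print(f"  t = {t:5.0f} h   " + "    ".join(row))
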
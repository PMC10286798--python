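"""Couple the published efficiency model to the growth ODEs.

For every label-resolvable LED treatment, predicts c_ε from the spectrum's
irradiance fractions with the packaged quartic model, simulates the
treatment to harvest, and compares the dry-mass error against the
constant-efficiency baseline (c_ε = 17.0×10⁻⁶ g/J).
"""

import spectragrow as sg

table = sg.coupled_prediction_table()
cols = ["treatment", "label", "observed_g_m2", "predicted_g_m2",
        "baseline_g_m2", "rel_error_model", "rel_error_baseline"]
print(table[cols].round(3).to_string(index=False))
print()
print(f"mean |relative error|: spectrum-aware {table['rel_error_model'].mean():.2f} "
      f"vs constant baseline {table['rel_error_baseline'].mean():.2f}")
print("The constant coefficient overshoots every treatment; scaling the")
print("efficiency with the spectral composition brings most predictions")
print("within tens of percent of the observed harvest mass.")
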
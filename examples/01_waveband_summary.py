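"""Integrate an LED spectrum into waveband photon fluxes and fraction ratios.

Builds the spectrum of the B20G20R120FR20 treatment (20 µmol m⁻² s⁻¹ of
blue, green and far-red light plus 120 of red), integrates it over the four
wavebands and prints the photon-flux and irradiance fraction ratios — the
features the quantum-use-efficiency regression consumes.
"""

import spectragrow as sg

label = sg.parse_treatment_label("B20G20R120FR20")
spectrum = sg.synth_led_spectrum(label.band_pfds)
bands = sg.integrate_bands(spectrum)

print(bands.to_frame().round(3).to_string(index=False))
print()
print("PFD fractions (B/G/R/FR):       ",
      [round(float(f), 3) for f in bands.pfd_fractions])
print("irradiance fractions (B/G/R/FR):",
      [round(float(f), 3) for f in bands.irradiance_fractions])
print()
print("Red photons carry less energy than blue, so red's irradiance share")
print(f"({100 * bands.irradiance_fractions[2]:.1f}%) sits below its photon share "
      f"({100 * bands.pfd_fractions[2]:.1f}%).")
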
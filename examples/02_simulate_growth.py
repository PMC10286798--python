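"""Simulate lettuce dry-mass accumulation under a 20-hour photoperiod.

Integrates the two-state growth ODEs for ten days under constant light
(35 W m⁻² of 400-750 nm irradiance during the photoperiod), 22 °C and
410 ppm CO₂, and prints the daily trajectory of structural, non-structural
and total dry mass.
"""

import spectragrow as sg

segments = []
for day in range(10):
    segments.append({"t_start_h": 24 * day, "t_end_h": 24 * day + 20,
                     "T_C": 22.0, "CO2_ppm": 410.0, "I_W_m2": 35.0})
    segments.append({"t_start_h": 24 * day + 20, "t_end_h": 24 * (day + 1),
                     "T_C": 20.0, "CO2_ppm": 410.0, "I_W_m2": 0.0})
env = sg.EnvironmentSchedule.from_segments(segments)

seedling = sg.PlantState(x_nsdm=0.005, x_sdm=0.045)  # 0.05 g/m2 transplant
traj = sg.simulate(seedling, env, c_eps=1.3e-5)

frame = traj.to_frame()
daily = frame[frame["time_h"] % 24 == 0]
print(daily.round(4).to_string(index=False))
print()
print(f"Final dry mass after 10 d: {traj.total[-1]:.3f} g/m2 "
      f"(structural share {traj.x_sdm[-1] / traj.total[-1]:.0%}).")
print("Mass dips during each 4-h dark period (maintenance respiration)")
print("and compounds during the photoperiod.")
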
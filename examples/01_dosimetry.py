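"""UV-B dosimetry: cumulative doses, biological weighting, photon ratios.

Reproduces the dose arithmetic of a six-treatment UV-B supplementation
experiment (6 or 12 h/day for 1-3 days at ~1 W m^-2 effective irradiance).
"""

from uvcanopy import dosimetry as dm

# the printed dose table implies the effective plant-level irradiance
e_eff = dm.effective_irradiance_from_dose(21.6, dm.ExposureSchedule(6, 1))
print(f"effective UV-B irradiance: {e_eff:.2f} W m^-2")

print("\ntreatment grid (unweighted and biologically effective doses):")
be = dm.calibrate_be_factor(21.6, 2.1)  # from the printed dose pair
for sched in dm.treatment_grid():
    dose = dm.cumulative_dose(e_eff, sched)
    print(f"  {sched.label:>9}: {dose:6.1f} kJ m^-2  (BE {be * dose:5.2f} kJ m^-2)")

# spectrum-based weighting with the generalized plant action spectrum
lamp = dm.gaussian_led_spectrum(peak_nm=310.0, fwhm_nm=10.0, total_irradiance_W_m2=e_eff)
print(f"\nbe factor from the 310 nm LED spectrum: {dm.be_factor(lamp):.3f}")
print(f"calibrated be factor from printed doses: {be:.4f}")

ratio = dm.photon_flux(e_eff, 310.0) / 200.0 * 100.0
print(f"\nUV-B : PAR photon ratio at 200 umol PAR: {ratio:.2f} %")
print(f"PAR daily light integral (16 h photoperiod): "
      f"{dm.daily_light_integral(200.0, 16.0):.2f} mol m^-2 d^-1")
# The BE doses scale the physical dose by the action-spectrum weighting of
# the lamp spectrum; the photon ratio shows how small the UV-B photon flux
# is next to the growth lighting.
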
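"""Partition a clear-sky day's evapotranspiration into canopy and soil.

Generates synthetic half-hourly forcing for the high-altitude maize
site on June 23 (day 174), runs the dual-source dual-leaf model, and
prints the midday fluxes plus daily totals in mm of water.
"""

from canopyflux import RunConfig, simulate_clearsky_day

config = RunConfig()
results = simulate_clearsky_day(config, day_of_year=174, lai=3.0, h_c=2.0)

noon = results.iloc[(results["solar_time"] - 12.0).abs().idxmin()]
print("--- midday half-hour ---")
print(f"latent heat flux      lambda_ET = {noon['lambda_et']:7.1f} W m-2")
print(f"canopy transpiration  lambda_Tc = {noon['lambda_tc']:7.1f} W m-2")
print(f"soil evaporation      lambda_Es = {noon['lambda_es']:7.1f} W m-2")
print(f"canopy conductance    G_sc      = {noon['gsc_dualleaf']:7.2f} mm s-1")

# half-hourly W m-2 -> mm of water per half hour (lambda ~ 2.45 MJ kg-1)
to_mm = 1800.0 / 2.45e6
day = results[results["sun_up"]]
et_mm = (day["lambda_et"] * to_mm).sum()
es_mm = (day["lambda_es"] * to_mm).sum()
print("\n--- daytime totals ---")
print(f"evapotranspiration {et_mm:5.2f} mm, of which soil evaporation {es_mm:4.2f} mm "
      f"({100 * es_mm / et_mm:.0f}%)")
print("A mid-season irrigated maize canopy transpires most of the water; the "
      "partly mulched, partly shaded soil contributes the small remainder.")
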
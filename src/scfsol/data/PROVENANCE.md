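# Provenance of `sumatriptan_sc_co2.csv`

Gravimetric equilibrium solubility of sumatriptan (C14H21N3O2S, Mw = 295.40
g/mol) in supercritical CO2 (Mw = 44.01 g/mol), 28 points on a 4-temperature
x 7-pressure grid. Each point is the mean of three replicate runs; the
source reports relative standard deviations consistently below 5%.

Transcription notes:

- Temperatures are stored as 308.2 / 318.2 / 328.2 / 338.2 K, the values the
  source text and abstract use throughout; the table header prints 308.0 etc.
  The 0.2 K difference is negligible for every fit in this package.
- The mole-fraction column is stored unscaled (the source prints y x 1e4);
  the standard-deviation column likewise (printed x 1e6).
- The 338.2 K row printed with a run-together pressure/density field
  ("300809.68") is transcribed as P = 30 MPa, rho = 809.68 kg/m3, consistent
  with the 7-pressure grid (12, 15, 18, 21, 24, 27, 30 MPa).
- The 308.2 K / 18 MPa density is printed identically to the 15 MPa value
  (816.10), which is physically impossible on an isotherm. It is transcribed
  as 846.10 kg/m3, a single-digit correction consistent with CO2 PVT
  behaviour at that state (~848 kg/m3).
- The g/L solubility column is informational only and is never used as a
  fit input. It agrees with rho*Mw_drug*y/(Mw_CO2*(1-y)) applied to the
  printed (rounded) y to within 8% at 15-30 MPa but is systematically
  inconsistent on the low-pressure rows: 318.2/12 (12.2%), 328.2/12
  (16.4%), 338.2/12 (10.9%), 338.2/15 (9.5%). On those rows the printed
  g/L implies a smaller y than the printed mole-fraction column (e.g.
  328.2 K / 12 MPa: 0.0190 g/L implies y = 0.056e-4, printed 0.065e-4).
  The mole-fraction column is kept as printed and is the only fit input.
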
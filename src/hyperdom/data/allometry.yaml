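# Default allometric coefficients, transcribed from the published sources
# they are conventionally taken from.  Units contract: D in cm, rho in
# g cm^-3, H in m, AGB output in kg.
#
# dicot: moist-forest model  AGB = coef * rho * D^2 * H
# height: per-region Weibull  H = a * (1 - exp(-b * D^c))
#         (NW and SW share the Western Amazonia fit)
# palm (Arecaceae/Strelitziaceae): ln(AGB) = ln_intercept + ln_slope * ln(D)
version: 1
dicot_coef: 0.0509
height:
  GS: {a: 42.845, b: 0.0433, c: 0.9372}
  BS: {a: 42.574, b: 0.0482, c: 0.8307}
  EC: {a: 48.131, b: 0.0375, c: 0.8228}
  NW: {a: 46.263, b: 0.0876, c: 0.6072}
  SW: {a: 46.263, b: 0.0876, c: 0.6072}
palm:
  ln_intercept: -3.3488
  ln_slope: 2.7483
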
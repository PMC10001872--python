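# Population exposure parameters for Nepalese rice consumers.
#
# ASSUMPTIONS, not survey values: per-group rice intake rates (ir, kg/day)
# and body weights (bw, kg) for Nepal are not published alongside the
# concentration survey, so these defaults are plausible values chosen to
# reproduce the national intake-to-bodyweight ratio implied by reported
# per-capita rice consumption (~0.32 kg/day over ~62 kg adult body weight,
# i.e. E[IR]*E[1/BW] ~ 5.3e-3 kg/kg/day). Group orderings follow the
# qualitative gradients reported for provinces (Madhesh highest intake),
# regions (Terai > Rural > Mountain > Urban > Hill) and vulnerable groups
# (preschoolers > toddlers > children > women). Replace with measured
# dietary-survey distributions for any real assessment.
#
# ef: exposure frequency (days/year); ed: exposure duration (years);
# averaging time defaults to ed*365 days, so ef*ed/at = 1.
groups:
  national:
    ir: {family: lognormal, mean: 0.32, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
    ef: 365
    ed: 30
  Province 1:
    ir: {family: lognormal, mean: 0.34, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Madhesh:
    ir: {family: lognormal, mean: 0.40, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Bagmati:
    ir: {family: lognormal, mean: 0.32, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Gandaki:
    ir: {family: lognormal, mean: 0.31, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Lumbini:
    ir: {family: lognormal, mean: 0.37, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Karnali:
    ir: {family: lognormal, mean: 0.33, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Sudurpashchim:
    ir: {family: lognormal, mean: 0.29, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Terai:
    ir: {family: lognormal, mean: 0.40, cv: 0.20}
    bw: {family: lognormal, mean: 61, cv: 0.15}
  Rural:
    ir: {family: lognormal, mean: 0.37, cv: 0.20}
    bw: {family: lognormal, mean: 61, cv: 0.15}
  Mountain:
    ir: {family: lognormal, mean: 0.35, cv: 0.20}
    bw: {family: lognormal, mean: 61, cv: 0.15}
  Urban:
    ir: {family: lognormal, mean: 0.33, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  Hill:
    ir: {family: lognormal, mean: 0.31, cv: 0.20}
    bw: {family: lognormal, mean: 62, cv: 0.15}
  toddlers:
    ir: {family: lognormal, mean: 0.146, cv: 0.25}
    bw: {family: lognormal, mean: 11.5, cv: 0.15}
    ed: 3
  preschoolers:
    ir: {family: lognormal, mean: 0.235, cv: 0.25}
    bw: {family: lognormal, mean: 16, cv: 0.15}
    ed: 4
  children:
    ir: {family: lognormal, mean: 0.246, cv: 0.25}
    bw: {family: lognormal, mean: 28, cv: 0.15}
    ed: 7
  women:
    ir: {family: lognormal, mean: 0.348, cv: 0.20}
    bw: {family: lognormal, mean: 54, cv: 0.15}
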
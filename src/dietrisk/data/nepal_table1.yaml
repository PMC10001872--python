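# Summary targets for the synthetic concentration generator: per-province
# geometric mean (gm), arithmetic SD (sd) and observed range of Cd, As, Pb
# and Cu in commercial white rice from the 2019 Nepal market survey
# (n = 170 across seven provinces), all in ug/kg dry weight.
# The "national" block is the pooled all-Nepal row; it drives the fitted
# concentration model used for exposure simulation.
stratum_key: province
seed: 0
strata:
  Province 1:
    n: 49
    Cd: {gm: 15.4, sd: 21.9, min: 1.76, max: 95.4}
    As: {gm: 36.6, sd: 18.8, min: 6.43, max: 92.3}
    Pb: {gm: 15.7, sd: 17.3, min: 5.49, max: 121.4}
    Cu: {gm: 1078, sd: 1920, min: 264, max: 10059}
  Madhesh:
    n: 20
    Cd: {gm: 17.5, sd: 13.5, min: 6.80, max: 46.4}
    As: {gm: 47.9, sd: 28.5, min: 17.0, max: 121}
    Pb: {gm: 17.3, sd: 10.3, min: 5.72, max: 36.9}
    Cu: {gm: 1364, sd: 1601, min: 453, max: 6559}
  Bagmati:
    n: 27
    Cd: {gm: 14.9, sd: 11.5, min: 2.68, max: 55.9}
    As: {gm: 46.4, sd: 14.8, min: 25.3, max: 81.7}
    Pb: {gm: 13.5, sd: 9.21, min: 5.91, max: 43.0}
    Cu: {gm: 1000, sd: 251, min: 519, max: 1556}
  Gandaki:
    n: 13
    Cd: {gm: 9.93, sd: 6.71, min: 1.31, max: 23.5}
    As: {gm: 47.2, sd: 15.8, min: 32.1, max: 85.6}
    Pb: {gm: 19.7, sd: 25.5, min: 7.94, max: 87.4}
    Cu: {gm: 1100, sd: 398, min: 491, max: 1959}
  Lumbini:
    n: 35
    Cd: {gm: 17.2, sd: 14.8, min: 1.73, max: 68.6}
    As: {gm: 49.2, sd: 18.1, min: 23.1, max: 85.8}
    Pb: {gm: 18.4, sd: 10.2, min: 6.02, max: 51.3}
    Cu: {gm: 949, sd: 358, min: 271, max: 2016}
  Karnali:
    n: 10
    Cd: {gm: 15.7, sd: 12.5, min: 3.86, max: 45.4}
    As: {gm: 54.4, sd: 20.3, min: 23.5, max: 83.3}
    Pb: {gm: 15.6, sd: 8.97, min: 6.94, max: 35.1}
    Cu: {gm: 1072, sd: 194, min: 823, max: 1383}
  Sudurpashchim:
    n: 16
    Cd: {gm: 17.0, sd: 12.5, min: 4.26, max: 51.9}
    As: {gm: 35.1, sd: 13.9, min: 17.3, max: 60.2}
    Pb: {gm: 12.9, sd: 5.94, min: 7.98, max: 26.8}
    Cu: {gm: 1051, sd: 316, min: 550, max: 1624}
national:
  n: 170
  Cd: {gm: 15.5, sd: 16.0, min: 1.31, max: 95.4}
  As: {gm: 43.4, sd: 19.6, min: 6.43, max: 121}
  Pb: {gm: 16.0, sd: 14.0, min: 5.49, max: 121.4}
  Cu: {gm: 1066, sd: 1210, min: 264, max: 10059}
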
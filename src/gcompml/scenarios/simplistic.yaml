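# Declarative simulation scenario for gcompml (load with gcompml.load_scenario).
# Coefficient values are synthetic illustrative calibrations, not values from
# any external study; edit freely and reload.
name: simplistic
covariates:
- name: X1
  family: normal
  intercept: 0.0
  sd: 1.0
  depends: {}
- name: X2
  family: normal
  intercept: 0.0
  sd: 1.0
  depends: {}
- name: X3
  family: normal
  intercept: 0.0
  sd: 1.0
  depends: {}
- name: X4
  family: normal
  intercept: 0.0
  sd: 1.0
  depends: {}
- name: X5
  family: normal
  intercept: 0.0
  sd: 1.0
  depends: {}
- name: X6
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends: {}
- name: X7
  family: bernoulli
  intercept: -0.847
  sd: 1.0
  depends: {}
- name: X8
  family: bernoulli
  intercept: -0.405
  sd: 1.0
  depends: {}
- name: X9
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends: {}
exposure_model:
  intercept: -0.4
  coefs:
    X1: 0.4
    X2: 0.3
    X3: -0.4
    X4: 0.3
    X6: 0.5
    X9: -0.3
outcome_model:
  intercept: -0.9
  exposure_coef: 0.7
  terms:
  - covariate: X1
    kind: linear
    coef: 0.35
    center: 0.0
    threshold: 0.0
  - covariate: X2
    kind: linear
    coef: -0.4
    center: 0.0
    threshold: 0.0
  - covariate: X3
    kind: linear
    coef: 0.45
    center: 0.0
    threshold: 0.0
  - covariate: X5
    kind: linear
    coef: 0.4
    center: 0.0
    threshold: 0.0
  - covariate: X6
    kind: linear
    coef: -0.5
    center: 0.0
    threshold: 0.0
  - covariate: X7
    kind: linear
    coef: 0.6
    center: 0.0
    threshold: 0.0
  interactions: []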
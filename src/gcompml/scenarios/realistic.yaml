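# Declarative simulation scenario for gcompml (load with gcompml.load_scenario).
# Coefficient values are synthetic illustrative calibrations, not values from
# any external study; edit freely and reload.
name: realistic
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
  depends:
    X1: 0.4
- name: X3
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X1: 0.5
    X2: -0.3
- name: X4
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X3: 0.6
- name: X5
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X2: 0.3
    X4: 0.3
- name: X6
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X5: 0.4
- name: X7
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X1: -0.3
    X6: 0.5
- name: X8
  family: bernoulli
  intercept: -0.4
  sd: 1.0
  depends:
    X7: 0.4
- name: X9
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X8: 0.5
- name: X10
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X2: 0.4
- name: X11
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X10: 0.5
- name: X12
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X11: 0.3
    X3: 0.4
- name: X13
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X12: -0.4
- name: X14
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X13: 0.5
- name: X15
  family: bernoulli
  intercept: -0.6
  sd: 1.0
  depends:
    X14: 0.3
- name: X16
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X15: 0.4
    X1: 0.2
- name: X17
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X16: -0.3
- name: X18
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X17: 0.5
- name: X19
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X18: 0.3
- name: X20
  family: normal
  intercept: 0.0
  sd: 1.0
  depends:
    X19: 0.4
    X5: 0.2
- name: X21
  family: bernoulli
  intercept: 0.3
  sd: 1.0
  depends:
    X20: -0.3
- name: X22
  family: bernoulli
  intercept: 0.0
  sd: 1.0
  depends:
    X21: 0.4
exposure_model:
  intercept: -0.5
  coefs:
    X1: 0.3
    X2: -0.35
    X4: 0.4
    X6: 0.4
    X8: -0.3
    X11: 0.3
    X14: 0.25
    X17: 0.3
outcome_model:
  intercept: -1.0
  exposure_coef: 0.65
  terms:
  - covariate: X2
    kind: linear
    coef: 0.4
    center: 0.0
    threshold: 0.0
  - covariate: X5
    kind: linear
    coef: -0.35
    center: 0.0
    threshold: 0.0
  - covariate: X8
    kind: linear
    coef: 0.5
    center: 0.0
    threshold: 0.0
  - covariate: X11
    kind: linear
    coef: 0.3
    center: 0.0
    threshold: 0.0
  - covariate: X1
    kind: quadratic
    coef: 0.25
    center: 0.0
    threshold: 0.0
  - covariate: X7
    kind: quadratic
    coef: -0.2
    center: 0.0
    threshold: 0.0
  - covariate: X14
    kind: quadratic
    coef: 0.3
    center: 0.0
    threshold: 0.0
  - covariate: X4
    kind: step
    coef: 0.6
    center: 0.0
    threshold: 0.0
  - covariate: X12
    kind: step
    coef: -0.5
    center: 0.0
    threshold: 0.0
  interactions:
  - covariate: X5
    coef: 0.4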
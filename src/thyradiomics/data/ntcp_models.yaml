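# External NTCP model registry for radiation-induced hypothyroidism.
#
# Coefficient values below are ILLUSTRATIVE defaults in the published
# functional forms; verify each against its cited source (DOI given)
# before drawing any clinical conclusion.  The package tests exercise the
# forms, never these literature values.
#
# Covariates: D_mean = mean thyroid dose (Gy), V_thyroid = thyroid volume (mL).
models:
  ronjom2013:
    form: mixture
    citation: "doi:10.1016/j.radonc.2013.08.029"
    components:
      - weight: 0.6
        intercept: -5.0
        coefficients: {D_mean: 0.12, V_thyroid: -0.12}
      - weight: 0.4
        intercept: -2.0
        coefficients: {D_mean: 0.05, V_thyroid: -0.06}
  boomsma2012:
    form: logistic
    citation: "doi:10.1016/j.ijrobp.2012.03.034"
    intercept: -2.4
    coefficients: {D_mean: 0.064, V_thyroid: -0.093}
  cella2012:
    form: logistic
    citation: "doi:10.1016/j.ijrobp.2011.11.064"
    intercept: -1.2
    coefficients: {D_mean: 0.06}
  vogelius2011:
    form: lkb
    citation: "doi:10.1016/j.ijrobp.2010.07.1990"
    td50: 40.0
    m: 0.35
    n: 1.0
    dose_covariate: D_mean
  bakhshandeh2013:
    form: lkb
    citation: "doi:10.1016/j.ijrobp.2012.03.034"
    td50: 44.0
    m: 0.26
    n: 1.0
    dose_covariate: D_mean
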
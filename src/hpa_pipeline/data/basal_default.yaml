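# Default basal parameter set of the HPA network (version 1).
#
# Calibrated once so that, under 10-fold uniform sampling and the strong
# stress pulse, the virtual population exhibits all three phenotypes
# (control majority, sustained-low and sustained-high cortisol) and the two
# positive feedback loops (CRH self-activation, GR self-activation) sit in
# an excitable regime at order-one weights with sigmoid gain 10.
sigma: 10.0
parameters:
  # regulatory weights (activation > 0, inhibition < 0)
  RCRH_SS: 1.0
  RCRH_CRH: 1.0
  RCRH_GR: -1.0
  RACTH_CRH: 0.8
  RACTH_GR: -0.8
  RCOR_ACTH: 0.8
  RGR_COR: 0.8
  RGR_GR: 1.0
  # background inputs (effects of components not modelled explicitly;
  # ACTH is driven purely by CRH and GR, hence no background term)
  RCRH_0: -0.4
  RACTH_0: 0.0
  RCOR_0: -0.3
  RGR_0: -0.8
  # relaxation rates (1/time, arbitrary units)
  ts_CRH: 1.0
  ts_ACTH: 1.0
  ts_COR: 1.0
  ts_GR: 1.0
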
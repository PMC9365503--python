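# Literature risk-model parameters.
# schneider: delta per (10,000 PY * Gy); gamma_e per year; gamma_a dimensionless;
#            alpha per Gy; repop R in [0,1]. beta is derived as alpha/(alpha_beta).
# lkb: volume exponent n, slope m, D50 in Gy, keyed (organ, endpoint).
# darby: excess relative risk per Gy mean heart dose.
alpha_beta: 3.0
schneider:
  lung:
    delta: 8.0
    gamma_e: 0.002
    gamma_a: 4.23
    alpha: 0.042
    repop: 0.83
    source: Schneider secondary-cancer model fit (lung)
  breast:
    delta: 8.2
    gamma_e: -0.037
    gamma_a: 1.70
    alpha: 0.044
    repop: 0.15
    source: Schneider secondary-cancer model fit (breast)
lkb:
  lung:
    symptomatic_pneumonitis:
      n: 1.000
      m: 0.35
      d50: 37.6
      source: Seppenwoolde/Lyman fits, symptomatic pneumonitis
    radiation_pneumonitis_g2:
      n: 0.990
      m: 0.37
      d50: 30.8
      source: Burman fits, radiation pneumonitis grade >= 2
darby:
  err_per_gy: 0.074
  source: Darby major-coronary-event case-control study
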
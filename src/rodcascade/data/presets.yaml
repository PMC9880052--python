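# Named mutant presets: override maps applied to a wild-type parameter set.
# "scale" entries multiply a field; "set" entries replace it.
# For vector fields (lambda_max), scales apply to states 1..n only; the
# terminal (arrestin-quenched) zero entry is preserved.

WT: {}

RGS9_0.2x:
  scale: {RGS9_0: 0.2}
RGS9_2x:
  scale: {RGS9_0: 2.0}
RGS9_4x:
  scale: {RGS9_0: 4.0}

RK_0.3x:
  scale: {lambda_max: 0.3333333333333333}
RK_S561L:
  scale: {lambda_max: 3.0}

GCAP2_KO:
  scale: {alpha_max: 0.40}
  set: {beta: 1.0, K_cyc1: 0.047}

GCAPs_KO:
  freeze_cyclase_dark: true

CNG_CaM_null:
  set: {cam_null: true}

PDE_0.1x:
  scale: {E0: 0.1}
PDE_10x:
  scale: {E0: 10.0}

Rec_KO:
  set: {Rec_tot: 0.0}
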
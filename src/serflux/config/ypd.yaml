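# YPD medium preset: rich medium opens uptake of all 20 amino acids and the
# 4 nucleobases on top of glucose. Magnitudes in mmol/gDW/h; exchange ids
# are editable placeholders to be mapped to the loaded model.
ypd:
  EX_glc: 10
  EX_ala: 1
  EX_arg: 1
  EX_asn: 1
  EX_asp: 1
  EX_cys: 1
  EX_gln: 1
  EX_glu: 1
  EX_gly: 1
  EX_his: 1
  EX_ile: 1
  EX_leu: 1
  EX_lys: 1
  EX_met: 1
  EX_phe: 1
  EX_pro: 1
  EX_ser: 1
  EX_thr: 1
  EX_trp: 1
  EX_tyr: 1
  EX_val: 1
  EX_ade: 1
  EX_gua: 1
  EX_ura: 1
  EX_thy: 1
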
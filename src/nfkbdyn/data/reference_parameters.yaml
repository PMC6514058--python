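metadata: nfkbdyn reference parameter set v1; units nM and hours; calibrated against
  the package's dynamical behavior checklist (see docs/methods.md)
parameters:
  syn_rela:
    value: 0.07
    group: Gr-I
  syn_p50:
    value: 3.0
    group: Gr-II
  syn_ikbb:
    value: 4.0
    group: Gr-VI
  txn_ikba_const:
    value: 0.1
    group: Gr-III
  txn_ikba_a50:
    value: 0.4
    group: Gr-III
  txn_ikba_a52:
    value: 0.4
    group: Gr-III
  txn_ikba_b50:
    value: 0.03
    group: Gr-III
  txn_ikba_b52:
    value: 0.03
    group: Gr-III
  deg_tikba:
    value: 0.9
    group: Gr-VIII
  tl_ikba:
    value: 30.0
    group: Gr-III
  txn_ikbe_const:
    value: 0.03
    group: Gr-VII
  txn_ikbe_a50:
    value: 0.02
    group: Gr-VII
  txn_ikbe_a52:
    value: 0.02
    group: Gr-VII
  txn_ikbe_b50:
    value: 0.002
    group: Gr-VII
  txn_ikbe_b52:
    value: 0.002
    group: Gr-VII
  deg_tikbe:
    value: 1.0
    group: Gr-IX
  tl_ikbe:
    value: 6.0
    group: Gr-VII
  txn_nfkb2_const:
    value: 0.05
    group: Gr-IV
  txn_nfkb2_a50:
    value: 0.15
    group: Gr-IV
  txn_nfkb2_a52:
    value: 0.15
    group: Gr-IV
  txn_nfkb2_b50:
    value: 0.03
    group: Gr-IV
  txn_nfkb2_b52:
    value: 0.03
    group: Gr-IV
  deg_tnfkb2:
    value: 1.0
    group: Gr-X
  tl_nfkb2:
    value: 6.0
    group: Gr-IV
  txn_relb_const:
    value: 0.0005
    group: Gr-V
  txn_relb_a50:
    value: 0.02
    group: Gr-V
  txn_relb_a52:
    value: 0.02
    group: Gr-V
  txn_relb_b50:
    value: 0.0008
    group: Gr-V
  txn_relb_b52:
    value: 0.0008
    group: Gr-V
  deg_trelb:
    value: 0.15
    group: Gr-XI
  tl_relb:
    value: 2.5
    group: Gr-V
  kdim_f_a50:
    value: 1.0
    group: Gr-XII
  kdim_r_a50:
    value: 0.2
    group: Gr-XII
  kdim_f_a52:
    value: 0.15
    group: Gr-XIII
  kdim_r_a52:
    value: 0.2
    group: Gr-XIII
  kdim_f_b50:
    value: 1.0
    group: Gr-XIV
  kdim_r_b50:
    value: 1.0
    group: Gr-XIV
  kdim_f_b52:
    value: 1.0
    group: Gr-XV
  kdim_r_b52:
    value: 1.0
    group: Gr-XV
  proc_p100:
    value: 0.04
    group: Gr-XVI
  kib_f_ikba_a50:
    value: 5.0
    group: Gr-XVII
  kib_r_ikba_a50:
    value: 0.05
    group: Gr-XVII
  kib_f_ikba_a52:
    value: 5.0
    group: Gr-XVII
  kib_r_ikba_a52:
    value: 0.05
    group: Gr-XVII
  kib_f_ikba_b50:
    value: 0.0005
    group: Gr-XVII
  kib_r_ikba_b50:
    value: 0.05
    group: Gr-XVII
  kib_f_ikba_b52:
    value: 0.0005
    group: Gr-XVII
  kib_r_ikba_b52:
    value: 0.05
    group: Gr-XVII
  kib_f_ikbb_a50:
    value: 1.0
    group: Gr-XVIII
  kib_r_ikbb_a50:
    value: 0.05
    group: Gr-XVIII
  kib_f_ikbb_a52:
    value: 1.0
    group: Gr-XVIII
  kib_r_ikbb_a52:
    value: 0.05
    group: Gr-XVIII
  kib_f_ikbe_a50:
    value: 1.0
    group: Gr-XIX
  kib_r_ikbe_a50:
    value: 0.05
    group: Gr-XIX
  kib_f_ikbe_a52:
    value: 1.0
    group: Gr-XIX
  kib_r_ikbe_a52:
    value: 0.05
    group: Gr-XIX
  kp100_f_a50:
    value: 0.05
    group: Gr-XX
  kp100_r_a50:
    value: 0.05
    group: Gr-XX
  kp100_f_b50:
    value: 2.0
    group: Gr-XX
  kp100_r_b50:
    value: 0.02
    group: Gr-XX
  kp100_f_b52:
    value: 2.0
    group: Gr-XX
  kp100_r_b52:
    value: 0.02
    group: Gr-XX
  k_imp_dimer:
    value: 2.4
    group: Gr-XXI
  k_imp_ikb:
    value: 1.5
    group: Gr-XXII
  k_exp_complex:
    value: 8.0
    group: Gr-XXIII
  deg_rela:
    value: 0.4
    group: Gr-XXIV
  deg_relb:
    value: 1.0
    group: Gr-XXV
  deg_p50:
    value: 0.4
    group: Gr-XXVI
  deg_p100:
    value: 0.05
    group: Gr-XXVII
  deg_p52:
    value: 0.4
    group: Gr-XXVIII
  deg_a50:
    value: 0.12
    group: Gr-XXIX
  deg_a52:
    value: 0.12
    group: Gr-XXIX
  deg_b50:
    value: 0.08
    group: Gr-XXIX
  deg_b52:
    value: 0.08
    group: Gr-XXIX
  deg_ikba:
    value: 3.0
    group: Gr-XXX
  degc_ikba:
    value: 0.03
    group: Gr-XXX
  deg_ikbb:
    value: 1.0
    group: Gr-XXXI
  degc_ikbb:
    value: 0.02
    group: Gr-XXXI
  deg_ikbe:
    value: 1.0
    group: Gr-XXXII
  degc_ikbe:
    value: 0.02
    group: Gr-XXXII
  degc_p100:
    value: 0.02
    group: Gr-XXVII
  ikk_deg_ikba:
    value: 0.3
    group: Gr-XXXIII
  ikk_degc_ikba:
    value: 0.06
    group: Gr-XXXIII
  ikk_deg_ikbb:
    value: 0.08
    group: Gr-XXXIV
  ikk_degc_ikbb:
    value: 0.08
    group: Gr-XXXIV
  ikk_deg_ikbe:
    value: 0.1
    group: Gr-XXXV
  ikk_degc_ikbe:
    value: 0.1
    group: Gr-XXXV
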
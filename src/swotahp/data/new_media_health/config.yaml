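factors: factors.csv
matrices:
  S: matrix_S.csv
  W: matrix_W.csv
  O: matrix_O.csv
  T: matrix_T.csv
cr_threshold: 0.1
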
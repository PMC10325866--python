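# Two-arm synthetic study: saline control vs a psilocin-like condition
# (broadband power x0.6 and coupling x0.7 in the first two post epochs).
seed: 7
output_dir: study_out
epoch_s: 60.0            # compressed epochs; omit (null) for 10-min epochs
groups:
  - name: SAL
    n: 4
  - name: PSI
    n: 4
    power_gain: 0.6
    coupling_gain: 0.7
selection:
  target_total_s: 50.0
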
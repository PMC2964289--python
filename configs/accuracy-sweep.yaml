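# Accuracy-demand sweep: five conditions scale (w_p, w_v) by
# {0.01, 0.1, 1, 10, 100} about this baseline.
cost:
  w_p: 1.0e4
  w_v: 1.0e2
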
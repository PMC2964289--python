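# Reduced sizes for quick smoke runs.
babble:
  n_samples: 10000
adaptation:
  replications: 5
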
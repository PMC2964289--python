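# Reference configuration: all values equal the package defaults.
# Any subset may be overridden; unknown keys are rejected.
{}
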
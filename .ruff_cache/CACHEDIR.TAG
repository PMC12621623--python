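Signature: 8a477f597d28d172789f06886806bc55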
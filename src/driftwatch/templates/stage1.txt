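[STAGE 1 / BLUE] Normal operation. All monitors nominal ({n_findings} open findings: {details}). No action required.
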
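[STAGE 4 / RED] Significant error: model output is not usable ({details}). Do not use the tool until a fix is implemented; the monitoring team has been alerted.
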
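[STAGE 2 / GREEN] Minor change to the tool's interface or layout ({details}). Informational only; no action required.
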
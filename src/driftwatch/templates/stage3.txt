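[STAGE 3 / YELLOW] Possible performance degradation ({n_findings} findings: {details}; scores {scores_age_days} day(s) old). Scores may still support decisions but can change once refreshed: use the tool at your discretion.
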
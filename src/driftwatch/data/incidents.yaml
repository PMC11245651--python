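# Incident log replayed as triage scenario fixtures.
# Each entry maps one documented production incident from a deployed
# clinical risk model onto a monitor finding and the category/stage the
# policy engine is expected to assign. The finding encodings are this
# package's interpretation of the incident descriptions.
incidents:
  - date: "2019-08-26"
    description: "Overnight database refresh made all model calls fail for several hours."
    finding:
      source: volume
      kind: pipeline_error
      root_cause: "nightly database refresh window"
    expected:
      category: technical_infrastructure
      stage: 4
  - date: "2019-11-27"
    description: "Unannounced server reboot caused unexpected downtime."
    finding:
      source: volume
      kind: pipeline_error
      root_cause: "server reboot schedule not communicated"
    expected:
      category: technical_infrastructure
      stage: 4
  - date: "2020-07-24"
    description: "Burst of real-time observation API calls led to prediction timeouts."
    finding:
      source: volume
      kind: volume_anomaly
      root_cause: "API call volume spike causing timeouts"
    expected:
      category: technical_infrastructure
      stage: 1
  - date: "2021-04-08"
    description: "EHR upgrade broke the scoring pipeline."
    finding:
      source: probabilities
      kind: pipeline_error
      root_cause: "EHR system upgrade"
    expected:
      category: technical_infrastructure
      stage: 4
  - date: "2021-07-30"
    description: >
      Gradual decline in a troponin lab feature traced to an unmapped new
      laboratory code; fixed by aliasing the new code to the feature.
    finding:
      source: historical_missingness
      kind: missingness_shift
      feature: troponin
      root_cause: "laboratory code change; new code not in training data"
    expected:
      category: explained_shift
      stage: 1
  - date: "2021-09-15"
    description: >
      Same troponin drift as first detected, before the root cause was
      identified.
    finding:
      source: historical_missingness
      kind: missingness_shift
      feature: troponin
    expected:
      category: unexplained_shift
      stage: 3
  - date: "2022-01-05"
    description: "Nightly database delay left the morning scores a day old."
    finding:
      source: probabilities
      kind: stale_scores
      root_cause: "delayed nightly database refresh"
    expected:
      category: technical_infrastructure
      stage: 3
  - date: "2022-05-16"
    description: "Queue-server certificate update caused server errors."
    finding:
      source: volume
      kind: pipeline_error
      root_cause: "expired message-queue certificate"
    expected:
      category: technical_infrastructure
      stage: 4
  - date: "2022-11-07"
    description: "Structural change in the diagnosis-code data mart broke an input query."
    finding:
      source: features
      kind: pipeline_error
      root_cause: "data mart schema change"
      blocking: true
    expected:
      category: technical_infrastructure
      stage: 4
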
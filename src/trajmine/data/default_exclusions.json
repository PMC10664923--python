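{
  "comment": "Default chapter-level exclusions for WHO ICD-10-style hierarchies: pregnancy/childbirth (XV), perinatal conditions (XVI), external causes (XX), and health-status/Z codes (XXI); Z85.51 stays whitelisted as a cohort anchor diagnosis.",
  "excluded": ["XV", "XVI", "XX", "XXI"],
  "whitelist": ["Z85.51"]
}
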
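# The eight neuropsychiatric adverse-event groups, assembled at HLT/HLGT
# level against the loaded hierarchy. The published analysis names the eight
# groups but not the exact HLT/HLGT terms behind them; these selectors are a
# documented reconstruction resolved against the synthetic toy hierarchy
# shipped with the package. Users with a licensed MedDRA release should
# replace the terms with the real ones for their version.
groups:
  headache:
    - {level: HLT, term: Headaches NEC}
  migraine:
    - {level: HLT, term: Migraine headaches}
  anxiety:
    - {level: HLT, term: Anxiety symptoms}
  depression:
    - {level: HLT, term: Depressive disorders}
  suicide-related:
    - {level: HLT, term: Suicidal and self-injurious behaviours}
  sleep disorders:
    - {level: HLGT, term: Sleep disorders and disturbances}
  olfactory nerve abnormalities:
    - {level: HLT, term: Olfactory nerve disorders}
  sensory nerve abnormalities:
    - {level: HLT, term: Sensory abnormalities NEC}
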
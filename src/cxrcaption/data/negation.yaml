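# Negation cues for the lexicon labeler. A sign phrase starting within
# scope_window tokens after a cue (same sentence) is treated as negated.
# Hedged findings ("possible consolidation") are treated as positive.
cues:
  - "no"
  - "not"
  - without
  - absence of
  - free of
  - negative for
scope_window: 6
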
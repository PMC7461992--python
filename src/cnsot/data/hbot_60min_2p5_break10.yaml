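# One hour of hyperbaric oxygen at 2.5 bar with a single 10-min air break
# (two 30-min oxygen periods; the break is not counted in the hour).
# The air segment's PO2 is that of air at 2.5 bar ambient (~0.52 bar); it
# contributes recovery only.
condition: dry_rest
segments:
  - {po2_bar: 2.5, duration_min: 30, kind: oxygen}
  - {po2_bar: 0.52, duration_min: 10, kind: air}
  - {po2_bar: 2.5, duration_min: 30, kind: oxygen}
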
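# First three oxygen periods of US Navy Treatment Table 6: 20 min of
# oxygen at 2.8 bar, repeated three times with 5-min air breaks between.
# Air at 2.8 bar ambient has PO2 ~0.59 bar; air segments are recovery only.
condition: dry_rest
segments:
  - {po2_bar: 2.8, duration_min: 20, kind: oxygen}
  - {po2_bar: 0.59, duration_min: 5, kind: air}
  - {po2_bar: 2.8, duration_min: 20, kind: oxygen}
  - {po2_bar: 0.59, duration_min: 5, kind: air}
  - {po2_bar: 2.8, duration_min: 20, kind: oxygen}
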
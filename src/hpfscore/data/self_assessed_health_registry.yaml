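# Registry entry for the bundled self-assessed health status fixture.
# The indicator is a weighted mean of ordinal response categories
# (excellent=5 ... poor=1), positively geared: higher is improvement.
indicators:
  - indicator_id: self_assessed_health
    measure_code: "1.17"
    label: Self-assessed health weighted rating
    direction_of_effect: 1
    measurement_kind: plain_rate
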
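# Dose-direction text templates used by the synthetic cohort generator.
# Placeholders: {qty} numeral, {qty_word} written-out number, {freq_phrase}
# a frequency phrase drawn from the frequency keyword table.
template_id,pattern
take_word,TAKE {qty_word} PUFFS {freq_phrase}
numeral_puffs,{qty} PUFFS {freq_phrase}
inhale_word,INHALE {qty_word} PUFFS {freq_phrase}
p_shorthand,{qty} P {freq_phrase}
take_numeral,TAKE {qty} {freq_phrase}
tablet,TAKE {qty_word} TABLET {freq_phrase}
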
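# Dose-frequency keyword table: uppercased phrase -> doses per day.
# Matched longest-phrase-first on word boundaries in the uppercased dose text.
# Reconstruction; extend with local prescribing shorthand as needed.
phrase,doses_per_day
MORNING AND NIGHT,2
MORNING AND EVENING,2
EVERY MORNING AND EVENING,2
THREE TIMES,3
FOUR TIMES,4
4 TIMES,4
3 TIMES,3
2 TIMES,2
TWICE,2
ONCE,1
NOCTE,1
MANE,1
BD,2
TDS,3
QDS,4
OD,1
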
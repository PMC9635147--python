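# Synthetic reconstruction of the non-asthma-indication keyword and brand exclusion list.
# applies_to: DOSE_TEXT | MEDICATION_NAME | FORMULATION | BRAND
# reason:     NON_ASTHMA_INDICATION | FORMULATION_EXCLUDED | NON_ASTHMA_BRAND | DELETED
# Keywords are matched as substrings of the uppercased, single-spaced field.
keyword,applies_to,reason
DELETE,DOSE_TEXT,DELETED
SPRAY,FORMULATION,FORMULATION_EXCLUDED
DROP,FORMULATION,FORMULATION_EXCLUDED
NASAL,DOSE_TEXT,NON_ASTHMA_INDICATION
NASAL,MEDICATION_NAME,NON_ASTHMA_INDICATION
NOSE,DOSE_TEXT,NON_ASTHMA_INDICATION
NOSTRIL,DOSE_TEXT,NON_ASTHMA_INDICATION
RHINITIS,DOSE_TEXT,NON_ASTHMA_INDICATION
HAYFEVER,DOSE_TEXT,NON_ASTHMA_INDICATION
HAY FEVER,DOSE_TEXT,NON_ASTHMA_INDICATION
ECZEMA,DOSE_TEXT,NON_ASTHMA_INDICATION
CROHN,DOSE_TEXT,NON_ASTHMA_INDICATION
CROHN,MEDICATION_NAME,NON_ASTHMA_INDICATION
COLITIS,DOSE_TEXT,NON_ASTHMA_INDICATION
ENEMA,DOSE_TEXT,NON_ASTHMA_INDICATION
ENEMA,MEDICATION_NAME,NON_ASTHMA_INDICATION
BECONASE,BRAND,NON_ASTHMA_BRAND
FLIXONASE,BRAND,NON_ASTHMA_BRAND
NASOBEC,BRAND,NON_ASTHMA_BRAND
RHINOCORT,BRAND,NON_ASTHMA_BRAND
NASONEX,BRAND,NON_ASTHMA_BRAND
PIRINASE,BRAND,NON_ASTHMA_BRAND
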
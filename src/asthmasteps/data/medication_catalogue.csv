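# Synthetic reconstruction of a UK asthma medication lookup table (2019 BTS/SIGN era).
# Band thresholds are the guideline "low / medium / high" daily-dose values in mcg/day,
# keyed per drug + inhaler type. Discontinued brands (AeroBec, Beclazone, Filair) are
# grouped under their parent drug + inhaler type. Combination and extrafine products
# are keyed by brand-safe tokens so that free-text matching is unambiguous.
# Edit or replace this file to align with a local formulary.
generic_name,class,brand_names,inhaler_type,licensed_strengths_mcg,band_low,band_medium,band_high
beclometasone,ICS,CLENIL;CLENIL MODULITE;AEROBEC;BECLAZONE;FILAIR,MDI,50;100;200;250,400,800,2000
qvar,ICS,QVAR;QVAR EASI-BREATHE,MDI,50;100,200,400,800
budesonide,ICS,PULMICORT;EASYHALER BUDESONIDE,DPI,100;200;400;500,400,800,1600
ciclesonide,ICS,ALVESCO,MDI,80;160,160,320,640
fluticasone,ICS,FLIXOTIDE,MDI,50;125;250;500,200,500,1000
fluticasone-salmeterol,ICS_LABA,SERETIDE,MDI,50;100;125;250;500,200,500,1000
budesonide-formoterol,ICS_LABA,SYMBICORT;DUORESP,DPI,100;200;400,400,800,1600
fluticasone-formoterol,ICS_LABA,FLUTIFORM,MDI,50;125;250,200,500,1000
salmeterol,LABA,SEREVENT,MDI,25;50,,,
formoterol,LABA,OXIS;FORADIL;ATIMOS,DPI,6;12,,,
salbutamol,SABA,VENTOLIN;AIROMIR;SALAMOL,MDI,100;200,,,
terbutaline,SABA,BRICANYL,DPI,500,,,
montelukast,LTRA,SINGULAIR,NA,4000;5000;10000,,,
theophylline,THEOPHYLLINE,UNIPHYLLIN;NUELIN;SLO-PHYLLIN,NA,200000;300000;400000,,,
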
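# Published report counts for the noninfectious myocarditis/pericarditis SMQ
# screen: bDMARD-exposed reports with ankylosing spondylitis indication vs the
# full FAERS database, 2004Q1-2022Q4.  exposed_total and database_total are the
# two ICSR margins; n11 is the exposed-with-event cell and event_total the
# full-database event margin for each PT.
event,n11,event_total,exposed_total,database_total
pericarditis,1874,13816,109943,19089556
red blood cell sedimentation rate increased,1329,12858,109943,19089556
pericardial effusion,154,24144,109943,19089556
extrasystoles,59,7817,109943,19089556
cardiac failure acute,42,6414,109943,19089556
myocarditis,45,9430,109943,19089556
electrocardiogram abnormal,33,9082,109943,19089556
atrioventricular block,22,8146,109943,19089556
bundle branch block left,35,5242,109943,19089556
dilatation ventricular,19,3479,109943,19089556
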
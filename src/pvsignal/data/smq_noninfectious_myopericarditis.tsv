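set_name	term
noninfectious_myocarditis_pericarditis	pericarditis
noninfectious_myocarditis_pericarditis	red blood cell sedimentation rate increased
noninfectious_myocarditis_pericarditis	pericardial effusion
noninfectious_myocarditis_pericarditis	extrasystoles
noninfectious_myocarditis_pericarditis	cardiac failure acute
noninfectious_myocarditis_pericarditis	myocarditis
noninfectious_myocarditis_pericarditis	electrocardiogram abnormal
noninfectious_myocarditis_pericarditis	atrioventricular block
noninfectious_myocarditis_pericarditis	bundle branch block left
noninfectious_myocarditis_pericarditis	dilatation ventricular
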
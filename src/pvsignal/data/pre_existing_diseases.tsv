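set_name	term
pre_existing_diseases	pericarditis
pre_existing_diseases	epstein-barr viral infections
pre_existing_diseases	cytomegalovirus infection
pre_existing_diseases	human herpesvirus 6 infection
pre_existing_diseases	parvovirus b19 infection
pre_existing_diseases	echovirus test positive
pre_existing_diseases	mycobacterium tuberculosis complex test positive
pre_existing_diseases	borrelia burgdorferi serology positive
pre_existing_diseases	coxiella infections
pre_existing_diseases	histoplasma infections
pre_existing_diseases	blastomyces infections
pre_existing_diseases	candida infections
pre_existing_diseases	toxoplasma infections
pre_existing_diseases	systemic lupus erythematosus
pre_existing_diseases	sjogren's syndrome
pre_existing_diseases	rheumatoid arthritis
pre_existing_diseases	scleroderma
pre_existing_diseases	eosinophilic granulomatosis with polyangiitis
pre_existing_diseases	familial mediterranean fever
pre_existing_diseases	tumor necrosis factor receptor-associated periodic syndrome
pre_existing_diseases	sarcoidosis
pre_existing_diseases	inflammatory bowel disease
pre_existing_diseases	pericardial mesothelioma malignant
pre_existing_diseases	lymphomas nec
pre_existing_diseases	non-small-cell lung cancer
pre_existing_diseases	small cell lung cancer
pre_existing_diseases	breast cancer
pre_existing_diseases	uremia
pre_existing_diseases	anorexia nervosa
pre_existing_diseases	pericardial disorders
pre_existing_diseases	postpericardiotomy syndrome
pre_existing_diseases	coronary artery bypass
pre_existing_diseases	cardiac pacemaker insertion
pre_existing_diseases	radiofrequency ablation
pre_existing_diseases	transcatheter aortic valve implantation
pre_existing_diseases	percutaneous coronary intervention
pre_existing_diseases	hypothyroidism
pre_existing_diseases	tuberculosis
pre_existing_diseases	noninfectious pericarditis
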
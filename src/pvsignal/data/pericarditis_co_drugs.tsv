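set_name	term
pericarditis_inducing_drugs	procainamide
pericarditis_inducing_drugs	hydralazine
pericarditis_inducing_drugs	methyldopa
pericarditis_inducing_drugs	isoniazid
pericarditis_inducing_drugs	phenytoin
pericarditis_inducing_drugs	beta-lactam antibacterials, penicillins
pericarditis_inducing_drugs	doxorubicin
pericarditis_inducing_drugs	daunorubicin
pericarditis_inducing_drugs	fluorouracil
pericarditis_inducing_drugs	cyclophosphamide
pericarditis_inducing_drugs	minocycline
pericarditis_inducing_drugs	sulfasalazine
pericarditis_inducing_drugs	enalapril
pericarditis_inducing_drugs	clofarabine
pericarditis_inducing_drugs	carfilzomib
pericarditis_inducing_drugs	bortezomib
pericarditis_inducing_drugs	dasatinib
pericarditis_inducing_drugs	ceritinib
pericarditis_inducing_drugs	clozapine
pericarditis_inducing_drugs	nivolumab
pericarditis_inducing_drugs	pembrolizumab
pericarditis_inducing_drugs	atezolizumab
pericarditis_inducing_drugs	ipilimumab
pericarditis_inducing_drugs	sulfamethoxazole and trimethoprim
pericarditis_inducing_drugs	interferon
pericarditis_inducing_drugs	minoxidil
pericarditis_inducing_drugs	lisinopril
pericarditis_inducing_drugs	apixaban
pericarditis_inducing_drugs	rivaroxaban
pericarditis_inducing_drugs	streptokinase
pericarditis_inducing_drugs	bromocriptine
pericarditis_inducing_drugs	dantrolene
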
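pt	hlt	hlgt	soc	primary_soc
Headache	Headaches NEC	Headaches	Nervous system disorders	Y
Head discomfort	Headaches NEC	Headaches	Nervous system disorders	Y
Tension headache	Headaches NEC	Headaches	Nervous system disorders	Y
Migraine	Migraine headaches	Headaches	Nervous system disorders	Y
Migraine with aura	Migraine headaches	Headaches	Nervous system disorders	Y
Anosmia	Olfactory nerve disorders	Cranial nerve disorders (excl neoplasms)	Nervous system disorders	Y
Parosmia	Olfactory nerve disorders	Cranial nerve disorders (excl neoplasms)	Nervous system disorders	Y
Hyposmia	Olfactory nerve disorders	Cranial nerve disorders (excl neoplasms)	Nervous system disorders	Y
Hypoaesthesia	Sensory abnormalities NEC	Neurological disorders NEC	Nervous system disorders	Y
Paraesthesia	Sensory abnormalities NEC	Neurological disorders NEC	Nervous system disorders	Y
Burning sensation	Sensory abnormalities NEC	Neurological disorders NEC	Nervous system disorders	Y
Allodynia	Sensory abnormalities NEC	Neurological disorders NEC	Nervous system disorders	Y
Dizziness	Neurological signs and symptoms NEC	Neurological disorders NEC	Nervous system disorders	Y
Dizziness	Inner ear signs and symptoms	Inner ear and VIIIth cranial nerve disorders	Ear and labyrinth disorders	N
Tremor	Neurological signs and symptoms NEC	Neurological disorders NEC	Nervous system disorders	Y
Somnolence	Neurological signs and symptoms NEC	Neurological disorders NEC	Nervous system disorders	Y
Somnolence	Hypersomnic disturbances	Sleep disorders and disturbances	Psychiatric disorders	N
Amnesia	Memory loss (excl dementia)	Mental impairment disorders	Nervous system disorders	Y
Memory impairment	Memory loss (excl dementia)	Mental impairment disorders	Nervous system disorders	Y
Anxiety	Anxiety symptoms	Anxiety disorders and symptoms	Psychiatric disorders	Y
Nervousness	Anxiety symptoms	Anxiety disorders and symptoms	Psychiatric disorders	Y
Stress	Anxiety symptoms	Anxiety disorders and symptoms	Psychiatric disorders	Y
Depression	Depressive disorders	Depressed mood disorders and disturbances	Psychiatric disorders	Y
Depressed mood	Depressive disorders	Depressed mood disorders and disturbances	Psychiatric disorders	Y
Major depression	Depressive disorders	Depressed mood disorders and disturbances	Psychiatric disorders	Y
Suicidal ideation	Suicidal and self-injurious behaviours	Suicidal and self-injurious behaviours NEC	Psychiatric disorders	Y
Suicide attempt	Suicidal and self-injurious behaviours	Suicidal and self-injurious behaviours NEC	Psychiatric disorders	Y
Self-injurious ideation	Suicidal and self-injurious behaviours	Suicidal and self-injurious behaviours NEC	Psychiatric disorders	Y
Insomnia	Disturbances in initiating and maintaining sleep	Sleep disorders and disturbances	Psychiatric disorders	Y
Initial insomnia	Disturbances in initiating and maintaining sleep	Sleep disorders and disturbances	Psychiatric disorders	Y
Middle insomnia	Disturbances in initiating and maintaining sleep	Sleep disorders and disturbances	Psychiatric disorders	Y
Nightmare	Parasomnias	Sleep disorders and disturbances	Psychiatric disorders	Y
Abnormal dreams	Parasomnias	Sleep disorders and disturbances	Psychiatric disorders	Y
Sleep disorder	Parasomnias	Sleep disorders and disturbances	Psychiatric disorders	Y
Sleep disorder	Neurological signs and symptoms NEC	Neurological disorders NEC	Nervous system disorders	N
Nausea	Nausea and vomiting symptoms	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	Y
Vomiting	Nausea and vomiting symptoms	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	Y
Diarrhoea	Diarrhoea (excl infective)	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	Y
Abdominal pain	Gastrointestinal and abdominal pains (excl oral and throat)	Gastrointestinal signs and symptoms	Gastrointestinal disorders	Y
Fatigue	Asthenic conditions	General system disorders NEC	General disorders and administration site conditions	Y
Asthenia	Asthenic conditions	General system disorders NEC	General disorders and administration site conditions	Y
Injection site pain	Injection site reactions	Administration site reactions	General disorders and administration site conditions	Y
Injection site erythema	Injection site reactions	Administration site reactions	General disorders and administration site conditions	Y
Decreased appetite	Appetite disorders	Appetite and general nutritional disorders	Metabolism and nutrition disorders	Y
Dehydration	Total fluid volume decreased	Total fluid volume alterations	Metabolism and nutrition disorders	Y
Blood glucose increased	Carbohydrate tolerance analyses (incl diabetes)	Metabolic investigations NEC	Investigations	Y
Weight decreased	Physical examination procedures and organ system status	Physical examination and organ system status topics	Investigations	Y
Alopecia	Alopecias	Epidermal and dermal conditions	Skin and subcutaneous tissue disorders	Y
Pancreatitis	Acute and chronic pancreatitis	Exocrine pancreas conditions	Gastrointestinal disorders	Y
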
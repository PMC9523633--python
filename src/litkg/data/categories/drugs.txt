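# Synthetic fixture list of clinical-drug concept identifiers (illustrative).
C0012854	Donepezil
C0135254	Memantine
C0771182	Galantamine
C0072227	Rivastigmine
C0002432	Amifostine
C0025598	Metformin
C0023947	Losartan
C0028978	Omeprazole
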
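# Synthetic fixture default of Alzheimer's-disease-related concept identifiers
# (illustrative subset; supply your own disease concept list for real runs).
C0002395	Alzheimer's Disease
C0276496	Familial Alzheimer's disease
C0494463	Alzheimer disease, late onset
C0750900	Alzheimer's disease, focal onset
C0750901	Alzheimer's disease, early onset
C1843013	Alzheimer disease, familial, type 3
C0002736	Amyotrophic-dementia complex
C0011265	Presenile dementia
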
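# Synthetic fixture list of dietary-supplement concept identifiers (illustrative).
C0006644	Calcium
C0008318	Choline
C0016410	Folic Acid
C0017817	Ginkgo biloba extract
C0025243	Melatonin
C0042866	Vitamin E
C0087162	Zinc supplement
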
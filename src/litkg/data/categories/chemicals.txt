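# Synthetic fixture list of chemical concept identifiers (illustrative).
C0008838	Cisplatin
C0012772	Dopamine
C0017725	Glucose
C0020268	Hydrogen Peroxide
C0028040	Nicotine
C0035339	Retinoids
C0041942	Ubiquinone
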
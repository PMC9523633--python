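# Illustrative semantic-type -> semantic-group map (small editable fixture;
# the full UMLS Semantic Network is licensed and not bundled).
phsu	Chemicals & Drugs
orch	Chemicals & Drugs
aapp	Chemicals & Drugs
dsyn	Disorders
mobd	Disorders
neop	Disorders
gngm	Genes & Molecular Sequences
ortf	Anatomy
bpoc	Anatomy
phsf	Physiology
celf	Physiology
food	Objects
inpr	Objects
acty	Activities & Behaviors
dora	Activities & Behaviors
idcn	Concepts & Ideas
qnco	Concepts & Ideas
ocdi	Occupations
orgt	Organizations
phpr	Phenomena
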
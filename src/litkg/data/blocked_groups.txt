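# Generic semantic groups removed before graph construction.
Activities & Behaviors
Concepts & Ideas
Objects
Occupations
Organizations
Phenomena
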
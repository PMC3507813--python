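# Type I beta-turn template (4-mer): positions 2 and 3 at the alphaR region centre.
# position<TAB>phi<TAB>psi; "*" = unconstrained. Tolerance is given at match time (default 40).
2	-80	-25
3	-80	-25
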
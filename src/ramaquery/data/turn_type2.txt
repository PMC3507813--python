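# Type II beta-turn template (4-mer): position 2 at the betaR centre, position 3 at the alphaL centre.
# position<TAB>phi<TAB>psi; "*" = unconstrained. Tolerance is given at match time (default 40).
2	-90	130
3	80	25
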
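# Default Ramachandran region table: name<TAB>phi_min<TAB>phi_max<TAB>psi_min<TAB>psi_max (degrees)
# Half-open boxes [min, max); the four defaults are pairwise disjoint.
alphaL	20	140	-40	90
alphaR	-140	-20	-90	40
betaL	20	160	-180	-80
betaR	-160	-20	80	180
# The zeta region has no agreed rectangular bounds; define your own, e.g.:
# zeta	-180	-140	50	100
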
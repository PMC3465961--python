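gene	neuron	assay	ci_wt	ci_mut	ci_diff	n_odors
wildtype	AWA	odortaxis	0.9
wildtype	AWB	odortaxis	-0.95
wildtype	AWC	odortaxis	0.85
wildtype	AWA	LTA	0.9		0.5
wildtype	AWC	LTA	0.85		0.65
odr-3	AWA	odortaxis	0.9		0.6	3
odr-3	AWB	odortaxis	-0.95		-0.7	3
odr-3	AWC	odortaxis	0.85		0.5	3
rgs-3	AWC	odortaxis	0.85		0.85	1
daf-11	AWB	odortaxis	-0.95		0.6	2
daf-11	AWC	odortaxis	0.85		0.5	2
dgk-1	AWC	odortaxis	0.85		0	1
eat-4	AWC	odortaxis	0.85		0.55	1
egl-30	AWC	odortaxis	0.85		0.65	1
goa-1	AWA	odortaxis	0.9		0.6	2
goa-1	AWC	odortaxis	0.85		0.6	2
odr-1	AWA	odortaxis	0.9		0	2
odr-1	AWC	odortaxis	0.85		0.85	2
tax-2	AWA	odortaxis	0.9		0.2	3
tax-2	AWB	odortaxis	-0.95		-0.8	3
tax-2	AWC	odortaxis	0.85		0.75	3
tax-4	AWA	odortaxis	0.9		0.5	2
tax-4	AWC	odortaxis	0.85		0.75	2
egl-4	AWA	odortaxis	0.9		0.8	2
egl-4	AWC	odortaxis	0.85		0.65	2
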
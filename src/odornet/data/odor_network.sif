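arr-1	interacts	odr-3
daf-11	interacts	tax-4
dgk-1	interacts	goa-1
eat-4	interacts	egl-4
egl-30	interacts	goa-1
egl-4	interacts	goa-1
egl-4	interacts	odr-3
egl-4	interacts	tax-2
egl-4	interacts	tax-6
gpa-13	interacts	gpa-3
gpa-3	interacts	odr-3
gpa-5	interacts	odr-1
gpa-5	interacts	odr-3
odr-3	interacts	rgs-3
odr-3	interacts	tax-2
tax-2	interacts	tax-4
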
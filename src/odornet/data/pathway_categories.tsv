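gene	category
gpa-3	class1_regulator
odr-3	class1_regulator
gpa-5	class1_regulator
gpa-13	class1_regulator
arr-1	class1_regulator
rgs-3	class1_regulator
egl-4	class2_regulator
tax-6	class2_regulator
odr-1	class2_regulator
daf-11	class2_regulator
tax-2	class2_regulator
tax-4	class2_regulator
goa-1	actuator
egl-30	actuator
dgk-1	actuator
eat-4	actuator
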
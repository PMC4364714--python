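# Worked-example weaning-age cohort: the two sentinel animals carry the
# published extreme ganglionic fractions (83.6% affected, 77.1%
# non-affected); the remaining rows are SYNTHETIC interior fillers.
id	sex	age_group	ganglionic_fraction	megacolon
w0001	M	weaning	62.4	True
w0002	M	weaning	70.8	True
w0003	M	weaning	75.5	True
w0004	M	weaning	83.6	True
w0005	F	weaning	72.9	True
w0006	M	weaning	77.1	False
w0007	M	weaning	84.2	False
w0008	F	weaning	88.3	False
w0009	F	weaning	91.6	False
w0010	F	weaning	95.0	False
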
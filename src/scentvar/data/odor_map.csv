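compound,odor_class
(E)-beta-ocimene,herbal
myrcene,herbal
alpha-pinene,herbal
3-hexen-1-ol,herbal
eucalyptol,cool
linalool,floral
toluene,floral
naphthalene,floral
methyl benzoate,fruity
ethyl benzoate,fruity
methyl 2-methylbutyrate,fruity
methyl tiglate,fruity
methyl hexanoate,fruity
methyl octanoate,fruity
"2-ethenyl-1,1-dimethyl-3-methylenecyclohexane",herbal
caryophyllene,spicy
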
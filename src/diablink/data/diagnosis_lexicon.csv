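term,category
diabetes,positive
sugar diabetes,positive
diabetes type 1,positive
diabetes type 2,positive
type 1 diabetes,positive
type 2 diabetes,positive
grade 2 diabetes,positive
controlled diabetes,positive
self-managed diabetes,positive
diabetes mellitus,positive
pre-diabetes,uncertain
prediabetes,uncertain
pre diabetes,uncertain
borderline diabetes,uncertain
diabetes insipidus,uncertain
impaired glucose tolerance,uncertain
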
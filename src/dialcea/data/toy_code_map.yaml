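# Toy diagnosis-code prefix map (ICD-9-style families) used by the synthetic
# pipeline and tests. Matching is by string prefix on the claim's code field.
# This is NOT a curated clinical dictionary.
diabetes: ["250"]
hypertension: ["401", "402", "403", "404", "405"]
chf: ["428"]
mi: ["410", "412"]
stroke: ["430", "431", "432", "433", "434", "436"]
chronic_liver: ["571"]
cad: ["414"]
dysrhythmia: ["427"]
pvd: ["443"]
hyperlipidemia: ["272"]
rheumatologic: ["710", "714"]
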
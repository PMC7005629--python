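{
  "multiple_reports": ["pathogenic", "pathogenicity", "causative", "deleterious"],
  "heteroplasmy": ["heteroplasm*", "homoplasm*", "mutant load"],
  "segregation": ["segregat*", "cosegregat*", "pedigree", "maternal relatives"],
  "histochemistry": ["histochem*", "cox deficient", "cox negative", "ragged red"],
  "biochemistry_oxphos": ["oxphos", "respiratory chain", "oxidative phosphorylation", "enzymatic activity", "biochemical defect"],
  "cybrid_steadystate": ["cybrid*", "transmitochondrial", "steady state"],
  "single_fiber": ["single fiber", "single fibre", "single muscle fiber"],
  "disease_phenotype": ["myopathy", "melas", "merrf", "narp", "cardiomyopathy", "encephalomyopathy", "encephalopathy", "deafness", "syndrome", "disease"]
}
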
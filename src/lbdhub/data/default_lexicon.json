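{
  "_comment": "Illustrative default lexicon for the six physiological themes; editable. Tokens are lowercase; documents matching none are labeled 'unknown'.",
  "themes": {
    "endocrine": [
      "endocrine", "hormone", "pituitary", "hypothalamic", "adrenal",
      "cortisol", "corticotropin", "aldosterone", "thyroid", "prolactin",
      "somatotropin", "gonadotropin"
    ],
    "inflammation": [
      "inflammation", "inflammatory", "cytokine", "interleukin", "storm",
      "immune", "interferon", "macrophage", "neutrophil", "tnf",
      "chemokine", "lymphocyte"
    ],
    "lipid": [
      "lipid", "cholesterol", "lipoprotein", "atherosclerosis",
      "triglyceride", "sphingomyelin", "dyslipidemia", "hdl", "ldl",
      "adipose", "lipolysis", "phospholipid"
    ],
    "sympathetic": [
      "sympathetic", "baroreceptor", "norepinephrine", "adrenergic",
      "vasoconstriction", "medulla", "autonomic", "catecholamine",
      "vagal", "nerve", "pressor", "neurogenic"
    ],
    "viral_entry": [
      "entry", "spike", "ace2", "receptor", "binding", "fusion",
      "endocytosis", "protease", "furin", "tmprss2", "virion", "uptake"
    ]
  }
}
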
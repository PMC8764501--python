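# Default cancer-site configuration and relative risks per consumption level.
#
# ICD-10 code sets follow the standard grouping for alcohol-associated cancer
# sites; the three non-core sites are the sensitivity-analysis extension
# (possible, less established associations).
#
# Relative risks are defaults drawn from the Bagnardi et al. (2015) dose-
# response meta-analysis of alcohol and site-specific cancer (light <=12.5,
# moderate 12.6-50, heavy >50 g ethanol/day; reference = non-drinkers
# including former drinkers). `significant: false` marks associations that
# were not statistically significant for that sex/level; the pipeline censors
# those to RR = 1 before any attribution. Replace this file to run with a
# different risk table.

sites:
  - name: oral_cavity_pharynx
    icd10: ["C00-C14"]
    sexes: [M, F]
    core: true
  - name: esophagus
    icd10: ["C15"]
    sexes: [M, F]
    core: true
  - name: colorectal
    icd10: ["C18-C20"]
    sexes: [M, F]
    core: true
  - name: liver
    icd10: ["C22"]
    sexes: [M, F]
    core: true
  - name: larynx
    icd10: ["C32"]
    sexes: [M, F]
    core: true
  - name: breast
    icd10: ["C50"]
    sexes: [F]
    core: true
  - name: melanoma
    icd10: ["C43"]
    sexes: [M, F]
    core: false
  - name: pancreas
    icd10: ["C25"]
    sexes: [M, F]
    core: false
  - name: prostate
    icd10: ["C61"]
    sexes: [M]
    core: false

relative_risks:
  - {site: oral_cavity_pharynx, sex: M, level: light,    rr: 1.13, significant: true}
  - {site: oral_cavity_pharynx, sex: M, level: moderate, rr: 1.83, significant: true}
  - {site: oral_cavity_pharynx, sex: M, level: heavy,    rr: 5.13, significant: true}
  - {site: oral_cavity_pharynx, sex: F, level: light,    rr: 1.13, significant: false}
  - {site: oral_cavity_pharynx, sex: F, level: moderate, rr: 1.83, significant: true}
  - {site: oral_cavity_pharynx, sex: F, level: heavy,    rr: 5.13, significant: true}

  - {site: esophagus, sex: M, level: light,    rr: 1.26, significant: true}
  - {site: esophagus, sex: M, level: moderate, rr: 2.23, significant: true}
  - {site: esophagus, sex: M, level: heavy,    rr: 4.95, significant: true}
  - {site: esophagus, sex: F, level: light,    rr: 1.26, significant: false}
  - {site: esophagus, sex: F, level: moderate, rr: 2.23, significant: true}
  - {site: esophagus, sex: F, level: heavy,    rr: 4.95, significant: true}

  - {site: colorectal, sex: M, level: light,    rr: 0.99, significant: false}
  - {site: colorectal, sex: M, level: moderate, rr: 1.17, significant: true}
  - {site: colorectal, sex: M, level: heavy,    rr: 1.44, significant: true}
  - {site: colorectal, sex: F, level: light,    rr: 0.99, significant: false}
  - {site: colorectal, sex: F, level: moderate, rr: 1.17, significant: false}
  - {site: colorectal, sex: F, level: heavy,    rr: 1.44, significant: false}

  - {site: liver, sex: M, level: light,    rr: 1.00, significant: false}
  - {site: liver, sex: M, level: moderate, rr: 1.08, significant: false}
  - {site: liver, sex: M, level: heavy,    rr: 2.07, significant: true}
  - {site: liver, sex: F, level: light,    rr: 1.00, significant: false}
  - {site: liver, sex: F, level: moderate, rr: 1.08, significant: false}
  - {site: liver, sex: F, level: heavy,    rr: 2.07, significant: true}

  - {site: larynx, sex: M, level: light,    rr: 0.87, significant: false}
  - {site: larynx, sex: M, level: moderate, rr: 1.44, significant: true}
  - {site: larynx, sex: M, level: heavy,    rr: 2.65, significant: true}
  - {site: larynx, sex: F, level: light,    rr: 0.87, significant: false}
  - {site: larynx, sex: F, level: moderate, rr: 1.44, significant: true}
  - {site: larynx, sex: F, level: heavy,    rr: 2.65, significant: false}

  - {site: breast, sex: F, level: light,    rr: 1.04, significant: true}
  - {site: breast, sex: F, level: moderate, rr: 1.23, significant: true}
  - {site: breast, sex: F, level: heavy,    rr: 1.61, significant: true}

  # sensitivity-analysis sites: treated as legitimate associations when enabled
  - {site: melanoma, sex: M, level: light,    rr: 1.10, significant: true}
  - {site: melanoma, sex: M, level: moderate, rr: 1.18, significant: true}
  - {site: melanoma, sex: M, level: heavy,    rr: 1.20, significant: true}
  - {site: melanoma, sex: F, level: light,    rr: 1.10, significant: true}
  - {site: melanoma, sex: F, level: moderate, rr: 1.18, significant: true}
  - {site: melanoma, sex: F, level: heavy,    rr: 1.20, significant: true}

  - {site: pancreas, sex: M, level: light,    rr: 1.03, significant: true}
  - {site: pancreas, sex: M, level: moderate, rr: 1.10, significant: true}
  - {site: pancreas, sex: M, level: heavy,    rr: 1.19, significant: true}
  - {site: pancreas, sex: F, level: light,    rr: 1.03, significant: true}
  - {site: pancreas, sex: F, level: moderate, rr: 1.10, significant: true}
  - {site: pancreas, sex: F, level: heavy,    rr: 1.19, significant: true}

  - {site: prostate, sex: M, level: light,    rr: 1.06, significant: true}
  - {site: prostate, sex: M, level: moderate, rr: 1.07, significant: true}
  - {site: prostate, sex: M, level: heavy,    rr: 1.09, significant: true}
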
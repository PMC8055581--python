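# Skinfold prediction-equation coefficient registry.
#
# The four systems here predict either fat percentage directly or body
# density (later converted with the Siri two-compartment equation).
# Coefficients are registry data, not code: each entry records the primary
# source it was transcribed from, and corrections are data edits only.
#
# Schema
#   equations.<name>:
#     output:    fat_percent | body_density
#     transform: linear_in_sum | log10_density | lohman_weight_age
#     folds:     skinfold sites entering the fold sum (order irrelevant)
#     source:    provenance of the transcription
#     coefficients.<sex>: either a flat mapping, or a list of
#       {age_min, age_max, ...} bands (first matching band wins).
registry_version: "1.0"
equations:
  slaughter:
    output: fat_percent
    transform: linear_in_sum
    folds: [triceps, medial_calf]
    source: >
      Slaughter MH, Lohman TG, Boileau RA, et al. Skinfold equations for
      estimation of body fatness in children and youth. Hum Biol 1988;
      60:709-723. Triceps + calf form, all maturation levels.
    coefficients:
      F: {slope: 0.610, intercept: 5.1}
      M: {slope: 0.735, intercept: 1.0}
  durnin_rahaman:
    output: body_density
    transform: log10_density
    folds: [triceps, biceps, subscapular, suprailiac]
    source: >
      Durnin JVGA, Rahaman MM. The assessment of the amount of fat in the
      human body from measurements of skinfold thickness. Br J Nutr 1967;
      21:681-689. Adolescent (boys 12.7-15.7 y, girls 13.2-16.4 y)
      coefficients.
    coefficients:
      F: {c0: 1.1369, c1: 0.0598}
      M: {c0: 1.1533, c1: 0.0643}
  johnston:
    output: body_density
    transform: log10_density
    folds: [triceps, biceps, subscapular, suprailiac]
    source: >
      Johnston JL, Leong MS, Checkland EG, et al. Body fat assessed from
      body density and estimated from skinfold thickness in normal children
      and children with cystic fibrosis. Am J Clin Nutr 1988; 48:1362-1366.
      Canadian children 8-14 y.
    coefficients:
      F: {c0: 1.1440, c1: 0.0610}
      M: {c0: 1.1660, c1: 0.0706}
  lohman:
    output: fat_percent
    transform: lohman_weight_age
    folds: [triceps, suprailiac]
    source: >
      Lohman TG and colleagues, fat-percentage prediction for American
      Indian children (Arizona, USA) from age, sex, body weight and the
      triceps + suprailiac fold sum. PROVISIONAL TRANSCRIPTION: the primary
      coefficient table could not be consulted directly; values below were
      fixed once to reproduce the output range this equation family gives
      in athletic adolescents and are the least certain entry in this
      registry (see docs/methods.md).
    coefficients:
      F: {intercept: 23.0, fold_sum: 0.23, weight: 0.33, age: -0.48}
      M: {intercept: 20.0, fold_sum: 0.23, weight: 0.33, age: -0.48}
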
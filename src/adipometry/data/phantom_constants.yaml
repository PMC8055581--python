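# Phantom reference-human constants and five-way fractionation partition.
#
# The Phantom is a unisex reference human (stature 170.18 cm) whose
# per-variable means (p) and SDs (s) allow dimensionally scaled z-scoring
# of any anthropometric measurement:
#
#   z = ( value * (170.18 / stature)^d  -  p ) / s
#
# with d the dimensional exponent (1 for lengths, girths and folds; 3 for
# masses).  Each tissue component (skin, adipose, muscle, bone, residual)
# averages the z-scores of its contributing variables and back-transforms
# through its phantom component mass:
#
#   mass = ( z_bar * s_mass + p_mass ) * (stature / 170.18)^3
#
# Muscle girths are corrected for the overlying subcutaneous fold
# (girth - pi * fold / 10, fold in mm, girth in cm) before z-scoring.
# Constants transcribed from the Phantom / five-way fractionation
# literature (Ross & Wilson reference tables; Kerr's five-way partition).
registry_version: "1.0"
phantom_stature: 170.18
variables:
  body_mass:                {p: 64.58, s: 8.60, dimension: 3}
  sitting_height:           {p: 89.92, s: 4.50, dimension: 1}
  skinfold_triceps:         {p: 15.4,  s: 4.47, dimension: 1}
  skinfold_subscapular:     {p: 17.2,  s: 5.07, dimension: 1}
  skinfold_supraspinale:    {p: 15.4,  s: 4.47, dimension: 1}
  skinfold_abdominal:       {p: 25.4,  s: 7.78, dimension: 1}
  skinfold_front_thigh:     {p: 27.0,  s: 8.33, dimension: 1}
  skinfold_medial_calf:     {p: 16.0,  s: 4.67, dimension: 1}
  girth_head:               {p: 56.00, s: 1.44, dimension: 1}
  girth_forearm:            {p: 25.13, s: 1.41, dimension: 1}
  girth_waist:              {p: 71.91, s: 4.45, dimension: 1}
  corrected_arm:            {p: 22.05, s: 1.91, dimension: 1}
  corrected_thigh:          {p: 47.34, s: 3.59, dimension: 1}
  corrected_calf:           {p: 30.22, s: 1.97, dimension: 1}
  corrected_chest:          {p: 82.46, s: 4.86, dimension: 1}
  breadth_biacromial:       {p: 38.04, s: 1.92, dimension: 1}
  breadth_biiliocristal:    {p: 28.84, s: 1.75, dimension: 1}
  breadth_humerus:          {p: 6.48,  s: 0.35, dimension: 1}
  breadth_femur:            {p: 9.52,  s: 0.48, dimension: 1}
  breadth_ap_chest:         {p: 17.50, s: 1.38, dimension: 1}
  breadth_transverse_chest: {p: 27.92, s: 1.74, dimension: 1}
# Fold-corrected girths: corrected = girth - pi * fold / 10
corrections:
  corrected_arm:   {girth: girth_relaxed_arm, fold: skinfold_triceps}
  corrected_thigh: {girth: girth_thigh,       fold: skinfold_front_thigh}
  corrected_calf:  {girth: girth_calf,        fold: skinfold_medial_calf}
  corrected_chest: {girth: girth_chest,       fold: skinfold_subscapular}
components:
  skin:
    p_mass: 3.64
    s_mass: 0.48
    variables: [body_mass]
  adipose:
    p_mass: 25.60
    s_mass: 5.85
    variables: [skinfold_triceps, skinfold_subscapular, skinfold_supraspinale,
                skinfold_abdominal, skinfold_front_thigh, skinfold_medial_calf]
  muscle:
    p_mass: 24.50
    s_mass: 3.44
    variables: [corrected_arm, girth_forearm, corrected_thigh,
                corrected_calf, corrected_chest]
  bone:
    p_mass: 10.49
    s_mass: 1.57
    variables: [girth_head, breadth_biacromial, breadth_biiliocristal,
                breadth_humerus, breadth_femur]
  residual:
    p_mass: 6.10
    s_mass: 1.24
    variables: [girth_waist, breadth_ap_chest, breadth_transverse_chest]
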
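"""Predict fat percentage for a few athletes with all five systems.

Builds a three-athlete table inline, runs the four skinfold equations and
the five-component fractionation, and prints one row per athlete.  The
four skinfold columns are fat percentages (% of body mass); adiposity is
the adipose-tissue mass fraction from the fractionation, and
five_component is that adiposity converted to a lipid-based fat
percentage through the Martin lipid fraction.
"""

from adipometry import AthleteRecord, Cohort, fractionate_cohort, predict_cohort

athletes = [
    AthleteRecord(
        id="swim_f_01", sex="F", age=14.8, body_mass=50.9, stature=160.5,
        sitting_height=84.0,
        skinfolds={"triceps": 14.0, "biceps": 7.0, "subscapular": 10.0,
                   "suprailiac": 12.0, "supraspinale": 7.5, "abdominal": 13.0,
                   "front_thigh": 21.0, "medial_calf": 11.5},
        girths={"head": 54.0, "relaxed_arm": 25.0, "forearm": 22.5,
                "thigh": 50.0, "calf": 33.5, "chest": 80.0, "waist": 66.0},
        breadths={"biacromial": 35.0, "biiliocristal": 27.0, "humerus": 6.0,
                  "femur": 8.9, "ap_chest": 16.0, "transverse_chest": 24.5},
    ),
    AthleteRecord(
        id="sprint_m_02", sex="M", age=15.2, body_mass=56.1, stature=168.3,
        sitting_height=87.5,
        skinfolds={"triceps": 9.0, "biceps": 5.0, "subscapular": 8.0,
                   "suprailiac": 8.0, "supraspinale": 5.5, "abdominal": 9.5,
                   "front_thigh": 11.5, "medial_calf": 7.0},
        girths={"head": 55.0, "relaxed_arm": 26.0, "forearm": 24.0,
                "thigh": 50.0, "calf": 34.5, "chest": 86.0, "waist": 71.0},
        breadths={"biacromial": 38.0, "biiliocristal": 27.5, "humerus": 6.7,
                  "femur": 9.4, "ap_chest": 17.5, "transverse_chest": 26.5},
    ),
    # no sitting height: the five-component column comes out unavailable
    AthleteRecord(
        id="judo_f_03", sex="F", age=13.5, body_mass=47.2, stature=155.0,
        skinfolds={"triceps": 16.0, "biceps": 8.0, "subscapular": 11.0,
                   "suprailiac": 13.5, "supraspinale": 9.0, "abdominal": 15.0,
                   "front_thigh": 23.0, "medial_calf": 12.5},
        girths={"head": 53.5, "relaxed_arm": 24.5, "forearm": 22.0,
                "thigh": 49.0, "calf": 33.0, "chest": 78.0, "waist": 64.0},
        breadths={"biacromial": 34.0, "biiliocristal": 26.5, "humerus": 5.9,
                  "femur": 8.7, "ap_chest": 15.5, "transverse_chest": 24.0},
    ),
]

cohort = Cohort(tuple(athletes), provenance="inline example")
table = predict_cohort(cohort)
frac = fractionate_cohort(cohort)
table["adiposity_percent"] = frac["adiposity_percent"]
table["five_component"] = frac["fat_percent"]

print(table.round(1).to_string())
print()
print("Each skinfold column is a predicted fat % of body mass; NaN marks an")
print("athlete whose measurements do not cover that system's inputs.")
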
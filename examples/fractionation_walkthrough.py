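"""Walk through the five-component fractionation and lipid conversion.

Fractionates one athlete into skin, adipose, muscle, bone and residual
masses via Phantom z-scoring, then follows the explicit five-step chain
that turns the adiposity percentage into a lipid-based fat percentage.
"""

from adipometry import AthleteRecord, fractionate, lipid_chain, phantom_z

record = AthleteRecord(
    id="swim_f_01", sex="F", age=14.8, body_mass=50.9, stature=160.5,
    sitting_height=84.0,
    skinfolds={"triceps": 14.0, "biceps": 7.0, "subscapular": 10.0,
               "suprailiac": 12.0, "supraspinale": 7.5, "abdominal": 13.0,
               "front_thigh": 21.0, "medial_calf": 11.5},
    girths={"head": 54.0, "relaxed_arm": 25.0, "forearm": 22.5,
            "thigh": 50.0, "calf": 33.5, "chest": 80.0, "waist": 66.0},
    breadths={"biacromial": 35.0, "biiliocristal": 27.0, "humerus": 6.0,
              "femur": 8.9, "ap_chest": 16.0, "transverse_chest": 24.5},
)
print(f"athlete {record.id}: {record.body_mass} kg, {record.stature} cm")

z = phantom_z(record.skinfolds["triceps"], record.stature, "skinfold_triceps")
print(f"triceps fold {record.skinfolds['triceps']} mm -> phantom z = {z:+.3f}")
print("(z < 0: thinner fold than the reference human at this stature)")

result = fractionate(record)
print("\ncomponent masses (kg):")
for comp, mass in result.masses.items():
    print(f"  {comp:<9s} {mass:6.2f}")
print(f"  structured sum {result.structured_mass_sum:6.2f}  (body mass {record.body_mass})")
print(f"adiposity: {result.adiposity_percent:.2f} % of body mass")

chain = lipid_chain(result.adiposity_percent, record.body_mass)
print("\nadiposity -> fat percentage, step by step:")
print(f"  1. adiposity            {chain.adiposity_percent:8.4f} %")
print(f"  2. fat (adipose) mass   {chain.fat_mass:8.4f} kg")
print(f"  3. lipid fraction       {chain.lipid_fraction:8.4f}   (0.327 + 0.0124 x %Adip)")
print(f"  4. lipid mass           {chain.lipid_mass:8.4f} kg")
print(f"  5. fat % of weight      {chain.fat_percent_weight:8.4f} %")
print("\nThe lipid fraction discounts the non-lipid part of adipose tissue,")
print("so the fat percentage is comparable with a DEXA fat estimate.")
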
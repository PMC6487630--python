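"""Allometric adiposity indices uncorrelated with height.

Regressing ln(adiposity measure) on ln(height) gives the power by which
height should be raised so the index measure/height^power carries no
height information: ~4 for fat mass (FMI), ~2 for fat-free mass (FFMI),
~3 for visceral and pericardial fat.
"""
from earlygrowth import SimConfig, simulate_cohort
from earlygrowth.indices import build_outcomes, estimate_power
from earlygrowth.pipeline import build_body_composition

cohort = simulate_cohort(SimConfig(n_children=3000, seed=5))
body = build_body_composition(cohort.wide)

for measure, col in (
    ("fat_mass", "fat_mass_kg"),
    ("fat_free_mass", "fat_free_mass_kg"),
    ("visceral_fat", "visceral_fat_g"),
    ("pericardial_fat", "pericardial_fat_g"),
):
    p = estimate_power(body[col], body["height_cm"] / 100.0, measure=measure)
    print(f"{measure:16s} slope {p.slope:5.2f} -> height^{p.rounded_power}; "
          f"index-height corr {p.decorrelation_corr:+.3f}  (n={p.n})")

panel = build_outcomes(body)
print("\noutcome panel medians:")
print(panel[["bmi", "fmi", "ffmi", "visceral_fat_index", "liver_fat_fraction"]].median().round(2).to_string())
# The SDS columns of the panel (log-transformed for the skewed measures)
# are the outcomes the association models use.
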
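"""Infant trajectory models: peak weight velocity and the adiposity peak.

The Reed1 curve W(t) = A + B t + C ln t + D/t (per sex, child offsets on
intercept and linear term) yields the peak weight velocity in closed form:
t* = 2D/C, PWV = B + C^2/(4D).  A cubic mixed model on log BMI over 2
weeks - 1.5 years yields the age (AGEAP) and BMI (BMIAP) at the adiposity
peak from the root of its derivative.
"""
from earlygrowth import SimConfig, simulate_cohort
from earlygrowth.anthro import bmi
from earlygrowth.trajectories import (
    adiposity_peak,
    fit_logbmi_cubic,
    fit_reed1,
    peak_weight_velocity,
    reed1_peak,
)

print("closed form: B=10, C=4, D=1 ->", reed1_peak(10.0, 4.0, 1.0))

cohort = simulate_cohort(SimConfig(n_children=1000, seed=4))
obs = cohort.observations.copy()
obs["age_yr"] = obs["age_mo"] / 12.0
fit = fit_reed1(obs, method="mixed")
peaks = peak_weight_velocity(fit)
print(f"mean PWV {peaks.pwv_kg_per_yr.mean():.1f} kg/y at median t* "
      f"{12 * peaks.t_peak_yr.median():.1f} months over {len(peaks)} children")

obs["bmi"] = bmi(obs["weight_kg"], obs["length_cm"])
cfit = fit_logbmi_cubic(obs)
ap = adiposity_peak(cfit)
ok = ap["flag"] == "interior"
print(f"median AGEAP {ap.loc[ok, 'ageap_mo'].median():.1f} months, "
      f"mean BMIAP {ap.loc[ok, 'bmiap'].mean():.1f} kg/m^2 "
      f"({ok.sum()} children with an interior peak)")
# PWV peaks in the first weeks of life; BMI peaks around 8-9 months before
# declining toward the school-age nadir.
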
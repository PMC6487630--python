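"""Closed-form anthropometric derivations.

Estimated fetal weight from ultrasound biometry (Hadlock head circumference /
abdominal circumference / femur length formula), body mass index, adipose
volume-to-mass conversion, and liver fat fraction aggregation.
"""
from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .errors import DomainError

#: Coefficients of the Hadlock HC/AC/FL estimated-fetal-weight formula:
#: log10(EFW [g]) = c0 + c_acfl*AC*FL + c_hc*HC + c_ac*AC + c_fl*FL, inputs in cm.
HADLOCK_COEF = {
    "intercept": 1.326,
    "ac_fl": -0.00326,
    "hc": 0.0107,
    "ac": 0.0438,
    "fl": 0.158,
}

#: Specific gravity of adipose tissue used to convert MRI fat volumes to mass.
ADIPOSE_TISSUE_DENSITY_G_PER_ML = 0.9

_GA_RANGE_WK = (10.0, 43.0)


def hadlock_log10_efw(
    head_circumference: np.ndarray,
    abdominal_circumference: np.ndarray,
    femur_length: np.ndarray,
    coef: dict[str, float] | None = None,
) -> np.ndarray:
    """log10 of estimated fetal weight in grams; biometry in cm. No validation."""
    c = HADLOCK_COEF if coef is None else coef
    hc = np.asarray(head_circumference, dtype=float)
    ac = np.asarray(abdominal_circumference, dtype=float)
    fl = np.asarray(femur_length, dtype=float)
    return c["intercept"] + c["ac_fl"] * ac * fl + c["hc"] * hc + c["ac"] * ac + c["fl"] * fl


def estimated_fetal_weight(
    head_circumference,
    abdominal_circumference,
    femur_length,
    gestational_age=None,
    coef: dict[str, float] | None = None,
):
    """Estimated fetal weight in grams from HC, AC and FL in centimetres.

    Missing (NaN) biometry propagates to a missing weight.  Nonpositive
    biometry, or a gestational age outside (10, 43) weeks when one is
    supplied, raises :class:`DomainError`.
    """
    hc = np.asarray(head_circumference, dtype=float)
    ac = np.asarray(abdominal_circumference, dtype=float)
    fl = np.asarray(femur_length, dtype=float)
    for name, arr in (("head circumference", hc), ("abdominal circumference", ac), ("femur length", fl)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise DomainError(f"nonpositive {name} supplied to estimated_fetal_weight")
    if gestational_age is not None:
        ga = np.asarray(gestational_age, dtype=float)
        bad = ~np.isnan(ga) & ((ga <= _GA_RANGE_WK[0]) | (ga >= _GA_RANGE_WK[1]))
        if np.any(bad):
            raise DomainError("gestational age outside (10, 43) weeks")
    efw = 10.0 ** hadlock_log10_efw(hc, ac, fl, coef)
    return efw if efw.ndim else float(efw)


def bmi(weight_kg, height_cm):
    """Body mass index: weight in kg divided by height in metres squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(h[~np.isnan(h)] <= 0):
        raise DomainError("nonpositive height supplied to bmi")
    out = w / (h / 100.0) ** 2
    return out if out.ndim else float(out)


def fat_volume_to_mass(volume_ml):
    """Convert an adipose tissue volume (mL) to mass (g) at 0.9 g/mL."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v[~np.isnan(v)] < 0):
        raise DomainError("negative fat volume")
    out = v * ADIPOSE_TISSUE_DENSITY_G_PER_ML
    return out if out.ndim else float(out)


def liver_fat_fraction(samples: Sequence[float]) -> float:
    """Mean liver fat fraction (%) over sampled hepatic regions.

    The acquisition standard takes four samples; any nonempty number of
    non-missing samples is averaged.
    """
    arr = np.asarray(samples, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise DomainError("liver_fat_fraction requires at least one non-missing sample")
    if np.any((arr < 0) | (arr > 100)):
        raise DomainError("liver fat fraction samples must lie in [0, 100] percent")
    return float(arr.mean())
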
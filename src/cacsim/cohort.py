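"""Synthetic study cohorts matched to the clinical population's marginals.

Each synthetic subject draws a target risk class from the study's observed
class mix (29.0 / 10.7 / 26.6 / 20.1 / 13.6 %), a BMI from a log-normal
matched to the study's median 26.1 and IQR 23.7-28.3 kg/m^2 (truncated to
the observed range 18.9-39.9), and a lesion set constructed to land the
noiseless 120 kVp Agatston score inside that class; the exact rasterized
score is verified and the subject is rejection-sampled until it matches.

Individual lesion anatomy (counts, areas, peak attenuations) is invented —
the study prints no per-lesion data — so simulated cohorts reproduce the
study's marginals, not its per-patient results.
"""

from __future__ import annotations

import math

import numpy as np

from . import study_data as sd
from .phantom import BLOOD_POOL_RADIUS_MM, LesionSpec, PatientPhantom
from .scoring import RiskClass, risk_class
from .volume import DEFAULT_MATRIX, DEFAULT_PIXEL_SPACING_MM

#: Slices per subject phantom: a thin slab (lesion slices + one for the
#: aortic ROI measurement); per-slice scoring makes the slab length a pure
#: cost knob, not a physics one.
DEFAULT_N_SLICES = 4

#: Target-score sampling windows per risk class (log-uniform within each).
#: They span essentially the whole class band — the study population is an
#: all-comer cohort (median CAC 42, IQR 0-199), so scores near class
#: boundaries are common and drive the observed reclassifications.  The
#: rejection check against the exact rasterized score keeps every accepted
#: subject inside its class.
_SCORE_WINDOWS = {
    RiskClass.LOW: (1.0, 10.4),
    RiskClass.MODERATE: (10.6, 100.4),
    RiskClass.HIGH: (100.6, 400.4),
    RiskClass.VERY_HIGH: (400.6, 1500.0),
}

#: Peak-HU sampling windows per density weight: the full 120 kVp threshold
#: band, trimmed by 1 HU so integer quantization cannot flip the planned
#: noiseless weight.
_PEAK_WINDOWS = {1: (131.0, 198.0), 2: (201.0, 298.0), 3: (301.0, 398.0), 4: (401.0, 990.0)}

_MIN_LESION_AREA = 1.6  # mm^2, safely above the 1 mm^2 detection rule


def _draw_bmi(rng: np.random.Generator) -> float:
    while True:
        bmi = float(np.exp(rng.normal(sd.BMI_LOG_MU, sd.BMI_LOG_SIGMA)))
        if sd.BMI_RANGE[0] <= bmi <= sd.BMI_RANGE[1]:
            return bmi


def _draw_lesion_plan(rng: np.random.Generator, target_score: float) -> list[tuple[int, float]]:
    """Split a target score into (density weight, area) lesion chunks."""
    if target_score < 12:
        return [(1, target_score)]  # one small weight-1 plaque
    heavy = target_score > 400
    w_probs = (0.15, 0.20, 0.25, 0.40) if heavy else (0.35, 0.30, 0.20, 0.15)
    max_area = 40.0 if heavy else 12.0
    plan: list[tuple[int, float]] = []
    remaining = target_score
    while remaining > 12 and len(plan) < 60:
        w = int(rng.choice((1, 2, 3, 4), p=w_probs))
        hi = min(max_area, remaining / w)
        if hi <= _MIN_LESION_AREA:
            break
        a = float(rng.uniform(_MIN_LESION_AREA, hi))
        plan.append((w, a))
        remaining -= w * a
    if remaining >= _MIN_LESION_AREA:
        plan.append((1, min(remaining, max_area)))
    return plan


def _place_lesions(
    rng: np.random.Generator,
    plan: list[tuple[int, float]],
    n_slices: int,
    pixel_spacing: float,
    matrix: int,
) -> list[LesionSpec] | None:
    """Place disc lesions in an annulus around (but clear of) the aorta.

    Returns None when a non-overlapping placement cannot be found.
    """
    center = matrix / 2.0
    pool_px = BLOOD_POOL_RADIUS_MM / pixel_spacing
    placed: list[tuple[int, float, float, float]] = []  # slice, row, col, radius_px
    lesions: list[LesionSpec] = []
    for w, area in plan:
        peak = float(rng.uniform(*_PEAK_WINDOWS[w]))
        radius_px = math.sqrt(area / math.pi) / pixel_spacing
        for _ in range(200):
            s = int(rng.integers(1, n_slices)) if n_slices > 1 else 0
            rho = float(rng.uniform(pool_px + radius_px + 12.0, matrix / 2.0 - radius_px - 8.0))
            theta = float(rng.uniform(0, 2 * math.pi))
            r = center + rho * math.sin(theta)
            c = center + rho * math.cos(theta)
            ok = all(
                s != s2 or math.hypot(r - r2, c - c2) > radius_px + rad2 + 3.0
                for s2, r2, c2, rad2 in placed
            )
            if ok:
                placed.append((s, r, c, radius_px))
                lesions.append(
                    LesionSpec(slice_index=s, center=(r, c), target_area=area, peak_hu_ref=peak)
                )
                break
        else:
            return None
    return lesions


def generate_subject(
    rng: np.random.Generator,
    target_class: RiskClass | None = None,
    n_slices: int = DEFAULT_N_SLICES,
    matrix: int = DEFAULT_MATRIX,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM,
    max_tries: int = 200,
) -> PatientPhantom:
    """Draw one synthetic subject, rejection-sampled until the noiseless
    120 kVp score falls in the target risk class."""
    if target_class is None:
        target_class = RiskClass(
            int(rng.choice(len(sd.RISK_CLASS_PROPORTIONS), p=sd.RISK_CLASS_PROPORTIONS))
        )
    bmi = _draw_bmi(rng)
    for _ in range(max_tries):
        if target_class == RiskClass.ZERO:
            lesions: list[LesionSpec] = []
        else:
            lo, hi = _SCORE_WINDOWS[target_class]
            target_score = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            plan = _draw_lesion_plan(rng, target_score)
            lesions = _place_lesions(rng, plan, n_slices, pixel_spacing, matrix) or []
            if plan and not lesions:
                continue
        phantom = PatientPhantom(
            lesions=lesions,
            bmi=bmi,
            aortic_roi_center=(0, matrix // 2, matrix // 2),
            grid=(n_slices, matrix, matrix),
            pixel_spacing=pixel_spacing,
        )
        if risk_class(phantom.noiseless_score()) == target_class:
            return phantom
    raise RuntimeError(f"could not realize a subject in class {target_class.label} after {max_tries} tries")


def generate_cohort(
    n: int,
    seed: int | np.random.Generator,
    n_slices: int = DEFAULT_N_SLICES,
    matrix: int = DEFAULT_MATRIX,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM,
) -> list[PatientPhantom]:
    """Generate ``n`` synthetic subjects; deterministic given the seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        generate_subject(rng, n_slices=n_slices, matrix=matrix, pixel_spacing=pixel_spacing)
        for _ in range(n)
    ]
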
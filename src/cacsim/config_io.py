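"""YAML read/write for phantom and cohort specifications.

Schema (one phantom)::

    bmi: 26.0
    grid: [4, 512, 512]
    pixel_spacing: 0.48828125
    slice_thickness: 2.5
    blood_pool_hu_ref: 48.5
    aortic_roi_center: [0, 256, 256]
    lesions:
      - {slice_index: 1, center: [200.0, 300.0], target_area: 4.0, peak_hu_ref: 320.0}

A cohort file holds ``subjects: [<phantom>, ...]`` plus an optional
``seed`` recording how it was generated.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .phantom import LesionSpec, PatientPhantom


def phantom_to_dict(phantom: PatientPhantom) -> dict:
    return {
        "bmi": float(phantom.bmi),
        "grid": list(phantom.grid),
        "pixel_spacing": float(phantom.pixel_spacing),
        "slice_thickness": float(phantom.slice_thickness),
        "blood_pool_hu_ref": float(phantom.blood_pool_hu_ref),
        "aortic_roi_center": list(phantom.aortic_roi_center),
        "lesions": [
            {
                "slice_index": int(l.slice_index),
                "center": [float(l.center[0]), float(l.center[1])],
                "target_area": float(l.target_area),
                "peak_hu_ref": float(l.peak_hu_ref),
            }
            for l in phantom.lesions
        ],
    }


def phantom_from_dict(data: dict) -> PatientPhantom:
    lesions = [
        LesionSpec(
            slice_index=l["slice_index"],
            center=tuple(l["center"]),
            target_area=l["target_area"],
            peak_hu_ref=l["peak_hu_ref"],
        )
        for l in data.get("lesions", [])
    ]
    return PatientPhantom(
        lesions=lesions,
        bmi=data.get("bmi", 26.0),
        aortic_roi_center=tuple(data["aortic_roi_center"]) if "aortic_roi_center" in data else (0, 256, 256),
        grid=tuple(data["grid"]) if "grid" in data else (4, 512, 512),
        pixel_spacing=data.get("pixel_spacing", 250.0 / 512.0),
        slice_thickness=data.get("slice_thickness", 2.5),
    )


def save_phantom(phantom: PatientPhantom, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(phantom_to_dict(phantom), fh, sort_keys=False)


def load_phantom(path: str | Path) -> PatientPhantom:
    with open(path) as fh:
        return phantom_from_dict(yaml.safe_load(fh))


def save_cohort(cohort: list[PatientPhantom], path: str | Path, seed: int | None = None) -> None:
    data: dict = {"subjects": [phantom_to_dict(p) for p in cohort]}
    if seed is not None:
        data["seed"] = int(seed)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_cohort(path: str | Path) -> list[PatientPhantom]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [phantom_from_dict(d) for d in data["subjects"]]
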
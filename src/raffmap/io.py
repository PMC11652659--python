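"""File formats: NIfTI image stacks with JSON sidecars, YAML run configs.

A weighted series is stored as a 3-D NIfTI volume with contrasts on the
last axis and a JSON sidecar listing the per-contrast preparation durations
in ms (the string ``"inf"`` marks the saturation image).  NIfTI has no
standard slot for preparation durations, hence the sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .mapping import Traff2Results, WeightedSeries


def _sidecar_path(nii_path) -> Path:
    p = Path(nii_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_series(series: WeightedSeries, nii_path, sidecar_path=None) -> None:
    """Write a weighted series as NIfTI (x, y, contrast) + JSON sidecar."""
    nii_path = Path(nii_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(nii_path)
    data = np.moveaxis(series.images, 0, -1)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(nii_path))
    prep = ["inf" if not math.isfinite(v) else float(v) for v in series.prep_ms]
    sidecar = {"prep_ms": prep}
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    if series.mask is not None:
        write_mask(series.mask, nii_path.with_name("mask_" + nii_path.name))


def read_series(nii_path, sidecar_path=None, mask=None) -> WeightedSeries:
    """Read a weighted series; errors if the contrast counts disagree."""
    nii_path = Path(nii_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(nii_path)
    data = np.asarray(nib.load(str(nii_path)).dataobj, dtype=float)
    sidecar = json.loads(Path(sidecar_path).read_text())
    prep = np.array([math.inf if str(v).lower() in ("inf", "infinity") else float(v)
                     for v in sidecar["prep_ms"]])
    n_img = data.shape[-1]
    if n_img != prep.size:
        raise ValueError(
            f"contrast-count mismatch: NIfTI has {n_img} images but sidecar "
            f"lists {prep.size} prep_ms entries"
        )
    images = np.moveaxis(data, -1, 0)
    return WeightedSeries(images=images, prep_ms=prep, mask=mask)


def write_map(img: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(img, dtype=float), affine=np.eye(4)), str(path))


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_mask(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4)),
             str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_fit_maps(results: Traff2Results, out_dir) -> dict:
    """Write traff2/a/b/sd/residual maps and flags to NIfTI files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in (("traff2", results.traff2_map), ("a", results.a_map),
                      ("b", results.b_map), ("sd", results.sd_map),
                      ("residual", results.residual_map)):
        p = out / f"{name}.nii"
        write_map(img, p)
        paths[name] = str(p)
    for name, img in results.flags.items():
        p = out / f"flag_{name}.nii"
        write_mask(img, p)
        paths[f"flag_{name}"] = str(p)
    return paths


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    pulse: dict = dataclasses.field(default_factory=dict)
    protocol: dict = dataclasses.field(default_factory=dict)
    phantom: dict = dataclasses.field(default_factory=dict)
    noise: dict = dataclasses.field(default_factory=dict)
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
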
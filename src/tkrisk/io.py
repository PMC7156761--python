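"""File interchange: NIfTI volumes/atlases, CSV subject tables, YAML specs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from tkrisk.synthetic import PhantomSpec, TissueAtlas, TissueSpec, records_to_frame

__all__ = [
    "save_volume",
    "load_volume",
    "save_atlas",
    "load_atlas",
    "save_subject_table",
    "load_spec",
    "save_spec",
]


def save_volume(array: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_atlas(atlas: TissueAtlas, path) -> None:
    """Label grid as NIfTI plus a sidecar ``<path>.labels.yaml`` name map."""
    img = nib.Nifti1Image(atlas.label_grid.astype(np.int16), np.eye(4))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    with open(f"{sidecar}.labels.yaml", "w") as fh:
        yaml.safe_dump({int(k): v for k, v in atlas.names.items()}, fh)


def load_atlas(path) -> TissueAtlas:
    grid = np.asarray(nib.load(str(path)).get_fdata()).astype(np.int32)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    with open(f"{sidecar}.labels.yaml") as fh:
        names = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    return TissueAtlas(label_grid=grid, names=names)


def save_subject_table(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def save_spec(spec: PhantomSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


def load_spec(path) -> PhantomSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["tissue_specs"] = [
        TissueSpec(
            name=t["name"], geometry=t["geometry"],
            center=tuple(t["center"]), radii=tuple(t["radii"]),
        )
        for t in raw.get("tissue_specs", [])
    ]
    for key in ("grid_shape", "visits_per_patient", "kl_probs",
                "koos_means", "koos_sds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomSpec(**raw)
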
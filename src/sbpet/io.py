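"""Subject-bundle NIfTI I/O.

One subject is a directory of co-registered NIfTI-1 volumes on a single
grid: ``mri``, ``pet``, ``mask``, ``gm``, ``wm``, ``csf`` (required) plus
``atlas`` and ``lesion`` (optional), each as ``<name>.nii.gz`` or
``<name>.nii``, with a JSON sidecar of the generating phantom parameters
when the subject is simulated.  Images are stored float32, masks uint8,
with RAS+ affines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .phantom import LesionSpec, PhantomParams, SubjectRecord
from .volume import Volume

__all__ = ["save_subject", "load_subject"]

_REQUIRED = ("mri", "pet", "mask", "gm", "wm", "csf")
_OPTIONAL = ("atlas", "lesion")
_MASK_NAMES = {"mask", "lesion"}


def _params_to_json(params: PhantomParams) -> dict:
    d = dataclasses.asdict(params)
    d["lesions"] = [dataclasses.asdict(l) for l in params.lesions]
    return d


def _params_from_json(d: dict) -> PhantomParams:
    lesions = tuple(LesionSpec(**{**l, "center": tuple(l["center"])}) for l in d.pop("lesions", []))
    d["uptake_ratios"] = tuple(d.get("uptake_ratios", (3.0, 1.0, 0.2)))
    d["mri_means_sds"] = tuple(tuple(x) for x in d.get("mri_means_sds", ()))
    return PhantomParams(lesions=lesions, **d)


def save_subject(record: SubjectRecord, out_dir, compress: bool = True) -> Path:
    """Write a subject bundle; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    for name, vol in record.volumes().items():
        dtype = np.uint8 if name in _MASK_NAMES else (np.int16 if name == "atlas" else np.float32)
        vol.save(out / f"{name}{ext}", dtype=dtype)
    sidecar = {"group": record.group}
    if record.params is not None:
        sidecar["params"] = _params_to_json(record.params)
    (out / "subject.json").write_text(json.dumps(sidecar, indent=2))
    return out


def _find(directory: Path, name: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        p = directory / f"{name}{ext}"
        if p.exists():
            return p
    return None


def load_subject(directory) -> SubjectRecord:
    """Load and validate a subject bundle.

    All volumes must share shape and affine (tolerance 1e-4 mm); masks are
    binarized; missing optional volumes are absent, not errors.
    """
    directory = Path(directory)
    vols: dict[str, Volume] = {}
    for name in _REQUIRED:
        path = _find(directory, name)
        if path is None:
            raise FileNotFoundError(f"missing required volume {name}.nii[.gz] in {directory}")
        vols[name] = Volume.load(path)
    for name in _OPTIONAL:
        path = _find(directory, name)
        if path is not None:
            vols[name] = Volume.load(path)

    ref_name = "mri"
    ref = vols[ref_name]
    for name, vol in vols.items():
        if vol.shape != ref.shape or not np.allclose(vol.affine, ref.affine, atol=1e-4):
            raise ValueError(
                f"{name}.nii[.gz] grid (shape {vol.shape}) does not match {ref_name} "
                f"(shape {ref.shape}) in {directory}"
            )
    for name in _MASK_NAMES & vols.keys():
        vols[name] = vols[name].with_data((vols[name].data > 0).astype(np.uint8))

    group, params = "CN", None
    sidecar = directory / "subject.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        group = meta.get("group", "CN")
        if "params" in meta:
            params = _params_from_json(meta["params"])

    return SubjectRecord(
        mri=vols["mri"],
        pet=vols["pet"],
        mask=vols["mask"],
        gm=vols["gm"],
        wm=vols["wm"],
        csf=vols["csf"],
        atlas=vols.get("atlas"),
        lesion_mask=vols.get("lesion"),
        group=group,
        params=params,
    )
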
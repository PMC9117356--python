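"""NIfTI / CSV / JSON input-output and provenance sidecars.

Volumes are NIfTI-1 (via nibabel).  Masks come in two dialects: a single
integer-labelled file (1=CE, 2=necrosis, 3=T2PZ, 4=GM, 5=WM, 6=CSF) or six
binary files; both load to the same :class:`~adctex.volume.MaskSet`.
Tables are plain UTF-8 CSV with '.' decimals.  Every written artifact gets
a JSON provenance sidecar (config hash, seed, package version) so equal
hashes imply equal outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import AdcVolume, MaskSet, MASK_NAMES

__all__ = [
    "LABEL_MAP",
    "read_adc",
    "read_masks",
    "read_subject",
    "write_subject",
    "write_table",
    "write_sidecar",
    "config_hash",
]

#: label value of each channel in the single-file mask dialect
LABEL_MAP = {name: i + 1 for i, name in enumerate(MASK_NAMES)}

_AFFINE_TOL = 1e-4


def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def read_adc(path: str | Path) -> AdcVolume:
    img = _load(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AdcVolume(values=data, spacing=spacing, affine=np.asarray(img.affine))


def _check_geometry(ref: nib.Nifti1Image, other: nib.Nifti1Image, a: str, b: str):
    if ref.shape[:3] != other.shape[:3]:
        raise ValueError(f"grid mismatch between {a} {ref.shape} and {b} {other.shape}")
    if not np.allclose(ref.affine, other.affine, atol=_AFFINE_TOL):
        raise ValueError(f"affine mismatch between {a} and {b}")


def read_masks(
    path_or_paths: str | Path | dict[str, str | Path],
    reference: nib.Nifti1Image | None = None,
) -> MaskSet:
    """Load masks from either dialect.

    A single path is read as an integer-labelled volume; a dict maps channel
    names (any subset of CE/necrosis/T2PZ/GM/WM/CSF; missing necrosis is an
    empty mask) to binary NIfTI files.  Non-binary values in a binary
    channel are rejected.
    """
    if isinstance(path_or_paths, (str, Path)):
        img = _load(path_or_paths)
        if reference is not None:
            _check_geometry(reference, img, "ADC", str(path_or_paths))
        labels = np.asarray(img.get_fdata())
        if not np.allclose(labels, np.round(labels)):
            raise ValueError(f"labelled mask {path_or_paths} has non-integer values")
        return MaskSet.from_label_volume(np.round(labels).astype(np.int16))
    channels: dict[str, np.ndarray] = {}
    for name, p in path_or_paths.items():
        if name not in MASK_NAMES:
            raise ValueError(f"unknown mask channel '{name}'")
        img = _load(p)
        if reference is not None:
            _check_geometry(reference, img, "ADC", str(p))
        data = np.asarray(img.get_fdata())
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError(
                f"mask '{name}' at {p} is not binary (values {uniq[:8]})"
            )
        channels[name] = data.astype(bool)
    missing = set(MASK_NAMES) - {"necrosis"} - set(channels)
    if missing:
        raise ValueError(f"missing mask channel(s): {sorted(missing)}")
    return MaskSet(**channels)


def read_subject(
    adc_path: str | Path,
    masks: str | Path | dict[str, str | Path],
) -> tuple[AdcVolume, MaskSet]:
    """Load one subject, enforcing grid/affine agreement."""
    img = _load(adc_path)
    adc = read_adc(adc_path)
    mask_set = read_masks(masks, reference=img)
    mask_set.check_consistent_with(adc)
    return adc, mask_set


def write_subject(
    out_dir: str | Path,
    subject_id: str,
    adc: AdcVolume,
    masks: MaskSet,
    labelled: bool = True,
) -> dict[str, Path]:
    """Write one subject's ADC map and masks; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = adc.affine if adc.affine is not None else np.diag([*adc.spacing, 1.0])
    paths: dict[str, Path] = {}
    adc_path = out_dir / f"{subject_id}_adc.nii.gz"
    nib.save(nib.Nifti1Image(adc.values.astype(np.float32), affine), str(adc_path))
    paths["adc"] = adc_path
    if labelled:
        p = out_dir / f"{subject_id}_masks.nii.gz"
        nib.save(nib.Nifti1Image(masks.to_label_volume(), affine), str(p))
        paths["masks"] = p
    else:
        for name in MASK_NAMES:
            p = out_dir / f"{subject_id}_mask_{name}.nii.gz"
            nib.save(
                nib.Nifti1Image(
                    getattr(masks, name).astype(np.uint8), affine
                ),
                str(p),
            )
            paths[f"mask_{name}"] = p
    return paths


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, lineterminator="\n")
    return path


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_sidecar(target: str | Path, config: dict, seed: int | None) -> Path:
    """JSON provenance sidecar next to ``target``."""
    from . import __version__

    target = Path(target)
    sidecar = target.with_name(target.name + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "config_hash": config_hash(config),
                "seed": seed,
                "package": "adctex",
                "version": __version__,
                "config": config,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
        + "\n"
    )
    return sidecar
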
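"""Core in-memory containers: the ADC volume and its co-registered mask set.

An ADC (apparent diffusion coefficient) map is a 3D scalar field in units of
1e-3 mm^2/s on a regular grid with physical voxel spacing.  All geometry in
the package is done in physical millimetres via the spacing; voxel indices
are 0-based in array order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdcVolume", "MaskSet", "MASK_NAMES"]

#: channel names in the fixed order used by labelled mask files (labels 1..6)
MASK_NAMES = ("ce", "necrosis", "t2pz", "gm", "wm", "csf")


@dataclass
class AdcVolume:
    """A 3D ADC map with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        ADC in 1e-3 mm^2/s.  Must be finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm, strictly positive.
    affine : ndarray or None
        Optional 4x4 voxel-to-world matrix, carried opaquely for I/O.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"ADC volume must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ADC volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("ADC volume contains negative values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class MaskSet:
    """Co-registered binary masks on a common grid.

    Channels: contrast-enhancing tumor (``ce``), necrotic core (``necrosis``),
    peritumoral T2-hyperintense zone (``t2pz``), gray matter (``gm``), white
    matter (``wm``) and CSF (``csf``).

    On construction, CE and necrotic voxels are removed from the T2PZ channel,
    so ``ce & t2pz`` and ``necrosis & t2pz`` are empty by construction — the
    peritumoral zone is defined as the non-enhancing, non-necrotic edema.
    A missing necrosis channel is treated as an empty mask.
    """

    ce: np.ndarray
    t2pz: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    necrosis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.necrosis is None:
            self.necrosis = np.zeros_like(np.asarray(self.ce), dtype=bool)
        for name in MASK_NAMES:
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 3:
                raise ValueError(f"mask '{name}' must be 3D")
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask '{name}' is not binary (values {uniq[:8]})")
            setattr(self, name, arr.astype(bool))
        shapes = {getattr(self, n).shape for n in MASK_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"masks disagree on grid shape: {sorted(shapes)}")
        # tumor and necrosis are excluded from the peritumoral zone
        self.t2pz = self.t2pz & ~self.ce & ~self.necrosis

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ce.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in MASK_NAMES}

    def check_consistent_with(self, adc: AdcVolume) -> None:
        if self.shape != adc.shape:
            raise ValueError(
                f"mask grid {self.shape} does not match ADC grid {adc.shape}"
            )

    def to_label_volume(self) -> np.ndarray:
        """Collapse the six channels into one integer label volume (1..6).

        Later channels overwrite earlier ones where masks overlap; with
        consistently built masks the tumor channels are disjoint, so only
        brain-tissue/tumor overlaps (e.g. edema inside WM) are affected and
        the tumor labels win because they are written last.
        """
        out = np.zeros(self.shape, dtype=np.int16)
        # write background tissue first so lesion compartments take precedence
        order = ("gm", "wm", "csf", "t2pz", "necrosis", "ce")
        for name in order:
            out[getattr(self, name)] = 1 + MASK_NAMES.index(name)
        return out

    @classmethod
    def from_label_volume(cls, labels: np.ndarray) -> "MaskSet":
        labels = np.asarray(labels)
        known = np.isin(labels, range(0, len(MASK_NAMES) + 1))
        if not known.all():
            bad = np.unique(labels[~known])
            raise ValueError(f"label volume contains unknown labels {bad[:8]}")
        channels = {
            name: labels == (i + 1) for i, name in enumerate(MASK_NAMES)
        }
        return cls(**channels)
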
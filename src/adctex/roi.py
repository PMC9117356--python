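"""Derivation of the three analysis compartments and the CSF-based voxel filter.

The three regions of interest are:

* the contrast-enhancing tumor (CE), with necrotic voxels removed,
* the peritumoral T2-hyperintense zone (T2PZ), already free of CE/necrosis,
* the tumor- and edema-free gray+white matter compartment (GMWMC),
  ``(GM | WM) \\ (CE | necrosis | T2PZ | CSF)``.

To suppress partial-volume contamination from CSF and non-brain voxels, each
subject gets an individual exclusion threshold derived from their own CSF
ADC distribution (mean minus two standard deviations); ROI voxels whose ADC
reaches that threshold are dropped before any statistic is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import AdcVolume, MaskSet

__all__ = [
    "RoiVoxels",
    "CsfStats",
    "roi_from_mask",
    "derive_gmwmc",
    "csf_reference_stats",
    "apply_csf_exclusion",
]


@dataclass
class RoiVoxels:
    """Voxels of one region of interest with their extracted ADC values.

    ``indices`` is an (n, 3) integer array of voxel coordinates in array
    order; ``values`` is aligned with it.  ``n_initial`` is the count before
    any CSF exclusion, ``n_retained`` after (equal until a filter runs).
    """

    name: str
    indices: np.ndarray
    values: np.ndarray
    n_initial: int
    n_retained: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.indices.shape[0] != self.values.shape[0]:
            raise ValueError("indices and values disagree in length")
        if self.n_retained > self.n_initial:
            raise ValueError("retained count exceeds initial count")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


@dataclass
class CsfStats:
    """Per-subject CSF ADC statistics and the derived exclusion threshold."""

    mean: float
    sd: float
    threshold: float  # mean - 2*sd
    estimator: str  # "sample" (n-1) or "population" (n)
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("CSF SD must be non-negative")


def roi_from_mask(
    adc: AdcVolume, mask: np.ndarray, name: str, exclude: np.ndarray | None = None
) -> RoiVoxels:
    """Extract a named ROI from a binary mask, optionally minus ``exclude``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != adc.shape:
        raise ValueError(f"ROI '{name}': mask shape {mask.shape} != ADC {adc.shape}")
    if exclude is not None:
        mask = mask & ~np.asarray(exclude, dtype=bool)
    idx = np.argwhere(mask)
    vals = adc.values[mask]
    n = idx.shape[0]
    return RoiVoxels(name=name, indices=idx, values=vals, n_initial=n, n_retained=n)


def derive_gmwmc(adc: AdcVolume, masks: MaskSet) -> RoiVoxels:
    """Tumor- and edema-free gray+white matter compartment.

    Returns ``(GM | WM) \\ (CE | necrosis | T2PZ | CSF)``; raises if the
    result is empty, because normalization would then be undefined.
    """
    masks.check_consistent_with(adc)
    keep = (masks.gm | masks.wm) & ~(masks.ce | masks.necrosis | masks.t2pz | masks.csf)
    roi = roi_from_mask(adc, keep, "gmwmc")
    if roi.is_empty:
        raise ValueError("empty GMWMC: no tumor- and edema-free brain voxels")
    return roi


def csf_reference_stats(
    adc: AdcVolume, masks: MaskSet, estimator: str = "sample"
) -> CsfStats:
    """Mean/SD of ADC over the subject's CSF mask and the exclusion threshold.

    ``estimator`` selects the SD denominator: ``"sample"`` (n-1, default) or
    ``"population"`` (n).  A single-voxel CSF mask yields SD 0 under either.
    """
    masks.check_consistent_with(adc)
    vals = adc.values[masks.csf]
    if vals.size == 0:
        raise ValueError("empty CSF mask: per-subject threshold cannot be determined")
    if estimator not in ("sample", "population"):
        raise ValueError(f"unknown SD estimator '{estimator}'")
    mean = float(vals.mean())
    if vals.size == 1:
        sd = 0.0
    else:
        sd = float(vals.std(ddof=1 if estimator == "sample" else 0))
    return CsfStats(
        mean=mean,
        sd=sd,
        threshold=mean - 2.0 * sd,
        estimator=estimator,
        n_voxels=int(vals.size),
    )


def apply_csf_exclusion(
    roi: RoiVoxels, csf: CsfStats, mode: str = "lower_bound"
) -> RoiVoxels:
    """Remove CSF-contaminated voxels from an ROI.

    Modes
    -----
    ``"lower_bound"`` (default)
        Drop voxels with ADC >= (CSF mean - 2 SD), i.e. any voxel whose
        diffusivity reaches the individual's CSF range.  This is the
        contamination-avoidance reading of the per-subject threshold.
    ``"outside_band"``
        Drop voxels outside [mean - 2 SD, mean + 2 SD] — the literal
        two-sided alternative; retains only CSF-like values and is offered
        for completeness, not as a sensible tumor-ROI filter.

    Idempotent: applying the same filter twice changes nothing.  Excluding
    every voxel yields an empty ROI (flagged downstream, not an error here).
    """
    if mode == "lower_bound":
        keep = roi.values < csf.threshold
    elif mode == "outside_band":
        keep = (roi.values >= csf.mean - 2.0 * csf.sd) & (
            roi.values <= csf.mean + 2.0 * csf.sd
        )
    else:
        raise ValueError(f"unknown CSF-exclusion mode '{mode}'")
    out = RoiVoxels(
        name=roi.name,
        indices=roi.indices[keep],
        values=roi.values[keep],
        n_initial=roi.n_initial,
        n_retained=int(keep.sum()),
    )
    if out.is_empty and not roi.is_empty:
        warnings.warn(
            f"CSF exclusion removed every voxel of ROI '{roi.name}'", stacklevel=2
        )
    return out
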
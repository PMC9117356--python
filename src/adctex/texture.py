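"""The 30-parameter imaging feature set.

First-order statistics (normalized mean and 5th-percentile ADC per region,
3D skewness/kurtosis), volumetric features, the ring-based ADC slope, and
direction-averaged 3D gray-level co-occurrence (Haralick) features of the
peritumoral ADC texture.

GLCM construction: ROI values are linearly quantized between the ROI minimum
and maximum into ``n_levels`` gray levels (default 64); co-occurrences are
counted for the 13 unique 3D direction offsets at voxel distance 1,
accumulated symmetrically, and each offset matrix is normalized to sum 1.
Each Haralick statistic is computed per offset and then averaged over the
offsets with at least one voxel pair ("mean" features).  Natural logarithms
throughout, with 0*log(0) = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import stats as sstats

from . import roi as roimod
from . import rings as ringmod
from .volume import AdcVolume, MaskSet

__all__ = [
    "GlcmSpec",
    "FeatureVector",
    "FEATURE_REGISTRY",
    "HARALICK_NAMES",
    "OFFSETS_3D_13",
    "first_order_stats",
    "roi_volume",
    "quantize",
    "glcm_3d",
    "haralick_features",
    "glcm_features",
    "extract_features",
]


def _load_registry() -> tuple[str, ...]:
    text = resources.files(__package__).joinpath("feature_registry.yaml").read_text()
    names = tuple(yaml.safe_load(text)["features"])
    assert len(names) == 30, f"feature registry must have 30 entries, has {len(names)}"
    return names


#: the canonical ordered names of the 30 imaging parameters
FEATURE_REGISTRY: tuple[str, ...] = _load_registry()

#: the 13 classic Haralick statistics, in registry order
HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)


def _unique_3d_offsets() -> tuple[tuple[int, int, int], ...]:
    """The 13 direction offsets: one of each +/- pair of 26-neighbours."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                o = (dx, dy, dz)
                if o == (0, 0, 0) or tuple(-c for c in o) in offs:
                    continue
                offs.append(o)
    return tuple(offs)


OFFSETS_3D_13 = _unique_3d_offsets()


@dataclass(frozen=True)
class GlcmSpec:
    """Construction parameters for the 3D co-occurrence matrices."""

    n_levels: int = 64
    distance: int = 1
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_3D_13
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.distance < 1:
            raise ValueError("offset distance must be >= 1")
        if any(o == (0, 0, 0) for o in self.offsets):
            raise ValueError("zero offset is not allowed")


@dataclass
class FeatureVector:
    """The 30 named imaging parameters for one subject.

    ``values`` always holds every registry name; degenerate regions yield
    NaN entries, recorded in ``missing`` with a reason.
    """

    subject_id: str
    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_REGISTRY:
            raise ValueError("feature names/order do not match the registry")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_REGISTRY])


# ---------------------------------------------------------------------------
# first-order and volumetric features


def first_order_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, 5th percentile (linear interpolation), 3D skewness and kurtosis.

    Skewness is the third standardized central moment m3/m2^1.5 and kurtosis
    is excess (Fisher) kurtosis m4/m2^2 - 3, both on the biased moment
    estimators.  Constant input leaves both NaN with a warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("first_order_stats needs at least one value")
    out = {
        "mean": float(values.mean()),
        "p5": float(np.percentile(values, 5.0)),
    }
    if values.size < 2 or np.ptp(values) == 0:
        warnings.warn("zero variance: skewness/kurtosis undefined", stacklevel=2)
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    else:
        out["skewness"] = float(sstats.skew(values, bias=True))
        out["kurtosis"] = float(sstats.kurtosis(values, fisher=True, bias=True))
    return out


def roi_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume in cm^3 (voxel count x voxel volume)."""
    mask = np.asarray(mask, dtype=bool)
    voxel_mm3 = float(np.prod(spacing))
    return float(mask.sum()) * voxel_mm3 / 1000.0


# ---------------------------------------------------------------------------
# gray-level co-occurrence


def quantize(
    volume: np.ndarray, roi_mask: np.ndarray, spec: GlcmSpec
) -> np.ndarray:
    """Linear min-max quantization of ROI voxels into levels 0..n_levels-1.

    Returns an integer volume with -1 outside the ROI (never paired).  A
    constant ROI cannot be binned and raises ``ValueError("degenerate
    quantization")``.
    """
    volume = np.asarray(volume, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    vals = volume[roi_mask]
    if vals.size == 0:
        raise ValueError("degenerate quantization: empty ROI")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("degenerate quantization: constant ROI")
    levels = np.full(volume.shape, -1, dtype=np.int64)
    scaled = (volume[roi_mask] - lo) / (hi - lo) * spec.n_levels
    levels[roi_mask] = np.minimum(scaled.astype(np.int64), spec.n_levels - 1)
    return levels


def glcm_3d(levels: np.ndarray, spec: GlcmSpec) -> dict[str, np.ndarray]:
    """Co-occurrence matrices for every offset of ``spec``.

    ``levels`` is a quantized volume with -1 marking non-ROI voxels.  For
    each offset d, pairs (v, v + distance*d) with both endpoints in the ROI
    are counted; with ``symmetric`` both orders are accumulated.  Returns
    integer count matrices ``counts`` of shape (n_offsets, Ng, Ng),
    normalized matrices ``p`` (rows of all-zero matrices stay zero), and a
    boolean ``valid`` flag per offset (any pair present).
    """
    levels = np.asarray(levels)
    ng = spec.n_levels
    n_off = len(spec.offsets)
    counts = np.zeros((n_off, ng, ng), dtype=np.int64)
    for k, off in enumerate(spec.offsets):
        d = tuple(c * spec.distance for c in off)
        src, dst = _offset_slices(levels.shape, d)
        a = levels[src]
        b = levels[dst]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            flat = a[ok].astype(np.int64) * ng + b[ok]
            cm = np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
            counts[k] = cm + cm.T if spec.symmetric else cm
    totals = counts.sum(axis=(1, 2))
    valid = totals > 0
    p = np.zeros_like(counts, dtype=float)
    p[valid] = counts[valid] / totals[valid, None, None]
    return {"counts": counts, "p": p, "valid": valid}


def _offset_slices(shape, d):
    src, dst = [], []
    for n, step in zip(shape, d):
        if step >= 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 13 classic Haralick statistics of one normalized GLCM.

    Natural logarithm; 0*log 0 = 0.  Correlation and the information
    measures are NaN for degenerate marginals (zero variance/entropy).
    Sum variance is centred on the sum average.
    """
    p = np.asarray(p, dtype=float)
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    # marginal distributions of i+j and |i-j|
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(
            ((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
        )
    else:
        correlation = float("nan")
    variance = float(((ii - mu_x) ** 2 * p).sum())  # sum-of-squares variance
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlogx(p_sum).sum())
    entropy = float(-_xlogx(p).sum())
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = float(-_xlogx(p_diff).sum())

    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log(pxy), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else float("nan")
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def glcm_features(glcm: dict[str, np.ndarray]) -> dict[str, float]:
    """Direction-averaged Haralick features over the valid offsets."""
    valid = np.asarray(glcm["valid"])
    if not valid.any():
        warnings.warn("no offset produced a voxel pair: GLCM features missing",
                      stacklevel=2)
        return {name: float("nan") for name in HARALICK_NAMES}
    per_offset = [haralick_features(m) for m, ok in zip(glcm["p"], valid) if ok]
    out = {}
    for name in HARALICK_NAMES:
        vals = np.array([f[name] for f in per_offset])
        # NaN from a degenerate marginal in one direction should not poison
        # the average if other directions are informative
        out[name] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
    return out


# ---------------------------------------------------------------------------
# full extraction


def extract_features(
    adc: AdcVolume,
    masks: MaskSet,
    subject_id: str = "subject",
    glcm_spec: GlcmSpec | None = None,
    csf_exclusion: str = "lower_bound",
    csf_sd_estimator: str = "sample",
    apply_exclusion_to_gmwmc: bool = True,
    kurtosis_convention: str = "fisher",
) -> FeatureVector:
    """Compute the full 30-parameter vector for one subject.

    Pipeline: derive CE (minus necrosis), T2PZ and GMWMC; per-subject CSF
    stats and voxel exclusion; normalization of CE/T2PZ/ring values by the
    GMWMC mean ADC; GMWMC's own mean and 5th percentile are normalized by
    the subject's mean CSF ADC (dividing the GMWMC mean by itself would be
    constant); ring partition of the retained T2PZ voxels; ADC slope on the
    raw ADC scale; 3D skewness/kurtosis of normalized T2PZ values; and the
    13 direction-averaged GLCM features of the quantized T2PZ ADC texture.

    Degenerate regions produce NaN entries (recorded in ``missing``); the
    vector always carries all 30 names.
    """
    glcm_spec = glcm_spec or GlcmSpec()
    masks.check_consistent_with(adc)
    values: dict[str, float] = {name: float("nan") for name in FEATURE_REGISTRY}
    missing: dict[str, str] = {}

    gmwmc = roimod.derive_gmwmc(adc, masks)
    csf = roimod.csf_reference_stats(adc, masks, estimator=csf_sd_estimator)

    ce = roimod.roi_from_mask(adc, masks.ce, "ce", exclude=masks.necrosis)
    t2pz = roimod.roi_from_mask(adc, masks.t2pz, "t2pz")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ce = roimod.apply_csf_exclusion(ce, csf, mode=csf_exclusion)
        t2pz = roimod.apply_csf_exclusion(t2pz, csf, mode=csf_exclusion)
        if apply_exclusion_to_gmwmc:
            gmwmc = roimod.apply_csf_exclusion(gmwmc, csf, mode=csf_exclusion)
    if gmwmc.is_empty:
        raise ValueError("empty GMWMC after CSF exclusion: normalization undefined")
    gmwmc_mean = float(gmwmc.values.mean())
    if gmwmc_mean <= 0:
        raise ValueError("non-positive GMWMC mean ADC")

    def set_norm_pair(tag: str, vals: np.ndarray, ref: float) -> None:
        if vals.size == 0:
            missing[f"norm_mean_adc_{tag}"] = "empty ROI"
            missing[f"norm_p5_adc_{tag}"] = "empty ROI"
            return
        values[f"norm_mean_adc_{tag}"] = float(vals.mean()) / ref
        values[f"norm_p5_adc_{tag}"] = float(np.percentile(vals, 5.0)) / ref

    set_norm_pair("ce", ce.values, gmwmc_mean)
    set_norm_pair("t2pz", t2pz.values, gmwmc_mean)
    # GMWMC standardized against the individual's CSF mean ADC
    set_norm_pair("gmwmc", gmwmc.values, csf.mean)

    values["volume_ce_cm3"] = roi_volume(masks.ce, adc.spacing)
    values["volume_t2pz_cm3"] = roi_volume(masks.t2pz, adc.spacing)

    # ring decomposition of the retained peritumoral voxels
    ring_tags = [f"ring{r}" for r in range(1, ringmod.N_RINGS + 1)]
    if t2pz.is_empty:
        for tag in ring_tags:
            missing[f"norm_mean_adc_{tag}"] = "empty T2PZ"
            missing[f"norm_p5_adc_{tag}"] = "empty T2PZ"
        missing["adc_slope"] = "empty T2PZ"
    else:
        rings = ringmod.ring_partition(masks, adc.spacing, voxels=t2pz)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = ringmod.ring_means_and_slope(t2pz.values, rings)
        for r, tag in enumerate(ring_tags, start=1):
            set_norm_pair(tag, t2pz.values[rings.labels == r], gmwmc_mean)
        if np.isnan(profile.slope):
            missing["adc_slope"] = "fewer than two non-empty rings"
        else:
            values["adc_slope"] = profile.slope

    # distribution shape and co-occurrence texture of the peritumoral zone
    if t2pz.is_empty:
        missing["skewness_3d_t2pz"] = "empty T2PZ"
        missing["kurtosis_3d_t2pz"] = "empty T2PZ"
        for name in HARALICK_NAMES:
            missing[f"glcm_mean_{name}"] = "empty T2PZ"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fo = first_order_stats(t2pz.values / gmwmc_mean)
        values["skewness_3d_t2pz"] = fo["skewness"]
        kurt = fo["kurtosis"]
        if kurtosis_convention == "pearson" and not np.isnan(kurt):
            kurt += 3.0
        values["kurtosis_3d_t2pz"] = kurt
        if np.isnan(fo["skewness"]):
            missing["skewness_3d_t2pz"] = "constant T2PZ values"
            missing["kurtosis_3d_t2pz"] = "constant T2PZ values"
        t2pz_mask = np.zeros(adc.shape, dtype=bool)
        t2pz_mask[t2pz.indices[:, 0], t2pz.indices[:, 1], t2pz.indices[:, 2]] = True
        try:
            levels = quantize(adc.values, t2pz_mask, glcm_spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tex = glcm_features(glcm_3d(levels, glcm_spec))
            for name, val in tex.items():
                values[f"glcm_mean_{name}"] = val
                if np.isnan(val):
                    missing[f"glcm_mean_{name}"] = "degenerate co-occurrence"
        except ValueError as exc:
            for name in HARALICK_NAMES:
                missing[f"glcm_mean_{name}"] = str(exc)

    return FeatureVector(subject_id=subject_id, values=values, missing=missing)
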
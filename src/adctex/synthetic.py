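"""Synthetic brain-metastasis phantoms and survival cohorts with known truth.

The phantom is deliberately simple: a cuboid brain of white matter with a
gray-matter slab, a planar CSF rim plus an ellipsoidal ventricle, and a
concentric tumor complex (necrotic core inside a contrast-enhancing sphere
inside a peritumoral edema shell) embedded in the white matter.  Every ROI
volume has a closed form, so geometric behaviour downstream is testable
against analytic values.  Voxel ADC values are drawn per compartment from a
normal distribution truncated at zero; an optional linear radial gradient
across the edema gives the ring/slope stage a known ground truth.

Survival times are linked to imaging features through a proportional-hazards
model with an exponential baseline: subject hazard is
``baseline_rate * exp(sum_i beta_i * z_i)``, with ``z_i`` either computed
from the subject's generated volume (image-backed cohorts) or drawn as
standard-normal feature scores (feature-level cohorts for large statistical
simulations).  Censoring is independent exponential, tuned to an expected
censored fraction.

Default compartment ADC means (WM 0.75, GM 0.85, CSF 3.0, CE 1.0, necrosis
2.0, edema 1.4, all 1e-3 mm^2/s) are package defaults from textbook ranges
and are fully overridable; they are stand-ins, not measured cohort values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import texture
from .volume import AdcVolume, MaskSet

__all__ = [
    "CompartmentAdc",
    "PhantomConfig",
    "CohortConfig",
    "generate_phantom",
    "generate_cohort",
    "simulate_feature_cohort",
    "simulate_survival",
    "DEFAULT_ADC",
]

#: textbook-range default ADC mean/SD per compartment, 1e-3 mm^2/s
DEFAULT_ADC = {
    "wm": (0.75, 0.05),
    "gm": (0.85, 0.05),
    "csf": (3.0, 0.10),
    "ce": (1.0, 0.10),
    "necrosis": (2.0, 0.15),
    "t2pz": (1.4, 0.10),
}

_DSGPA_LEVELS = ("I", "II", "III")  # I = 0-1.5 (worst) .. III = 3.0-4.0 (best)
_RPA_LEVELS = ("I", "II", "III")  # I = best prognosis


@dataclass(frozen=True)
class CompartmentAdc:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("compartment ADC mean must be positive")
        if self.sd < 0:
            raise ValueError("compartment ADC SD must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity model of one synthetic subject.

    Radii are physical mm.  The contrast-enhancing radius must exceed 5 mm
    (lesions of diameter <= 1 cm are below the size floor of the intended
    use case and are rejected), and the edema outer radius must exceed the
    CE radius.  ``t2pz_gradient`` adds ``g * (distance from the CE surface)``
    to the edema mean, in 1e-3 mm^2/s per mm.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ce_radius_mm: float = 6.0
    t2pz_radius_mm: float = 15.0
    necrosis_radius_mm: float = 2.0
    adc: dict[str, CompartmentAdc] = field(
        default_factory=lambda: {
            k: CompartmentAdc(*v) for k, v in DEFAULT_ADC.items()
        }
    )
    t2pz_gradient: float = 0.0
    csf_slab_voxels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.ce_radius_mm <= 5.0:
            raise ValueError(
                "CE radius must exceed 5 mm (lesion diameter must exceed 1 cm)"
            )
        if self.t2pz_radius_mm <= self.ce_radius_mm:
            raise ValueError("T2PZ outer radius must exceed the CE radius")
        if not 0 <= self.necrosis_radius_mm < self.ce_radius_mm:
            raise ValueError("necrosis radius must lie inside the CE sphere")
        missing = set(DEFAULT_ADC) - set(self.adc)
        if missing:
            raise ValueError(f"missing ADC settings for compartments {sorted(missing)}")


@dataclass(frozen=True)
class CohortConfig:
    """A cohort of image-backed subjects with hazard-linked survival."""

    n_subjects: int = 40
    base_phantom: PhantomConfig = field(default_factory=PhantomConfig)
    ce_radius_range: tuple[float, float] = (5.5, 9.0)
    # edema thickness (outer radius - CE radius); the lower bound keeps all
    # three 3-mm rings populated so every subject has a defined ADC slope
    t2pz_margin_range: tuple[float, float] = (6.5, 12.0)
    adc_mean_jitter: float = 0.05  # relative SD of per-subject compartment means
    betas: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 1.0 / 12.0  # events per month
    censoring_target: float = 0.2
    dsgpa_probs: tuple[float, float, float] = (0.3, 0.45, 0.25)
    rpa_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if not 0 <= self.censoring_target < 1:
            raise ValueError("censoring target must be in [0, 1)")
        for probs in (self.dsgpa_probs, self.rpa_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"group probabilities must sum to 1, got {probs}")
        unknown = set(self.betas) - set(texture.FEATURE_REGISTRY)
        if unknown:
            raise ValueError(
                f"unknown feature name(s) in betas: {sorted(unknown)}; "
                f"valid names: {list(texture.FEATURE_REGISTRY)}"
            )


# ---------------------------------------------------------------------------
# phantom


def generate_phantom(config: PhantomConfig) -> tuple[AdcVolume, MaskSet]:
    """Build one subject: concentric tumor complex in a two-tissue brain.

    Deterministic for a fixed config (seed included): identical seeds give
    bit-identical volumes and masks.  Raises if the tumor complex or the
    fixed brain furniture does not fit inside the grid.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    sp = np.asarray(config.spacing, dtype=float)

    # physical coordinates of voxel centers
    axes = [np.arange(n) * s for n, s in zip(shape, sp)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")

    extent = [(n - 1) * s for n, s in zip(shape, sp)]
    slab = config.csf_slab_voxels
    if slab < 1 or slab * 3 >= shape[0]:
        raise ValueError("CSF slab does not fit along axis 0")

    # brain cuboid: everything except a one-voxel air margin
    brain = np.ones(shape, dtype=bool)

    # planar CSF slab at the low-x face; gray-matter slab next to it
    x_idx = np.arange(shape[0])[:, None, None]
    csf = np.broadcast_to(x_idx < slab, shape).copy()
    gm = np.broadcast_to((x_idx >= slab) & (x_idx < 2 * slab), shape).copy()

    # tumor complex centred in the white-matter block
    center = np.array(
        [
            (2 * slab * sp[0] + extent[0]) / 2.0,
            extent[1] / 2.0,
            extent[2] / 2.0,
        ]
    )
    r = np.sqrt(
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    )
    r_t2 = config.t2pz_radius_mm
    lo_x = 2 * slab * sp[0]
    margins = {
        "x_low": center[0] - lo_x,
        "x_high": extent[0] - center[0],
        "y": min(center[1], extent[1] - center[1]),
        "z": min(center[2], extent[2] - center[2]),
    }
    for name, avail in margins.items():
        if r_t2 >= avail:
            raise ValueError(
                f"T2PZ outer radius {r_t2} mm does not fit: only {avail:.1f} mm "
                f"available along {name}"
            )

    necrosis = r <= config.necrosis_radius_mm if config.necrosis_radius_mm > 0 else np.zeros(shape, bool)
    ce = (r <= config.ce_radius_mm) & ~necrosis
    t2pz = (r > config.ce_radius_mm) & (r <= r_t2)

    # ellipsoidal ventricle in the far corner of the white matter, clear of the tumor
    vent_center = np.array([extent[0] * 0.82, extent[1] * 0.2, extent[2] * 0.2])
    vent_semi = np.array([5.0, 4.0, 4.0])
    vent = (
        ((xx - vent_center[0]) / vent_semi[0]) ** 2
        + ((yy - vent_center[1]) / vent_semi[1]) ** 2
        + ((zz - vent_center[2]) / vent_semi[2]) ** 2
    ) <= 1.0
    if (vent & (r <= r_t2)).any():
        raise ValueError("ventricle overlaps the tumor complex; enlarge the grid")
    csf = csf | vent

    tumor = ce | necrosis | t2pz
    gm = gm & ~tumor & ~csf
    wm = brain & ~gm & ~csf & ~tumor

    adc_vals = np.zeros(shape, dtype=float)
    comp_masks = {
        "wm": wm, "gm": gm, "csf": csf, "ce": ce,
        "necrosis": necrosis, "t2pz": t2pz,
    }
    for name, mask in comp_masks.items():
        n = int(mask.sum())
        if n == 0:
            continue
        c = config.adc[name]
        draws = rng.normal(c.mean, c.sd, size=n) if c.sd > 0 else np.full(n, c.mean)
        if name == "t2pz" and config.t2pz_gradient != 0.0:
            draws = draws + config.t2pz_gradient * (r[mask] - config.ce_radius_mm)
        adc_vals[mask] = np.maximum(draws, 0.0)

    adc = AdcVolume(values=adc_vals, spacing=tuple(sp), affine=np.diag([*sp, 1.0]))
    masks = MaskSet(ce=ce, necrosis=necrosis, t2pz=t2pz, gm=gm, wm=wm, csf=csf)
    return adc, masks


# ---------------------------------------------------------------------------
# survival linkage


def simulate_survival(
    linear_predictor: np.ndarray,
    baseline_rate: float,
    censoring_target: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-baseline proportional-hazards survival with censoring.

    Event times ~ Exp(rate = baseline_rate * exp(lp)); censoring times are
    independent Exp with rate chosen so a null-model subject is censored
    with probability ``censoring_target``.  Returns (time, event).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    rate = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censoring_target > 0:
        c_rate = baseline_rate * censoring_target / (1.0 - censoring_target)
        t_cens = rng.exponential(1.0 / c_rate, size=lp.shape)
    else:
        t_cens = np.full(lp.shape, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against zero survival time in months resolution
    time = np.maximum(time, 1e-6)
    return time, event


def _clinical_frame(
    n: int,
    time: np.ndarray,
    event: np.ndarray,
    dsgpa_probs,
    rpa_probs,
    rng: np.random.Generator,
) -> pd.DataFrame:
    dsgpa = rng.choice(_DSGPA_LEVELS, size=n, p=list(dsgpa_probs))
    rpa = rng.choice(_RPA_LEVELS, size=n, p=list(rpa_probs))
    age = rng.normal(62.0, 11.0, size=n).clip(18, 95).round(1)
    kps = rng.choice([">70", "<70"], size=n, p=[0.8, 0.2])
    extracranial = rng.choice([1, 0], size=n, p=[0.7, 0.3])
    systemic = rng.choice(
        ["progressive", "stable", "response"], size=n, p=[0.6, 0.3, 0.1]
    )
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "os_months": time,
            "event": event,
            "dsgpa_group": dsgpa,
            "rpa_class": rpa,
            "age": age,
            "kps": kps,
            "extracranial": extracranial,
            "systemic_status": systemic,
        }
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[tuple[AdcVolume, MaskSet]], pd.DataFrame, pd.DataFrame]:
    """Image-backed cohort: phantoms, their feature table, and clinical data.

    Per-subject geometry and compartment means are sampled from the config
    ranges; each subject's 30 features are computed from the generated
    volume, and survival is drawn with hazard proportional to
    ``exp(sum beta_i * feature_i)`` (features standardized across the cohort
    before entering the hazard so the betas are per-SD effects).

    Returns ``(subjects, features, clinical)`` where ``features`` is one row
    per subject indexed like ``clinical``.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=config.n_subjects)
    subjects: list[tuple[AdcVolume, MaskSet]] = []
    rows = []
    for i in range(config.n_subjects):
        sub_rng = np.random.default_rng(seeds[i])
        ce_r = sub_rng.uniform(*config.ce_radius_range)
        t2_r = ce_r + sub_rng.uniform(*config.t2pz_margin_range)
        adc_cfg = {
            name: CompartmentAdc(
                mean=c.mean * (1.0 + config.adc_mean_jitter * sub_rng.standard_normal()),
                sd=c.sd,
            )
            for name, c in config.base_phantom.adc.items()
        }
        pcfg = replace(
            config.base_phantom,
            ce_radius_mm=ce_r,
            t2pz_radius_mm=t2_r,
            necrosis_radius_mm=min(config.base_phantom.necrosis_radius_mm, 0.5 * ce_r),
            adc=adc_cfg,
            seed=int(seeds[i]),
        )
        adc, masks = generate_phantom(pcfg)
        subjects.append((adc, masks))
        fv = texture.extract_features(adc, masks, subject_id=f"S{i:04d}")
        rows.append(fv.values)
    features = pd.DataFrame(rows, index=[f"S{i:04d}" for i in range(config.n_subjects)])
    features.index.name = "subject_id"

    lp = np.zeros(config.n_subjects)
    for name, beta in config.betas.items():
        col = features[name].to_numpy()
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lp += beta * z
    time, event = simulate_survival(
        lp, config.baseline_rate, config.censoring_target, rng
    )
    clinical = _clinical_frame(
        config.n_subjects, time, event, config.dsgpa_probs, config.rpa_probs, rng
    )
    return subjects, features, clinical


def simulate_feature_cohort(
    n_subjects: int,
    betas: dict[str, float],
    noise_features: int = 0,
    baseline_rate: float = 1.0 / 12.0,
    censoring_target: float = 0.2,
    dsgpa_probs=(0.3, 0.45, 0.25),
    rpa_probs=(0.25, 0.5, 0.25),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level cohort for large statistical simulations.

    Feature scores are i.i.d. standard normal (named effect features plus
    ``noise_features`` numbered null columns); survival uses the same
    proportional-hazards linkage as the image-backed generator but skips
    volume synthesis, making thousands of subjects cheap.  Returns
    ``(features, clinical)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(betas) + [f"noise_{j}" for j in range(noise_features)]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    X = rng.standard_normal((n_subjects, len(names)))
    features = pd.DataFrame(
        X, columns=names, index=[f"S{i:04d}" for i in range(n_subjects)]
    )
    features.index.name = "subject_id"
    lp = X[:, : len(betas)] @ np.array(list(betas.values())) if betas else np.zeros(n_subjects)
    time, event = simulate_survival(lp, baseline_rate, censoring_target, rng)
    clinical = _clinical_frame(n_subjects, time, event, dsgpa_probs, rpa_probs, rng)
    return features, clinical
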
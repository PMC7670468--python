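"""Synthetic phantom cohorts for the post-conization residual-disease study.

Each phantom case carries a T2-weighted volume, a b=0/b=800 DWI pair
consistent with a prescribed ADC field, uterus and conization-cavity
masks, a residual/nonresidual label, a noisy positive-margin flag, and a
censored follow-up record. Geometry is deliberately minimal: the uterus
is an ellipsoid and the conization cavity a cone-like frustum removed
from its inferior pole, which is exactly the containment structure
(uterus ⊃ cavity ⊃ margin band) the VOI builder needs.

The residual class differs from the nonresidual class only inside the
band of tissue adjacent to the cavity surface, where it receives
spatially correlated noise of shorter correlation length and higher
amplitude, plus a lowered ADC level; both contrasts scale linearly with
``texture_effect``, so ``texture_effect = 0`` produces two statistically
identical classes (the null configuration) while the default 1.0 is the
"strong" preset used for the end-to-end study.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, MaskSet

__all__ = ["PhantomConfig", "PhantomCase", "generate_cohort", "perturb_segmentation", "write_cohort"]

#: texture_effect at or above this is the documented "strong" preset
TEXTURE_EFFECT_STRONG = 1.0


@dataclass
class PhantomConfig:
    """Phantom-cohort parameters.

    Defaults mirror the study conditions: 110 hysterectomy-cohort cases
    with ~32% residual prevalence, 36-month administrative censoring, a
    positive-margin flag with ~0.65 sensitivity / ~0.70 specificity
    against the residual label, and 1 x 1 x 3 mm voxels.
    """

    n_cases: int = 110
    residual_fraction: float = 35 / 110
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    texture_effect: float = TEXTURE_EFFECT_STRONG
    #: mean ADC (mm^2/s) for (residual lesion tissue, normal tissue)
    adc_levels: tuple[float, float] = (1.0e-3, 1.4e-3)
    noise_sd: float = 0.05
    seg_jitter_mm: float = 1.0
    #: P(flag | residual) and P(no flag | nonresidual)
    pm_sensitivity: float = 0.65
    pm_specificity: float = 0.70
    #: exponential event hazard per month for (residual, nonresidual);
    #: the residual rate gives ~79% event probability by 36 months, so a
    #: 28-case preservation cohort at ~18% prevalence carries ~4 expected
    #: events, concentrated in true-residual cases
    hazard_per_month: tuple[float, float] = (0.043, 0.0005)
    followup_months: float = 36.0
    #: uterus ellipsoid semi-axes (mm), jittered per case
    uterus_semiaxes_mm: tuple[float, float, float] = (17.0, 15.0, 27.0)
    band_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 4:
            raise ValueError("n_cases must be at least 4")
        if not 0.0 < self.residual_fraction < 1.0:
            raise ValueError("residual_fraction must lie in (0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be nonnegative")


@dataclass
class PhantomCase:
    case_id: str
    t2: ImageVolume
    dwi_b0: ImageVolume
    dwi_b800: ImageVolume
    masks: MaskSet
    adc_field: np.ndarray
    label: str  # "residual" | "nonresidual"
    margin_positive: bool
    followup_time: float
    event: bool


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center_mm, semiaxes_mm):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _cavity_frustum(shape, spacing, center_mm, semi_z, r_base, r_tip, depth) -> np.ndarray:
    """Cone-like frustum along z, opening at the inferior (low-z) pole."""
    x, y, z = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    z0 = center_mm[2] - semi_z  # inferior pole
    frac = np.clip((z - z0) / depth, 0.0, 1.0)
    radius = r_base + (r_tip - r_base) * frac
    inplane = np.sqrt((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2)
    return (z >= z0) & (z <= z0 + depth) & (inplane <= radius)


def _case_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> MaskSet:
    shape, spacing = cfg.grid_shape, cfg.spacing_mm
    fov = [n * s for n, s in zip(shape, spacing)]
    semi = np.array(cfg.uterus_semiaxes_mm) * rng.uniform(0.9, 1.1, size=3)
    for a, f in zip(semi, fov):
        if 2 * a + 2 * cfg.band_mm > f:
            raise ValueError(
                f"grid too small for the uterus ellipsoid: semi-axes {tuple(semi)} mm in FOV {fov} mm"
            )
    center = [f / 2 for f in fov]
    uterus = _ellipsoid(shape, spacing, center, semi)
    depth = rng.uniform(14.0, 18.0)
    cavity = _cavity_frustum(
        shape, spacing, center, semi[2],
        r_base=rng.uniform(6.5, 8.5), r_tip=rng.uniform(2.0, 3.0), depth=depth,
    )
    cavity &= uterus
    if not cavity.any():
        raise ValueError("degenerate geometry: empty conization cavity")
    return MaskSet(uterus, cavity, spacing)


def _lesion_region(masks: MaskSet, band: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A focal sub-region of the margin band around a random cavity-surface
    point (lesion radius ~4-10 mm); falls back to the whole band if the
    blob misses it."""
    surface = masks.cavity & ~ndimage.binary_erosion(masks.cavity)
    pts = np.argwhere(surface if surface.any() else masks.cavity)
    center = pts[rng.integers(len(pts))] * np.asarray(masks.spacing_mm)
    radius = rng.uniform(4.0, 10.0)
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(masks.shape, masks.spacing_mm)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    lesion = band & (d2 <= radius**2)
    return lesion if lesion.any() else band


def _margin_band(masks: MaskSet, band_mm: float) -> np.ndarray:
    """Tissue within band_mm of the cavity surface (distance transform in mm)."""
    dist = ndimage.distance_transform_edt(~masks.cavity, sampling=masks.spacing_mm)
    return (dist <= band_mm) & masks.uterus & ~masks.cavity


def generate_cohort(config: PhantomConfig) -> list[PhantomCase]:
    """Generate a deterministic phantom cohort.

    The DWI pair satisfies b800 = b0 * exp(-800 * ADC) voxelwise before
    noise; follow-up times are exponential with class-dependent hazard and
    administrative censoring at ``followup_months``.
    """
    cfg = config
    root = np.random.default_rng(cfg.seed)
    # labels: Bernoulli at residual_fraction, redrawn until both classes present
    while True:
        labels = root.random(cfg.n_cases) < cfg.residual_fraction
        if labels.any() and not labels.all():
            break
    case_seeds = root.integers(0, 2**31 - 1, size=cfg.n_cases)

    cases = []
    for idx in range(cfg.n_cases):
        rng = np.random.default_rng(int(case_seeds[idx]))
        residual = bool(labels[idx])
        masks = _case_geometry(cfg, rng)
        band = _margin_band(masks, cfg.band_mm)
        shape, spacing = cfg.grid_shape, cfg.spacing_mm
        # label-independent per-case physiology: texture correlation length,
        # smooth-vs-voxel noise composition, and post-surgical band-level
        # offsets (edema/granulation around the cavity) all vary across
        # patients; they survive the per-case z-scoring and make whole
        # feature families co-vary as nuisance blocks, as real radiomics
        # features do
        corr_len = rng.uniform(2.0, 3.2)
        white_frac = rng.uniform(0.05, 0.55)
        edema_t2 = rng.normal(0.0, 1.0) * cfg.noise_sd
        edema_adc = rng.normal(0.0, 0.10) * cfg.adc_levels[1]
        sigma_long = [corr_len / s for s in spacing]
        sigma_short = [1.0 / s for s in spacing]  # ~1 mm, the planted lesion texture

        def mixed_noise():
            return (1.0 - white_frac) * _smooth_noise(rng, shape, sigma_long) + \
                white_frac * rng.standard_normal(shape)

        # T2: tissue baseline + physiological texture + band-level offset
        t2 = np.where(masks.uterus, 1.0, 0.15).astype(float)
        t2[masks.cavity] = 1.6  # fluid/defect signal
        t2 += cfg.noise_sd * mixed_noise()
        t2[band] += edema_t2
        # ADC field: smooth normal-tissue level + band-level offset
        adc_normal = cfg.adc_levels[1]
        adc = adc_normal * (1.0 + 0.1 * mixed_noise())
        adc[band] += edema_adc
        if residual and cfg.texture_effect > 0:
            # focal lesion: a blob of the margin band around a random point
            # on the cavity surface, with per-case conspicuity, so lesion
            # visibility varies across cases as it does across patients
            # the lesion is diffusion-restricting but essentially T2-occult
            # (as small high-grade cervical lesions tend to be): the class
            # contrast lives in a compact set of ADC features while the T2
            # catalogue contributes only nuisance dimensions
            lesion = _lesion_region(masks, band, rng)
            conspicuity = rng.uniform(0.35, 1.0) * cfg.texture_effect
            adc_tex = _smooth_noise(rng, shape, sigma_short)
            shift = 0.8 * (cfg.adc_levels[0] - adc_normal) * conspicuity
            adc[lesion] += shift + conspicuity * 0.15 * adc_normal * adc_tex[lesion]
        adc = np.clip(adc, 1e-5, None)

        b0 = np.where(masks.uterus, 1.0, 0.2) + 0.1 * _smooth_noise(rng, shape, sigma_long)
        b0 = np.clip(b0, 0.05, None)
        b800 = b0 * np.exp(-800.0 * adc)
        if cfg.noise_sd > 0:
            t2 += 0.2 * cfg.noise_sd * rng.standard_normal(shape)
            b0n = b0 + 0.2 * cfg.noise_sd * rng.standard_normal(shape)
            b800n = b800 + 0.1 * cfg.noise_sd * rng.standard_normal(shape)
        else:
            b0n, b800n = b0, b800

        flag = rng.random() < (cfg.pm_sensitivity if residual else 1.0 - cfg.pm_specificity)
        hazard = cfg.hazard_per_month[0] if residual else cfg.hazard_per_month[1]
        raw_t = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        event = raw_t <= cfg.followup_months
        time = float(min(raw_t, cfg.followup_months))

        cid = f"case{idx:03d}"
        cases.append(
            PhantomCase(
                case_id=cid,
                t2=ImageVolume(t2, spacing, f"{cid}_t2"),
                dwi_b0=ImageVolume(b0n, spacing, f"{cid}_b0"),
                dwi_b800=ImageVolume(b800n, spacing, f"{cid}_b800"),
                masks=masks,
                adc_field=adc,
                label="residual" if residual else "nonresidual",
                margin_positive=bool(flag),
                followup_time=time,
                event=bool(event),
            )
        )
    return cases


def perturb_segmentation(masks: MaskSet, jitter_mm: float, rng_seed: int) -> MaskSet:
    """Displace mask boundaries by a smooth random field of RMS ``jitter_mm``.

    One displacement field warps uterus and cavity together (as a rater
    redrawing both), the warped cavity is clipped to the warped uterus,
    and each mask keeps its largest connected component so topology is
    preserved. ``jitter_mm = 0`` returns the input unchanged.
    """
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be nonnegative")
    if jitter_mm == 0:
        return masks.copy()
    rng = np.random.default_rng(rng_seed)
    shape = masks.shape
    spacing = np.asarray(masks.spacing_mm)
    sigma = [3.0 / s for s in spacing]  # ~3 mm correlation length
    disp_mm = np.stack([_smooth_noise(rng, shape, sigma) for _ in range(3)])
    rms = np.sqrt(np.mean(np.sum(disp_mm**2, axis=0)))
    disp_mm *= jitter_mm / rms

    base = np.indices(shape).astype(float)
    coords = base - disp_mm / spacing[:, None, None, None]

    def warp(mask: np.ndarray) -> np.ndarray:
        f = ndimage.map_coordinates(mask.astype(float), coords, order=1, mode="nearest")
        return f > 0.5

    uterus = _largest_component(warp(masks.uterus))
    cavity = _largest_component(warp(masks.cavity) & uterus)
    if not uterus.any() or not cavity.any():
        raise ValueError("perturbation emptied a mask (jitter too large for this geometry)")
    return MaskSet(uterus, cavity, masks.spacing_mm)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def write_cohort(cases: list[PhantomCase], out_dir: str | Path, split: dict[str, str] | None = None) -> Path:
    """Write per-case NIfTI volumes/masks and the cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "cohort_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "label", "margin_positive", "followup_time", "event", "split"])
        for case in cases:
            cdir = out_dir / case.case_id
            cdir.mkdir(exist_ok=True)
            case.t2.save(cdir / "t2.nii.gz")
            case.dwi_b0.save(cdir / "dwi_b0.nii.gz")
            case.dwi_b800.save(cdir / "dwi_b800.nii.gz")
            case.masks.save(cdir)
            w.writerow([
                case.case_id, case.label, int(case.margin_positive),
                f"{case.followup_time:.3f}", int(case.event),
                (split or {}).get(case.case_id, ""),
            ])
    return manifest
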
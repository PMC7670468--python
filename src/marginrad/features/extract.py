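"""Per-case extraction of the full feature catalogue on both sequences.

The same margin VOI (delineated on T2) is applied unchanged to the ADC
map. Each sequence is z-scored over the uterus, discretized over the VOI
with a fixed bin count, and run through every feature family; shape
features depend only on the mask and are therefore identical between the
two sequence tags.

Feature ids are ``{family}_{name}``; the cohort table prefixes the
sequence tag, giving columns like ``T2WI_glcm_Contrast``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..prep import compute_adc, discretize, normalize_intensity
from ..voi import build_margin_voi
from ..volumes import ImageVolume, MaskSet
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from . import texture as tx

__all__ = ["FeatureVector", "PrepConfig", "catalogue_ids", "extract_features", "extract_case"]


@dataclass
class PrepConfig:
    """Preparation and extraction parameters.

    n_levels : fixed bin count for gray-level discretization (default 32).
    normalization : "zscore" over the uterus mask, or "none".
    b_low / b_high : the DWI b-value pair (s/mm^2).
    gldm_alpha : level-similarity tolerance for the dependence matrix.
    """

    n_levels: int = 32
    normalization: str = "zscore"
    b_low: float = 0.0
    b_high: float = 800.0
    gldm_alpha: int = 0
    band_mm: float = 5.0
    erosion_px: int = 3


@dataclass
class FeatureVector:
    """Named feature map for one VOI on one sequence."""

    entries: dict[str, float]
    sequence_tag: str
    case_id: str = ""
    flags: list[str] = field(default_factory=list)


FAMILIES = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": tx.GLCM_NAMES,
    "gldm": tx.GLDM_NAMES,
    "glrlm": tx.GLRLM_NAMES,
    "glszm": tx.GLSZM_NAMES,
    "ngtdm": tx.NGTDM_NAMES,
}


def catalogue_ids() -> list[str]:
    """The fixed feature catalogue for one sequence (94 ids)."""
    return [f"{fam}_{name}" for fam, names in FAMILIES.items() for name in names]


def extract_features(
    vol: ImageVolume,
    voi: np.ndarray,
    uterus: np.ndarray,
    config: PrepConfig,
    sequence_tag: str,
    case_id: str = "",
    shape_cache: tuple[dict, list] | None = None,
) -> FeatureVector:
    """Run the full catalogue for one sequence over a prepared VOI.

    Non-finite voxels (e.g. invalid ADC) are dropped from the VOI before
    discretization. ``shape_cache`` lets callers reuse the mask-only shape
    panel across sequences.
    """
    voi = np.asarray(voi, dtype=bool) & np.isfinite(vol.values)
    if not voi.any():
        raise ValueError(f"VOI empty after dropping invalid voxels for {sequence_tag}")
    if config.normalization == "zscore":
        norm_mask = uterus & np.isfinite(vol.values)
        vol = normalize_intensity(vol, norm_mask)
    dvol = discretize(vol, voi, config.n_levels)

    entries: dict[str, float] = {}
    flags: list[str] = []

    fo, fl = first_order_features(vol.values[voi], dvol.levels[voi])
    entries.update({f"firstorder_{k}": v for k, v in fo.items()})
    flags += [f"firstorder_{k}" for k in fl]

    if shape_cache is None:
        shape_cache = shape_features(voi, vol.spacing_mm)
    sh, fl = shape_cache
    entries.update({f"shape_{k}": v for k, v in sh.items()})
    flags += [f"shape_{k}" for k in fl]

    for fam, fn in [
        ("glcm", lambda d: tx.glcm_features(d)),
        ("gldm", lambda d: tx.gldm_features(d, alpha=config.gldm_alpha)),
        ("glrlm", tx.glrlm_features),
        ("glszm", tx.glszm_features),
        ("ngtdm", tx.ngtdm_features),
    ]:
        feats, fl = fn(dvol)
        entries.update({f"{fam}_{k}": v for k, v in feats.items()})
        flags += [f"{fam}_{k}" for k in fl]

    return FeatureVector(entries, sequence_tag, case_id, flags)


def extract_case(case, masks: MaskSet | None = None, config: PrepConfig | None = None):
    """Extract the (T2WI, ADC) feature-vector pair for one phantom case.

    If ``masks`` carries no margin VOI it is built with the config's band
    and erosion parameters. The ADC map is computed from the case's DWI
    pair and shares the T2-delineated VOI.
    """
    config = config or PrepConfig()
    masks = masks if masks is not None else case.masks
    if masks.margin_voi is None:
        masks = build_margin_voi(masks, band_mm=config.band_mm, erosion_px=config.erosion_px)
    voi = masks.margin_voi
    shape_cache = shape_features(voi, case.t2.spacing_mm)

    fv_t2 = extract_features(case.t2, voi, masks.uterus, config, "T2WI", case.case_id, shape_cache)
    adc = compute_adc(case.dwi_b0, case.dwi_b800, config.b_high - config.b_low)
    fv_adc = extract_features(adc, voi, masks.uterus, config, "ADC", case.case_id, shape_cache)
    return fv_t2, fv_adc
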
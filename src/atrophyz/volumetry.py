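"""Volume computation from tissue probability maps, plus lesion handling.

Tissue-class maps hold the per-voxel fraction of grey matter (GM), white
matter (WM) and cerebrospinal fluid (CSF). A tissue volume is the sum of the
voxel fractions times the voxel volume, reported in ml. Regional volumes
multiply the tissue maps with a pre-aligned binary atlas mask first, using a
fixed per-region tissue rule: thalamus and putamen use GM+WM, the caudate
nucleus GM only and the corpus callosum WM only. Brain parenchyma (BP) is
GM+WM; the head-size covariate TIV is taken as GM+WM+CSF (a tissue-sum
surrogate for intracranial volume, flagged as such in output metadata).

Lesion filling replaces lesion-voxel intensities in a T1 image with the
estimated healthy-WM intensity so that WM hyperintensities do not bias a
subsequent tissue segmentation.

No resampling or registration is performed: all grids must share shape and
voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EstimationError, ValidationError

__all__ = [
    "TissueMaps", "RegionMask", "LesionMap",
    "tissue_volume", "regional_volume", "brain_parenchyma_volume",
    "estimate_tiv", "lesion_load", "lesion_fill",
    "TISSUE_RULES", "volume_table",
]

#: Fixed tissue rule per atlas region.
TISSUE_RULES = {
    "thalamus": "gm+wm",
    "putamen": "gm+wm",
    "caudate": "gm",
    "corpus_callosum": "wm",
}

#: mm^3 -> ml
_MM3_TO_ML = 1.0 / 1000.0


def _check_fractions(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValidationError(f"{name} voxel fractions must lie in [0, 1]")
    return arr


def _voxel_ml(voxel_size) -> float:
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValidationError("voxel_size must be three positive mm lengths")
    return float(np.prod(vs)) * _MM3_TO_ML


@dataclass
class TissueMaps:
    """GM/WM/CSF fraction maps on a common grid with a common voxel size."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.gm = _check_fractions(self.gm, "gm")
        self.wm = _check_fractions(self.wm, "wm")
        self.csf = _check_fractions(self.csf, "csf")
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValidationError("tissue maps must share one grid shape")
        _voxel_ml(self.voxel_size)

    @property
    def shape(self):
        return self.gm.shape


@dataclass
class RegionMask:
    """Binary atlas mask with its name and fixed tissue rule."""

    mask: np.ndarray
    name: str
    tissue_rule: str = ""

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"mask {self.name!r} must be binary")
        self.mask = arr.astype(bool)
        if not self.tissue_rule:
            self.tissue_rule = TISSUE_RULES.get(self.name, "gm+wm")
        if self.tissue_rule not in ("gm+wm", "gm", "wm"):
            raise ValidationError(f"unknown tissue rule {self.tissue_rule!r}")


@dataclass
class LesionMap:
    """Binary lesion mask on the same grid as the tissue maps."""

    mask: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("lesion map must be binary")
        self.mask = arr.astype(bool)
        _voxel_ml(self.voxel_size)


def tissue_volume(fraction_map: np.ndarray, voxel_size) -> float:
    """Volume in ml of one tissue-class fraction map: sum * voxel volume."""
    arr = _check_fractions(fraction_map, "tissue map")
    return float(arr.sum()) * _voxel_ml(voxel_size)


def _rule_map(maps: TissueMaps, rule: str) -> np.ndarray:
    if rule == "gm+wm":
        return maps.gm + maps.wm
    return getattr(maps, rule)


def regional_volume(maps: TissueMaps, region: RegionMask) -> float:
    """Masked tissue volume in ml using the region's tissue rule."""
    if region.mask.shape != maps.shape:
        raise ValidationError(
            f"mask {region.name!r} shape {region.mask.shape} does not match "
            f"tissue maps {maps.shape}")
    combined = _rule_map(maps, region.tissue_rule)
    return float(combined[region.mask].sum()) * _voxel_ml(maps.voxel_size)


def brain_parenchyma_volume(maps: TissueMaps) -> float:
    """BP = GM volume + WM volume, in ml."""
    return tissue_volume(maps.gm, maps.voxel_size) \
        + tissue_volume(maps.wm, maps.voxel_size)


def estimate_tiv(maps: TissueMaps) -> float:
    """Head-size covariate: GM + WM + CSF volume (tissue-sum TIV surrogate)."""
    return brain_parenchyma_volume(maps) \
        + tissue_volume(maps.csf, maps.voxel_size)


def lesion_load(lesions: LesionMap) -> float:
    """Total lesion volume in ml: binary voxel count times voxel volume."""
    return float(np.count_nonzero(lesions.mask)) * _voxel_ml(lesions.voxel_size)


def lesion_fill(t1: np.ndarray, lesions: LesionMap, wm_map: np.ndarray,
                wm_threshold: float = 0.9, noise_sd: float | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Replace lesion-voxel intensities with estimated healthy-WM intensity.

    Healthy WM is taken as voxels with WM fraction above ``wm_threshold`` and
    outside the lesion mask; lesion voxels receive the mean of those
    intensities, optionally with Gaussian noise at the healthy-WM SD
    (``noise_sd=None`` disables noise; pass ``"estimate"`` to use the
    estimated SD). Voxels outside the lesion mask are returned unchanged.
    """
    t1 = np.asarray(t1, dtype=float)
    wm = _check_fractions(wm_map, "wm map")
    if t1.shape != lesions.mask.shape or t1.shape != wm.shape:
        raise ValidationError("t1, lesion map and wm map must share one shape")
    healthy = (wm > wm_threshold) & ~lesions.mask
    if not healthy.any():
        raise EstimationError(
            "no healthy white-matter voxels available to estimate intensity")
    mean = float(t1[healthy].mean())
    out = t1.copy()
    n_lesion = int(np.count_nonzero(lesions.mask))
    if n_lesion == 0:
        return out
    if noise_sd is None:
        fill = mean
    else:
        sd = float(t1[healthy].std(ddof=1)) if noise_sd == "estimate" \
            else float(noise_sd)
        rng = rng if rng is not None else np.random.default_rng()
        fill = mean + rng.normal(0.0, sd, size=n_lesion)
    out[lesions.mask] = fill
    return out


def volume_table(maps: TissueMaps, regions: dict | None = None,
                 lesions: LesionMap | None = None) -> dict:
    """All standard volumes for one subject as a flat dict (ml).

    ``tiv_method`` flags the TIV value as the tissue-sum surrogate.
    """
    out = {
        "gm": tissue_volume(maps.gm, maps.voxel_size),
        "wm": tissue_volume(maps.wm, maps.voxel_size),
        "csf": tissue_volume(maps.csf, maps.voxel_size),
        "bp": brain_parenchyma_volume(maps),
        "tiv": estimate_tiv(maps),
        "tiv_method": "tissue-sum-surrogate",
    }
    for name, mask in (regions or {}).items():
        region = mask if isinstance(mask, RegionMask) else RegionMask(mask, name)
        out[name] = regional_volume(maps, region)
    if lesions is not None:
        out["lesion_load"] = lesion_load(lesions)
    return out
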
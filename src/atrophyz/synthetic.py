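"""Synthetic cohorts and digital phantoms for the volumetry pipeline.

The tabular generators emulate the data the analysis assumes: a large
reference control cohort used to fit head-size and age adjustments, smaller
scanner-specific control cohorts that define the normative moments, and a
two-phenotype MS patient cohort (RRMS/SPMS) in which subgroups carry
configurable thalamic and whole-brain-parenchyma (BP) atrophy effects
expressed in control-SD units, so that the expected z-score of an affected
subject equals the configured shift.

The phantom generator builds small voxel grids of nested ellipsoids (CSF /
grey matter / white matter shells plus named subcortical region masks and
white-matter lesion blobs) whose ground-truth volumes are obtained by voxel
counting on the generated maps, so that the volumetry stage can be checked
bit-exactly against them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PlacementError

__all__ = [
    "RegionParams",
    "CohortConfig",
    "PhantomConfig",
    "PhantomResult",
    "generate_reference_cohort",
    "generate_scanner_controls",
    "generate_patient_cohort",
    "generate_phantom",
    "COHORT_COLUMNS",
]

#: Documented column dictionary for cohort CSV tables.
COHORT_COLUMNS = [
    "id", "cohort", "scanner", "age", "tiv",
    "gm", "wm", "bp", "thalamus", "putamen", "caudate", "corpus_callosum",
    "lesion_load", "edss", "sdmt", "disease_duration", "treatment",
]

#: Atrophy-group labels used for ground truth (mirrors the downstream classifier).
GROUP_LABELS = ("group0", "group1", "group2")


@dataclass(frozen=True)
class RegionParams:
    """Generating model for one region: v = baseline + tiv_slope*(TIV - tiv_ref)
    + age_linear*(age - age_ref) + age_quad*(age - age_ref)^2 + N(0, sd)."""

    baseline: float          # ml at reference TIV and age
    tiv_slope: float         # ml per ml of TIV
    age_linear: float        # ml per year
    age_quad: float          # ml per year^2 (negative: accelerating loss)
    sd: float                # residual SD, ml

    def surface(self, tiv, age, tiv_ref, age_ref):
        d = np.asarray(age, dtype=float) - age_ref
        return (self.baseline
                + self.tiv_slope * (np.asarray(tiv, dtype=float) - tiv_ref)
                + self.age_linear * d + self.age_quad * d * d)


def _default_regions() -> dict:
    # Baselines and residual SDs chosen at adult-brain scale (ml); age terms
    # give a smooth monotone-decreasing trajectory over the adult range.
    return {
        "gm": RegionParams(650.0, 0.30, -1.60, -0.012, 28.0),
        "wm": RegionParams(520.0, 0.28, -0.50, -0.008, 24.0),
        "thalamus": RegionParams(15.5, 0.0060, -0.035, -0.00040, 0.90),
        "putamen": RegionParams(10.5, 0.0040, -0.030, -0.00030, 0.80),
        "caudate": RegionParams(8.0, 0.0030, -0.020, -0.00020, 0.70),
        "corpus_callosum": RegionParams(24.0, 0.0080, -0.040, -0.00040, 1.60),
    }


@dataclass
class CohortConfig:
    """Everything the tabular generators need; the seed fully determines output.

    Atrophy effects are given per ground-truth group as (thalamus, BP) shifts
    in units of the control SD of the respective (adjusted) volume. Scanner
    effects are an affine transform ``v -> scale*v + offset`` applied to every
    measured region volume of subjects on that scanner.
    """

    n_reference: int = 316
    n_controls_per_scanner: tuple = (50, 34)
    n_rrms: int = 128
    n_spms: int = 57
    age_range: tuple = (20.0, 70.0)
    age_ref: float = 45.0
    tiv_mean: float = 1500.0
    tiv_sd: float = 130.0
    regions: dict = field(default_factory=_default_regions)
    scanner_names: tuple = ("philips", "ge")
    scanner_offsets: tuple = (0.0, 0.0)       # ml, additive per region
    scanner_scales: tuple = (1.0, 1.02)
    # (thalamus_shift, bp_shift) per ground-truth group, in control-SD units
    group_effects: dict = field(default_factory=lambda: {
        "group0": (0.0, 0.0),
        "group1": (-3.0, -1.0),
        "group2": (-4.5, -3.0),
    })
    # phenotype -> probability of each group, ordered as GROUP_LABELS
    group_probs: dict = field(default_factory=lambda: {
        "RRMS": (61 / 126, 37 / 126, 28 / 126),
        "SPMS": (10 / 57, 18 / 57, 29 / 57),
    })
    # clinical-score links (medians follow phenotype base + per-group shift)
    edss_base: dict = field(default_factory=lambda: {"RRMS": 1.5, "SPMS": 5.5})
    edss_group_shift: tuple = (0.0, 0.0, 0.5)
    sdmt_base: dict = field(default_factory=lambda: {"RRMS": -0.5, "SPMS": -1.5})
    sdmt_group_shift: tuple = (0.0, -0.25, -0.5)
    lesion_load_median: dict = field(default_factory=lambda: {
        "RRMS": (1.0, 3.8, 11.2), "SPMS": (4.1, 11.6, 24.3)})
    lesion_load_log_sd: float = 0.9
    duration_median: dict = field(default_factory=lambda: {"RRMS": 5.0, "SPMS": 16.0})
    duration_log_sd: float = 0.8
    treatment_prob: dict = field(default_factory=lambda: {"RRMS": 0.656, "SPMS": 0.421})
    patient_scanner_probs: tuple = (55 / 185, 130 / 185)
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_reference, self.n_rrms, self.n_spms,
                  *self.n_controls_per_scanner]
        if any(int(c) != c or c < 0 for c in counts):
            raise ConfigError("all cohort sizes must be non-negative integers")
        if not self.regions:
            raise ConfigError("at least one region must be configured")
        for name, p in self.regions.items():
            if p.sd < 0:
                raise ConfigError(f"residual SD for region {name!r} must be >= 0")
        if self.tiv_sd <= 0:
            raise ConfigError("tiv_sd must be > 0")
        if not (self.age_range[0] < self.age_range[1]):
            raise ConfigError("age_range must be increasing")
        if len(self.scanner_names) != len(self.n_controls_per_scanner):
            raise ConfigError("one control count per scanner is required")
        if len(self.scanner_offsets) != len(self.scanner_names) or \
                len(self.scanner_scales) != len(self.scanner_names):
            raise ConfigError("scanner offset/scale lists must match scanner_names")
        for g, probs in self.group_probs.items():
            if len(probs) != len(GROUP_LABELS) or abs(sum(probs) - 1.0) > 1e-9 \
                    or min(probs) < 0:
                raise ConfigError(f"group_probs[{g!r}] must be a probability vector")

    def truth(self) -> dict:
        """Generating parameters in plain-dict form (JSON sidecar content)."""
        return {
            "tiv_mean": self.tiv_mean, "tiv_sd": self.tiv_sd,
            "age_ref": self.age_ref, "age_range": list(self.age_range),
            "regions": {k: dataclasses.asdict(v) for k, v in self.regions.items()},
            "scanner_offsets": dict(zip(self.scanner_names, self.scanner_offsets)),
            "scanner_scales": dict(zip(self.scanner_names, self.scanner_scales)),
            "group_effects": {k: list(v) for k, v in self.group_effects.items()},
            "seed": self.seed,
        }


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # One sub-stream per generator so cohorts are independently reproducible.
    return np.random.default_rng([int(config.seed), stream])


def _bp_sd(config: CohortConfig) -> float:
    return float(np.hypot(config.regions["gm"].sd, config.regions["wm"].sd))


def _draw_base(config: CohortConfig, n: int, rng, cohort: str,
               scanner: str, prefix: str) -> pd.DataFrame:
    age = rng.uniform(*config.age_range, size=n)
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, size=n)
    df = pd.DataFrame({
        "id": [f"{prefix}{i:05d}" for i in range(n)],
        "cohort": cohort, "scanner": scanner,
        "age": age, "tiv": tiv,
    })
    for name, p in config.regions.items():
        df[name] = p.surface(tiv, age, config.tiv_mean, config.age_ref) \
            + rng.normal(0.0, p.sd, size=n)
    return df


def _finalize(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    df["bp"] = df["gm"] + df["wm"]
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    out = df[cols + extra].reset_index(drop=True)
    out.attrs["truth"] = config.truth()
    return out


def _apply_scanner(df: pd.DataFrame, config: CohortConfig, idx: int) -> None:
    scale, offset = config.scanner_scales[idx], config.scanner_offsets[idx]
    for name in config.regions:
        df[name] = scale * df[name] + offset


def generate_reference_cohort(config: CohortConfig) -> pd.DataFrame:
    """Reference (OASIS-like) healthy controls used to fit the adjustments."""
    config.validate()
    rng = _rng(config, 1)
    df = _draw_base(config, config.n_reference, rng,
                    cohort="reference-control", scanner="reference", prefix="REF")
    df["lesion_load"] = 0.0
    return _finalize(df, config)


def generate_scanner_controls(config: CohortConfig) -> pd.DataFrame:
    """Local healthy controls per scanner, with scanner offset/scale applied."""
    config.validate()
    rng = _rng(config, 2)
    parts = []
    for idx, (scanner, n) in enumerate(
            zip(config.scanner_names, config.n_controls_per_scanner)):
        df = _draw_base(config, n, rng, cohort="scanner-control",
                        scanner=scanner, prefix=f"HC{idx}_")
        _apply_scanner(df, config, idx)
        parts.append(df)
    out = pd.concat(parts, ignore_index=True)
    out["lesion_load"] = 0.0
    return _finalize(out, config)


def generate_patient_cohort(config: CohortConfig) -> pd.DataFrame:
    """RRMS + SPMS patients with group-dependent atrophy and clinical scores.

    Each record carries its hidden ground-truth group in a ``true_group``
    column. Thalamus/BP shifts are applied before the scanner transform so
    that the expected downstream z-score equals the configured shift.
    """
    config.validate()
    for g in GROUP_LABELS:
        if g not in config.group_effects:
            raise ConfigError(f"group_effects missing {g!r}")
    rng = _rng(config, 3)
    bp_sd = _bp_sd(config)
    thal_sd = config.regions["thalamus"].sd
    parts = []
    for phenotype, n in (("RRMS", config.n_rrms), ("SPMS", config.n_spms)):
        df = _draw_base(config, n, rng, cohort=phenotype, scanner="",
                        prefix=f"{phenotype}_")
        groups = rng.choice(len(GROUP_LABELS), size=n,
                            p=config.group_probs[phenotype])
        scanner_idx = rng.choice(len(config.scanner_names), size=n,
                                 p=config.patient_scanner_probs)
        df["scanner"] = np.asarray(config.scanner_names)[scanner_idx]
        df["true_group"] = np.asarray(GROUP_LABELS)[groups]
        thal_shift = np.array([config.group_effects[GROUP_LABELS[g]][0]
                               for g in groups])
        bp_shift = np.array([config.group_effects[GROUP_LABELS[g]][1]
                             for g in groups])
        df["thalamus"] += thal_shift * thal_sd
        # split the BP shift between GM and WM so bp = gm + wm moves by
        # bp_shift control-SDs of the BP volume
        df["gm"] += 0.5 * bp_shift * bp_sd
        df["wm"] += 0.5 * bp_shift * bp_sd
        for idx in range(len(config.scanner_names)):
            sel = scanner_idx == idx
            sub = df.loc[sel].copy()
            _apply_scanner(sub, config, idx)
            df.loc[sel] = sub
        # clinical scores: ordinal draws with group-shifted medians
        edss = (config.edss_base[phenotype]
                + np.take(config.edss_group_shift, groups)
                + rng.normal(0.0, 1.0, size=n))
        df["edss"] = np.clip(np.round(edss * 2) / 2, 0.0, 10.0)
        sdmt = (config.sdmt_base[phenotype]
                + np.take(config.sdmt_group_shift, groups)
                + rng.normal(0.0, 0.75, size=n))
        df["sdmt"] = np.round(sdmt * 4) / 4
        med = np.array([config.lesion_load_median[phenotype][g] for g in groups])
        df["lesion_load"] = med * np.exp(
            rng.normal(0.0, config.lesion_load_log_sd, size=n))
        df["disease_duration"] = config.duration_median[phenotype] * np.exp(
            rng.normal(0.0, config.duration_log_sd, size=n))
        df["treatment"] = rng.random(n) < config.treatment_prob[phenotype]
        parts.append(df)
    return _finalize(pd.concat(parts, ignore_index=True), config)


# ---------------------------------------------------------------------------
# Digital phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple      # voxel coordinates
    semi_axes: tuple   # voxels

    def mask(self, shape) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        r2 = sum(((g - c) / a) ** 2
                 for g, c, a in zip(grids, self.center, self.semi_axes))
        return r2 <= 1.0


@dataclass
class PhantomConfig:
    """Nested-ellipsoid head phantom on a small voxel grid."""

    shape: tuple = (48, 48, 48)
    voxel_size: tuple = (1.0, 1.0, 1.0)      # mm per axis
    head: Ellipsoid = None                   # outer skull boundary
    brain: Ellipsoid = None                  # GM outer boundary
    wm_core: Ellipsoid = None                # WM boundary (inside brain)
    region_ellipsoids: dict = None           # name -> Ellipsoid
    n_lesions: int = 3
    lesion_radius: float = 2.0               # voxels
    wm_threshold: float = 0.5                # lesions only where wm > threshold
    t1_intensities: dict = None              # tissue -> mean intensity
    t1_noise_sd: float = 0.0
    lesion_intensity: float = 60.0
    seed: int = 0

    def __post_init__(self):
        c = tuple(s / 2 for s in self.shape)
        if self.head is None:
            self.head = Ellipsoid(c, tuple(0.45 * s for s in self.shape))
        if self.brain is None:
            self.brain = Ellipsoid(c, tuple(0.38 * s for s in self.shape))
        if self.wm_core is None:
            self.wm_core = Ellipsoid(c, tuple(0.28 * s for s in self.shape))
        if self.region_ellipsoids is None:
            cx, cy, cz = c
            self.region_ellipsoids = {
                "thalamus": Ellipsoid((cx - 4, cy, cz), (3, 4, 3)),
                "putamen": Ellipsoid((cx + 5, cy + 3, cz), (2, 3, 2)),
                # straddles the GM/WM boundary so its GM-only volume is > 0
                "caudate": Ellipsoid((cx + 15, cy, cz), (2, 2, 2)),
                "corpus_callosum": Ellipsoid((cx, cy, cz + 5), (6, 2, 2)),
            }
        if self.t1_intensities is None:
            self.t1_intensities = {"wm": 100.0, "gm": 80.0, "csf": 30.0}

    def validate(self):
        for ell in [self.head, self.brain, self.wm_core,
                    *self.region_ellipsoids.values()]:
            for c, a, s in zip(ell.center, ell.semi_axes, self.shape):
                if c - a < 0 or c + a > s:
                    raise ConfigError("ellipsoid does not fit inside the grid")
        if self.n_lesions < 0 or self.lesion_radius <= 0:
            raise ConfigError("invalid lesion parameters")


@dataclass
class PhantomResult:
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    masks: dict           # region name -> binary ndarray
    lesions: np.ndarray   # binary
    t1: np.ndarray
    voxel_size: tuple
    truth: dict           # region/tissue name -> ml, by voxel counting


def generate_phantom(config: PhantomConfig) -> PhantomResult:
    """Build binary tissue maps, region masks, lesions and a T1 image.

    Ground-truth volumes are computed by voxel counting on the generated
    maps (never from the analytic ellipsoid volume), applying the same
    tissue rules the volumetry stage uses, so comparisons can be bit-exact.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 7])
    shape = config.shape
    head = config.head.mask(shape)
    brain = config.brain.mask(shape)
    core = config.wm_core.mask(shape)
    csf = (head & ~brain).astype(np.float64)
    gm = (brain & ~core).astype(np.float64)
    wm = core.astype(np.float64)
    masks = {name: ell.mask(shape).astype(np.uint8)
             for name, ell in config.region_ellipsoids.items()}

    lesions = np.zeros(shape, dtype=np.uint8)
    if config.n_lesions > 0:
        candidates = np.argwhere(wm > config.wm_threshold)
        if len(candidates) == 0:
            raise PlacementError("no white-matter voxels above the threshold")
        centers = candidates[rng.choice(len(candidates), size=config.n_lesions,
                                        replace=False)]
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        for cx, cy, cz in centers:
            r2 = sum((g - c) ** 2 for g, c in zip(grids, (cx, cy, cz)))
            lesions |= (r2 <= config.lesion_radius ** 2)
        lesions &= (wm > config.wm_threshold)  # keep blobs inside WM
        lesions = lesions.astype(np.uint8)

    t1 = (config.t1_intensities["wm"] * wm
          + config.t1_intensities["gm"] * gm
          + config.t1_intensities["csf"] * csf)
    if config.t1_noise_sd > 0:
        t1 = t1 + rng.normal(0.0, config.t1_noise_sd, size=shape)
    t1 = np.where(lesions > 0, config.lesion_intensity, t1)

    vox_ml = float(np.prod(config.voxel_size)) / 1000.0
    truth = {
        "gm": gm.sum() * vox_ml,
        "wm": wm.sum() * vox_ml,
        "csf": csf.sum() * vox_ml,
        "bp": (gm + wm).sum() * vox_ml,
        "tiv": (gm + wm + csf).sum() * vox_ml,
        "lesion_load": float(lesions.sum()) * vox_ml,
    }
    # tissue rules mirror the volumetry stage: thalamus/putamen GM+WM,
    # caudate GM-only, corpus callosum WM-only
    rules = {"thalamus": gm + wm, "putamen": gm + wm,
             "caudate": gm, "corpus_callosum": wm}
    for name, mask in masks.items():
        truth[name] = (rules[name] * mask).sum() * vox_ml
    return PhantomResult(gm=gm, wm=wm, csf=csf, masks=masks, lesions=lesions,
                         t1=t1, voxel_size=config.voxel_size, truth=truth)
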
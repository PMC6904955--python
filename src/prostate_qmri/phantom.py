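"""Digital prostate phantom: ground-truth anatomy, baselines, and treatment effects.

The phantom is a geometric stand-in for pelvic anatomy: an ellipsoidal
prostate containing an anteriorly shifted central-gland (CG) ellipsoid, so
that the remaining posterior crescent forms the peripheral zone (PZ), with a
single spherical tumor embedded in the PZ, all inside a large "body"
ellipsoid surrounded by air.  Ground-truth T2 (ms) and ADC (mm^2/s) maps are
piecewise constant per region, optionally modulated by a smooth
median-preserving within-region field.

Treatment response is modelled as per-week multiplicative factors applied to
each region's truth values, stratified by hormonal-therapy status.  Default
week-5 factors follow the observed cohort medians (hormonal therapy: CG
-12 % T2 / -8 % ADC, PZ -17 % / -18 %, tumor +5 % / +7 %; no hormonal
therapy: tumor +20 % ADC, CG -4 % / PZ -5 % ADC), interpolated linearly from
1.0 at week 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridSpec, QuantMap, VolumeGrid

__all__ = [
    "GeometryError",
    "ConfigurationError",
    "PhantomGeometry",
    "PhantomTruth",
    "EffectProfile",
    "build_phantom",
    "apply_effect",
    "default_effect_profiles",
    "BASELINE_T2_MS",
    "BASELINE_ADC_A",
    "BASELINE_ADC_B",
    "LABELS",
]


class GeometryError(ValueError):
    """Requested phantom geometry is inconsistent (e.g. tumor does not fit in the PZ)."""


class ConfigurationError(KeyError):
    """A required effect profile or configuration entry is missing."""


# integer labels in the phantom label volume; bladder/rectum are background
# tissue classes that anchor through-plane registration
LABELS = {"air": 0, "body": 1, "CG": 2, "PZ": 3, "tumor": 4, "bladder": 5, "rectum": 6}

# population-median pretreatment baselines per region
BASELINE_T2_MS = {"CG": 93.0, "PZ": 110.0, "tumor": 80.0}
# ADC in mm^2/s; the two protocol dialects sit at systematically different levels
BASELINE_ADC_A = {"CG": 1.30e-3, "PZ": 1.37e-3, "tumor": 1.07e-3}
BASELINE_ADC_B = {"CG": 1.09e-3, "PZ": 1.24e-3, "tumor": 0.90e-3}

# interquartile ranges of the same tables, used for per-patient baseline draws
BASELINE_T2_IQR = {"CG": 19.0, "PZ": 26.0, "tumor": 9.0}
BASELINE_ADC_IQR_A = {"CG": 0.13e-3, "PZ": 0.19e-3, "tumor": 0.20e-3}
BASELINE_ADC_IQR_B = {"CG": 0.18e-3, "PZ": 0.24e-3, "tumor": 0.28e-3}

# surrounding tissue / air: not analysed, but needed for realistic signal and
# for inter-tissue contrast the rigid registration can latch onto
BACKGROUND_VALUES = {
    "air": {"T2": 1.0, "ADC": 1.0e-5, "S0": 0.0},
    "body": {"T2": 45.0, "ADC": 1.5e-3, "S0": 80.0},
    "bladder": {"T2": 300.0, "ADC": 3.0e-3, "S0": 120.0},  # urine: long T2, free water
    "rectum": {"T2": 25.0, "ADC": 1.0e-3, "S0": 40.0},  # gas/wall mix: dark
}
PROSTATE_S0 = 100.0


@dataclass(frozen=True)
class PhantomGeometry:
    """Ellipsoid/sphere layout of the phantom, all lengths in mm.

    Axis convention: x left-right, y anterior(-)/posterior(+), z feet-head.
    """

    shape: tuple[int, int, int] = (110, 110, 70)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    prostate_semiaxes: tuple[float, float, float] = (23.0, 20.0, 20.0)
    cg_semiaxes: tuple[float, float, float] = (20.0, 10.0, 17.0)
    cg_offset: tuple[float, float, float] = (0.0, -7.0, 0.0)
    tumor_center: tuple[float, float, float] = (8.0, 11.0, 0.0)
    tumor_radius: float = 6.5
    body_semiaxes: tuple[float, float, float] = (52.0, 44.0, 48.0)
    bladder_center: tuple[float, float, float] = (0.0, -25.0, 20.0)
    bladder_semiaxes: tuple[float, float, float] = (18.0, 14.0, 14.0)
    rectum_center_xy: tuple[float, float] = (0.0, 30.0)
    rectum_radius: float = 9.0

    def grid(self) -> GridSpec:
        origin = tuple(
            -0.5 * (self.shape[a] - 1) * self.spacing[a] for a in range(3)
        )
        return GridSpec(self.shape, self.spacing, origin)


@dataclass
class PhantomTruth:
    """Ground-truth label volume and quantitative maps of one phantom."""

    label_volume: VolumeGrid
    t2_truth: QuantMap
    adc_truth: QuantMap
    s0_truth: VolumeGrid

    def roi_mask(self, roi: str) -> np.ndarray:
        lab = self.label_volume.data
        if roi == "prostate":
            return np.isin(lab, [LABELS["CG"], LABELS["PZ"], LABELS["tumor"]])
        if roi == "CG":
            return lab == LABELS["CG"]
        if roi in ("PZ", "pz"):
            # the tumor sits inside the PZ; the PZ compartment proper excludes it
            return lab == LABELS["PZ"]
        if roi == "tumor":
            return lab == LABELS["tumor"]
        raise KeyError(f"unknown ROI {roi!r}")

    def validate(self) -> None:
        lab = self.label_volume.data
        prostate = self.roi_mask("prostate")
        if not (self.roi_mask("CG").any() and self.roi_mask("PZ").any()):
            raise GeometryError("CG or PZ region is empty")
        tum = self.roi_mask("tumor")
        if not tum.any():
            raise GeometryError("tumor region is empty")
        if np.any(tum & ~prostate):
            raise GeometryError("tumor extends outside the prostate")
        for qmap in (self.t2_truth, self.adc_truth):
            if np.any(qmap.values.data[prostate] <= 0):
                raise GeometryError("non-positive truth value inside the prostate")


@dataclass(frozen=True)
class EffectProfile:
    """Multiplicative weekly response factors for one region/map/stratum."""

    roi: str  # 'CG' | 'PZ' | 'tumor'
    map_type: str  # 'T2' | 'ADC'
    stratum: str  # 'HT' | 'noHT'
    weekly_factors: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weekly_factors) != 6:
            raise ConfigurationError("weekly_factors must cover weeks 0..5")
        if abs(self.weekly_factors[0] - 1.0) > 1e-12:
            raise ConfigurationError("week-0 factor must be exactly 1.0")
        if any(f <= 0 for f in self.weekly_factors):
            raise ConfigurationError("weekly factors must be positive")


def _linear_profile(roi: str, map_type: str, stratum: str, week5: float) -> EffectProfile:
    factors = tuple(1.0 + (week5 - 1.0) * w / 5.0 for w in range(6))
    return EffectProfile(roi, map_type, stratum, factors)


# week-5 multiplicative factors per stratum, region, and map
WEEK5_FACTORS = {
    ("HT", "CG", "T2"): 0.88,
    ("HT", "PZ", "T2"): 0.83,
    ("HT", "tumor", "T2"): 1.05,
    ("HT", "CG", "ADC"): 0.92,
    ("HT", "PZ", "ADC"): 0.82,
    ("HT", "tumor", "ADC"): 1.07,
    ("noHT", "CG", "ADC"): 0.96,
    ("noHT", "PZ", "ADC"): 0.95,
    ("noHT", "tumor", "ADC"): 1.20,
    # T2 trends without hormonal therapy were not quantified at cohort level
    ("noHT", "CG", "T2"): 1.0,
    ("noHT", "PZ", "T2"): 1.0,
    ("noHT", "tumor", "T2"): 1.0,
}


def default_effect_profiles() -> dict[tuple[str, str, str], EffectProfile]:
    """Default cohort-median effect profiles, linear from 1.0 to the week-5 factor.

    Keyed by ``(stratum, roi, map_type)``.
    """
    return {
        key: _linear_profile(key[1], key[2], key[0], f5)
        for key, f5 in WEEK5_FACTORS.items()
    }


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (
        ((x[:, None, None] - cx) / ax) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((z[None, None, :] - cz) / az) ** 2
    ) <= 1.0


def _smooth_field(shape, sigma_vox: float, rng: np.random.Generator) -> np.ndarray:
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma_vox)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def build_phantom(
    geometry: PhantomGeometry | None = None,
    baseline_t2: dict[str, float] | None = None,
    baseline_adc: dict[str, float] | None = None,
    within_roi_variation: float = 0.0,
    rng: np.random.Generator | None = None,
    s0_texture: float = 0.15,
) -> PhantomTruth:
    """Rasterize the phantom and attach ground-truth T2/ADC/S0 values.

    Parameters
    ----------
    geometry
        Ellipsoid layout; defaults to :class:`PhantomGeometry`.
    baseline_t2, baseline_adc
        Per-region medians (``{'CG':..., 'PZ':..., 'tumor':...}``) in ms and
        mm^2/s.  Defaults are the population medians for T2 and the dialect-B
        ADC table.
    within_roi_variation
        Coefficient of variation of a smooth multiplicative within-region
        field.  The field is renormalized per region so the regional *median*
        equals the configured baseline exactly, variation or not.
    rng
        Required when ``within_roi_variation > 0``.
    s0_texture
        Coefficient of variation of a smooth multiplicative texture on the
        proton-density S0 inside all tissue (applied only when ``rng`` is
        given).  S0 texture shows up in every simulated series and gives the
        mutual-information registration realistic intensity structure;
        without it the piecewise-constant phantom under-constrains rotation.
    """
    geometry = geometry or PhantomGeometry()
    baseline_t2 = dict(baseline_t2 or BASELINE_T2_MS)
    baseline_adc = dict(baseline_adc or BASELINE_ADC_B)
    for name, table in (("T2", baseline_t2), ("ADC", baseline_adc)):
        for roi in ("CG", "PZ", "tumor"):
            if table.get(roi, 0.0) <= 0:
                raise GeometryError(f"baseline {name} for {roi} must be positive")
    if geometry.tumor_radius <= 0:
        raise GeometryError("tumor radius must be positive")

    gs = geometry.grid()
    coords = gs.world_coords()
    x, y, z = coords

    body = _ellipsoid(coords, (0.0, 0.0, 0.0), geometry.body_semiaxes)
    prostate = _ellipsoid(coords, (0.0, 0.0, 0.0), geometry.prostate_semiaxes)
    cg_core = _ellipsoid(coords, geometry.cg_offset, geometry.cg_semiaxes)
    r = geometry.tumor_radius
    tumor = _ellipsoid(coords, geometry.tumor_center, (r, r, r))

    cg = prostate & cg_core
    pz = prostate & ~cg
    if not tumor.any():
        raise GeometryError("tumor radius too small: empty tumor mask")
    if np.any(tumor & ~pz):
        raise GeometryError(
            "tumor sphere exceeds the peripheral-zone shell (overlaps CG or "
            "extends outside the prostate)"
        )
    pz = pz & ~tumor

    prostate_all = cg | pz | tumor
    bladder = (
        _ellipsoid(coords, geometry.bladder_center, geometry.bladder_semiaxes)
        & body
        & ~prostate_all
    )
    rx, ry = geometry.rectum_center_xy
    rr = geometry.rectum_radius
    rectum_2d = ((x[:, None] - rx) / rr) ** 2 + ((y[None, :] - ry) / rr) ** 2 <= 1.0
    rectum = rectum_2d[:, :, None] & body & ~prostate_all & ~bladder

    lab = np.zeros(gs.shape, dtype=np.int16)
    lab[body] = LABELS["body"]
    lab[bladder] = LABELS["bladder"]
    lab[rectum] = LABELS["rectum"]
    lab[cg] = LABELS["CG"]
    lab[pz] = LABELS["PZ"]
    lab[tumor] = LABELS["tumor"]

    t2 = np.full(gs.shape, BACKGROUND_VALUES["air"]["T2"])
    adc = np.full(gs.shape, BACKGROUND_VALUES["air"]["ADC"])
    s0 = np.full(gs.shape, BACKGROUND_VALUES["air"]["S0"])
    for name, mask in (("body", body), ("bladder", bladder), ("rectum", rectum)):
        t2[mask] = BACKGROUND_VALUES[name]["T2"]
        adc[mask] = BACKGROUND_VALUES[name]["ADC"]
        s0[mask] = BACKGROUND_VALUES[name]["S0"]

    roi_masks = {"CG": cg, "PZ": pz, "tumor": tumor}
    if within_roi_variation > 0:
        if rng is None:
            raise ValueError("within_roi_variation > 0 requires an rng")
        field_t2 = np.exp(within_roi_variation * _smooth_field(gs.shape, 4.0, rng))
        field_adc = np.exp(within_roi_variation * _smooth_field(gs.shape, 4.0, rng))
    else:
        field_t2 = field_adc = np.ones(gs.shape)

    for roi, mask in roi_masks.items():
        f_t2 = field_t2[mask]
        f_adc = field_adc[mask]
        # median-preserving modulation: regional median stays at the baseline
        t2[mask] = baseline_t2[roi] * f_t2 / np.median(f_t2)
        adc[mask] = baseline_adc[roi] * f_adc / np.median(f_adc)
        s0[mask] = PROSTATE_S0

    if s0_texture > 0 and rng is not None:
        tex = np.exp(s0_texture * _smooth_field(gs.shape, 4.0, rng))
        s0 = np.where(lab > 0, s0 * tex, s0)

    label_vol = VolumeGrid(lab, gs.spacing, gs.origin)
    valid = lab > 0
    truth = PhantomTruth(
        label_volume=label_vol,
        t2_truth=QuantMap(VolumeGrid(t2, gs.spacing, gs.origin), valid, "T2"),
        adc_truth=QuantMap(VolumeGrid(adc, gs.spacing, gs.origin), valid, "ADC"),
        s0_truth=VolumeGrid(s0, gs.spacing, gs.origin),
    )
    truth.validate()
    return truth


def apply_effect(
    truth: PhantomTruth,
    profiles: dict[tuple[str, str, str], EffectProfile],
    week: int,
    stratum: str,
) -> PhantomTruth:
    """Scale each region's truth maps by its weekly response factor.

    Week 0 returns values identical to the input.  Raises
    :class:`ConfigurationError` if a region/map profile is missing for the
    requested stratum.
    """
    if week not in range(6):
        raise ValueError(f"week must be in 0..5, got {week}")
    t2 = truth.t2_truth.values.data.copy()
    adc = truth.adc_truth.values.data.copy()
    for roi in ("CG", "PZ", "tumor"):
        mask = truth.roi_mask(roi)
        for map_type, arr in (("T2", t2), ("ADC", adc)):
            key = (stratum, roi, map_type)
            if key not in profiles:
                raise ConfigurationError(f"no effect profile for {key}")
            arr[mask] *= profiles[key].weekly_factors[week]
    return PhantomTruth(
        label_volume=truth.label_volume,
        t2_truth=QuantMap(
            truth.t2_truth.values.with_data(t2), truth.t2_truth.valid, "T2"
        ),
        adc_truth=QuantMap(
            truth.adc_truth.values.with_data(adc), truth.adc_truth.valid, "ADC"
        ),
        s0_truth=truth.s0_truth,
    )
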
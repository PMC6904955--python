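"""Synthetic longitudinal cohort generator.

Emulates a weekly prostate qMRI study: for each patient a digital phantom is
built with per-patient baseline T2/ADC values drawn around the population
medians (spread matched to the published interquartile ranges), weekly
multiplicative treatment effects stratified by hormonal-therapy status are
applied, and each weekly exam is synthesized on acquisition grids of the
chosen protocol dialect with Rician noise and a known random rigid
misalignment with respect to the pretreatment exam.  Weeks can be missing at
random, reproducing the incomplete-exam patterns that drive the downstream
exclusion rules.  Everything is deterministic under the configured seed.

The forward models are the same mono-exponential decays the fitting module
inverts: S(TE) = S0 exp(-TE/T2) for the multi-echo series and
S(b) = S0 exp(-b ADC) for DWI.  Magnitude noise is Rician: the modulus of
the noiseless signal plus complex Gaussian noise of standard deviation
sigma = S0_prostate / SNR per channel.

A trajectory-level generator (:func:`simulate_trajectory_cohort`) produces
per-patient ROI-median trajectories directly — same baselines, effects and
missingness, with a lognormal measurement error on each median — for
statistics-level experiments (e.g. many-replicate null calibration) where
re-simulating images would add nothing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import AcquisitionSeries, GridSpec, QuantMap, VolumeGrid
from .phantom import (
    BASELINE_ADC_A,
    BASELINE_ADC_B,
    BASELINE_ADC_IQR_A,
    BASELINE_ADC_IQR_B,
    BASELINE_T2_IQR,
    BASELINE_T2_MS,
    EffectProfile,
    PhantomGeometry,
    PhantomTruth,
    PROSTATE_S0,
    WEEK5_FACTORS,
    apply_effect,
    build_phantom,
    default_effect_profiles,
)
from .protocols import DIALECTS, ProtocolDialect
from .registration import RigidTransform, resample

__all__ = [
    "SimConfig",
    "ExamRecord",
    "PatientRecord",
    "Cohort",
    "rician",
    "simulate_echo_series",
    "simulate_dwi_series",
    "synthesize_t2w",
    "generate_cohort",
    "simulate_trajectory_cohort",
    "save_cohort",
    "load_cohort",
]

WEEKS = tuple(range(6))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort.

    ``snr`` is the ratio of prostate S0 to the per-channel Gaussian noise
    sigma.  ``misalignment_max_mm``/``deg`` bound the uniform random rigid
    offsets of weekly exams relative to the pretreatment exam.
    ``missing_prob`` is the per-week probability that a follow-up exam was
    not scanned (week 0 is always present).  ``baseline_variation`` scales
    the IQR-matched per-patient baseline spread and ``effect_jitter_sd`` the
    lognormal per-patient spread of the week-5 effect factor.
    """

    n_patients: int = 20
    ht_fraction: float = 0.5
    dialect: str = "B"  # 'A' | 'B'
    snr: float = 30.0
    # the anatomical TSE scan is a much higher-SNR acquisition than the
    # quantitative series; 100 relative to S0=100 puts tissue SNR near 30
    t2w_snr: float = 100.0
    misalignment_max_mm: float = 5.0
    misalignment_max_deg: float = 5.0
    missing_prob: float = 0.1
    seed: int = 0
    baseline_variation: float = 1.0
    effect_jitter_sd: float = 0.02
    within_roi_variation: float = 0.05
    median_noise_sd: float = 0.02  # trajectory-level generator only
    week5_factors: dict | None = None  # override {"stratum/roi/map_type": factor}

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown protocol dialect {self.dialect!r}")
        if not (0.0 <= self.ht_fraction <= 1.0):
            raise ValueError("ht_fraction must lie in [0, 1]")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob must lie in [0, 1)")


@dataclass
class ExamRecord:
    """One weekly exam: anatomical T2w, acquisition series, and truth sidecar."""

    week: int
    t2w: VolumeGrid
    dwi: AcquisitionSeries
    echoes: AcquisitionSeries | None
    true_align: RigidTransform  # transform that resamples this exam onto the pre grid
    adc_map: QuantMap | None = None
    t2_map: QuantMap | None = None
    registration_echo: VolumeGrid | None = None

    @property
    def b0(self) -> VolumeGrid | None:
        try:
            return self.dwi.volume_at(0.0)
        except KeyError:
            return None


@dataclass
class PatientRecord:
    """A patient's ground truth, ROI masks on the pretreatment grid, and exams."""

    patient_id: str
    ht: bool
    dialect: str
    truth: PhantomTruth
    baselines: dict
    effect_week5: dict
    exams: dict[int, ExamRecord] = field(default_factory=dict)

    @property
    def stratum(self) -> str:
        return "HT" if self.ht else "noHT"

    def available_weeks(self) -> list[int]:
        return sorted(self.exams)

    def roi_masks(self) -> dict[str, VolumeGrid]:
        lab = self.truth.label_volume
        return {
            roi: lab.with_data(self.truth.roi_mask(roi).astype(np.uint8))
            for roi in ("prostate", "PZ", "tumor")
        }


@dataclass
class Cohort:
    config: SimConfig
    patients: list[PatientRecord]

    def manifest(self) -> pd.DataFrame:
        """Exam-level manifest: one row per patient x available week."""
        rows = []
        for p in self.patients:
            for w in p.available_weeks():
                exam = p.exams[w]
                rows.append(
                    {
                        "patient": p.patient_id,
                        "ht": p.ht,
                        "week": w,
                        "dialect": p.dialect,
                        "has_adc": exam.dwi is not None,
                        "has_t2": exam.echoes is not None,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Noise and forward models


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex signal under per-channel Gaussian noise of std sigma."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, float).copy()
    re = signal + rng.normal(0.0, sigma, size=np.shape(signal))
    im = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(re, im)


def _acquisition_grid(phantom_grid: GridSpec, voxel_mm) -> GridSpec:
    """A grid with the requested voxel size covering the phantom field of view."""
    extent = [
        (phantom_grid.shape[a] - 1) * phantom_grid.spacing[a] for a in range(3)
    ]
    shape = tuple(int(np.floor(extent[a] / voxel_mm[a])) + 1 for a in range(3))
    origin = tuple(
        phantom_grid.center()[a] - 0.5 * (shape[a] - 1) * voxel_mm[a] for a in range(3)
    )
    return GridSpec(shape, tuple(float(v) for v in voxel_mm), origin)


def _sample_truth(
    truth: PhantomTruth, grid: GridSpec, misalign: RigidTransform | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truth T2/ADC/S0 sampled (once) onto an acquisition grid, optionally misaligned."""
    t = misalign or RigidTransform.identity(tuple(grid.center()))
    t2 = resample(truth.t2_truth.values, t, grid, mode="linear").data
    adc = resample(truth.adc_truth.values, t, grid, mode="linear").data
    s0 = resample(truth.s0_truth, t, grid, mode="linear").data
    # outside the phantom FOV there is air: no signal
    s0 = np.where(np.isfinite(s0), s0, 0.0)
    t2 = np.where(np.isfinite(t2) & (t2 > 0), t2, 1.0)
    adc = np.where(np.isfinite(adc) & (adc > 0), adc, 1e-5)
    return t2, adc, s0


def simulate_echo_series(
    truth: PhantomTruth,
    echo_times,
    snr: float | None,
    rng: np.random.Generator | int | None = None,
    *,
    grid: GridSpec | None = None,
    misalign: RigidTransform | None = None,
) -> AcquisitionSeries:
    """Simulate a multi-echo spin-echo series S(TE) = S0 exp(-TE/T2) with Rician noise.

    ``snr=None`` (or ``numpy.inf``) gives the noiseless forward model; the
    noise sigma is S0_prostate / snr per channel.
    """
    te = np.asarray(echo_times, float)
    if te.size == 0 or np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be non-empty and strictly increasing")
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = grid or truth.t2_truth.grid
    t2, _, s0 = _sample_truth(truth, grid, misalign)
    sigma = 0.0 if snr is None or np.isinf(snr) else PROSTATE_S0 / snr
    vols = []
    for t in te:
        clean = s0 * np.exp(-t / t2)
        vols.append(
            VolumeGrid(rician(clean, sigma, rng), grid.spacing, grid.origin)
        )
    return AcquisitionSeries(vols, te, "echo")


def simulate_dwi_series(
    truth: PhantomTruth,
    b_values,
    snr: float | None,
    rng: np.random.Generator | int | None = None,
    *,
    grid: GridSpec | None = None,
    misalign: RigidTransform | None = None,
) -> AcquisitionSeries:
    """Simulate a DWI series S(b) = S0 exp(-b ADC) with Rician noise."""
    b = np.asarray(b_values, float)
    if b.size == 0 or np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if not np.isclose(b, 0.0).any():
        raise ValueError("DWI series must include b=0")
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = grid or truth.adc_truth.grid
    _, adc, s0 = _sample_truth(truth, grid, misalign)
    sigma = 0.0 if snr is None or np.isinf(snr) else PROSTATE_S0 / snr
    vols = []
    for bv in b:
        clean = s0 * np.exp(-bv * adc)
        vols.append(VolumeGrid(rician(clean, sigma, rng), grid.spacing, grid.origin))
    return AcquisitionSeries(vols, b, "dwi")


def synthesize_t2w(
    truth: PhantomTruth,
    te: float = 120.0,
    snr: float | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    grid: GridSpec | None = None,
    misalign: RigidTransform | None = None,
    psf_sigma_mm: tuple[float, float, float] | None = (0.5, 0.5, 1.0),
) -> VolumeGrid:
    """Anatomical T2-weighted volume: the spin-echo forward model at one TE.

    At TE = 120 ms the prostate compartments show realistic inter-tissue
    contrast, which is what the rigid registration consumes.  Unlike the
    quantitative series, the signal is formed on the truth grid, blurred with
    a Gaussian acquisition point-spread (``psf_sigma_mm``), and only then
    sampled onto the acquisition grid — band-limiting that mirrors a real
    acquisition and avoids lattice aliasing that would otherwise bias the
    registration metric.  Rician noise is added per acquired voxel.
    """
    from scipy import ndimage

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tgrid = truth.t2_truth.grid
    grid = grid or tgrid
    sig = truth.s0_truth.data * np.exp(-te / np.maximum(truth.t2_truth.values.data, 1e-6))
    if psf_sigma_mm is not None:
        sig = ndimage.gaussian_filter(
            sig, sigma=np.asarray(psf_sigma_mm) / np.asarray(tgrid.spacing)
        )
    vol = VolumeGrid(sig, tgrid.spacing, tgrid.origin)
    t = misalign or RigidTransform.identity(tuple(grid.center()))
    out = resample(vol, t, grid, mode="linear")
    out.data[~np.isfinite(out.data)] = 0.0
    sigma = 0.0 if snr is None or np.isinf(snr) else PROSTATE_S0 / snr
    return VolumeGrid(rician(out.data, sigma, rng), grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_baselines(dialect: str, scale: float, rng: np.random.Generator) -> dict:
    """Per-patient baselines: lognormal around the population medians, IQR-matched."""
    adc_med = BASELINE_ADC_A if dialect == "A" else BASELINE_ADC_B
    adc_iqr = BASELINE_ADC_IQR_A if dialect == "A" else BASELINE_ADC_IQR_B
    out = {"T2": {}, "ADC": {}}
    for roi in ("CG", "PZ", "tumor"):
        for map_type, med, iqr in (
            ("T2", BASELINE_T2_MS[roi], BASELINE_T2_IQR[roi]),
            ("ADC", adc_med[roi], adc_iqr[roi]),
        ):
            sigma = scale * iqr / (2 * 0.6745 * med)  # lognormal sigma matching the IQR
            out[map_type][roi] = med * np.exp(rng.normal(0.0, sigma)) if sigma > 0 else med
    return out


def _patient_profiles(
    stratum: str, jitter_sd: float, rng: np.random.Generator, week5_override: dict | None
) -> dict:
    profiles = {}
    base = dict(WEEK5_FACTORS)
    if week5_override:
        for k, v in week5_override.items():
            key = tuple(k.split("/")) if isinstance(k, str) else tuple(k)
            base[key] = float(v)
    for (strat, roi, map_type), f5 in base.items():
        if strat != stratum:
            continue
        f5_i = f5 * np.exp(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else f5
        factors = tuple(1.0 + (f5_i - 1.0) * w / 5.0 for w in range(6))
        profiles[(strat, roi, map_type)] = EffectProfile(roi, map_type, strat, factors)
    return profiles


def _random_rigid(
    max_mm: float, max_deg: float, center, rng: np.random.Generator
) -> RigidTransform:
    rot = rng.uniform(-max_deg, max_deg, 3) if max_deg > 0 else np.zeros(3)
    tra = rng.uniform(-max_mm, max_mm, 3) if max_mm > 0 else np.zeros(3)
    return RigidTransform(tuple(rot), tuple(tra), tuple(center))


def generate_patient(
    config: SimConfig,
    index: int,
    geometry: PhantomGeometry | None = None,
    forced_missing: dict[int, list[int]] | None = None,
) -> PatientRecord:
    """Simulate one patient's pretreatment and weekly exams.

    Each patient has an independent random stream derived from
    ``(config.seed, index)``, so patients can be generated one at a time (or
    in any order) and a whole cohort never has to be held in memory at once.
    Weekly exams (weeks 1-5) are synthesized under a known random rigid
    misalignment relative to the pretreatment grid; the sidecar transform
    ``true_align`` is the transform that resamples the exam back onto the
    pretreatment grid, i.e. exactly what registration should recover.
    """
    geometry = geometry or PhantomGeometry()
    dialect = DIALECTS[config.dialect]
    rng = np.random.default_rng([config.seed, index])
    n_ht = int(round(config.n_patients * config.ht_fraction))

    phantom_grid = geometry.grid()
    t2w_grid = _acquisition_grid(phantom_grid, dialect.t2w_voxel_mm)
    dwi_grid = _acquisition_grid(phantom_grid, dialect.dwi_recon_voxel_mm)
    echo_grid = (
        _acquisition_grid(phantom_grid, dialect.echo_acquired_voxel_mm)
        if dialect.has_t2_mapping
        else None
    )

    ht = index < n_ht
    stratum = "HT" if ht else "noHT"
    baselines = _draw_baselines(config.dialect, config.baseline_variation, rng)
    truth0 = build_phantom(
        geometry,
        baseline_t2=baselines["T2"],
        baseline_adc=baselines["ADC"],
        within_roi_variation=config.within_roi_variation,
        rng=rng,
    )
    profiles = _patient_profiles(
        stratum, config.effect_jitter_sd, rng, config.week5_factors
    )
    week5 = {(k[1], k[2]): p.weekly_factors[5] for k, p in profiles.items()}

    missing = {w for w in WEEKS[1:] if rng.uniform() < config.missing_prob}
    if forced_missing and index in forced_missing:
        missing |= set(forced_missing[index])

    record = PatientRecord(
        patient_id=f"P{index:03d}",
        ht=ht,
        dialect=config.dialect,
        truth=truth0,
        baselines=baselines,
        effect_week5=week5,
    )

    def _compact(vol: VolumeGrid) -> VolumeGrid:
        # float32 is ample for simulated magnitudes and halves cohort memory
        vol.data = np.asarray(vol.data, dtype=np.float32)
        return vol

    for w in WEEKS:
        if w in missing:
            continue
        truth_w = apply_effect(truth0, profiles, w, stratum)
        if w == 0:
            t_align = RigidTransform.identity(tuple(phantom_grid.center()))
            mis = None
        else:
            t_align = _random_rigid(
                config.misalignment_max_mm,
                config.misalignment_max_deg,
                phantom_grid.center(),
                rng,
            )
            # the exam is the truth observed under the inverse transform
            mis = t_align.inverse()
        t2w = _compact(
            synthesize_t2w(
                truth_w, dialect.t2w_te_ms, config.t2w_snr, rng, grid=t2w_grid,
                misalign=mis,
            )
        )
        dwi = simulate_dwi_series(
            truth_w, dialect.dwi_b_values, config.snr, rng, grid=dwi_grid, misalign=mis
        )
        for vol in dwi.volumes:
            _compact(vol)
        echoes = None
        if dialect.has_t2_mapping:
            echoes = simulate_echo_series(
                truth_w,
                dialect.echo_times_ms,
                config.snr,
                rng,
                grid=echo_grid,
                misalign=mis,
            )
            for vol in echoes.volumes:
                _compact(vol)
        record.exams[w] = ExamRecord(
            week=w, t2w=t2w, dwi=dwi, echoes=echoes, true_align=t_align
        )
    return record


def iter_cohort(
    config: SimConfig,
    geometry: PhantomGeometry | None = None,
    forced_missing: dict[int, list[int]] | None = None,
):
    """Yield the cohort's patients one at a time (constant memory)."""
    for i in range(config.n_patients):
        yield generate_patient(config, i, geometry, forced_missing)


def generate_cohort(
    config: SimConfig,
    geometry: PhantomGeometry | None = None,
    forced_missing: dict[int, list[int]] | None = None,
) -> Cohort:
    """Simulate the full longitudinal image cohort described by ``config``.

    Materializes every patient; for large cohorts prefer :func:`iter_cohort`
    and process patients as they stream.
    """
    return Cohort(
        config=config,
        patients=list(iter_cohort(config, geometry, forced_missing)),
    )


def simulate_trajectory_cohort(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Per-patient ROI-median trajectories without image synthesis.

    Same baselines, per-patient effects and missingness as the image-level
    generator; each measured median carries an independent lognormal error of
    scale ``config.median_noise_sd``.  Returns a tidy table with columns
    (patient, ht, dialect, roi, map_type, week, median_value, measured).
    """
    rng = (
        np.random.default_rng(config.seed if rng is None else rng)
        if not isinstance(rng, np.random.Generator)
        else rng
    )
    n_ht = int(round(config.n_patients * config.ht_fraction))
    has_t2 = DIALECTS[config.dialect].has_t2_mapping
    rows = []
    for i in range(config.n_patients):
        ht = i < n_ht
        stratum = "HT" if ht else "noHT"
        baselines = _draw_baselines(config.dialect, config.baseline_variation, rng)
        profiles = _patient_profiles(
            stratum, config.effect_jitter_sd, rng, config.week5_factors
        )
        missing = {w for w in WEEKS[1:] if rng.uniform() < config.missing_prob}
        for roi in ("CG", "PZ", "tumor"):
            for map_type in ("T2", "ADC"):
                if map_type == "T2" and not has_t2:
                    continue
                base = baselines[map_type][roi]
                factors = profiles[(stratum, roi, map_type)].weekly_factors
                for w in WEEKS:
                    if w in missing:
                        continue
                    noise = (
                        np.exp(rng.normal(0.0, config.median_noise_sd))
                        if config.median_noise_sd > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "patient": f"P{i:03d}",
                            "ht": ht,
                            "dialect": config.dialect,
                            "roi": roi,
                            "map_type": map_type,
                            "week": w,
                            "median_value": base * factors[w] * noise,
                            "measured": True,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk representation


def save_patient(p: PatientRecord, directory: str | Path) -> Path:
    """Write one patient's subtree (truth, masks, exams) under the cohort directory."""
    pdir = Path(directory) / p.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    masks = p.roi_masks()
    for roi, vol in masks.items():
        vol.save(pdir / f"mask_{roi.lower()}.nii.gz")
    p.truth.label_volume.save(pdir / "truth_labels.nii.gz")
    p.truth.t2_truth.values.save(pdir / "truth_t2.nii.gz")
    p.truth.adc_truth.values.save(pdir / "truth_adc.nii.gz")
    p.truth.s0_truth.save(pdir / "truth_s0.nii.gz")
    meta = {
        "patient": p.patient_id,
        "ht": p.ht,
        "dialect": p.dialect,
        "baselines": {
            m: {r: float(v) for r, v in d.items()} for m, d in p.baselines.items()
        },
        "effect_week5": {f"{r}/{m}": float(v) for (r, m), v in p.effect_week5.items()},
    }
    (pdir / "patient.json").write_text(json.dumps(meta, indent=1))
    for w, exam in p.exams.items():
        edir = pdir / f"week{w}"
        edir.mkdir(exist_ok=True)
        exam.t2w.save(edir / "t2w.nii.gz")
        exam.dwi.save(edir, "dwi")
        if exam.echoes is not None:
            exam.echoes.save(edir, "echo")
        exam.true_align.save(edir / "true_align.json")
    return pdir


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write the cohort tree: NIfTI volumes, JSON sidecars, and a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        save_patient(p, directory)
    cohort.manifest().to_csv(directory / "manifest.csv", index=False)
    cfg = asdict(cohort.config)
    (directory / "sim_config.json").write_text(json.dumps(cfg, indent=1, default=str))
    return directory


def load_patient(directory: str | Path, patient_id: str, weeks) -> PatientRecord:
    """Read one patient's subtree back into memory."""
    from .grid import load_volume
    from .phantom import PhantomTruth

    pdir = Path(directory) / patient_id
    meta = json.loads((pdir / "patient.json").read_text())
    labels = load_volume(pdir / "truth_labels.nii.gz")
    labels.data = np.rint(labels.data).astype(np.int16)
    truth = PhantomTruth(
        label_volume=labels,
        t2_truth=QuantMap(load_volume(pdir / "truth_t2.nii.gz"), labels.data > 0, "T2"),
        adc_truth=QuantMap(
            load_volume(pdir / "truth_adc.nii.gz"), labels.data > 0, "ADC"
        ),
        s0_truth=load_volume(pdir / "truth_s0.nii.gz"),
    )
    record = PatientRecord(
        patient_id=meta["patient"],
        ht=bool(meta["ht"]),
        dialect=meta["dialect"],
        truth=truth,
        baselines=meta["baselines"],
        effect_week5={tuple(k.split("/")): v for k, v in meta["effect_week5"].items()},
    )
    for w in sorted(int(w) for w in weeks):
        edir = pdir / f"week{w}"
        echoes = (
            AcquisitionSeries.load(edir, "echo")
            if (edir / "echo.json").exists()
            else None
        )
        record.exams[w] = ExamRecord(
            week=w,
            t2w=load_volume(edir / "t2w.nii.gz"),
            dwi=AcquisitionSeries.load(edir, "dwi"),
            echoes=echoes,
            true_align=RigidTransform.load(edir / "true_align.json"),
        )
    return record


def iter_saved_cohort(directory: str | Path):
    """Yield patients of an on-disk cohort one at a time (constant memory)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    for pid, g in manifest.groupby("patient", sort=True):
        yield load_patient(directory, pid, g["week"])


def load_cohort(directory: str | Path) -> Cohort:
    """Read a cohort tree written by :func:`save_cohort` back into memory."""
    directory = Path(directory)
    config = SimConfig(**json.loads((directory / "sim_config.json").read_text()))
    return Cohort(config=config, patients=list(iter_saved_cohort(directory)))
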
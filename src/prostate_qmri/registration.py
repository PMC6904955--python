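"""Rigid alignment of weekly exams to the pretreatment reference.

Transforms are 6-DOF rigid mappings parameterized as three Euler angles
(degrees, extrinsic x-y-z order) plus three translations (mm), pivoting about
an explicit center point.  Following the resampling convention of ITK, a
transform maps points of the *target* (fixed) space into the *source*
(moving) space, so ``resample(moving, t, target_grid)`` pulls the moving
volume onto the target grid.

Registration itself delegates to SimpleITK: histogram-based Mattes mutual
information, a 3-level multi-resolution pyramid, and gradient-descent
optimization of a centered Euler3D transform.  Correctness is defined by the
recovery contract exercised in the test suite: simulated misalignments up to
+/-5 mm and +/-5 deg must be recovered to within 0.5 mm and 0.5 deg on
phantom data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grid import GridSpec, QuantMap, VolumeGrid

__all__ = [
    "NoSignalError",
    "GridMismatchError",
    "RigidTransform",
    "register_rigid",
    "compose",
    "resample",
    "reference_grid",
    "propagate_exam",
]


class NoSignalError(ValueError):
    """Registration input has no intensity structure (constant image)."""


class GridMismatchError(ValueError):
    """Transform chaining attempted across incompatible grids."""


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform: y = R(x - c) + c + t.

    The point mapping goes from ``source_grid`` space to ``target_grid``
    space.  During resampling the mapping runs from the output grid into the
    volume being pulled: to resample volume V onto grid G, use a transform
    with ``source_grid == G`` and ``target_grid == V.grid`` (this is the ITK
    fixed-to-moving convention; :func:`register_rigid` returns exactly that).
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_grid: GridSpec | None = None
    target_grid: GridSpec | None = None

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the point mapping."""
        R = self.rotation_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from source-grid space to target-grid space."""
        pts = np.asarray(points, dtype=float)
        R = self.rotation_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ R.T + c + t

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix()
        inv = np.linalg.inv(self.matrix())
        rot = Rotation.from_matrix(inv[:3, :3]).as_euler("xyz", degrees=True)
        c = np.asarray(self.center_mm)
        t = inv[:3, 3] - c + inv[:3, :3] @ c
        return RigidTransform(
            tuple(rot),
            tuple(t),
            self.center_mm,
            source_grid=self.target_grid,
            target_grid=self.source_grid,
        )

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation_deg, 0, atol=tol)
            and np.allclose(self.translation_mm, 0, atol=tol)
        )

    @classmethod
    def identity(
        cls,
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
        source_grid: GridSpec | None = None,
        target_grid: GridSpec | None = None,
    ) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), tuple(center), source_grid, target_grid)

    # -- serialization (JSON sidecar interchange) ---------------------------
    def to_dict(self) -> dict:
        d = {
            "rotation_deg_xyz": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
        }
        for name, g in (("source_grid", self.source_grid), ("target_grid", self.target_grid)):
            if g is not None:
                d[name] = {
                    "shape": list(g.shape),
                    "spacing": list(g.spacing),
                    "origin": list(g.origin),
                }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        def grid(key):
            if key not in d:
                return None
            g = d[key]
            return GridSpec(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))

        return cls(
            tuple(d["rotation_deg_xyz"]),
            tuple(d["translation_mm"]),
            tuple(d["center_mm"]),
            grid("source_grid"),
            grid("target_grid"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``a`` then ``b`` pointwise.

    Used to chain per-stage registrations (e.g. DWI-to-exam then
    exam-to-pretreatment) so each quantitative map is interpolated once.
    """
    if a.target_grid is not None and b.source_grid is not None:
        if not a.target_grid.approx_equal(b.source_grid):
            raise GridMismatchError("compose: a.target_grid differs from b.source_grid")
    m = b.matrix() @ a.matrix()
    rot = Rotation.from_matrix(m[:3, :3]).as_euler("xyz", degrees=True)
    c = np.asarray(b.center_mm)
    t = m[:3, 3] - c + m[:3, :3] @ c
    return RigidTransform(
        tuple(rot),
        tuple(t),
        tuple(c),
        source_grid=a.source_grid,
        target_grid=b.target_grid,
    )


# ---------------------------------------------------------------------------
# SimpleITK bridge


def _to_sitk(vol: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T, dtype=np.float32))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    return img


def _to_sitk_transform(t: RigidTransform) -> sitk.Euler3DTransform:
    out = sitk.Euler3DTransform()
    out.SetCenter(tuple(float(x) for x in t.center_mm))
    out.SetMatrix(tuple(t.rotation_matrix().ravel()))
    out.SetTranslation(tuple(float(x) for x in t.translation_mm))
    return out


def _from_sitk_transform(
    t: sitk.Euler3DTransform,
    source_grid: GridSpec | None,
    target_grid: GridSpec | None,
) -> RigidTransform:
    R = np.asarray(t.GetMatrix()).reshape(3, 3)
    rot = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    return RigidTransform(
        tuple(rot),
        tuple(t.GetTranslation()),
        tuple(t.GetCenter()),
        source_grid,
        target_grid,
    )


def register_rigid(
    moving: VolumeGrid,
    fixed: VolumeGrid,
    init: RigidTransform | None = None,
    *,
    bins: int = 50,
    working_spacing: tuple[float, float, float] | None = (1.4, 1.4, 3.0),
    sampling_fraction: float = 0.25,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0),
    iterations: int = 200,
    refine_iterations: int = 100,
    polish_iterations: int = 0,
    sampling_seed: int = 12345,
) -> RigidTransform:
    """Estimate the 6-DOF transform aligning ``moving`` to ``fixed`` by mutual information.

    Three stages: (1) a 3-level multi-resolution capture stage at an internal
    working resolution (high-resolution anatomical volumes carry more voxels
    than the rigid parameters need); (2) a full-metric-sampling refinement at
    the working resolution; (3) a short polish at the native resolution.
    Stages 2/3 matter because the stochastic capture stage alone can stall a
    few tenths of a degree from the metric optimum.  ``refine_iterations=0``
    / ``polish_iterations=0`` skip the respective stage (faster, slightly
    less accurate — sufficient when only region medians are consumed
    downstream).

    Returns the transform mapping fixed-space points into moving space, i.e.
    the transform to hand to :func:`resample` to pull the moving volume onto
    the fixed grid.
    """
    for name, vol in (("moving", moving), ("fixed", fixed)):
        if not np.isfinite(vol.data).any() or np.ptp(vol.data[np.isfinite(vol.data)]) == 0:
            raise NoSignalError(f"{name} image is constant; cannot register")

    def _downsample(vol: VolumeGrid) -> VolumeGrid:
        g = vol.grid
        sp = tuple(max(w, s) for w, s in zip(working_spacing, g.spacing))
        if np.allclose(sp, g.spacing):
            return vol
        # anti-alias before decimation: ~0.5 new-voxel Gaussian
        sig_vox = [
            0.5 * sp[a] / g.spacing[a] if sp[a] > g.spacing[a] * 1.01 else 0.0
            for a in range(3)
        ]
        smoothed = vol.with_data(
            ndimage.gaussian_filter(np.asarray(vol.data, float), sigma=sig_vox)
        )
        extent = [(g.shape[a] - 1) * g.spacing[a] for a in range(3)]
        shape = tuple(int(np.floor(extent[a] / sp[a])) + 1 for a in range(3))
        origin = tuple(g.center()[a] - 0.5 * (shape[a] - 1) * sp[a] for a in range(3))
        out = resample(
            smoothed, RigidTransform.identity(tuple(g.center())), GridSpec(shape, sp, origin)
        )
        out.data[~np.isfinite(out.data)] = 0.0
        return out

    if working_spacing is not None:
        fixed_w = _downsample(fixed)
        moving_w = _downsample(moving)
    else:
        fixed_w, moving_w = fixed, moving

    if init is None:
        t0 = sitk.Euler3DTransform()
        t0.SetCenter(tuple(fixed.grid.center()))
    else:
        t0 = _to_sitk_transform(init)

    def _run(f_img, m_img, sampling, shrink, sigmas, iters, min_step, lr):
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling, sampling_seed)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=lr,
            minStep=min_step,
            numberOfIterations=iters,
            relaxationFactor=0.6,
            gradientMagnitudeTolerance=1e-7,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(shrink))
        reg.SetSmoothingSigmasPerLevel(list(sigmas))
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(t0, inPlace=True)
        reg.Execute(f_img, m_img)

    f_w = _to_sitk(fixed_w)
    m_w = _to_sitk(moving_w)
    _run(f_w, m_w, sampling_fraction, shrink_factors, smoothing_sigmas, iterations, 5e-5, 1.0)
    if refine_iterations > 0:
        # scale-space continuation: a smoothed full-sampling pass first walks
        # out of noise-induced local optima, then the sharp pass locks in
        _run(f_w, m_w, 1.0, (1, 1, 1), (2.0, 1.0, 0.0), refine_iterations, 1e-5, 1.0)
    if polish_iterations > 0:
        _run(
            _to_sitk(fixed),
            _to_sitk(moving),
            sampling_fraction,
            (1,),
            (0.0,),
            polish_iterations,
            2e-5,
            0.3,
        )
    return _from_sitk_transform(t0, source_grid=fixed.grid, target_grid=moving.grid)


def mutual_information(
    a: VolumeGrid, b: VolumeGrid, transform: RigidTransform | None = None, bins: int = 32
) -> float:
    """Mutual information (nats) between ``a`` and ``b`` resampled under ``transform``.

    Direct evaluation of the registration objective, for diagnostics and for
    verifying that the unperturbed alignment scores at least as high as rigid
    perturbations.
    """
    if transform is None:
        transform = RigidTransform.identity(tuple(a.grid.center()))
    b_on_a = resample(b, transform, a.grid, mode="linear")
    x = a.data.ravel()
    y = b_on_a.data.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    h, _, _ = np.histogram2d(x[ok], y[ok], bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# Resampling


def resample(
    volume: VolumeGrid | QuantMap,
    transform: RigidTransform,
    target: GridSpec,
    mode: str = "linear",
):
    """Pull a volume or quantitative map onto ``target`` through a rigid transform.

    ``mode='linear'`` (intensities and quantitative maps) marks voxels that
    map outside the source field of view — or touch invalid source voxels —
    as NaN/invalid rather than zero-filling them; ``mode='nearest'`` is for
    masks and label volumes and yields exact source values.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")

    if isinstance(volume, QuantMap):
        data = np.where(volume.valid, volume.values.data, np.nan)
        src = volume.values.with_data(data)
        out = resample(src, transform, target, mode="linear")
        valid = np.isfinite(out.data)
        values = np.where(valid, out.data, -1.0)
        return QuantMap(
            VolumeGrid(values, target.spacing, target.origin),
            valid,
            volume.map_type,
            dict(volume.fit_meta),
        )

    xs, ys, zs = target.world_coords()
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    mapped = transform.apply(pts.reshape(-1, 3))
    idx = volume.grid.world_to_index(mapped).T.reshape(3, *target.shape)

    if mode == "nearest":
        out = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), idx, order=0, mode="constant", cval=0.0
        )
        if np.array_equal(np.unique(volume.data), np.unique(volume.data).astype(int)):
            out = out.astype(volume.data.dtype)
    else:
        out = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float),
            idx,
            order=1,
            mode="constant",
            cval=np.nan,
        )
    return VolumeGrid(out, target.spacing, target.origin)


def reference_grid(
    prostate_mask: VolumeGrid, pad_mm: float = 20.0, spacing_mm: float = 1.0
) -> GridSpec:
    """Axis-aligned isotropic analysis grid bounding the pretreatment prostate.

    All registered maps and masks are resampled onto this grid (1 mm isotropic
    by default) before erosion and median extraction.
    """
    mask = np.asarray(prostate_mask.data) > 0
    if not mask.any():
        raise ValueError("prostate mask is empty; cannot build reference grid")
    lo_w = []
    hi_w = []
    nz = np.nonzero(mask)
    for a in range(3):
        lo = nz[a].min()
        hi = nz[a].max()
        lo_w.append(prostate_mask.origin[a] + lo * prostate_mask.spacing[a] - pad_mm)
        hi_w.append(prostate_mask.origin[a] + hi * prostate_mask.spacing[a] + pad_mm)
    shape = tuple(int(np.floor((hi_w[a] - lo_w[a]) / spacing_mm)) + 1 for a in range(3))
    return GridSpec(shape, (spacing_mm,) * 3, tuple(lo_w))


def propagate_exam(
    exam,
    pre_t2w: VolumeGrid,
    reference: GridSpec,
    *,
    override_exam_to_pre: RigidTransform | None = None,
    within_exam: str = "identity",
    registration_kwargs: dict | None = None,
):
    """Carry one exam's quantitative maps onto the pretreatment reference grid.

    The ADC map travels through (b0 -> exam T2w) o (exam T2w -> pre T2w); the
    T2 map through (selected echo -> exam T2w) o (exam T2w -> pre T2w).  Each
    map is resampled exactly once: transforms are composed first.

    ``override_exam_to_pre`` supplies a manually adapted exam-to-pretreatment
    transform and skips the automatic registration (the analog of manual
    adaptation of failed registrations).  ``within_exam`` is ``'identity'``
    when the series of an exam are already co-registered (true for simulated
    exams) or ``'register'`` to estimate the intra-exam chains too.

    Returns ``(maps, transforms)`` where ``maps`` holds the propagated
    :class:`QuantMap` per map type and ``transforms`` the chain actually used.
    """
    kw = registration_kwargs or {}
    if within_exam not in ("identity", "register"):
        raise ValueError(f"unknown within_exam policy {within_exam!r}")

    if override_exam_to_pre is not None:
        t_exam2pre = override_exam_to_pre
    else:
        t_exam2pre = register_rigid(exam.t2w, pre_t2w, **kw)

    maps: dict[str, QuantMap] = {}
    transforms: dict[str, RigidTransform] = {"exam_to_pre": t_exam2pre}

    if exam.adc_map is not None:
        if exam.b0 is None:
            raise ValueError("exam has an ADC map but no b=0 volume for the chain")
        if within_exam == "register":
            t_b0 = register_rigid(exam.b0, exam.t2w, **kw)
        else:
            t_b0 = RigidTransform.identity(
                tuple(exam.t2w.grid.center()),
                source_grid=exam.t2w.grid,
                target_grid=exam.b0.grid,
            )
        chain = compose(t_exam2pre, t_b0)
        transforms["adc_chain"] = chain
        maps["ADC"] = resample(exam.adc_map, chain, reference, mode="linear")

    if exam.t2_map is not None:
        if within_exam == "register" and exam.registration_echo is not None:
            t_echo = register_rigid(exam.registration_echo, exam.t2w, **kw)
        else:
            t_echo = RigidTransform.identity(
                tuple(exam.t2w.grid.center()),
                source_grid=exam.t2w.grid,
                target_grid=exam.t2_map.grid,
            )
        chain = compose(t_exam2pre, t_echo)
        transforms["t2_chain"] = chain
        maps["T2"] = resample(exam.t2_map, chain, reference, mode="linear")

    return maps, transforms
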
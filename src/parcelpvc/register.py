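"""Rigid and affine coregistration of PET to a modeled-PET reference.

The clinical chain of cross-modality registrations is collapsed here to
a same-modality problem: the PET image is registered to a PET model built
from the MRI parcellation, so simple intensity costs work.  Two costs are
offered: sum-of-squared differences (the default for the fine-tuning step)
and normalized mutual information (32-bin histograms), with a 3-level
multi-resolution, derivative-free (Powell) search.  Nonlinear estimation
is never re-implemented: it is a pluggable adapter whose contract is "a
displacement field on the reference grid".

Transforms act on world coordinates (mm) and are push-forward: applying a
translation of +2 mm in x moves image content +2 mm in world x.  Rotations
are about the world origin, which for package-generated volumes coincides
with the volume center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volumes import ScalarVolume, Volume

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "DisplacementField",
    "apply_transform",
    "estimate_rigid",
    "estimate_affine",
    "nonlinear_adapter",
    "register_nonlinear_backend",
    "normalized_mutual_information",
]


def _rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Rz @ Ry @ Rx with angles in degrees."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class RigidTransform:
    """6-dof transform: rotations (deg) about the world origin + translation (mm)."""

    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    final_cost: float | None = None
    converged: bool | None = None

    def __post_init__(self):
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = _rotation_matrix(*self.rotation_deg)
        m[:3, 3] = self.translation_mm
        return m

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


@dataclass
class AffineTransform:
    """12-parameter world-coordinate affine (stored as a 4x4 matrix)."""

    matrix: np.ndarray
    final_cost: float | None = None
    converged: bool | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape == (3, 4):
            self.matrix = np.vstack([self.matrix, [0, 0, 0, 1]])
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 3x4 or 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("degenerate affine transform")

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def to_text(self, path) -> None:
        np.savetxt(path, self.matrix[:3, :], fmt="%.12g")

    @classmethod
    def from_text(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path))


@dataclass
class DisplacementField:
    """Per-voxel world displacement (mm), shape (3, nx, ny, nz), on a reference grid."""

    field: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 4 or self.field.shape[0] != 3:
            raise ValueError("displacement field must have shape (3, nx, ny, nz)")
        if not np.isfinite(self.field).all():
            raise ValueError("displacement field contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)


_ORDER = {"nearest": 0, "linear": 1, "cubic": 3}


def apply_transform(
    moving: ScalarVolume,
    t,
    reference: Volume | None = None,
    interpolation: str = "linear",
    return_valid: bool = False,
):
    """Resample ``moving`` onto the reference grid under transform ``t``.

    Out-of-field voxels are set to 0; with ``return_valid=True`` a binary
    validity mask marking in-field voxels is returned alongside.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_ORDER)}")
    order = _ORDER[interpolation]
    ref = moving if reference is None else reference
    inv_mov = np.linalg.inv(moving.affine)

    if isinstance(t, (RigidTransform, AffineTransform)):
        m = t.matrix
        # sample moving at A_mov^-1 M^-1 A_ref v  (push-forward semantics)
        b = inv_mov @ np.linalg.inv(m) @ ref.affine
        out = ndimage.affine_transform(
            moving.data, b[:3, :3], offset=b[:3, 3], output_shape=ref.shape,
            order=order, mode="constant", cval=0.0,
        )
        if return_valid:
            ones = np.ones(moving.shape)
            valid = ndimage.affine_transform(
                ones, b[:3, :3], offset=b[:3, 3], output_shape=ref.shape,
                order=0, mode="constant", cval=0.0,
            )
    elif isinstance(t, DisplacementField):
        if t.field.shape[1:] != ref.shape:
            raise ValueError("displacement field is not on the reference grid")
        idx = np.indices(ref.shape, dtype=float)
        world = np.einsum("ab,b...->a...", ref.affine[:3, :3], idx) + ref.affine[
            :3, 3
        ].reshape(3, 1, 1, 1)
        world = world + t.field
        vox = np.einsum("ab,b...->a...", inv_mov[:3, :3], world) + inv_mov[:3, 3].reshape(
            3, 1, 1, 1
        )
        out = ndimage.map_coordinates(
            moving.data, vox, order=order, mode="constant", cval=0.0
        )
        if return_valid:
            valid = ndimage.map_coordinates(
                np.ones(moving.shape), vox, order=0, mode="constant", cval=0.0
            )
    else:
        raise TypeError(f"unsupported transform type: {type(t)!r}")

    result = ScalarVolume(out, ref.affine.copy())
    if return_valid:
        return result, ScalarVolume(valid, ref.affine.copy())
    return result


# --------------------------------------------------------------------------
# similarity costs
# --------------------------------------------------------------------------


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """(H(A) + H(B)) / H(A, B) from a joint histogram; higher is better."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    hxy = -np.sum(p[nz] * np.log(p[nz]))
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hxy == 0:
        return 2.0
    return float((hx + hy) / hxy)


def _downsample(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0, mode="constant")
    sub = sm[::factor, ::factor, ::factor]
    scale = np.diag([factor, factor, factor, 1.0])
    return ScalarVolume(sub, vol.affine @ scale)


def _cost_fn(name: str):
    if name == "least_squares":
        return lambda a, b: _ssd(a, b)
    if name == "normalized_mutual_information":
        return lambda a, b: -normalized_mutual_information(a, b)
    raise ValueError(f"unknown cost: {name!r}")


def _normalize_levels(levels):
    """Level specs: int factor, or (factor, interp_order, maxiter) tuples."""
    out = []
    for lv in levels:
        if np.isscalar(lv):
            out.append((int(lv), 1, 200))
        else:
            f, order, maxiter = lv
            out.append((int(f), int(order), int(maxiter)))
    return out


def _optimize_levels(moving, fixed, cost, params0, make_transform, bounds, levels):
    """Coarse-to-fine Powell descent; returns (params, final_cost, success).

    A final cubic-interpolation polish (when requested in the level spec)
    removes the sub-degree bias trilinear resampling leaves at the optimum.
    """
    costf = _cost_fn(cost)
    params = np.asarray(params0, dtype=float)
    success = True
    final = np.inf
    for factor, order, maxiter in _normalize_levels(levels):
        mov = _downsample(moving, factor)
        fix = _downsample(fixed, factor)
        coeffs = ndimage.spline_filter(mov.data, order=3) if order == 3 else mov.data
        inv_mov = np.linalg.inv(mov.affine)

        def objective(p):
            b = inv_mov @ np.linalg.inv(make_transform(p).matrix) @ fix.affine
            res = ndimage.affine_transform(
                coeffs, b[:3, :3], offset=b[:3, 3], output_shape=fix.shape,
                order=order, mode="constant", cval=0.0, prefilter=False,
            )
            return costf(res, fix.data)

        res = optimize.minimize(
            objective,
            params,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": maxiter},
        )
        params = res.x
        final = float(res.fun)
        # a capped polish stage (small maxiter) is not a convergence failure
        success = success and (bool(res.success) or res.status == 2)
    return params, final, success


def estimate_rigid(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    cost: str = "least_squares",
    rotation_bounds_deg: float = 30.0,
    translation_bounds_mm: float = 40.0,
    levels: tuple = ((4, 1, 200), (2, 1, 200), (1, 1, 200), (1, 3, 8)),
    init: RigidTransform | None = None,
) -> RigidTransform:
    """6-dof registration of ``moving`` to ``fixed`` by multi-resolution search.

    Returns the transform t such that ``apply_transform(moving, t, fixed)``
    best matches ``fixed`` under the chosen cost; the final cost and
    convergence status are recorded on the result.  If the optimizer fails
    to converge, the best-so-far transform is still returned (flagged).
    """
    p0 = np.zeros(6)
    if init is not None:
        p0 = np.concatenate([init.translation_mm, init.rotation_deg])
    tb, rb = translation_bounds_mm, rotation_bounds_deg
    bounds = [(-tb, tb)] * 3 + [(-rb, rb)] * 3

    def make(p):
        return RigidTransform(p[:3], p[3:])

    p, final, ok = _optimize_levels(moving, fixed, cost, p0, make, bounds, levels)
    if not ok:
        warnings.warn("rigid registration did not fully converge; returning best-so-far")
    return RigidTransform(p[:3], p[3:], final_cost=final, converged=ok)


def estimate_affine(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    translation_bounds_mm: tuple[float, float] = (-20.0, 20.0),
    cost: str = "least_squares",
    levels: tuple[int, ...] = (4, 2, 1),
    init: AffineTransform | None = None,
) -> AffineTransform:
    """12-parameter affine registration with a bounded translation search.

    Minimizes sum-of-squared differences subject to per-axis translation
    bounds (default [-20, 20] mm); a warning is emitted when the optimum is
    pinned at a bound.
    """
    lo, hi = translation_bounds_mm
    p0 = np.concatenate([np.zeros(3), np.eye(3).ravel()])
    if init is not None:
        p0 = np.concatenate([init.matrix[:3, 3], init.matrix[:3, :3].ravel()])
    lin_bounds = []
    for idx in range(9):
        diag = idx in (0, 4, 8)
        lin_bounds.append((0.5, 1.5) if diag else (-0.5, 0.5))
    bounds = [(lo, hi)] * 3 + lin_bounds

    def make(p):
        m = np.eye(4)
        m[:3, :3] = p[3:].reshape(3, 3)
        m[:3, 3] = p[:3]
        return AffineTransform(m)

    p, final, ok = _optimize_levels(moving, fixed, cost, p0, make, bounds, levels)
    if not ok:
        warnings.warn("affine registration did not fully converge; returning best-so-far")
    if np.any(np.isclose(p[:3], lo, atol=0.05)) or np.any(np.isclose(p[:3], hi, atol=0.05)):
        warnings.warn(
            f"affine optimum pinned at a translation bound {translation_bounds_mm}"
        )
    out = make(p)
    out.final_cost = final
    out.converged = ok
    return out


# --------------------------------------------------------------------------
# nonlinear adapter
# --------------------------------------------------------------------------

_NONLINEAR_BACKENDS: dict = {}


def register_nonlinear_backend(name: str, fn) -> None:
    """Register a callable (moving, fixed) -> DisplacementField."""
    _NONLINEAR_BACKENDS[name] = fn


def _identity_backend(moving: ScalarVolume, fixed: ScalarVolume) -> DisplacementField:
    return DisplacementField(np.zeros((3,) + tuple(fixed.shape)), fixed.affine.copy())


def _simpleitk_backend(moving: ScalarVolume, fixed: ScalarVolume) -> DisplacementField:
    """Demons registration via SimpleITK, if installed."""
    import SimpleITK as sitk  # optional dependency

    fix = sitk.GetImageFromArray(np.ascontiguousarray(fixed.data.T))
    mov = sitk.GetImageFromArray(np.ascontiguousarray(moving.data.T))
    fix.SetSpacing(tuple(float(s) for s in fixed.spacing))
    mov.SetSpacing(tuple(float(s) for s in moving.spacing))
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(30)
    demons.SetStandardDeviations(2.0)
    disp = demons.Execute(fix, mov)
    arr = sitk.GetArrayFromImage(disp)  # (z, y, x, 3)
    field = np.moveaxis(arr, -1, 0)[:, ...].transpose(0, 3, 2, 1)
    return DisplacementField(field, fixed.affine.copy())


register_nonlinear_backend("identity", _identity_backend)
register_nonlinear_backend("simpleitk", _simpleitk_backend)


def nonlinear_adapter(
    moving: ScalarVolume, fixed: ScalarVolume, backend: str = "identity"
) -> DisplacementField:
    """Delegate nonlinear estimation to a named backend.

    The package never re-implements nonlinear registration; backends must
    return a finite displacement field on the reference grid.  The
    ``identity`` backend returns a zero field.
    """
    if backend not in _NONLINEAR_BACKENDS:
        raise ValueError(
            f"nonlinear backend {backend!r} not available "
            f"(registered: {sorted(_NONLINEAR_BACKENDS)}; 'identity' is the fallback)"
        )
    out = _NONLINEAR_BACKENDS[backend](moving, fixed)
    if not np.isfinite(out.field).all():
        raise ValueError(f"backend {backend!r} produced non-finite displacements")
    return out
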
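"""Rigid-body (rotation + translation) transforms and resampling.

Conventions
-----------
* Coordinates are ``(x, y)`` = (horizontal/column, vertical/row), 0-based.
* Angles are degrees, counterclockwise in the ``(x, y)`` plane.
* A transform maps a source-image point ``p`` to
  ``R (p - c) + c + t`` where ``c`` is the rotation center — by default the
  image center ``((W-1)/2, (H-1)/2)`` — and ``t = (t_x, t_y)`` in pixels.
* Applying a transform to an image produces the image whose content has
  moved by the transform: pixels mapped from outside the source frame are
  zero-filled and marked invalid in the mask.

The displacement field of a rigid transform, ``u(p) = R(p-c)+c+t - p``, has
a closed-form total variation ``2 A (1 - cos a + |sin a|)`` over an area
``A`` — notably independent of ``t``, which is why TV of the displacement
field cannot drive a rigid registration and the difference-map TV is used
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imagemath import Image2D


def _normalize_angle(angle_deg: float) -> float:
    """Map an angle to (-180, 180]."""
    a = float(angle_deg) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``angle_deg`` about ``center`` followed by translation.

    ``center`` is ``(c_x, c_y)`` in pixel coordinates; ``None`` means "the
    center of whatever image the transform is applied to", resolved at
    application time.
    """

    angle_deg: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "angle_deg", _normalize_angle(self.angle_deg))

    @property
    def translation(self) -> tuple[float, float]:
        return (self.t_x, self.t_y)

    def rotation_matrix(self) -> np.ndarray:
        """2x2 counterclockwise rotation acting on (x, y) column vectors."""
        a = np.deg2rad(self.angle_deg)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])

    def resolve_center(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def apply_to_points(self, pts: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Map (N, 2) points in (x, y) through the transform."""
        if self.center is None and shape is None:
            raise ValueError("transform with implicit center needs an image shape")
        c = np.asarray(self.resolve_center(shape) if shape else self.center)
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        t = np.array([self.t_x, self.t_y])
        return (self.rotation_matrix() @ (pts - c).T).T + c + t

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.angle_deg) <= tol and abs(self.t_x) <= tol and abs(self.t_y) <= tol
        )


def identity() -> RigidTransform2D:
    return RigidTransform2D()


def invert(T: RigidTransform2D) -> RigidTransform2D:
    """The transform undoing ``T`` (same rotation center)."""
    Rinv = RigidTransform2D(angle_deg=-T.angle_deg).rotation_matrix()
    t = -(Rinv @ np.array([T.t_x, T.t_y]))
    return RigidTransform2D(-T.angle_deg, float(t[0]), float(t[1]), T.center)


def compose(T1: RigidTransform2D, T2: RigidTransform2D) -> RigidTransform2D:
    """Transform equivalent to applying ``T1`` first, then ``T2``.

    Both transforms must share a rotation-center convention (either the
    same explicit center or both implicit image-center).
    """
    if T1.center != T2.center:
        raise ValueError("cannot compose transforms with different rotation centers")
    R2 = RigidTransform2D(angle_deg=T2.angle_deg).rotation_matrix()
    t1 = np.array([T1.t_x, T1.t_y])
    t = R2 @ t1 + np.array([T2.t_x, T2.t_y])
    return RigidTransform2D(
        T1.angle_deg + T2.angle_deg, float(t[0]), float(t[1]), T1.center
    )


def apply_rigid(
    img: Image2D, T: RigidTransform2D, interpolation_order: int = 1
) -> Image2D:
    """Resample an image under a rigid transform.

    ``interpolation_order`` is 0 (nearest), 1 (bilinear, the default used by
    the search — higher orders ring at sharp edges and inflate the TV) or 3
    (bicubic).  Output pixels that pull from outside the source raster, or
    whose interpolation stencil touches an invalid pixel, are zero-filled
    and masked invalid.
    """
    if interpolation_order not in (0, 1, 3):
        raise ValueError(f"unsupported interpolation order {interpolation_order}")
    if T.is_identity():
        return img.copy()
    c_x, c_y = T.resolve_center(img.shape)
    # Inverse map: src_xy = Rinv (out_xy - c - t) + c, re-expressed in scipy's
    # (row, col) order as src_rc = Minv_rc @ out_rc + off_rc.
    Rinv_xy = RigidTransform2D(angle_deg=-T.angle_deg).rotation_matrix()
    off_xy = -Rinv_xy @ np.array([c_x + T.t_x, c_y + T.t_y]) + np.array([c_x, c_y])
    off_rc = off_xy[::-1]
    Minv_rc = np.array(
        [[Rinv_xy[1, 1], Rinv_xy[1, 0]], [Rinv_xy[0, 1], Rinv_xy[0, 0]]]
    )
    pixels = ndimage.affine_transform(
        img.pixels, Minv_rc, offset=off_rc, order=interpolation_order,
        mode="constant", cval=0.0,
    )
    # Mask: resample the float mask with the same (or linear) footprint and
    # keep only pixels whose whole stencil was valid and in-frame.
    mask_order = max(interpolation_order, 1)
    warped_mask = ndimage.affine_transform(
        img.mask.astype(np.float64), Minv_rc, offset=off_rc, order=mask_order,
        mode="constant", cval=0.0,
    )
    mask = warped_mask > 1.0 - 1e-6
    pixels = np.where(mask, pixels, 0.0)
    return Image2D(pixels, mask)


@dataclass
class DisplacementField:
    """Per-pixel displacement components of a transform, in pixels."""

    u_x: np.ndarray
    u_y: np.ndarray
    area: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape


def displacement_field(T: RigidTransform2D, shape: tuple[int, int]) -> DisplacementField:
    """Evaluate ``u(p) = R(p - c) + c + t - p`` on every pixel of ``shape``."""
    h, w = shape
    c_x, c_y = T.resolve_center(shape)
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    R = T.rotation_matrix()
    dx = xs - c_x
    dy = ys - c_y
    u_x = R[0, 0] * dx + R[0, 1] * dy + c_x + T.t_x - xs
    u_y = R[1, 0] * dx + R[1, 1] * dy + c_y + T.t_y - ys
    return DisplacementField(u_x, u_y, area=float(h * w))


def rigid_tv_closed_form(alpha_deg: float, area: float) -> float:
    """Exact TV of a rigid displacement field: ``2 A (1 - cos a + |sin a|)``."""
    a = np.deg2rad(alpha_deg)
    return float(2.0 * area * (1.0 - np.cos(a) + abs(np.sin(a))))


# ---------------------------------------------------------------------------
# plain-text serialization (used by the stack-registration outputs)

def transform_to_record(T: RigidTransform2D, shape: tuple[int, int] | None = None) -> dict:
    c = T.resolve_center(shape) if (T.center is not None or shape is not None) else (None, None)
    return {
        "angle_deg": T.angle_deg,
        "tx": T.t_x,
        "ty": T.t_y,
        "center_x": c[0],
        "center_y": c[1],
    }


def write_transform_record(path, T: RigidTransform2D, shape: tuple[int, int] | None = None,
                           extra: dict | None = None) -> None:
    rec = transform_to_record(T, shape)
    if extra:
        rec.update(extra)
    with open(path, "w") as fh:
        for key, val in rec.items():
            fh.write(f"{key} = {val}\n")


def read_transform_record(path) -> RigidTransform2D:
    fields: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            try:
                fields[key.strip()] = float(val.strip())
            except ValueError:
                continue
    center = None
    if "center_x" in fields and "center_y" in fields:
        center = (fields["center_x"], fields["center_y"])
    return RigidTransform2D(
        fields.get("angle_deg", 0.0), fields.get("tx", 0.0), fields.get("ty", 0.0), center
    )
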
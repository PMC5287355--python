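"""2D coordinate frames and point transforms.

The correlative workflow chains several planar coordinate frames: FM tile
pixels, the stitched FM mosaic, the FM stage (micrometres), and the EM side
(image pixels or stage micrometres).  Everything here treats a point as a
column 2-vector ``(x, y)``; in NumPy code points are row-stacked into
``(n, 2)`` arrays.  Image frames use 0-based coordinates at pixel centres,
x rightward, y downward, origin at the top-left pixel centre; stage frames
are in micrometres with the same axis orientation.

A :class:`Transform2D` maps its ``source`` frame to its ``target`` frame as

    p_target = M @ p_source + t

with ``M`` a 2x2 linear part and ``t`` a translation.  Two model classes are
supported: *similarity* (isotropic scale x rotation, optionally with a
reflection) and *affine* (any invertible linear part).  Similarity fits are
solved in closed form (orthogonal Procrustes with isotropic scale); affine
fits by linear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Point2D",
    "FrameID",
    "Transform2D",
    "FitReport",
    "FRAME_NAMES",
    "compose",
    "fit_transform",
    "identity_transform",
]

#: Canonical frame labels used across the package.
FRAME_NAMES = (
    "fm_tile_px",
    "fm_mosaic_px",
    "fm_stage_um",
    "em_image_px",
    "em_montage_px",
    "em_stage_um",
)

_STAGE_FRAMES = {"fm_stage_um", "em_stage_um"}

#: Condition-number limit beyond which a fit geometry is treated as degenerate.
COND_LIMIT = 1e8


class Point2D(NamedTuple):
    """A point in some planar frame (micrometres for stage frames, pixels
    for image frames)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class FrameID:
    """Label of a coordinate frame, with the pixel size for image frames.

    ``pixel_size`` is the physical length of one pixel (micrometres for FM
    frames, nanometres or micrometres for EM frames as the caller prefers);
    it is ``None`` for stage frames, which are already metric.
    """

    name: str
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def is_stage(self) -> bool:
        return self.name in _STAGE_FRAMES


def _as_points(points) -> np.ndarray:
    """Coerce a Point2D, sequence of Point2D, or array-like to ``(n, 2)``."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected points of shape (n, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("points must be finite")
    return arr


@dataclass(frozen=True)
class Transform2D:
    """Invertible planar map ``p -> matrix @ p + translation``."""

    matrix: np.ndarray
    translation: np.ndarray
    source: FrameID | None = None
    target: FrameID | None = None
    model: str = "affine"
    allow_reflection: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)
        if self.model not in ("similarity", "affine"):
            raise ValueError(f"unknown transform model {self.model!r}")
        det = float(np.linalg.det(m))
        if det == 0.0 or not np.isfinite(det):
            raise ValueError("transform linear part is singular")
        if self.model == "similarity":
            # M must be s*R (or s*R*F with reflection): M.T @ M == s^2 * I
            g = m.T @ m
            s2 = 0.5 * (g[0, 0] + g[1, 1])
            if not np.allclose(g, s2 * np.eye(2), rtol=1e-6, atol=1e-9 * s2):
                raise ValueError("similarity transform has anisotropic/shear linear part")
            if det < 0 and not self.allow_reflection:
                raise ValueError("reflection present but allow_reflection=False")

    # -- algebra ---------------------------------------------------------
    def apply(self, points, frame: FrameID | None = None) -> np.ndarray:
        """Map points from the source frame to the target frame.

        ``frame``, when given, is checked against ``self.source`` so that
        cross-frame mistakes fail loudly instead of silently producing
        nonsense coordinates.
        """
        if frame is not None and self.source is not None and frame.name != self.source.name:
            raise ValueError(
                f"point frame {frame.name!r} does not match transform source "
                f"{self.source.name!r}"
            )
        pts = _as_points(points)
        out = pts @ self.matrix.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def apply_point(self, p: Point2D) -> Point2D:
        x, y = self.apply(np.array([p.x, p.y]))
        return Point2D(float(x), float(y))

    def inverse(self) -> "Transform2D":
        """The inverse map, with source/target swapped."""
        det = float(np.linalg.det(self.matrix))
        if det == 0.0:
            raise ValueError("cannot invert a singular transform")
        minv = np.linalg.inv(self.matrix)
        return Transform2D(
            matrix=minv,
            translation=-minv @ self.translation,
            source=self.target,
            target=self.source,
            model=self.model,
            allow_reflection=self.allow_reflection,
        )

    @property
    def scale(self) -> float:
        """Isotropic scale factor, |det M|^(1/2)."""
        return math.sqrt(abs(float(np.linalg.det(self.matrix))))

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the (possibly reflected) similarity part."""
        m = self.matrix
        if np.linalg.det(m) < 0:
            m = m @ np.diag([1.0, -1.0])
        return math.degrees(math.atan2(m[1, 0], m[0, 0]))

    def with_frames(self, source: FrameID | None, target: FrameID | None) -> "Transform2D":
        return replace(self, source=source, target=target)

    # -- serialization ---------------------------------------------------
    def to_text(self) -> str:
        """Serialize to a plain-text key=value block.

        Coefficients are printed with 17 significant digits so the decimal
        round trip is exact for IEEE doubles.
        """
        lines = [
            f"model = {self.model}",
            f"allow_reflection = {str(self.allow_reflection).lower()}",
        ]
        m, t = self.matrix, self.translation
        for key, val in (
            ("a11", m[0, 0]), ("a12", m[0, 1]), ("a21", m[1, 0]), ("a22", m[1, 1]),
            ("tx", t[0]), ("ty", t[1]),
        ):
            lines.append(f"{key} = {val:.17g}")
        for role, fr in (("source", self.source), ("target", self.target)):
            if fr is not None:
                lines.append(f"{role} = {fr.name}")
                if fr.pixel_size is not None:
                    lines.append(f"{role}_pixel_size = {fr.pixel_size:.17g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Transform2D":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        m = np.array(
            [[float(kv["a11"]), float(kv["a12"])], [float(kv["a21"]), float(kv["a22"])]]
        )
        t = np.array([float(kv["tx"]), float(kv["ty"])])
        frames: dict[str, FrameID | None] = {}
        for role in ("source", "target"):
            if role in kv:
                px = kv.get(f"{role}_pixel_size")
                frames[role] = FrameID(kv[role], float(px) if px else None)
            else:
                frames[role] = None
        return cls(
            matrix=m,
            translation=t,
            source=frames["source"],
            target=frames["target"],
            model=kv.get("model", "affine"),
            allow_reflection=kv.get("allow_reflection", "true") == "true",
        )


def identity_transform(
    frame: FrameID | None = None, model: str = "similarity"
) -> Transform2D:
    return Transform2D(np.eye(2), np.zeros(2), source=frame, target=frame, model=model)


def compose(a: Transform2D, b: Transform2D) -> Transform2D:
    """The map "first ``a``, then ``b``": ``compose(a, b).apply(p) == b.apply(a.apply(p))``.

    Frames must chain (``a.target == b.source``) when both carry frame labels.
    """
    if a.target is not None and b.source is not None and a.target.name != b.source.name:
        raise ValueError(
            f"cannot compose: first transform targets {a.target.name!r} but "
            f"second expects source {b.source.name!r}"
        )
    model = "similarity" if a.model == b.model == "similarity" else "affine"
    return Transform2D(
        matrix=b.matrix @ a.matrix,
        translation=b.matrix @ a.translation + b.translation,
        source=a.source,
        target=b.target,
        model=model,
        allow_reflection=a.allow_reflection or b.allow_reflection,
    )


@dataclass
class FitReport:
    """Residual diagnostics of a point-pair transform fit.

    ``loo_rms`` is the leave-one-out prediction RMS: each pair is held out in
    turn, the transform refitted on the remainder, and the held-out point's
    prediction error recorded.  It estimates how well the fit *predicts* new
    positions (the quantity that matters for targeting), whereas
    ``rms_residual`` only measures in-sample agreement and is optimistic.
    ``loo_rms`` is ``None`` when there are too few pairs to hold one out.
    """

    rms_residual: float
    per_point_residuals: np.ndarray
    n_points: int
    loo_rms: float | None = None

    def __post_init__(self) -> None:
        self.per_point_residuals = np.asarray(self.per_point_residuals, dtype=float)


_MIN_PAIRS = {"similarity": 2, "affine": 3}


def _fit_similarity(src: np.ndarray, dst: np.ndarray, allow_reflection: bool) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least-squares similarity (Umeyama/Procrustes).

    Minimizes sum ||s R x_i + t - y_i||^2 over scale s > 0, rotation (or
    rotation*reflection when allowed) R and translation t.
    """
    n = src.shape[0]
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    ys = dst - mu_d
    var_s = float((xs ** 2).sum()) / n
    if var_s == 0.0:
        raise ValueError("degenerate geometry: all source points coincide")
    cov = ys.T @ xs / n
    u, d, vt = np.linalg.svd(cov)
    s_diag = np.ones(2)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        s_diag[-1] = -1.0
    rot = u @ np.diag(s_diag) @ vt
    scale = float(d @ s_diag) / var_s
    if scale <= 0:
        raise ValueError("degenerate geometry: non-positive fitted scale")
    matrix = scale * rot
    translation = mu_d - matrix @ mu_s
    return matrix, translation


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = src.shape[0]
    design = np.column_stack([src, np.ones(n)])
    if np.linalg.cond(design) > COND_LIMIT:
        raise ValueError(
            "degenerate geometry for affine fit (collinear or coincident points)"
        )
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    return coef[:2].T.copy(), coef[2].copy()


def fit_transform(
    src,
    dst,
    model: str = "similarity",
    allow_reflection: bool = True,
    source: FrameID | None = None,
    target: FrameID | None = None,
    compute_loo: bool = True,
) -> tuple[Transform2D, FitReport]:
    """Least-squares fit of a transform from matched point pairs.

    Parameters
    ----------
    src, dst : array-like, shape (n, 2)
        Matched points; ``dst[i]`` is the same physical feature as ``src[i]``
        expressed in the target frame.
    model : {"similarity", "affine"}
        Similarity needs >= 2 pairs, affine >= 3 non-collinear pairs.
    allow_reflection : bool
        For similarity fits, whether the linear part may include a mirror
        flip.  FM and EM images can differ in handedness, so the default is
        permissive; the fitted determinant sign is the one minimizing the
        residual.

    Returns
    -------
    (Transform2D, FitReport)
    """
    src = _as_points(src)
    dst = _as_points(dst)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same number of points")
    n = src.shape[0]
    if model not in _MIN_PAIRS:
        raise ValueError(f"unknown model {model!r}")
    if n < _MIN_PAIRS[model]:
        raise ValueError(
            f"{model} fit needs at least {_MIN_PAIRS[model]} pairs, got {n}"
        )

    if model == "similarity":
        matrix, translation = _fit_similarity(src, dst, allow_reflection)
    else:
        matrix, translation = _fit_affine(src, dst)

    t = Transform2D(
        matrix=matrix,
        translation=translation,
        source=source,
        target=target,
        model=model,
        allow_reflection=allow_reflection,
    )
    residuals = np.linalg.norm(t.apply(src) - dst, axis=1)
    rms = float(np.sqrt(np.mean(residuals ** 2)))

    loo: float | None = None
    if compute_loo and n >= _MIN_PAIRS[model] + 1:
        errs = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            try:
                if model == "similarity":
                    m_i, t_i = _fit_similarity(src[keep], dst[keep], allow_reflection)
                else:
                    m_i, t_i = _fit_affine(src[keep], dst[keep])
            except ValueError:
                errs[i] = np.nan
                continue
            pred = m_i @ src[i] + t_i
            errs[i] = np.linalg.norm(pred - dst[i])
        errs = errs[np.isfinite(errs)]
        if errs.size:
            loo = float(np.sqrt(np.mean(errs ** 2)))

    return t, FitReport(
        rms_residual=rms,
        per_point_residuals=residuals,
        n_points=n,
        loo_rms=loo,
    )
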
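"""Landmark-based 2D coregistration of histology to matched micro-CT slices.

Three or more structural features (vessels, airway branch points, pleural
landmarks) visible in both a histological section and its matched micro-CT
slice give point correspondences; a planar transform fitted to them maps
the moving (histology) image onto the fixed (micro-CT) frame.  Similarity
(rotation + uniform scale + translation) is the default model — sectioning
geometry is rigid up to uniform shrinkage — with affine available for
shear from sectioning distortion.  Fits are closed-form least squares
(Umeyama for similarity, normal equations for affine); landmark sets are
small and curated, so no robust weighting is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class LandmarkSet:
    """Paired (x, y) pixel coordinates: moving image -> fixed image."""

    moving: np.ndarray  # (n, 2)
    fixed: np.ndarray   # (n, 2)

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=float)
        if self.moving.shape != self.fixed.shape or self.moving.ndim != 2 \
                or self.moving.shape[1] != 2:
            raise ValueError("landmarks must be matching (n, 2) arrays")

    def __len__(self) -> int:
        return len(self.moving)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        """Read columns moving_x, moving_y, fixed_x, fixed_y."""
        df = pd.read_csv(path)
        return cls(df[["moving_x", "moving_y"]].to_numpy(),
                   df[["fixed_x", "fixed_y"]].to_numpy())


@dataclass
class PlanarTransform:
    """2D transform p_fixed = A @ p_moving + t, points as (x, y).

    ``matrix`` is the 2x3 array [A | t].  For similarity fits ``scale``,
    ``rotation_rad`` and ``translation`` carry the decomposition.
    """

    model: str
    matrix: np.ndarray
    rms_residual: float
    scale: float | None = None
    rotation_rad: float | None = None
    translation: np.ndarray | None = None

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "PlanarTransform":
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        Ai = np.linalg.inv(A)
        return PlanarTransform(model=self.model,
                               matrix=np.hstack([Ai, (-Ai @ t)[:, None]]),
                               rms_residual=self.rms_residual)

    def to_json(self, path: str | Path) -> None:
        obj = {"model": self.model, "matrix": self.matrix.tolist(),
               "rms_residual": self.rms_residual}
        if self.scale is not None:
            obj.update(scale=self.scale, rotation_rad=self.rotation_rad,
                       translation=list(self.translation))
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanarTransform":
        obj = json.loads(Path(path).read_text())
        return cls(model=obj["model"], matrix=np.asarray(obj["matrix"]),
                   rms_residual=obj["rms_residual"], scale=obj.get("scale"),
                   rotation_rad=obj.get("rotation_rad"),
                   translation=None if "translation" not in obj
                   else np.asarray(obj["translation"]))


def _check_degenerate(pts: np.ndarray, model: str) -> None:
    if model == "similarity":
        if len(pts) < 2:
            raise ValueError("similarity needs >= 2 landmark pairs")
        if np.allclose(pts, pts[0]):
            raise ValueError("degenerate landmarks: all moving points coincide")
    else:
        if len(pts) < 3:
            raise ValueError("affine needs >= 3 landmark pairs")
        d = pts - pts[0]
        if np.linalg.matrix_rank(d, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
            raise ValueError("degenerate landmarks: moving points are collinear")


def fit_transform(landmarks: LandmarkSet, model: str = "similarity") -> PlanarTransform:
    """Least-squares planar transform minimizing sum ||T(p_moving) - p_fixed||^2.

    ``model`` is "similarity" (Umeyama closed form: scale > 0, rotation,
    translation) or "affine" (normal equations).  Reports the RMS residual
    over the landmark pairs.  Degenerate configurations (coincident points
    for similarity, collinear for affine) raise with the geometry named.
    """
    if model not in ("similarity", "affine"):
        raise ValueError(f"unknown model {model!r}")
    src, dst = landmarks.moving, landmarks.fixed
    _check_degenerate(src, model)

    if model == "similarity":
        mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
        cs, cd = src - mu_s, dst - mu_d
        cov = cd.T @ cs / len(src)
        U, S, Vt = np.linalg.svd(cov)
        sign = np.sign(np.linalg.det(U @ Vt))
        D = np.diag([1.0, sign])
        R = U @ D @ Vt
        var_s = (cs ** 2).sum() / len(src)
        scale = float((S * np.diag(D)).sum() / var_s)
        t = mu_d - scale * R @ mu_s
        A = scale * R
        matrix = np.hstack([A, t[:, None]])
        rot = float(np.arctan2(R[1, 0], R[0, 0]))
        res = src @ A.T + t - dst
        rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
        return PlanarTransform("similarity", matrix, rms, scale=scale,
                               rotation_rad=rot, translation=t)

    X = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    matrix = coef.T  # 2x3
    res = X @ coef - dst
    rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    return PlanarTransform("affine", matrix, rms)


def apply_transform(image: np.ndarray, transform: PlanarTransform,
                    output_shape: tuple[int, int] | None = None,
                    fill_value: float = 0.0) -> np.ndarray:
    """Resample ``image`` into the fixed frame under ``transform``.

    The output pixel (row, col) takes the bilinearly interpolated value of
    the moving image at T^-1 (col, row); out-of-domain pixels get
    ``fill_value``.  Whole-pixel translations are exact in the overlap.
    """
    if output_shape is None:
        output_shape = image.shape
    inv = transform.inverse().matrix  # maps fixed (x, y) -> moving (x, y)
    # ndimage maps output (row, col) -> input coords via matrix @ o + offset;
    # convert from (x, y) to (row, col) ordering
    A_xy, t_xy = inv[:, :2], inv[:, 2]
    P = np.array([[0, 1], [1, 0]], dtype=float)  # swap row/col <-> y/x
    A_rc = P @ A_xy @ P
    t_rc = P @ t_xy
    return ndimage.affine_transform(
        np.asarray(image, dtype=float), A_rc, offset=t_rc,
        output_shape=output_shape, order=1, mode="constant", cval=fill_value)
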
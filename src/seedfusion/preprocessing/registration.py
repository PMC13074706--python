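"""Cross-sensor registration: homography estimation and IR resampling.

The projective fit is a Hartley-normalised DLT (as implemented by
``skimage.transform.ProjectiveTransform.estimate``); calibration corners
are clean, so no robust loop is needed.  Coordinates follow the (x, y) =
(column, row) convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

__all__ = ["Homography", "HomographyError", "estimate_homography", "register_ir"]


class HomographyError(ValueError):
    pass


@dataclass(frozen=True)
class Homography:
    matrix: np.ndarray             # 3x3, normalised so matrix[2, 2] == 1
    reprojection_error_px: float   # mean Euclidean error over the fit points

    def __post_init__(self):
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise HomographyError("homography is singular")
        if self.reprojection_error_px < 0:
            raise HomographyError("reprojection error must be >= 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        hom = self.matrix @ np.column_stack([pts, np.ones(len(pts))]).T
        return (hom[:2] / hom[2]).T

    @property
    def inverse(self) -> "Homography":
        inv = np.linalg.inv(self.matrix)
        return Homography(inv / inv[2, 2], self.reprojection_error_px)


def estimate_homography(src_corners: np.ndarray,
                        dst_corners: np.ndarray) -> Homography:
    """Least-squares projective fit mapping ``src`` points onto ``dst``.

    Requires at least 4 non-degenerate point pairs; reports the mean
    reprojection error of the fit.
    """
    src = np.asarray(src_corners, dtype=float)
    dst = np.asarray(dst_corners, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise HomographyError("src and dst must be matching (n, 2) arrays")
    if len(src) < 4:
        raise HomographyError(f"need >= 4 point pairs, got {len(src)}")
    for name, pts in (("src", src), ("dst", dst)):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise HomographyError(f"{name} points are collinear")
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:  # FailedEstimation is falsy
        raise HomographyError("degenerate point configuration")
    M = tform.params
    if not np.all(np.isfinite(M)) or abs(np.linalg.det(M)) < 1e-12:
        raise HomographyError("degenerate point configuration")
    M = M / M[2, 2]
    proj = tform(src)
    err = float(np.linalg.norm(proj - dst, axis=1).mean())
    return Homography(matrix=M, reprojection_error_px=err)


def register_ir(ir_frame: np.ndarray, homography: Homography | np.ndarray,
                target_shape: tuple[int, int]) -> np.ndarray:
    """Resample the IR frame into the RGB coordinate system.

    Bilinear interpolation; pixels that map outside the IR frame are 0.
    ``homography`` maps IR (x, y) into RGB (x, y).
    """
    M = homography.matrix if isinstance(homography, Homography) else np.asarray(
        homography, dtype=float)
    if abs(np.linalg.det(M)) < 1e-12:
        raise HomographyError("homography is singular")
    inv = np.linalg.inv(M)
    return warp(np.asarray(ir_frame, dtype=float),
                ProjectiveTransform(matrix=inv),
                output_shape=target_shape, order=1, cval=0.0,
                preserve_range=True)
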
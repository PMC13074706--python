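"""Checkerboard calibration imagery for cross-sensor registration."""

from __future__ import annotations

import numpy as np
from skimage.transform import ProjectiveTransform, warp

__all__ = ["render_checkerboard"]


def render_checkerboard(true_homography: np.ndarray,
                        grid: tuple[int, int] = (10, 7),
                        square_px: int = 8,
                        margin_px: int | None = None):
    """Render a calibration checkerboard under both sensor geometries.

    The board lives in the IR frame; the RGB view is the board imaged
    through ``true_homography`` (IR (x, y) -> RGB (x, y)).  Returns
    ``(rgb_board, ir_board, corner_pairs)`` where ``corner_pairs`` is an
    ``(n, 2, 2)`` array of exact inner-corner coordinates, ``[:, 0]`` in the
    IR frame and ``[:, 1]`` in the RGB frame.

    Raises ``ValueError`` for a singular homography.
    """
    H = np.asarray(true_homography, dtype=float)
    if H.shape != (3, 3) or abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("homography must be an invertible 3x3 matrix")
    nx, ny = grid
    sq = int(square_px)
    if sq <= 0 or nx < 2 or ny < 2:
        raise ValueError("grid must be at least 2x2 with positive square size")
    m = sq if margin_px is None else int(margin_px)

    w_i, h_i = nx * sq + 2 * m, ny * sq + 2 * m
    yy, xx = np.mgrid[0:h_i, 0:w_i]
    parity = (((xx - m) // sq) + ((yy - m) // sq)) % 2
    inside = (xx >= m) & (xx < m + nx * sq) & (yy >= m) & (yy < m + ny * sq)
    ir_board = np.where(inside, parity.astype(float), 0.5)

    # exact inner corners in IR coordinates, mapped exactly through H
    cx, cy = np.meshgrid(np.arange(1, nx), np.arange(1, ny))
    src = np.stack([m + cx.ravel() * sq, m + cy.ravel() * sq], axis=1).astype(float)
    hom = H @ np.column_stack([src, np.ones(len(src))]).T
    dst = (hom[:2] / hom[2]).T
    corner_pairs = np.stack([src, dst], axis=1)

    # RGB board: sample the IR board back through the inverse mapping
    x_max = int(np.ceil(dst[:, 0].max() + m * 2))
    y_max = int(np.ceil(dst[:, 1].max() + m * 2))
    rgb_board = warp(ir_board, ProjectiveTransform(matrix=np.linalg.inv(H)),
                     output_shape=(max(y_max, 8), max(x_max, 8)), order=1,
                     cval=0.5, preserve_range=True)
    return rgb_board, ir_board, corner_pairs
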
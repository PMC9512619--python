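"""Two-frame dense optical flow via polynomial expansion (Farnebäck 2003).

Each image neighborhood is approximated by a quadratic polynomial
``f(x) ≈ x^T A x + b^T x + c`` fit by Gaussian-weighted least squares.
Under a local translation ``d`` the two frames' coefficients satisfy
``A d = -(b2 - b1) / 2``; the per-pixel normal equations are averaged over
an integration window before solving, which is what the ``winsize``
parameter (the paper-visible "kernel size") controls.  A coarse-to-fine
image pyramid handles displacements larger than the polynomial
neighborhood.

Internally all displacements are (row, col); the public wrapper in
:mod:`fidgetlab.flow` converts to (x, y) = (col, row) ordering.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["poly_expansion", "farneback"]


def _gaussian_kernel(n: int, sigma: float) -> np.ndarray:
    x = np.arange(-n, n + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def poly_expansion(img: np.ndarray, n: int = 3, sigma: float = 1.5):
    """Fit ``f ≈ x^T A x + b^T x + c`` around every pixel.

    Returns ``(A, b, c)`` with shapes (H, W, 2, 2), (H, W, 2), (H, W);
    coordinates are (row, col) offsets from the center pixel.
    """
    img = np.asarray(img, dtype=np.float64)
    x = np.arange(-n, n + 1, dtype=np.float64)
    g = _gaussian_kernel(n, sigma)
    wg, wx, wx2 = g, x * g, (x**2) * g

    def sep(krow, kcol):
        t = ndimage.correlate1d(img, krow, axis=0, mode="nearest")
        return ndimage.correlate1d(t, kcol, axis=1, mode="nearest")

    # raw weighted moments of the image against the monomial basis
    m = np.stack(
        [
            sep(wg, wg),    # 1
            sep(wx, wg),    # r
            sep(wg, wx),    # c
            sep(wx2, wg),   # r^2
            sep(wg, wx2),   # c^2
            sep(wx, wx),    # r c
        ],
        axis=-1,
    )

    # Gram matrix of the basis under the separable Gaussian weight
    rr, cc = np.meshgrid(x, x, indexing="ij")
    w2d = np.outer(g, g).ravel()
    basis = np.stack(
        [np.ones_like(rr), rr, cc, rr**2, cc**2, rr * cc], axis=-1
    ).reshape(-1, 6)
    gram = basis.T @ (w2d[:, None] * basis)
    coef = m @ np.linalg.inv(gram).T

    c0 = coef[..., 0]
    b = coef[..., 1:3]
    A = np.empty(img.shape + (2, 2), dtype=np.float64)
    A[..., 0, 0] = coef[..., 3]
    A[..., 1, 1] = coef[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * coef[..., 5]
    return A, b, c0


def _sample(field: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(field, [rows, cols], order=1, mode="nearest")


def _flow_one_level(
    A1, b1, A2, b2, d0: np.ndarray, winsize: int, iterations: int
) -> np.ndarray:
    h, w = b1.shape[:2]
    grid_r, grid_c = np.meshgrid(
        np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij"
    )
    d = d0.copy()
    size = max(int(winsize), 3)
    for _ in range(iterations):
        rows = np.clip(grid_r + d[..., 0], 0, h - 1)
        cols = np.clip(grid_c + d[..., 1], 0, w - 1)
        A2d = np.stack(
            [
                _sample(A2[..., 0, 0], rows, cols),
                _sample(A2[..., 0, 1], rows, cols),
                _sample(A2[..., 1, 1], rows, cols),
            ],
            axis=-1,
        )
        b2d = np.stack(
            [_sample(b2[..., 0], rows, cols), _sample(b2[..., 1], rows, cols)],
            axis=-1,
        )
        a00 = 0.5 * (A1[..., 0, 0] + A2d[..., 0])
        a01 = 0.5 * (A1[..., 0, 1] + A2d[..., 1])
        a11 = 0.5 * (A1[..., 1, 1] + A2d[..., 2])
        db0 = -0.5 * (b2d[..., 0] - b1[..., 0]) + a00 * d[..., 0] + a01 * d[..., 1]
        db1 = -0.5 * (b2d[..., 1] - b1[..., 1]) + a01 * d[..., 0] + a11 * d[..., 1]

        # normal equations of A d = Δb, box-averaged over the window
        g00 = ndimage.uniform_filter(a00 * a00 + a01 * a01, size)
        g01 = ndimage.uniform_filter(a01 * (a00 + a11), size)
        g11 = ndimage.uniform_filter(a01 * a01 + a11 * a11, size)
        h0 = ndimage.uniform_filter(a00 * db0 + a01 * db1, size)
        h1 = ndimage.uniform_filter(a01 * db0 + a11 * db1, size)

        det = g00 * g11 - g01 * g01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        d = np.stack([(g11 * h0 - g01 * h1) / det, (g00 * h1 - g01 * h0) / det], axis=-1)
    return d


def farneback(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    winsize: int = 30,
    levels: int = 3,
    pyr_scale: float = 0.5,
    iterations: int = 3,
    poly_n: int = 7,
    poly_sigma: float = 1.5,
) -> np.ndarray:
    """Dense displacement field (row, col) mapping frame_a onto frame_b."""
    if frame_a.shape != frame_b.shape:
        raise ValueError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    if frame_a.ndim != 2:
        raise ValueError("frames must be 2-D grayscale arrays")
    f1 = np.asarray(frame_a, dtype=np.float64)
    f2 = np.asarray(frame_b, dtype=np.float64)

    # coarse-to-fine pyramid; smooth before decimation to avoid aliasing
    pyr1, pyr2 = [f1], [f2]
    for _ in range(levels - 1):
        if min(pyr1[-1].shape) * pyr_scale < 2 * poly_n + 1:
            break
        sigma = 0.5 / pyr_scale
        pyr1.append(ndimage.zoom(ndimage.gaussian_filter(pyr1[-1], sigma), pyr_scale, order=1))
        pyr2.append(ndimage.zoom(ndimage.gaussian_filter(pyr2[-1], sigma), pyr_scale, order=1))

    n = poly_n // 2
    d = np.zeros(pyr1[-1].shape + (2,), dtype=np.float64)
    for lvl in range(len(pyr1) - 1, -1, -1):
        g1, g2 = pyr1[lvl], pyr2[lvl]
        if d.shape[:2] != g1.shape:
            zoom_r = g1.shape[0] / d.shape[0]
            zoom_c = g1.shape[1] / d.shape[1]
            d = np.stack(
                [
                    ndimage.zoom(d[..., 0], (zoom_r, zoom_c), order=1) * zoom_r,
                    ndimage.zoom(d[..., 1], (zoom_r, zoom_c), order=1) * zoom_c,
                ],
                axis=-1,
            )
        win = max(3, int(round(winsize * g1.shape[0] / f1.shape[0])))
        A1, b1, _ = poly_expansion(g1, n=n, sigma=poly_sigma)
        A2, b2, _ = poly_expansion(g2, n=n, sigma=poly_sigma)
        d = _flow_one_level(A1, b1, A2, b2, d, win, iterations)
    return d
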
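"""GLCM texture and texture-derivative analysis of parametric maps.

First pass: grey-level co-occurrence matrices (16 levels, distance 1, four
angles pooled, symmetric) over a raster yield four Haralick-style features:
contrast (CON), correlation (COR), energy (ENE) and homogeneity (HOM).

Second pass ("texture derivatives"): a 15 x 15 sliding window produces four
texture-encoded maps (one per feature), and the GLCM feature extraction is
applied again to each map, yielding 16 features named FIRST-SECOND (e.g.
``ENE-HOM`` is the homogeneity of the energy map).

Missing raster cells (NaN) are excluded from quantization ranges and from
co-occurrence pairs; correlation is undefined (NaN) for zero-variance GLCMs
and propagates as a missing feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "QuantizationError",
    "EmptyGLCMError",
    "TextureSizeError",
    "GLCMatrix",
    "TextureFeatureSet",
    "TextureMapSet",
    "GLCM_FEATURE_NAMES",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "texture_map",
    "texture_derivative_features",
]

GLCM_FEATURE_NAMES = ("CON", "COR", "ENE", "HOM")

#: Default number of grey levels for quantization.
DEFAULT_LEVELS = 16
#: Default sliding-window side for texture-encoded maps (pixels).
TEXTURE_WINDOW = 15

# Angle -> (row, col) offset at unit distance; rows increase with depth.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class QuantizationError(ValueError):
    """Raster has no finite values to quantize."""


class EmptyGLCMError(ValueError):
    """No valid co-occurrence pairs in the raster."""


class TextureSizeError(ValueError):
    """Raster smaller than the sliding window."""


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities pooled over angles."""

    probabilities: np.ndarray
    n_levels: int
    distance: int
    angles: tuple
    symmetric: bool


class TextureFeatureSet(NamedTuple):
    con: float
    cor: float
    ene: float
    hom: float

    def as_dict(self) -> dict:
        return {"CON": self.con, "COR": self.cor, "ENE": self.ene, "HOM": self.hom}


@dataclass
class TextureMapSet:
    """Four texture-encoded rasters from sliding-window GLCM analysis."""

    con: np.ndarray
    cor: np.ndarray
    ene: np.ndarray
    hom: np.ndarray
    window: int
    stride: int

    def as_dict(self) -> dict:
        return {"CON": self.con, "COR": self.cor, "ENE": self.ene, "HOM": self.hom}


def quantize_map(raster: np.ndarray, n_levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin a raster's finite values into ``n_levels`` grey levels.

    Bins span [min, max] of the non-missing cells; a constant raster maps to
    level 0 everywhere.  Missing (non-finite) cells become -1.  The result is
    invariant under affine rescaling of the raster.
    """
    r = np.asarray(raster, dtype=float)
    finite = np.isfinite(r)
    if not finite.any():
        raise QuantizationError("all raster cells are missing")
    vmin = r[finite].min()
    vmax = r[finite].max()
    q = np.full(r.shape, -1, dtype=np.int64)
    if vmax == vmin:
        q[finite] = 0
        return q
    scaled = (r[finite] - vmin) / (vmax - vmin) * n_levels
    q[finite] = np.clip(np.floor(scaled), 0, n_levels - 1).astype(np.int64)
    return q


def compute_glcm(
    quantized: np.ndarray,
    distance: int = 1,
    angles: tuple = (0, 45, 90, 135),
    symmetric: bool = True,
    n_levels: int | None = None,
) -> GLCMatrix:
    """Pooled, symmetrized, normalized grey-level co-occurrence matrix.

    Pairs are counted over all in-bounds offsets for each angle; cells with
    level -1 (missing) never participate.
    """
    q = np.asarray(quantized, dtype=np.int64)
    if q.ndim != 2:
        raise ValueError("quantized raster must be 2D")
    L = int(n_levels) if n_levels is not None else int(q.max()) + 1
    if q.max() >= L:
        raise ValueError("raster levels exceed n_levels")
    L = max(L, 1)
    counts = np.zeros(L * L, dtype=np.float64)
    H, W = q.shape
    for ang in angles:
        dr, dc = _ANGLE_OFFSETS[ang]
        dr *= distance
        dc *= distance
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        counts += np.bincount(a[ok] * L + b[ok], minlength=L * L)
        if symmetric:
            counts += np.bincount(b[ok] * L + a[ok], minlength=L * L)
    total = counts.sum()
    if total == 0:
        raise EmptyGLCMError("no valid co-occurrence pairs")
    return GLCMatrix(
        probabilities=(counts / total).reshape(L, L),
        n_levels=L,
        distance=distance,
        angles=tuple(angles),
        symmetric=symmetric,
    )


def glcm_features(glcm: GLCMatrix) -> TextureFeatureSet:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    ``CON = sum (i-j)^2 P``, ``ENE = sum P^2``, ``HOM = sum P / (1+|i-j|)``,
    ``COR = sum (i-mu_i)(j-mu_j) P / (sigma_i sigma_j)``; COR is NaN when
    either marginal standard deviation vanishes.
    """
    P = glcm.probabilities
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    con = float(np.sum((i - j) ** 2 * P))
    ene = float(np.sum(P**2))
    hom = float(np.sum(P / (1.0 + np.abs(i - j))))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mi = float(np.sum(np.arange(L) * pi))
    mj = float(np.sum(np.arange(L) * pj))
    vi = float(np.sum((np.arange(L) - mi) ** 2 * pi))
    vj = float(np.sum((np.arange(L) - mj) ** 2 * pj))
    if vi <= 0 or vj <= 0:
        cor = float("nan")
    else:
        cor = float(np.sum((i - mi) * (j - mj) * P) / np.sqrt(vi * vj))
    return TextureFeatureSet(con=con, cor=cor, ene=ene, hom=hom)


def _window_features(sub: np.ndarray, n_levels: int, distance: int, angles: tuple) -> TextureFeatureSet:
    if not np.isfinite(sub).any():
        return TextureFeatureSet(np.nan, np.nan, np.nan, np.nan)
    q = quantize_map(sub, n_levels)
    try:
        g = compute_glcm(q, distance=distance, angles=angles, n_levels=n_levels)
    except EmptyGLCMError:
        return TextureFeatureSet(np.nan, np.nan, np.nan, np.nan)
    return glcm_features(g)


try:  # compiled fast path for sliding-window analysis
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@_njit(fastmath=False)
def _sliding_glcm_kernel(r, window, stride, n_levels, distance, offsets, symmetric):
    H, W = r.shape
    nr = (H - window) // stride + 1
    nc = (W - window) // stride + 1
    con_m = np.full((nr, nc), np.nan)
    cor_m = np.full((nr, nc), np.nan)
    ene_m = np.full((nr, nc), np.nan)
    hom_m = np.full((nr, nc), np.nan)
    q = np.empty((window, window), dtype=np.int64)
    counts = np.empty((n_levels, n_levels), dtype=np.float64)
    for ri in range(nr):
        for ci in range(nc):
            r0 = ri * stride
            c0 = ci * stride
            # per-window min/max over finite cells
            vmin = np.inf
            vmax = -np.inf
            nfin = 0
            for a in range(window):
                for b in range(window):
                    v = r[r0 + a, c0 + b]
                    if np.isfinite(v):
                        nfin += 1
                        if v < vmin:
                            vmin = v
                        if v > vmax:
                            vmax = v
            if nfin == 0:
                continue
            if vmax == vmin:
                for a in range(window):
                    for b in range(window):
                        q[a, b] = 0 if np.isfinite(r[r0 + a, c0 + b]) else -1
            else:
                scale = n_levels / (vmax - vmin)
                for a in range(window):
                    for b in range(window):
                        v = r[r0 + a, c0 + b]
                        if np.isfinite(v):
                            lev = int((v - vmin) * scale)
                            if lev >= n_levels:
                                lev = n_levels - 1
                            q[a, b] = lev
                        else:
                            q[a, b] = -1
            counts[:] = 0.0
            total = 0.0
            for o in range(offsets.shape[0]):
                dr = offsets[o, 0] * distance
                dc = offsets[o, 1] * distance
                for a in range(max(0, -dr), min(window, window - dr)):
                    for b in range(max(0, -dc), min(window, window - dc)):
                        u = q[a, b]
                        v = q[a + dr, b + dc]
                        if u >= 0 and v >= 0:
                            counts[u, v] += 1.0
                            if symmetric:
                                counts[v, u] += 1.0
                            total += 2.0 if symmetric else 1.0
            if total == 0.0:
                continue
            con = 0.0
            ene = 0.0
            hom = 0.0
            for ii in range(n_levels):
                for jj in range(n_levels):
                    p = counts[ii, jj] / total
                    d = ii - jj
                    con += d * d * p
                    ene += p * p
                    hom += p / (1.0 + abs(d))
            mi = 0.0
            mj = 0.0
            for ii in range(n_levels):
                pi = 0.0
                pj = 0.0
                for jj in range(n_levels):
                    pi += counts[ii, jj]
                    pj += counts[jj, ii]
                mi += ii * pi / total
                mj += ii * pj / total
            vi = 0.0
            vj = 0.0
            cov = 0.0
            for ii in range(n_levels):
                pi = 0.0
                pj = 0.0
                for jj in range(n_levels):
                    pi += counts[ii, jj]
                    pj += counts[jj, ii]
                    cov += (ii - mi) * (jj - mj) * counts[ii, jj] / total
                vi += (ii - mi) ** 2 * pi / total
                vj += (ii - mj) ** 2 * pj / total
            con_m[ri, ci] = con
            ene_m[ri, ci] = ene
            hom_m[ri, ci] = hom
            if vi > 0.0 and vj > 0.0:
                cor_m[ri, ci] = cov / np.sqrt(vi * vj)
    return con_m, cor_m, ene_m, hom_m


def texture_map(
    raster: np.ndarray,
    window: int = TEXTURE_WINDOW,
    stride: int = 1,
    n_levels: int = DEFAULT_LEVELS,
    distance: int = 1,
    angles: tuple = (0, 45, 90, 135),
    engine: str = "auto",
) -> TextureMapSet:
    """Texture-encoded maps by sliding-window GLCM analysis (valid mode).

    Each output pixel holds the GLCM feature of the ``window x window``
    neighbourhood (quantized per window); output dimensions are
    ``input - window + 1`` per axis at stride 1.  ``engine`` selects the
    compiled kernel (``"numba"``), the reference implementation
    (``"python"``) or the compiled one when available (``"auto"``); both
    produce the same maps.
    """
    r = np.asarray(raster, dtype=float)
    if r.ndim != 2:
        raise ValueError("raster must be 2D")
    H, W = r.shape
    if H < window or W < window:
        raise TextureSizeError(f"raster {r.shape} smaller than {window}x{window} window")
    use_numba = engine == "numba" or (engine == "auto" and _HAVE_NUMBA)
    if use_numba:
        offsets = np.array([_ANGLE_OFFSETS[a] for a in angles], dtype=np.int64)
        con, cor, ene, hom = _sliding_glcm_kernel(
            r, window, stride, n_levels, distance, offsets, True
        )
        return TextureMapSet(con=con, cor=cor, ene=ene, hom=hom, window=window, stride=stride)
    rows = range(0, H - window + 1, stride)
    cols = range(0, W - window + 1, stride)
    out = {k: np.full((len(rows), len(cols)), np.nan) for k in GLCM_FEATURE_NAMES}
    for ri, r0 in enumerate(rows):
        for ci, c0 in enumerate(cols):
            f = _window_features(r[r0 : r0 + window, c0 : c0 + window], n_levels, distance, angles)
            out["CON"][ri, ci] = f.con
            out["COR"][ri, ci] = f.cor
            out["ENE"][ri, ci] = f.ene
            out["HOM"][ri, ci] = f.hom
    return TextureMapSet(
        con=out["CON"], cor=out["COR"], ene=out["ENE"], hom=out["HOM"], window=window, stride=stride
    )


def texture_derivative_features(
    raster: np.ndarray,
    window: int = TEXTURE_WINDOW,
    stride: int = 1,
    n_levels: int = DEFAULT_LEVELS,
    distance: int = 1,
    angles: tuple = (0, 45, 90, 135),
) -> dict:
    """Second-pass GLCM features of the four texture-encoded maps.

    Returns 16 features named ``FIRST-SECOND`` (the SECOND-pass feature of
    the FIRST-pass map), e.g. ``ENE-HOM``.  If the raster is too small for
    the sliding window, all 16 are flagged missing (NaN).
    """
    names = [f"{a}-{b}" for a in GLCM_FEATURE_NAMES for b in GLCM_FEATURE_NAMES]
    try:
        tmaps = texture_map(raster, window, stride, n_levels, distance, angles)
    except TextureSizeError:
        return {n: float("nan") for n in names}
    out = {}
    for first, tmap in tmaps.as_dict().items():
        if np.isfinite(tmap).any():
            f = _window_features(tmap, n_levels, distance, angles)
        else:
            f = TextureFeatureSet(np.nan, np.nan, np.nan, np.nan)
        for second, val in f.as_dict().items():
            out[f"{first}-{second}"] = val
    return out
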
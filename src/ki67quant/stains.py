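"""H-DAB stain separation and the DAB pseudo-intensity channel.

Brightfield RGB pixels are converted to optical density (OD) per channel via
Beer-Lambert, unmixed into hematoxylin / DAB / residual contributions with a
configurable stain-vector basis (default: the Ruifrok-Johansen H-DAB vectors),
and the DAB plane is re-expressed on a 0-255 pseudo-intensity scale where 255
is unstained white and values around 25 correspond to dense dark-brown DAB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "StainBasis",
    "RUIFROK_HDAB",
    "rgb_to_od",
    "separate_stains",
    "dab_pseudo_intensity",
    "od_from_stains",
    "render_rgb",
]

#: Maximum acceptable condition number for a stain basis matrix.
_COND_LIMIT = 1e6

#: White point used throughout: a fully transparent pixel reads 255.
WHITE = 255.0


@dataclass(frozen=True)
class RGBImage:
    """An RGB brightfield image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Integer channel intensities in [0, 255].
    microns_per_pixel : float
        Physical edge length of one pixel in micrometres (scanners used
        here operate at 0.23 um/pixel at 40x).
    """

    pixels: np.ndarray
    microns_per_pixel: float = 0.23

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixel array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _residual_vector(h: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Ruifrok-style complement of two stain vectors: per-channel
    sqrt(1 - h_c^2 - d_c^2), clipped at zero and renormalised.  Unlike the
    raw cross product this is non-negative, i.e. a physically plausible
    absorbance direction."""
    r = np.sqrt(np.clip(1.0 - h**2 - d**2, 0.0, None))
    n = np.linalg.norm(r)
    if n == 0:
        raise ValueError("residual vector degenerate; check stain vectors")
    return r / n


@dataclass(frozen=True)
class StainBasis:
    """Three unit optical-density direction vectors (rows: hematoxylin,
    DAB, residual), each over the (R, G, B) channels."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.hematoxylin, dtype=float)
        d = np.asarray(self.dab, dtype=float)
        if h.shape != (3,) or d.shape != (3,):
            raise ValueError("stain vectors must have length 3")
        if (h < 0).any() or (d < 0).any():
            raise ValueError("stain vectors must be non-negative")
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        if self.residual is None:
            r = _residual_vector(h, d)
        else:
            r = np.asarray(self.residual, dtype=float)
            if (r < 0).any():
                raise ValueError("residual vector must be non-negative")
            r = r / np.linalg.norm(r)
        object.__setattr__(self, "hematoxylin", h)
        object.__setattr__(self, "dab", d)
        object.__setattr__(self, "residual", r)
        if np.linalg.cond(self.matrix) >= _COND_LIMIT:
            raise ValueError(
                f"stain basis is numerically degenerate "
                f"(condition number >= {_COND_LIMIT:g})"
            )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with one stain vector per row."""
        return np.stack([self.hematoxylin, self.dab, self.residual])


#: Published Ruifrok-Johansen hematoxylin/DAB absorbance directions.
RUIFROK_HDAB = StainBasis(
    hematoxylin=np.array([0.650, 0.704, 0.286]),
    dab=np.array([0.268, 0.570, 0.776]),
)


def rgb_to_od(
    image: RGBImage | np.ndarray,
    background: float | tuple[float, float, float] = WHITE,
) -> np.ndarray:
    """Convert RGB intensities to per-channel optical density.

    OD_c = -log10((I_c + 1) / (background_c + 1)), clamped below at zero.
    The +1 offset bounds the OD at pixel value 0 without special-casing.

    Parameters
    ----------
    image : RGBImage or (H, W, 3) array
    background : scalar or per-channel triple in (0, 255]

    Returns
    -------
    ndarray, shape (H, W, 3)
        Non-negative optical densities.
    """
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    bg = np.broadcast_to(np.asarray(background, dtype=float), (3,))
    if (bg <= 0).any() or (bg > 255).any():
        raise ValueError("background intensities must lie in (0, 255]")
    od = -np.log10((px.astype(float) + 1.0) / (bg + 1.0))
    return np.clip(od, 0.0, None)


def separate_stains(
    od: np.ndarray, basis: StainBasis = RUIFROK_HDAB
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix OD planes into per-stain contribution maps.

    Each pixel's OD vector is projected onto the basis by solving the
    3x3 linear system (exact least squares for a full-rank square basis);
    negative coefficients are clamped to zero.

    Returns
    -------
    (hematoxylin, dab, residual) : three (H, W) float arrays, >= 0
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("od must have shape (H, W, 3)")
    # od = coeffs @ M  with M rows = stain vectors  =>  coeffs = od @ M^-1
    coeffs = od @ np.linalg.inv(basis.matrix)
    coeffs = np.clip(coeffs, 0.0, None)
    return coeffs[..., 0], coeffs[..., 1], coeffs[..., 2]


def dab_pseudo_intensity(dab: np.ndarray) -> np.ndarray:
    """Map DAB optical density to the 0-255 pseudo-intensity convention.

    value = 255 * 10**(-OD), clamped to [0, 255] and kept real-valued
    (rounding happens only at per-nucleus averaging/export).  OD 0 maps to
    255 (white); OD 1 maps to 25.5, matching the dark-brown floor of ~25.
    """
    dab = np.asarray(dab, dtype=float)
    if (dab < 0).any():
        raise ValueError("DAB optical density must be non-negative")
    return np.clip(WHITE * np.power(10.0, -dab), 0.0, WHITE)


def od_from_stains(
    hema: np.ndarray, dab: np.ndarray, basis: StainBasis = RUIFROK_HDAB
) -> np.ndarray:
    """Composite per-stain OD amounts back into per-channel OD planes.

    Inverse of :func:`separate_stains` (no residual term).  Used by the
    synthetic slide generator and by round-trip tests.
    """
    hema = np.asarray(hema, dtype=float)
    dab = np.asarray(dab, dtype=float)
    return (
        hema[..., None] * basis.hematoxylin[None, None, :]
        + dab[..., None] * basis.dab[None, None, :]
    )


def render_rgb(od: np.ndarray, background: float = WHITE) -> np.ndarray:
    """Render per-channel OD planes to an 8-bit RGB image.

    I_c = (background + 1) * 10**(-OD_c) - 1, rounded and clipped to
    [0, 255].  Exact inverse of :func:`rgb_to_od` up to quantisation.
    """
    intensity = (background + 1.0) * np.power(10.0, -np.asarray(od, float)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
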
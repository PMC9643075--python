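"""Pixel-based morphometrics from dorsal specimen images.

Traits are measured on cropped specimen scans (24-bit sRGB at a known
dpi) with explicit boolean masks for body and wing pixels — mask
derivation from real scans (manual cropping) is deliberately outside
this module; synthetic images carry exact masks.

Conventions:

* the body axis runs vertically, so each pixel row crosses the body
  perpendicular to its axis and the row's body-pixel count is a local
  body width;
* body volume treats each pixel row as a cylindrical disc:
  V = Σ_r π·(n_r·s/2)²·s with n_r body pixels in row r and s the pixel
  edge length in cm;
* color lightness of a pixel is the unweighted mean of its R, G, B
  channels (0 black … 255 white); species lightness is the mean over
  the body plus — for butterflies — the third of each wing nearest the
  body (odonates use the body alone);
* wing area is the wing-pixel count times the pixel area, and the
  dispersal proxy is the residual of ln(wing area) on ln(body volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SpecimenImage",
    "MorphometricRecord",
    "pixel_edge_cm",
    "body_volume",
    "proximal_wing_region",
    "color_lightness",
    "wing_area",
    "residual_wing_area",
    "measure_specimen",
]

#: scan resolution of the source drawings, pixels per inch
DEFAULT_DPI = 1200.0
#: fraction of each wing (nearest the body) scored for lightness
PROXIMAL_WING_FRACTION = 1.0 / 3.0


@dataclass
class SpecimenImage:
    """An RGB specimen image with its body/wing masks and resolution."""

    pixels: np.ndarray  # (H, W, 3) uint8
    dpi: float
    body_mask: np.ndarray  # (H, W) bool
    wing_mask: np.ndarray  # (H, W) bool

    def __post_init__(self):
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        h, w = self.pixels.shape[:2]
        for m in (self.body_mask, self.wing_mask):
            if m.shape != (h, w):
                raise ValueError("mask shape does not match image")
        if np.any(self.body_mask & self.wing_mask):
            raise ValueError("body and wing masks must be disjoint")


@dataclass
class MorphometricRecord:
    body_volume_cm3: float
    color_lightness: float
    wing_area_cm2: float
    residual_wing_area: float | None = None


def pixel_edge_cm(dpi: float) -> float:
    """Edge length of one pixel in cm (2.54 cm per inch)."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return 2.54 / dpi


def body_volume(body_mask: np.ndarray, dpi: float) -> float:
    """Cylinder-stack body volume in cm³ from a boolean body mask.

    Each pixel row is a disc of diameter (body pixels in the row × s)
    and thickness s, so V = Σ_r π (n_r s / 2)² s.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("empty body mask")
    s = pixel_edge_cm(dpi)
    n_r = body_mask.sum(axis=1).astype(float)
    return float(np.sum(np.pi * (n_r * s / 2.0) ** 2 * s))


def proximal_wing_region(wing_mask: np.ndarray, body_mask: np.ndarray,
                         fraction: float = PROXIMAL_WING_FRACTION
                         ) -> np.ndarray:
    """Per-wing nearest-to-body fraction of the wing mask, by pixel count.

    For each connected wing component the pixels with the smallest
    Euclidean distance to the body mask are retained until
    ⌈fraction × component size⌉ pixels are kept (ties broken by
    distance, then row-major order).  An empty wing mask yields an
    empty mask.
    """
    wing_mask = np.asarray(wing_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if np.any(wing_mask & body_mask):
        raise ValueError("body and wing masks must be disjoint")
    out = np.zeros_like(wing_mask)
    if not wing_mask.any():
        return out
    dist = ndimage.distance_transform_edt(~body_mask)
    labels, ncomp = ndimage.label(wing_mask)
    flat_dist = dist.ravel()
    flat_out = out.ravel()
    flat_labels = labels.ravel()
    for comp in range(1, ncomp + 1):
        idx = np.flatnonzero(flat_labels == comp)
        keep = int(np.ceil(fraction * len(idx)))
        order = np.lexsort((idx, flat_dist[idx]))
        flat_out[idx[order[:keep]]] = True
    return out


def color_lightness(pixels: np.ndarray, body_mask: np.ndarray,
                    wing_mask: np.ndarray | None = None, *,
                    proximal_fraction: float = PROXIMAL_WING_FRACTION,
                    include_wings: bool = True) -> float:
    """Mean 8-bit gray value over the scored region.

    The scored region is the body mask plus, when ``include_wings``
    (butterfly mode), the proximal ``proximal_fraction`` of each wing;
    odonate mode (``include_wings=False``) scores the body only.  Each
    pixel contributes (R+G+B)/3.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    selection = body_mask.copy()
    if include_wings and wing_mask is not None:
        selection |= proximal_wing_region(wing_mask, body_mask,
                                          proximal_fraction)
    if not selection.any():
        raise ValueError("empty pixel selection")
    sel = np.asarray(pixels, dtype=np.float64)[selection]
    return float(sel.mean())


def wing_area(wing_mask: np.ndarray, dpi: float) -> float:
    """Wing area in cm²: wing-pixel count × pixel area."""
    s = pixel_edge_cm(dpi)
    return float(np.count_nonzero(wing_mask) * s * s)


def residual_wing_area(wing_areas, body_volumes) -> np.ndarray:
    """Size-corrected wing area: OLS residuals of ln(area) on ln(volume).

    Requires strictly positive inputs and at least three species; the
    regression includes an intercept, so the residuals sum to zero.
    """
    a = np.asarray(wing_areas, dtype=float)
    v = np.asarray(body_volumes, dtype=float)
    if a.shape != v.shape or a.ndim != 1:
        raise ValueError("areas and volumes must be equal-length vectors")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 species for the size regression")
    if np.any(a <= 0) or np.any(v <= 0):
        raise ValueError("wing areas and body volumes must be positive")
    x = np.log(v)
    if np.ptp(x) == 0:
        raise ValueError("singular design: all body volumes identical")
    ylog = np.log(a)
    design = np.column_stack((np.ones_like(x), x))
    coef, *_ = np.linalg.lstsq(design, ylog, rcond=None)
    return ylog - design @ coef


def measure_specimen(img: SpecimenImage, *,
                     include_wings: bool = True) -> MorphometricRecord:
    """Body volume, lightness and wing area for one specimen image."""
    return MorphometricRecord(
        body_volume_cm3=body_volume(img.body_mask, img.dpi),
        color_lightness=color_lightness(img.pixels, img.body_mask,
                                        img.wing_mask,
                                        include_wings=include_wings),
        wing_area_cm2=wing_area(img.wing_mask, img.dpi),
    )


def morphometric_table(images: dict[str, SpecimenImage], *,
                       include_wings: bool = True) -> pd.DataFrame:
    """Measure a set of specimens and add the residual wing area column."""
    rows = {sp: measure_specimen(im, include_wings=include_wings)
            for sp, im in images.items()}
    df = pd.DataFrame(
        {sp: {"body_volume_cm3": r.body_volume_cm3,
              "color_lightness": r.color_lightness,
              "wing_area_cm2": r.wing_area_cm2}
         for sp, r in rows.items()}).T
    df.index.name = "species"
    df["residual_wing_area"] = residual_wing_area(
        df["wing_area_cm2"], df["body_volume_cm3"])
    return df
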
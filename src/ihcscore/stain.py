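"""Hematoxylin/DAB stain separation and compartment-level positive-pixel quantification.

The stain model is Beer-Lambert in base-10 optical density (OD): a pixel's
RGB transmission is ``v = 255 * 10**(-OD_h * H - OD_d * D)`` for unit stain
vectors ``H`` (hematoxylin) and ``D`` (DAB).  Deconvolution inverts this by
projecting per-channel OD onto the stain basis, which makes quantification
exactly invertible (up to quantisation and noise) on synthetically rendered
cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .scoring import assess_evaluability

# Ruifrok & Johnston H-DAB absorbance unit vectors (RGB order).
HEMATOXYLIN_VECTOR = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN_VECTOR = HEMATOXYLIN_VECTOR / np.linalg.norm(HEMATOXYLIN_VECTOR)
DAB_VECTOR = np.array([0.268, 0.570, 0.776])
DAB_VECTOR = DAB_VECTOR / np.linalg.norm(DAB_VECTOR)

#: Tissue-class label encoding shared across the whole package.
BACKGROUND, TUMOUR_POSITIVE, TUMOUR_NEGATIVE, STROMA, LYMPHOCYTE = 0, 1, 2, 3, 4
CLASS_NAMES = {
    BACKGROUND: "background",
    TUMOUR_POSITIVE: "tumour_positive",
    TUMOUR_NEGATIVE: "tumour_negative",
    STROMA: "stroma",
    LYMPHOCYTE: "lymphocyte",
}
TUMOUR_CLASSES = (TUMOUR_POSITIVE, TUMOUR_NEGATIVE)

#: Normalisation ceiling mapping mean DAB OD onto the [0, 1] intensity scale.
OD_MAX = 2.0


@dataclass(frozen=True)
class PositivityThresholds:
    """DAB-OD cut points defining positive pixels and their weak/medium/strong bins."""

    weak: float = 0.15
    medium: float = 0.40
    strong: float = 0.80

    def __post_init__(self) -> None:
        if not (0 <= self.weak < self.medium < self.strong):
            raise ValueError("thresholds must satisfy 0 <= weak < medium < strong")


@dataclass
class ChannelQuant:
    """Positive-pixel summary for one compartment (nuclear or cytoplasmic)."""

    total_px: int = 0
    positive_px: int = 0
    weak_px: int = 0
    medium_px: int = 0
    strong_px: int = 0
    mean_positive_od: float = 0.0

    @property
    def positive_fraction(self) -> float:
        return self.positive_px / self.total_px if self.total_px else 0.0

    @property
    def intensity(self) -> float:
        """Mean positive OD normalised by :data:`OD_MAX` onto [0, 1]."""
        return min(self.mean_positive_od / OD_MAX, 1.0)


@dataclass
class CompartmentQuant:
    """Nuclear + cytoplasmic quantification for one core."""

    nuclear: ChannelQuant = field(default_factory=ChannelQuant)
    cytoplasmic: ChannelQuant = field(default_factory=ChannelQuant)
    tumour_px: int = 0
    evaluable: bool = False

    def validate(self) -> None:
        for ch in (self.nuclear, self.cytoplasmic):
            if ch.positive_px > ch.total_px:
                raise ValueError("positive_px exceeds total_px")
            if ch.weak_px + ch.medium_px + ch.strong_px != ch.positive_px:
                raise ValueError("intensity bins do not partition positive pixels")
            if ch.mean_positive_od < 0:
                raise ValueError("mean_positive_od must be >= 0")
        if self.tumour_px < self.nuclear.total_px + self.cytoplasmic.total_px:
            raise ValueError("compartments exceed tumour area")


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if image.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input")
    return image


def deconvolve_stains(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an 8-bit RGB H-DAB image into (hematoxylin OD, DAB OD) rasters.

    Per-channel OD is ``-log10((v + 1) / 256)``; the OD vector at each pixel is
    projected onto the hematoxylin/DAB unit vectors and negative projections are
    clipped to zero.
    """
    image = _check_rgb8(image)
    od = -np.log10((image.astype(np.float64) + 1.0) / 256.0)
    basis = np.stack([HEMATOXYLIN_VECTOR, DAB_VECTOR], axis=1)  # 3 x 2
    coeffs, *_ = np.linalg.lstsq(basis, od.reshape(-1, 3).T, rcond=None)
    coeffs = np.clip(coeffs, 0.0, None)
    h_od = coeffs[0].reshape(image.shape[:2])
    d_od = coeffs[1].reshape(image.shape[:2])
    return h_od, d_od


def segment_nuclei(
    hematoxylin_od: np.ndarray,
    tumour_mask: np.ndarray,
    dab_od: np.ndarray | None = None,
    min_area: int = 30,
    dab_rescue_od: float = 0.9,
    rescue_min_h: float = 0.3,
) -> np.ndarray:
    """Nuclear mask within tumour from the hematoxylin channel.

    Otsu threshold on hematoxylin OD restricted to tumour; optionally rescues
    counterstain-quenched positive nuclei showing strong DAB with moderate
    hematoxylin.  Holes are filled and objects below ``min_area`` px removed.
    An empty tumour mask yields an empty nuclear mask.
    """
    hematoxylin_od = np.asarray(hematoxylin_od, dtype=np.float64)
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    if hematoxylin_od.shape != tumour_mask.shape:
        raise ValueError("raster dimensions differ")
    if not tumour_mask.any():
        return np.zeros_like(tumour_mask)
    vals = hematoxylin_od[tumour_mask]
    if np.ptp(vals) < 1e-9:
        return np.zeros_like(tumour_mask)
    thr = threshold_otsu(vals)
    mask = tumour_mask & (hematoxylin_od >= thr)
    if dab_od is not None:
        # counterstain-quenched positive nuclei: strong DAB with hematoxylin
        # clearly above the cytoplasmic floor (absolute, so that heavy DAB
        # cytoplasm cannot leak in when the Otsu threshold sits low)
        rescue = (
            tumour_mask
            & (np.asarray(dab_od) >= dab_rescue_od)
            & (hematoxylin_od >= max(0.5 * thr, rescue_min_h))
        )
        mask |= rescue
    mask = ndi.binary_fill_holes(mask) & tumour_mask
    # drop speckle objects below the minimum nucleus area
    lbl, n = ndi.label(mask)
    if n:
        sizes = np.bincount(lbl.ravel())
        keep = sizes >= min_area
        keep[0] = False
        mask = keep[lbl]
    return mask


def _quantify_channel(
    dab_od: np.ndarray, mask: np.ndarray, thresholds: PositivityThresholds
) -> ChannelQuant:
    vals = dab_od[mask]
    positive = vals > thresholds.weak
    pos_vals = vals[positive]
    q = ChannelQuant(
        total_px=int(mask.sum()),
        positive_px=int(positive.sum()),
        weak_px=int(((pos_vals > thresholds.weak) & (pos_vals <= thresholds.medium)).sum()),
        medium_px=int(((pos_vals > thresholds.medium) & (pos_vals <= thresholds.strong)).sum()),
        strong_px=int((pos_vals > thresholds.strong).sum()),
        mean_positive_od=float(pos_vals.mean()) if pos_vals.size else 0.0,
    )
    return q


def quantify_compartments(
    image: np.ndarray,
    tissue_labels: np.ndarray,
    thresholds: PositivityThresholds | None = None,
    min_tumour_px: int = 2000,
    min_nucleus_area: int = 30,
) -> CompartmentQuant:
    """Positive-pixel quantification of nuclear and cytoplasmic DAB within tumour.

    Tumour is the union of the two tumour classes in ``tissue_labels``; the
    nuclear compartment comes from :func:`segment_nuclei` and cytoplasm is
    tumour minus nuclei.  A pixel is positive when its DAB OD exceeds the weak
    threshold; positives are binned weak/medium/strong.
    """
    image = _check_rgb8(image)
    tissue_labels = np.asarray(tissue_labels)
    if tissue_labels.shape != image.shape[:2]:
        raise ValueError("tissue map does not match image dimensions")
    present = set(np.unique(tissue_labels).tolist())
    if not present <= set(CLASS_NAMES):
        raise ValueError(f"unknown tissue labels: {sorted(present - set(CLASS_NAMES))}")
    thresholds = thresholds or PositivityThresholds()

    h_od, d_od = deconvolve_stains(image)
    tumour = np.isin(tissue_labels, TUMOUR_CLASSES)
    nuclei = segment_nuclei(h_od, tumour, dab_od=d_od, min_area=min_nucleus_area)
    cytoplasm = tumour & ~nuclei

    quant = CompartmentQuant(
        nuclear=_quantify_channel(d_od, nuclei, thresholds),
        cytoplasmic=_quantify_channel(d_od, cytoplasm, thresholds),
        tumour_px=int(tumour.sum()),
    )
    quant.evaluable = assess_evaluability(quant, min_tumour_px=min_tumour_px)
    quant.validate()
    return quant


RED = np.array([255, 0, 0], dtype=np.uint8)
ORANGE = np.array([255, 165, 0], dtype=np.uint8)
YELLOW = np.array([255, 255, 0], dtype=np.uint8)


def render_markup(
    image: np.ndarray,
    nuclear_positive: np.ndarray,
    cytoplasmic_positive: np.ndarray,
    cytoplasmic_weak: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudo-colour mark-up: positive nuclei red, positive cytoplasm orange,
    weak cytoplasm yellow; everything else keeps its original colour."""
    image = _check_rgb8(image)
    for mask in (nuclear_positive, cytoplasmic_positive):
        if np.asarray(mask).shape != image.shape[:2]:
            raise ValueError("mask dimensions do not match image")
    out = image.copy()
    cyt = np.asarray(cytoplasmic_positive, dtype=bool)
    if cytoplasmic_weak is not None:
        weak = np.asarray(cytoplasmic_weak, dtype=bool) & cyt
        out[cyt & ~weak] = ORANGE
        out[weak] = YELLOW
    else:
        out[cyt] = ORANGE
    out[np.asarray(nuclear_positive, dtype=bool)] = RED
    return out
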
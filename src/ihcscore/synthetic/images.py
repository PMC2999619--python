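"""Synthetic H-DAB TMA-core renderer with pixel-level ground truth.

A core is a circular tissue disc containing tumour nests (elliptical nuclei
plus a cytoplasmic annulus), stromal matrix and small dense lymphocyte
clusters, composited over a white slide background.  Staining follows the
Beer-Lambert model used by :mod:`ihcscore.stain`: each pixel carries a
hematoxylin OD and a DAB OD, Gaussian OD noise is added pre-exponentiation,
and RGB = round(255 * 10**(-OD_h*H - OD_d*D)).

The generator keeps full bookkeeping — which nuclei were drawn positive, at
what OD, where the cytoplasm lies — so that every downstream estimate can be
checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ..stain import (
    BACKGROUND,
    DAB_VECTOR,
    HEMATOXYLIN_VECTOR,
    LYMPHOCYTE,
    STROMA,
    TUMOUR_NEGATIVE,
    TUMOUR_POSITIVE,
    ChannelQuant,
    CompartmentQuant,
    PositivityThresholds,
)

# Relative hematoxylin pickup of the non-nuclear textures.
_STROMA_H_FACTOR = 0.35
_LYMPHOCYTE_H_FACTOR = 1.35
_CYTOPLASM_H_FACTOR = 0.12


@dataclass(frozen=True)
class StainParams:
    """Latent staining and layout parameters of one synthetic core."""

    fraction_positive_nuclei: float = 0.5
    fraction_positive_cytoplasm: float = 0.5
    nuclear_dab_od: float = 0.6
    cytoplasmic_dab_od: float = 0.45
    hematoxylin_od: float = 0.7
    tumour_area_fraction: float = 0.45
    lymphocyte_area_fraction: float = 0.06
    nuclei_per_1000px2: float = 8.0
    noise_sd: float = 0.02

    def validate(self) -> None:
        for name in ("fraction_positive_nuclei", "fraction_positive_cytoplasm",
                     "tumour_area_fraction", "lymphocyte_area_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tumour_area_fraction + self.lymphocyte_area_fraction > 1.0:
            raise ValueError("tumour + lymphocyte area fractions exceed 1")
        for name in ("nuclear_dab_od", "cytoplasmic_dab_od", "hematoxylin_od",
                     "nuclei_per_1000px2", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Per-pixel labels and exact quantification bookkeeping for one core."""

    class_mask: np.ndarray
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    nuclear_positive_mask: np.ndarray
    cytoplasm_positive_mask: np.ndarray
    n_nuclei: int
    true_quant: CompartmentQuant

    def validate(self) -> None:
        shapes = {m.shape for m in (self.class_mask, self.nuclear_mask,
                                    self.cytoplasm_mask, self.nuclear_positive_mask,
                                    self.cytoplasm_positive_mask)}
        if len(shapes) != 1:
            raise ValueError("ground-truth rasters disagree on dimensions")
        if (self.nuclear_mask & self.cytoplasm_mask).any():
            raise ValueError("nuclear and cytoplasm masks overlap")
        tumour = np.isin(self.class_mask, (TUMOUR_POSITIVE, TUMOUR_NEGATIVE))
        if ((self.nuclear_mask | self.cytoplasm_mask) & ~tumour).any():
            raise ValueError("compartment pixels outside tumour classes")


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float,
               angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    y = yy - cy
    x = xx - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        y, x = c * y - s * x, s * y + c * x
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _place_blobs(rng, region: np.ndarray, target_px: int, rmin: float, rmax: float,
                 max_tries: int = 4000) -> np.ndarray:
    """Union of random ellipses inside ``region`` until ~target_px covered."""
    out = np.zeros_like(region)
    shape = region.shape
    ys, xs = np.nonzero(region)
    if ys.size == 0 or target_px <= 0:
        return out
    tries = 0
    while out.sum() < target_px and tries < max_tries:
        tries += 1
        i = rng.integers(ys.size)
        ry = rng.uniform(rmin, rmax)
        rx = rng.uniform(rmin, rmax)
        blob = _disk_mask(shape, ys[i], xs[i], ry, rx, rng.uniform(0, np.pi))
        out |= blob & region
    return out


def _true_quant(params: StainParams, gt_masks: dict, thresholds: PositivityThresholds,
                tumour_px: int) -> CompartmentQuant:
    """Exact quantification from the generator's own noiseless bookkeeping."""

    def channel(mask, pos_mask, od):
        total = int(mask.sum())
        pos = int(pos_mask.sum()) if od > thresholds.weak else 0
        q = ChannelQuant(total_px=total, positive_px=pos,
                         mean_positive_od=od if pos else 0.0)
        if pos:
            if od <= thresholds.medium:
                q.weak_px = pos
            elif od <= thresholds.strong:
                q.medium_px = pos
            else:
                q.strong_px = pos
        return q

    quant = CompartmentQuant(
        nuclear=channel(gt_masks["nuclear"], gt_masks["nuclear_positive"],
                        params.nuclear_dab_od),
        cytoplasmic=channel(gt_masks["cytoplasm"], gt_masks["cytoplasm_positive"],
                            params.cytoplasmic_dab_od),
        tumour_px=tumour_px,
    )
    quant.evaluable = quant.tumour_px > 0 and quant.nuclear.total_px > 0
    quant.validate()
    return quant


def generate_core_image(
    params: StainParams,
    width: int = 256,
    height: int = 256,
    seed: int | None = None,
    thresholds: PositivityThresholds | None = None,
    cytoplasm_width: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic TMA core and its exact ground truth.

    Deterministic given ``seed``; the RNG stream is local to the call.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    params.validate()
    thresholds = thresholds or PositivityThresholds()
    rng = np.random.default_rng(seed)
    shape = (height, width)

    core_r = 0.47 * min(width, height)
    core = _disk_mask(shape, height / 2, width / 2, core_r, core_r)
    core_px = int(core.sum())

    # --- tumour nests -----------------------------------------------------
    nest_scale = 0.10 * min(width, height)
    nests = _place_blobs(rng, core, int(params.tumour_area_fraction * core_px),
                         0.6 * nest_scale, 1.4 * nest_scale)
    # --- lymphocyte clusters in the remaining tissue ----------------------
    lymph = _place_blobs(rng, core & ~nests,
                         int(params.lymphocyte_area_fraction * core_px), 3.0, 7.0)

    class_mask = np.full(shape, BACKGROUND, dtype=np.uint8)
    class_mask[core] = STROMA
    class_mask[lymph] = LYMPHOCYTE
    class_mask[nests] = TUMOUR_NEGATIVE  # refined per-nest below

    # --- nuclei on a jittered grid inside nests ---------------------------
    nuclear_mask = np.zeros(shape, dtype=bool)
    nucleus_ids = np.zeros(shape, dtype=np.int32)
    if params.nuclei_per_1000px2 > 0:
        spacing = max(4.0, np.sqrt(1000.0 / params.nuclei_per_1000px2))
    else:
        spacing = None
    nucleus_list: list[int] = []
    if spacing is not None:
        nid = 0
        for gy in np.arange(spacing / 2, height, spacing):
            for gx in np.arange(spacing / 2, width, spacing):
                cy = gy + rng.uniform(-0.1, 0.1) * spacing
                cx = gx + rng.uniform(-0.1, 0.1) * spacing
                iy, ix = int(round(cy)), int(round(cx))
                if not (0 <= iy < height and 0 <= ix < width and nests[iy, ix]):
                    continue
                ry = rng.uniform(3.0, 4.0)
                rx = rng.uniform(3.0, 4.0)
                nucleus = _disk_mask(shape, cy, cx, ry, rx, rng.uniform(0, np.pi))
                nucleus &= nests & ~nuclear_mask
                # skip boundary-clipped slivers below the downstream area floor
                if nucleus.sum() < 30:
                    continue
                nid += 1
                nuclear_mask |= nucleus
                nucleus_ids[nucleus] = nid
                nucleus_list.append(nid)
    n_nuclei = len(nucleus_list)

    # --- cytoplasm: nest minus nuclei (optionally a fixed-width annulus) ---
    if n_nuclei:
        if cytoplasm_width is None:
            cytoplasm_mask = nests & ~nuclear_mask
        else:
            dil = ndi.binary_dilation(nuclear_mask, iterations=cytoplasm_width)
            cytoplasm_mask = dil & nests & ~nuclear_mask
        # parent nucleus of each cytoplasm pixel (nearest nucleus)
        _, (iy, ix) = ndi.distance_transform_edt(nucleus_ids == 0, return_indices=True)
        parent = nucleus_ids[iy, ix]
    else:
        cytoplasm_mask = np.zeros(shape, dtype=bool)
        parent = np.zeros(shape, dtype=np.int32)

    # --- per-nucleus positivity ------------------------------------------
    nuc_positive = rng.random(n_nuclei + 1) < params.fraction_positive_nuclei
    cyt_positive = rng.random(n_nuclei + 1) < params.fraction_positive_cytoplasm
    nuc_positive[0] = cyt_positive[0] = False
    nuclear_positive_mask = nuclear_mask & nuc_positive[nucleus_ids]
    cytoplasm_positive_mask = cytoplasm_mask & cyt_positive[parent]

    # --- tumour-positive class: pixels of DAB-positive nuclei/cytoplasm ---
    class_mask[nuclear_positive_mask | cytoplasm_positive_mask] = TUMOUR_POSITIVE

    # --- stain OD fields --------------------------------------------------
    h_field = np.zeros(shape)
    h_field[core] = 0.0
    h_field[class_mask == STROMA] = _STROMA_H_FACTOR * params.hematoxylin_od
    h_field[class_mask == LYMPHOCYTE] = _LYMPHOCYTE_H_FACTOR * params.hematoxylin_od
    h_field[np.isin(class_mask, (TUMOUR_POSITIVE, TUMOUR_NEGATIVE))] = (
        _CYTOPLASM_H_FACTOR * params.hematoxylin_od
    )
    h_field[nuclear_mask] = params.hematoxylin_od

    d_field = np.zeros(shape)
    d_field[nuclear_positive_mask] = params.nuclear_dab_od
    d_field[cytoplasm_positive_mask] = params.cytoplasmic_dab_od

    if params.noise_sd > 0:
        h_field = h_field + rng.normal(0.0, params.noise_sd, shape)
        d_field = d_field + rng.normal(0.0, params.noise_sd, shape)
        np.clip(h_field, 0.0, None, out=h_field)
        np.clip(d_field, 0.0, None, out=d_field)

    od = (h_field[..., None] * HEMATOXYLIN_VECTOR
          + d_field[..., None] * DAB_VECTOR)
    image = np.clip(np.round(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)

    masks = {
        "nuclear": nuclear_mask,
        "cytoplasm": cytoplasm_mask,
        "nuclear_positive": nuclear_positive_mask,
        "cytoplasm_positive": cytoplasm_positive_mask,
    }
    tumour_px = int(np.isin(class_mask, (TUMOUR_POSITIVE, TUMOUR_NEGATIVE)).sum())
    truth = GroundTruth(
        class_mask=class_mask,
        nuclear_mask=nuclear_mask,
        cytoplasm_mask=cytoplasm_mask,
        nuclear_positive_mask=nuclear_positive_mask,
        cytoplasm_positive_mask=cytoplasm_positive_mask,
        n_nuclei=n_nuclei,
        true_quant=_true_quant(params, masks, thresholds, tumour_px),
    )
    truth.validate()
    return image, truth
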
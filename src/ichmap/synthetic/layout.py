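"""Geometric section template for the synthetic cohorts.

The template is a deliberately simple coronal-section cartoon: an
elliptical tissue outline with a cortical band (CTX), two lateral
striatal blobs (STR) with a lesion carved out of the ipsilateral one,
central thalamus (TH), a ventral deep-brain band (DEEP, standing in for
pallidum/hypothalamus/midbrain/pons), three ventricular cavities and a
choroid-plexus (CP) blob inside each cavity.  It is not an atlas; it
exists to give every spot and pixel an unambiguous ground-truth
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

REGIONS = (
    "CTX",
    "STR",
    "TH",
    "CP",
    "DEEP",
    "lesion",
    "ventricle_ipsi",
    "ventricle_contra",
    "ventricle_third",
)

#: anatomical scoring regions; DEEP is the composite of these four
DEEP_CONSTITUENTS = ("PAL", "HY", "MB", "P")
SCORING_REGIONS = ("TH", "CTX", "CP", "STR") + DEEP_CONSTITUENTS


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             radii: tuple[float, float]) -> np.ndarray:
    """Boolean ellipse; center and radii in fractions of (height, width)."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cr, cw = center[0] * h, center[1] * w
    ra, rb = radii[0] * h, radii[1] * w
    return ((rr - cr) / ra) ** 2 + ((cc - cw) / rb) ** 2 <= 1.0


@dataclass
class SectionLayout:
    """Region masks of the section template.

    ``region_masks`` maps each label in :data:`REGIONS` to a boolean
    mask; masks are mutually disjoint.  ``outline`` is the tissue
    outline, ``lesion_center_px`` the (row, col) of the injection site.
    """

    width_px: int
    height_px: int
    px_size_um: float
    region_masks: dict[str, np.ndarray]
    outline: np.ndarray
    lesion_center_px: tuple[float, float]
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def validate(self) -> None:
        """Check the structural invariants of the template."""
        total = np.zeros(self.shape, dtype=int)
        for name in REGIONS:
            mask = self.region_masks[name]
            if mask.shape != self.shape:
                raise ValueError(f"mask {name!r} has wrong shape")
            total += mask.astype(int)
        if (total > 1).any():
            raise ValueError("region masks overlap")
        if (total.astype(bool) & ~self.outline).any():
            raise ValueError("region masks extend beyond the section outline")
        str_hull = convex_hull_image(
            self.region_masks["STR"] | self.region_masks["lesion"]
        )
        if (self.region_masks["lesion"] & ~str_hull).any():
            raise ValueError("lesion not contained in the striatum")
        # each ventricle mask is a ring around its CP core, so its convex
        # hull is the filled cavity and must contain the CP pixels
        cp = self.region_masks["CP"]
        cavity = np.zeros(self.shape, dtype=bool)
        for v in ("ventricle_ipsi", "ventricle_contra", "ventricle_third"):
            cavity |= convex_hull_image(self.region_masks[v])
        if (cp & ~cavity).any():
            raise ValueError("CP mask outside the ventricular cavities")

    def region_of(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Region label per pixel coordinate; '' for unlabeled pixels."""
        out = np.full(len(rows), "", dtype=object)
        for name in REGIONS:
            hit = self.region_masks[name][rows, cols]
            out[hit] = name
        return out


def build_layout(size_px: int = 512, px_size_um: float = 20.0,
                 lesion_radius_frac: float = 0.05) -> SectionLayout:
    """Build the default section template at the requested raster size.

    ``lesion_radius_frac`` scales the lesion disc (fraction of the image
    side); pass 0 for a lesion-free (no-injection) section.
    """
    shape = (size_px, size_px)
    # clearly anisotropic outline (wider than tall) so the principal
    # axis of the section is well defined for moment-based registration;
    # enough border margin that a 10% scale-up plus a 10 px shift never
    # clips the section at the field edge
    outline = _ellipse(shape, (0.50, 0.50), (0.36, 0.43))
    inner = _ellipse(shape, (0.50, 0.50), (0.36 * 0.80, 0.43 * 0.80))

    # cavities and their CP cores; ipsilateral = high column index
    cav_i = _ellipse(shape, (0.42, 0.575), (0.065, 0.048))
    cav_c = _ellipse(shape, (0.42, 0.425), (0.065, 0.048))
    cav_3 = _ellipse(shape, (0.615, 0.500), (0.055, 0.034))
    cp_i = _ellipse(shape, (0.42, 0.575), (0.038, 0.028))
    cp_c = _ellipse(shape, (0.42, 0.425), (0.038, 0.028))
    cp_3 = _ellipse(shape, (0.615, 0.500), (0.032, 0.020))
    cp = cp_i | cp_c | cp_3

    str_i = _ellipse(shape, (0.38, 0.72), (0.135, 0.115))
    str_c = _ellipse(shape, (0.38, 0.28), (0.135, 0.115))
    lesion_center = (0.38 * size_px, 0.74 * size_px)
    if lesion_radius_frac > 0:
        lesion = _ellipse(
            shape, (0.38, 0.74), (lesion_radius_frac, lesion_radius_frac)
        ) & str_i
    else:
        lesion = np.zeros(shape, dtype=bool)

    rr = np.arange(size_px)[:, None] / size_px
    deep_band = inner & (np.broadcast_to(rr > 0.62, shape))

    taken = np.zeros(shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}

    def claim(name: str, mask: np.ndarray) -> None:
        nonlocal taken
        m = mask & outline & ~taken
        masks[name] = m
        taken = taken | m

    claim("lesion", lesion)
    claim("CP", cp)
    claim("ventricle_ipsi", cav_i)
    claim("ventricle_contra", cav_c)
    claim("ventricle_third", cav_3)
    claim("STR", str_i | str_c)
    claim("CTX", outline & ~inner)
    claim("DEEP", deep_band)
    claim("TH", inner)

    layout = SectionLayout(
        width_px=size_px,
        height_px=size_px,
        px_size_um=px_size_um,
        region_masks=masks,
        outline=outline,
        lesion_center_px=lesion_center,
        meta={"lesion_radius_frac": lesion_radius_frac},
    )
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# histology parcels


def _hemisphere_split(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    cols = np.broadcast_to(np.arange(w)[None, :], shape)
    return cols >= w / 2, cols < w / 2  # (ipsi, contra)


def parcel_labels(layout: SectionLayout,
                  perilesional_um: float = 300.0
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Disjoint parcel label image + table for histology quantification.

    Bilateral regions are split at the midline into ``_ipsi`` (high
    column index, the injection side) and ``_contra`` parcels; CP and
    ventricles are named by cavity.  A ``perilesional_STR`` ring of
    width ``perilesional_um`` is carved out of the ipsilateral striatum
    around the lesion.
    """
    shape = layout.shape
    ipsi, contra = _hemisphere_split(shape)
    m = layout.region_masks

    halves = {}
    for name in ("CTX", "STR", "TH", "DEEP"):
        halves[f"{name}_ipsi"] = m[name] & ipsi
        halves[f"{name}_contra"] = m[name] & contra

    n_dilate = max(1, int(round(perilesional_um / layout.px_size_um)))
    if m["lesion"].any():
        peri = ndimage.binary_dilation(m["lesion"], iterations=n_dilate)
        peri = peri & halves["STR_ipsi"]
        halves["STR_ipsi"] = halves["STR_ipsi"] & ~peri
    else:
        peri = np.zeros(shape, dtype=bool)

    cp_parts = {
        "CP_ipsi": convex_hull_image(m["ventricle_ipsi"]),
        "CP_contra": convex_hull_image(m["ventricle_contra"]),
        "CP_third": convex_hull_image(m["ventricle_third"]),
    }
    parcels: dict[str, np.ndarray] = {}
    parcels["lesion"] = m["lesion"]
    parcels["perilesional_STR"] = peri
    for cp_name, hull in cp_parts.items():
        parcels[cp_name] = m["CP"] & ndimage.binary_dilation(hull, iterations=2)
    parcels["ventricle_ipsi"] = m["ventricle_ipsi"]
    parcels["ventricle_contra"] = m["ventricle_contra"]
    parcels["ventricle_third"] = m["ventricle_third"]
    parcels.update(halves)
    rest = layout.outline.copy()
    for mask in parcels.values():
        rest &= ~mask
    parcels["other_ipsi"] = rest & ipsi
    parcels["other_contra"] = rest & contra

    labels = np.zeros(shape, dtype=np.uint16)
    rows = []
    for i, (name, mask) in enumerate(parcels.items(), start=1):
        labels[mask] = i
        rows.append({"label": i, "compartment": name})
    return labels, pd.DataFrame(rows)


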
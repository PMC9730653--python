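"""Quantitative immunofluorescence: section selection, registration to a
common template, cross-animal average-intensity maps, dextran-leakage
quantification, and per-compartment mean intensities.

Registration uses image moments of the section outline: the centroid
difference gives the translation, the principal-axis angle difference
the rotation (with the 180-degree ambiguity resolved by the side of the
ventral ventricle centroid), and the square root of the outline-area
ratio the isotropic scale.  Sections are intensity-normalized by the
median of the contralateral hemisphere before any averaging, so maps
are in units of contralateral-median fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktransform

from .datatypes import IntensityMap, SectionImage

log = logging.getLogger(__name__)

#: composite compartments resolvable from parcel-label names
COMPOSITE_COMPARTMENTS = {
    "CP": ["CP_ipsi", "CP_contra", "CP_third"],
    "STR": ["STR_ipsi", "STR_contra", "lesion", "perilesional_STR"],
    "hemisphere_ipsi": [
        "CTX_ipsi", "STR_ipsi", "TH_ipsi", "DEEP_ipsi", "other_ipsi",
        "lesion", "perilesional_STR", "CP_ipsi", "ventricle_ipsi",
    ],
    "hemisphere_contra": [
        "CTX_contra", "STR_contra", "TH_contra", "DEEP_contra",
        "other_contra", "CP_contra", "ventricle_contra",
    ],
}


def compartment_mask(labels: np.ndarray, table: pd.DataFrame,
                     compartment: str) -> np.ndarray:
    """Boolean mask for a parcel or a composite compartment name."""
    names = COMPOSITE_COMPARTMENTS.get(compartment, [compartment])
    present = table.loc[table["compartment"].isin(names), "label"]
    if present.empty:
        raise KeyError(f"compartment {compartment!r} not found in label table")
    return np.isin(labels, present.to_numpy())


__all__ = [
    "SimilarityTransform",
    "compartment_mask",
    "select_standard_sections",
    "estimate_registration",
    "warp_to_template",
    "normalize_section",
    "average_intensity_map",
    "build_intensity_maps",
    "quantify_leakage",
    "compartment_mean_intensity",
]


@dataclass
class SimilarityTransform:
    """Rotation + isotropic scale + translation in (row, col) pixels.

    Internally a 3x3 homogeneous matrix acting on (col, row) points, the
    scikit-image convention.  ``apply`` then ``inverse().apply`` returns
    the identity to well below 1e-6 px.
    """

    matrix: np.ndarray

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, rotation_deg: float = 0.0, scale: float = 1.0,
                    translation_rc: tuple[float, float] = (0.0, 0.0),
                    center_rc: tuple[float, float] = (0.0, 0.0),
                    ) -> "SimilarityTransform":
        """T(p) = R*s*(p - c) + c + t, all in (row, col) pixels."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        cy, cx = center_rc
        ty, tx = translation_rc
        to_origin = sktransform.SimilarityTransform(translation=(-cx, -cy))
        rot = sktransform.SimilarityTransform(
            rotation=math.radians(rotation_deg), scale=scale
        )
        back = sktransform.SimilarityTransform(translation=(cx + tx, cy + ty))
        return cls((to_origin + rot + back).params.copy())

    @property
    def scale(self) -> float:
        return float(np.sqrt(np.linalg.det(self.matrix[:2, :2])))

    @property
    def rotation_deg(self) -> float:
        return math.degrees(
            math.atan2(self.matrix[1, 0], self.matrix[0, 0])
        )

    def params_about(self, center_rc: tuple[float, float]
                     ) -> tuple[float, float, tuple[float, float]]:
        """(rotation_deg, scale, translation_rc) of the center-anchored form."""
        cy, cx = center_rc
        out = self.apply(np.array([[cy, cx]]))[0]
        return self.rotation_deg, self.scale, (out[0] - cy, out[1] - cx)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: (self.compose(other))(p) = self(other(p))."""
        return SimilarityTransform(self.matrix @ other.matrix)

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform(np.linalg.inv(self.matrix))

    def apply(self, points_rc: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_rc, dtype=float)
        xy = np.column_stack([pts[:, 1], pts[:, 0], np.ones(len(pts))])
        out = xy @ self.matrix.T
        return np.column_stack([out[:, 1], out[:, 0]])

    def warp(self, image: np.ndarray, output_shape: tuple[int, int] | None = None,
             order: int = 1, fill: float = np.nan) -> np.ndarray:
        """Apply the forward transform to an image (NaN outside the field)."""
        sk = sktransform.SimilarityTransform(matrix=self.matrix)
        return sktransform.warp(
            np.asarray(image, dtype=float), inverse_map=sk.inverse,
            output_shape=output_shape, order=order, cval=fill,
            preserve_range=True, mode="constant",
        )


def select_standard_sections(positions_um: Sequence[float],
                             start_um: float = 300.0,
                             step_sections: int = 2,
                             n_sections: int = 8) -> list[int]:
    """Standardized section pick: first section at/after ``start_um``,
    then every ``step_sections``-th, ``n_sections`` in total."""
    pos = np.asarray(positions_um, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("section positions must be sorted ascending")
    at = np.nonzero(pos >= start_um)[0]
    if at.size == 0:
        raise ValueError(f"no section at or beyond {start_um} um")
    first = int(at[0])
    idx = [first + i * step_sections for i in range(n_sections)]
    if idx[-1] >= len(pos):
        need = idx[-1] + 1 - first
        have = len(pos) - first
        raise ValueError(
            f"stack too short: need {need} sections from the start position, "
            f"have {have}"
        )
    return idx


# ---------------------------------------------------------------------------
# registration


def _outline_moments(mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(centroid_rc, orientation_rad in (-pi/2, pi/2], area) of a mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("outline mask is empty")
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    return np.array([cy, cx]), theta, float(ys.size)


def _ventral_anchor(section: SectionImage) -> np.ndarray | None:
    """Centroid of the midline (third-ventricle) compartments, if present."""
    names = [
        n for n in section.label_table["compartment"]
        if n in ("ventricle_third", "CP_third")
    ]
    if not names:
        return None
    mask = np.zeros(section.labels.shape, dtype=bool)
    for n in names:
        mask |= section.parcel_mask(n)
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    return np.array([ys.mean(), xs.mean()])


def _boundary_points(mask: np.ndarray, max_points: int = 2000) -> np.ndarray:
    edge = mask & ~ndimage.binary_erosion(mask)
    pts = np.column_stack(np.nonzero(edge)).astype(float)
    if len(pts) > max_points:
        step = len(pts) // max_points
        pts = pts[::step]
    return pts


def estimate_registration(section: SectionImage, template: SectionImage,
                          residual_threshold_px: float = 5.0,
                          ) -> tuple[SimilarityTransform, float, bool]:
    """Moment-based similarity transform mapping section -> template.

    Returns (transform, mean boundary residual in template px,
    low_confidence flag).
    """
    sec_mask = section.labels > 0
    tmp_mask = template.labels > 0
    if not sec_mask.any() or not tmp_mask.any():
        raise ValueError("hemisphere outline missing in section or template")
    c_s, th_s, a_s = _outline_moments(sec_mask)
    c_t, th_t, a_t = _outline_moments(tmp_mask)
    scale = math.sqrt(a_t / a_s)
    rot = th_t - th_s
    # fold into (-90, 90] then resolve the 180-degree ambiguity with the
    # ventral-ventricle anchor direction
    while rot <= -math.pi / 2:
        rot += math.pi
    while rot > math.pi / 2:
        rot -= math.pi
    candidates = [rot, rot + math.pi]
    anchor_s = _ventral_anchor(section)
    anchor_t = _ventral_anchor(template)
    best = candidates[0]
    if anchor_s is not None and anchor_t is not None:
        v_s = anchor_s - c_s
        v_t = anchor_t - c_t
        scores = []
        for cand in candidates:
            ca, sa = math.cos(cand), math.sin(cand)
            # rotate (row, col) vector: treat as (y, x)
            vy = sa * v_s[1] + ca * v_s[0]
            vx = ca * v_s[1] - sa * v_s[0]
            scores.append(vx * v_t[1] + vy * v_t[0])
        best = candidates[int(np.argmax(scores))]
    tform = SimilarityTransform.from_params(
        rotation_deg=math.degrees(best), scale=scale,
        translation_rc=(c_t[0] - c_s[0], c_t[1] - c_s[1]),
        center_rc=(c_s[0], c_s[1]),
    )
    # residual: mean distance of warped section boundary to template boundary
    warped = tform.apply(_boundary_points(sec_mask))
    edge_t = tmp_mask & ~ndimage.binary_erosion(tmp_mask)
    dist = ndimage.distance_transform_edt(~edge_t)
    rr = np.clip(np.round(warped[:, 0]).astype(int), 0, dist.shape[0] - 1)
    cc = np.clip(np.round(warped[:, 1]).astype(int), 0, dist.shape[1] - 1)
    residual = float(dist[rr, cc].mean())
    low_confidence = residual > residual_threshold_px
    if low_confidence:
        log.warning("registration residual %.2f px above threshold", residual)
    return tform, residual, low_confidence


def warp_to_template(image: np.ndarray, tform: SimilarityTransform,
                     template_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear warp onto the template grid; out-of-field pixels are NaN."""
    return tform.warp(image, output_shape=template_shape, order=1, fill=np.nan)


# ---------------------------------------------------------------------------
# normalization and averaging


def normalize_section(section: SectionImage, marker: str,
                      normalizer: str = "hemisphere_contra") -> np.ndarray:
    """Channel image divided by the median over the normalizer compartment."""
    img = section.channels[marker]
    mask = compartment_mask(section.labels, section.label_table, normalizer)
    med = float(np.median(img[mask]))
    if med <= 0:
        raise ValueError(f"non-positive normalizer median for {marker!r}")
    return img / med


def average_intensity_map(sections: Iterable[SectionImage], marker: str,
                          template: SectionImage,
                          normalize: bool = True,
                          register: bool = True) -> IntensityMap:
    """Per-pixel mean of registered, normalized sections of one group.

    NaN-aware: each template pixel averages only the sections whose
    field of view covers it; ``coverage`` counts contributors.
    """
    shape = template.labels.shape
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    n_sections = 0
    animals: set[str] = set()
    time_h: float | None = None
    genotype = ""
    for sec in sections:
        img = normalize_section(sec, marker) if normalize \
            else np.asarray(sec.channels[marker], dtype=float)
        if register:
            tform, _, _ = estimate_registration(sec, template)
            img = warp_to_template(img, tform, shape)
        ok = np.isfinite(img)
        total[ok] += img[ok]
        count += ok
        n_sections += 1
        animals.add(sec.animal)
        time_h = sec.time_h
        genotype = sec.genotype
    if n_sections == 0:
        raise ValueError("no sections supplied for averaging")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return IntensityMap(
        marker=marker, time_h=time_h, genotype=genotype, image=mean,
        coverage=count, n_sections=n_sections, n_animals=len(animals),
    )


def build_intensity_maps(sections: Iterable[SectionImage],
                         markers: Sequence[str],
                         template: SectionImage,
                         normalize: bool = True,
                         ) -> dict[tuple[str, float | None, str], IntensityMap]:
    """Streaming group-wise averaging over (marker, time, genotype).

    Registers each section once and accumulates every requested marker,
    so an arbitrarily large cohort is averaged in constant memory.
    """
    shape = template.labels.shape
    acc: dict[tuple, list] = {}
    for sec in sections:
        tform, _, _ = estimate_registration(sec, template)
        for marker in markers:
            if marker not in sec.channels:
                continue
            img = normalize_section(sec, marker) if normalize \
                else np.asarray(sec.channels[marker], dtype=float)
            img = warp_to_template(img, tform, shape)
            key = (marker, sec.time_h, sec.genotype)
            if key not in acc:
                acc[key] = [np.zeros(shape), np.zeros(shape, dtype=int),
                            0, set()]
            slot = acc[key]
            ok = np.isfinite(img)
            slot[0][ok] += img[ok]
            slot[1] += ok
            slot[2] += 1
            slot[3].add(sec.animal)
    out = {}
    for (marker, t, g), (total, count, n_sec, animals) in acc.items():
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        out[(marker, t, g)] = IntensityMap(
            marker=marker, time_h=t, genotype=g, image=mean,
            coverage=count, n_sections=n_sec, n_animals=len(animals),
        )
    return out


# ---------------------------------------------------------------------------
# leakage and compartment quantification


def quantify_leakage(image: np.ndarray, injection_site_px: tuple[float, float],
                     background_mask: np.ndarray, px_size_um: float,
                     k_sigma: float = 3.0, site_radius_um: float = 200.0,
                     ) -> tuple[float, float]:
    """Supra-threshold leakage area (mm^2) and its mean intensity.

    Threshold = background mean + ``k_sigma`` * background SD; the
    leakage is the union of 8-connected supra-threshold components that
    intersect a ``site_radius_um`` disc around the injection site.
    Returns (0.0, NaN) when no component reaches the site.
    """
    img = np.asarray(image, dtype=float)
    bg = img[background_mask]
    if bg.size == 0:
        raise ValueError("empty background mask")
    thr = bg.mean() + k_sigma * bg.std()
    supra = img > thr
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3), dtype=int))
    rr, cc = np.ogrid[0:img.shape[0], 0:img.shape[1]]
    r_px = site_radius_um / px_size_um
    disc = ((rr - injection_site_px[0]) ** 2
            + (cc - injection_site_px[1]) ** 2) <= r_px ** 2
    hit = np.unique(labels[disc & supra])
    hit = hit[hit > 0]
    if hit.size == 0:
        return 0.0, float("nan")
    leak = np.isin(labels, hit)
    area_mm2 = float(leak.sum()) * (px_size_um / 1000.0) ** 2
    return area_mm2, float(img[leak].mean())


def compartment_mean_intensity(section: SectionImage, marker: str,
                               compartments: Sequence[str],
                               normalize: bool = True) -> dict[str, float]:
    """Mean (normalized) intensity over each named compartment.

    Composite names (``CP``, ``hemisphere_ipsi``, ...) resolve to parcel
    unions; an empty compartment yields NaN with a logged warning.
    """
    img = normalize_section(section, marker) if normalize \
        else np.asarray(section.channels[marker], dtype=float)
    out: dict[str, float] = {}
    for comp in compartments:
        mask = compartment_mask(section.labels, section.label_table, comp)
        if not mask.any():
            log.warning("compartment %r is empty", comp)
            out[comp] = float("nan")
        else:
            out[comp] = float(img[mask].mean())
    return out
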
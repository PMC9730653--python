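"""Synthetic multichannel fluorescence sections with planted dynamics.

Each animal contributes a stack of 60-µm-spaced coronal sections whose
lesion cross-section shrinks away from the injection center.  Channel
intensities are built in the template frame (background + compartment
signal), jittered by a per-animal similarity transform (mimicking
mounting variability), and finished with Poisson shot noise plus
Gaussian read noise.

Planted dynamics follow the study conditions: dextran leakage is a
perilesional blob whose area and plateau intensity are biphasic with
peaks at 12 h and 48 h; CP dextran is highest at 2 h with
CP_ipsi > CP_third > CP_contra; CD45 peaks in the CP at 24 h while the
perilesional CD45 signal rises only from 48 h; ICAM1 peaks in the CP at
36 h; knockout and sham genotypes suppress the inflammatory CP signals
to near background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd

from ..datatypes import SectionImage
from ..histology import SimilarityTransform
from .layout import build_layout, parcel_labels
from .programs import KNOCKOUT_GENOTYPES, CohortDesign

SECTION_SPACING_UM = 60.0
STACK_START_UM = 300.0
LESION_CENTER_UM = 720.0
LESION_EXTENT_UM = 600.0

#: inflammatory CP signal left in knockouts and shams (fraction of wildtype)
SUPPRESSED_CP_FRACTION = 0.05
#: lesion-driven signal (leakage, perilesional infiltration) left in shams
SHAM_LESION_FRACTION = 0.05


def _bump(t: float, peak: float, width_log: float) -> float:
    z = (math.log(t) - math.log(peak)) / width_log
    return math.exp(-0.5 * z * z)


def leakage_area_factor(time_h: float) -> float:
    """Biphasic (12 h / 48 h) relative leakage area, plus the small acute
    mechanical component right after injection."""
    return (1.0 * _bump(time_h, 12.0, 0.35)
            + 1.1 * _bump(time_h, 48.0, 0.35)
            + 0.3 * _bump(time_h, 2.0, 0.5))


def leakage_intensity_factor(time_h: float) -> float:
    """Biphasic plateau intensity with an early (2-12 h) and a 48 h peak."""
    return (1.0 * _bump(time_h, 12.0, 0.5)
            + 0.9 * _bump(time_h, 48.0, 0.5)
            + 0.8 * _bump(time_h, 2.0, 0.6))


@dataclass
class ChannelModel:
    """Intensity model of one fluorescence channel (arbitrary units)."""

    name: str
    baseline_in: float = 120.0
    baseline_out: float = 20.0
    cp_amp: float = 0.0
    cp_peak_h: float | None = None
    cp_width: float = 0.5
    cp_side: tuple[float, float, float] = (1.0, 1.0, 1.0)  # ipsi, third, contra
    cp_inflammatory: bool = True  # suppressed in knockouts
    peri_amp: float = 0.0
    peri_peak_h: float | None = None
    peri_width: float = 0.5
    leakage: bool = False
    leak_radius_um: float = 600.0
    leak_intensity: float = 900.0
    leak_area_scale: float = 1.0
    read_sigma: float = 8.0

    def cp_signal(self, time_h: float | None) -> float:
        if self.cp_peak_h is None or time_h is None:
            return 0.0
        return self.cp_amp * _bump(time_h, self.cp_peak_h, self.cp_width)

    def peri_signal(self, time_h: float | None) -> float:
        if self.peri_peak_h is None or time_h is None:
            return 0.0
        return self.peri_amp * _bump(time_h, self.peri_peak_h, self.peri_width)


def _dextran(name: str, area_scale: float) -> ChannelModel:
    return ChannelModel(
        name=name, cp_amp=1000.0, cp_peak_h=2.0, cp_width=0.7,
        cp_side=(1.0, 0.7, 0.4), cp_inflammatory=False,
        leakage=True, leak_area_scale=area_scale,
    )


CHANNEL_MODELS: dict[str, ChannelModel] = {
    "dextran10": _dextran("dextran10", 1.2),
    "dextran70": _dextran("dextran70", 1.0),
    "dextran155": _dextran("dextran155", 0.8),
    "CD45": ChannelModel(
        name="CD45", cp_amp=900.0, cp_peak_h=24.0, cp_width=0.5,
        peri_amp=700.0, peri_peak_h=96.0, peri_width=0.45,
    ),
    "ICAM1": ChannelModel(
        name="ICAM1", cp_amp=1000.0, cp_peak_h=36.0, cp_width=0.5,
        peri_amp=150.0, peri_peak_h=96.0, peri_width=0.45,
    ),
    "F480": ChannelModel(
        name="F480", cp_amp=800.0, cp_peak_h=24.0, cp_width=0.5,
        peri_amp=400.0, peri_peak_h=96.0, peri_width=0.45,
    ),
    "Hoechst": ChannelModel(name="Hoechst", baseline_in=400.0),
}


def genotype_factors(genotype: str) -> tuple[float, float]:
    """(cp_inflammatory_factor, lesion_factor) for a genotype."""
    if genotype == "sham":
        return SUPPRESSED_CP_FRACTION, SHAM_LESION_FRACTION
    if genotype in KNOCKOUT_GENOTYPES:
        return SUPPRESSED_CP_FRACTION, 1.0
    return 1.0, 1.0


def section_positions_um(n_stack: int = 16) -> np.ndarray:
    return STACK_START_UM + SECTION_SPACING_UM * np.arange(n_stack)


def lesion_profile(position_um: float) -> float:
    """Relative lesion cross-section radius along the AP axis (0..1)."""
    z = (position_um - LESION_CENTER_UM) / LESION_EXTENT_UM
    return math.sqrt(max(0.0, 1.0 - z * z))


@lru_cache(maxsize=64)
def _section_template(size_px: int, px_size_um: float, lesion_scale_q: int):
    """Cached (layout, parcel labels, table) at a quantized lesion scale."""
    frac = 0.05 * lesion_scale_q / 1000.0
    layout = build_layout(size_px, px_size_um, lesion_radius_frac=frac)
    labels, table = parcel_labels(layout)
    return layout, labels, table


def template_section(size_px: int = 512, px_size_um: float = 20.0,
                     ) -> SectionImage:
    """Unjittered template section (labels only) used as the
    registration target and averaging grid."""
    _, labels, table = _section_template(size_px, px_size_um, 1000)
    return SectionImage(
        channels={}, labels=labels, label_table=table,
        px_size_um=px_size_um, section_position_um=LESION_CENTER_UM,
        animal="template", time_h=None, genotype="template",
    )


def _masks_for_signal(layout, labels, table):
    def mask(name):
        lab = table.loc[table["compartment"] == name, "label"].to_numpy()
        return np.isin(labels, lab)

    return {
        "cp_ipsi": mask("CP_ipsi"),
        "cp_third": mask("CP_third"),
        "cp_contra": mask("CP_contra"),
        "peri": mask("lesion") | mask("perilesional_STR"),
    }


def render_section(model: ChannelModel, time_h: float | None, genotype: str,
                   layout, labels, table, lesion_scale: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Noisy intensity image of one channel in the template frame."""
    g_cp, g_les = genotype_factors(genotype)
    cp_factor = g_cp if model.cp_inflammatory else g_les
    shape = layout.shape
    sig = np.full(shape, model.baseline_out)
    sig[layout.outline] = model.baseline_in

    masks = _masks_for_signal(layout, labels, table)
    cp_val = model.cp_signal(time_h) * cp_factor
    side = dict(zip(("cp_ipsi", "cp_third", "cp_contra"), model.cp_side))
    for key in ("cp_ipsi", "cp_third", "cp_contra"):
        sig[masks[key]] += cp_val * side[key]
    peri_val = model.peri_signal(time_h) * g_les
    sig[masks["peri"]] += peri_val

    truth = {"cp_signal": cp_val, "peri_signal": peri_val,
             "leak_radius_px": 0.0, "leak_area_mm2": 0.0,
             "leak_intensity": 0.0}
    if model.leakage and time_h is not None:
        area = leakage_area_factor(time_h) * model.leak_area_scale
        r_um = model.leak_radius_um * math.sqrt(area / 1.4) * lesion_scale
        r_px = r_um / layout.px_size_um
        inten = model.leak_intensity * leakage_intensity_factor(time_h) * g_les
        rr, cc = np.ogrid[0:shape[0], 0:shape[1]]
        cy, cx = layout.lesion_center_px
        blob = ((rr - cy) ** 2 + (cc - cx) ** 2) <= r_px ** 2
        blob &= layout.outline
        sig[blob] += inten
        truth.update(
            leak_radius_px=r_px,
            leak_area_mm2=float(blob.sum()) * (layout.px_size_um / 1000) ** 2,
            leak_intensity=inten,
        )
    img = rng.poisson(sig).astype(float)
    img += rng.normal(0.0, model.read_sigma, shape)
    return np.clip(img, 0.0, None), truth


def generate_section_cohort(design: CohortDesign,
                            channels: list[str],
                            size_px: int = 512,
                            px_size_um: float = 20.0,
                            n_stack: int = 16,
                            jitter: bool = True,
                            ) -> Iterator[SectionImage]:
    """Yield the sections of an imaging cohort, animal by animal.

    Each animal gets one similarity jitter (rotation within 10 degrees,
    translation within 8 px, scale within 5%) applied identically to
    every channel and to the label masks.  Deterministic given
    ``design.seed``.  Unknown channel names are rejected.
    """
    for ch in channels:
        if ch not in CHANNEL_MODELS:
            raise ValueError(f"unknown channel {ch!r}; "
                             f"known: {sorted(CHANNEL_MODELS)}")
    rng = np.random.default_rng(design.seed)
    positions = section_positions_um(n_stack)
    for sample_id, animal, time_h, genotype in design.samples():
        if jitter:
            rot = rng.uniform(-10, 10)
            shift = rng.uniform(-8, 8, size=2)
            scale = rng.uniform(0.95, 1.05)
        else:
            rot, shift, scale = 0.0, np.zeros(2), 1.0
        center = ((size_px - 1) / 2.0, (size_px - 1) / 2.0)
        tform = SimilarityTransform.from_params(
            rotation_deg=rot, scale=scale,
            translation_rc=tuple(shift), center_rc=center,
        )
        for pos in positions:
            lesion_scale = lesion_profile(pos)
            q = int(round(1000 * lesion_scale))
            layout, labels, table = _section_template(size_px, px_size_um, q)
            imgs: dict[str, np.ndarray] = {}
            truth: dict = {
                "sample_id": sample_id,
                "jitter_rotation_deg": rot,
                "jitter_scale": scale,
                "jitter_translation_rc": tuple(shift),
                "lesion_scale": lesion_scale,
            }
            for ch in channels:
                clean, ch_truth = render_section(
                    CHANNEL_MODELS[ch], time_h, genotype,
                    layout, labels, table, lesion_scale, rng,
                )
                if jitter:
                    warped = tform.warp(
                        clean, order=1, fill=CHANNEL_MODELS[ch].baseline_out
                    )
                else:
                    warped = clean
                imgs[ch] = warped.astype(np.float32)
                truth[ch] = ch_truth
            if jitter:
                wl = tform.warp(labels.astype(float), order=0, fill=0.0)
                out_labels = wl.astype(np.uint16)
            else:
                out_labels = labels
            yield SectionImage(
                channels=imgs, labels=out_labels, label_table=table.copy(),
                px_size_um=px_size_um, section_position_um=float(pos),
                animal=animal, time_h=time_h, genotype=genotype, truth=truth,
            )
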
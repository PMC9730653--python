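"""Temporal expression programs, the gene catalog, and cohort designs.

The planted structure mirrors the biology of striatal whole-blood
injection: an erythrocyte-transcript pulse (hemoglobin subunits, Alas2)
at 2 h wherever blood reaches (lesion, striatum, CP), an acute
choroid-plexus inflammatory wave spiking at 12 h (cytokines, interferon
response, adhesion molecules), a MyD88-dependent TLR-signaling program
in the CP peaking at 24 h, a delayed perilesional macrophage wave
peaking at 96 h, and a biphasic pan-leukocyte (Ptprc/CD45) program in
the CP with peaks at 24 h and 96 h.

Temporal kernels are Gaussian bumps in log-time; a biphasic program is
the sum of two bumps.  Fold changes are multiplicative on the baseline
relative expression and equal 1 at the no-injection control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datatypes import GeneSetCatalog
from .layout import DEEP_CONSTITUENTS, SCORING_REGIONS

ALLOWED_PEAKS = (2.0, 12.0, 24.0, 36.0, 48.0, 96.0)
KNOCKOUT_GENOTYPES = ("TLR4ko", "MyD88ko")
GENOTYPES = ("wildtype",) + KNOCKOUT_GENOTYPES + ("sham",)


@dataclass
class TemporalProgram:
    """A compartment-restricted multiplicative expression program.

    ``fold(t)`` = 1 + (amplitude-1) * exp(-(ln t - ln peak)^2 / (2 w^2)),
    plus an optional second bump for biphasic programs.  ``compartments``
    lists the region labels the program acts on; spots/pixels elsewhere
    are untouched.
    """

    name: str
    genes: list[str]
    compartments: tuple[str, ...]
    peak_time_h: float
    amplitude: float
    width_log: float = 0.45
    second_peak_time_h: float | None = None
    second_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 1:
            raise ValueError("amplitude must be >= 1")
        for peak in (self.peak_time_h, self.second_peak_time_h):
            if peak is not None and peak not in ALLOWED_PEAKS:
                raise ValueError(
                    f"peak time {peak} h not on the sampling grid {ALLOWED_PEAKS}"
                )
        if (self.second_peak_time_h is None) != (self.second_amplitude is None):
            raise ValueError("biphasic programs need both second peak and amplitude")

    def _bump(self, t: float, peak: float, amp: float) -> float:
        z = (math.log(t) - math.log(peak)) / self.width_log
        return (amp - 1.0) * math.exp(-0.5 * z * z)

    def fold(self, time_h: float | None) -> float:
        """Multiplicative fold at ``time_h`` (control time -> 1)."""
        if time_h is None or time_h <= 0:
            return 1.0
        f = 1.0 + self._bump(time_h, self.peak_time_h, self.amplitude)
        if self.second_peak_time_h is not None:
            f += self._bump(
                time_h, self.second_peak_time_h, self.second_amplitude
            )
        return f

    @property
    def is_cp_program(self) -> bool:
        """CP-restricted inflammatory programs; these are the ones the
        knockout genotypes suppress.  Programs that merely reach the CP
        (e.g. the erythrocyte pulse carried by the injected blood) are
        not knocked out."""
        return all(c == "CP" for c in self.compartments)


@dataclass
class CohortDesign:
    """Sampling design of a synthetic cohort.

    ``time_points_h`` uses ``None`` for the no-injection control.
    Knockout genotypes zero the CP-program amplitudes only; sham animals
    keep the lesion geometry but all injection-driven programs are off.
    """

    time_points_h: tuple[float | None, ...]
    animals_per_timepoint: int = 1
    genotypes: tuple[str, ...] = ("wildtype",)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.genotypes) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotypes: {sorted(unknown)}")

    def samples(self):
        """Yield (sample_id, animal, time_h, genotype) tuples."""
        i = 0
        for genotype in self.genotypes:
            for t in self.time_points_h:
                for a in range(self.animals_per_timepoint):
                    tag = "ctrl" if t is None else f"{t:g}h"
                    sid = f"{genotype}_{tag}_a{a}"
                    yield sid, f"animal_{i:03d}", t, genotype
                    i += 1


def program_fold(program: TemporalProgram, time_h: float | None,
                 genotype: str) -> float:
    """Fold of one program for a sample, honoring genotype suppression."""
    if genotype == "sham":
        return 1.0
    if genotype in KNOCKOUT_GENOTYPES and program.is_cp_program:
        return 1.0
    return program.fold(time_h)


# ---------------------------------------------------------------------------
# gene catalog

_REGION_MARKERS: dict[str, list[str]] = {
    "CTX": ["Slc17a7", "Cux2", "Satb2", "Mef2c", "Rorb", "Lamp5"],
    "STR": ["Ppp1r1b", "Pde10a", "Drd1", "Drd2", "Adora2a", "Gpr88"],
    "TH": ["Tcf7l2", "Ntng1", "Prkcd", "Plekhg1", "Ramp3", "Rora"],
    "CP": ["Ttr", "Folr1", "Clic6", "Kcnj13", "Otx2", "Prlr"],
    "PAL": ["Npas1", "Gbx1", "Elfn1", "Rab3b", "Magel2", "Slc6a1"],
    "HY": ["Hcrt", "Pmch", "Agrp", "Oxt", "Avp", "Gal"],
    "MB": ["Th", "Slc6a3", "Ddc", "En1", "Foxa2", "Pax5"],
    "P": ["Phox2b", "Dbh", "Tph2", "Chat", "Slc5a7", "Slc6a2"],
}

ERYTHROCYTE_GENES = ["Hba-a1", "Hbb-bs", "Hbb-bt", "Alas2"]
CP_WAVE_GENES = [
    "Icam1", "Vcam1", "Ccl20", "Cxcl10", "Ccl5",
    "Irf7", "Ifi27l2a", "Lcn2", "Serpina3n", "Bst2",
]
TLR_MYD88_GENES = [
    "Myd88", "Tirap", "Irak1", "Irak4", "Traf6",
    "Tlr2", "Tlr4", "Tlr5", "Tlr6", "Tlr9",
]
STR_WAVE_GENES = [
    "Cd68", "Lyz2", "Hmox1", "Ftl1", "Aif1", "Mpeg1", "Ctss", "Fcgr1",
]
LEUKOCYTE_GENES = ["Ptprc"]


def default_baseline(n_housekeeping: int = 120,
                     marker_fold: float = 10.0,
                     deep_fold: float = 5.0) -> pd.DataFrame:
    """Baseline relative-expression table: one row per gene.

    Columns: ``symbol``, ``baseline`` (relative weight), and one fold
    column per spot region label in {CTX, STR, TH, CP, DEEP, lesion}.
    Marker genes carry ``marker_fold`` in their own region; markers of
    the four deep-brain constituents all carry ``deep_fold`` in DEEP,
    which is what lets the clustering stage discover the composite
    deep-brain cluster.
    """
    spot_regions = ("CTX", "STR", "TH", "CP", "DEEP", "lesion")
    rows = []
    # baselines are spread over a realistic abundance range so that the
    # expression-binned control-gene sampling sees a continuous spectrum
    # (a flat baseline would put all markers into the same bins)
    marker_levels = (0.4, 0.7, 1.1, 0.5, 0.9, 1.4)

    def add(symbol: str, baseline: float, folds: dict[str, float]) -> None:
        row = {"symbol": symbol, "baseline": baseline}
        for r in spot_regions:
            row[r] = folds.get(r, 1.0)
        rows.append(row)

    for region, markers in _REGION_MARKERS.items():
        for j, g in enumerate(markers):
            if region in spot_regions:
                folds = {region: marker_fold}
                if region == "STR":
                    folds["lesion"] = marker_fold  # lesion lies in striatum
            else:  # deep-brain constituent
                folds = {"DEEP": deep_fold}
            add(g, marker_levels[j % len(marker_levels)], folds)

    for j, g in enumerate(ERYTHROCYTE_GENES + CP_WAVE_GENES
                          + TLR_MYD88_GENES + STR_WAVE_GENES
                          + LEUKOCYTE_GENES):
        add(g, float(np.round(0.6 + 0.25 * (j % 4), 2)), {})
    for i in range(n_housekeeping):
        # deterministic log-spaced abundance spectrum
        add(f"Hk{i:04d}",
            float(np.round(10 ** (-0.6 + 1.2 * i / max(n_housekeeping - 1, 1)),
                           3)),
            {})

    table = pd.DataFrame(rows)
    if table["symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in baseline table")
    return table


def default_programs() -> list[TemporalProgram]:
    """The planted study conditions (amplitudes are fold-changes)."""
    return [
        TemporalProgram(
            "erythrocyte_pulse", ERYTHROCYTE_GENES,
            ("STR", "lesion", "CP"), peak_time_h=2.0, amplitude=8.0,
            width_log=0.6,
        ),
        TemporalProgram(
            "cp_inflammatory_wave", CP_WAVE_GENES,
            ("CP",), peak_time_h=12.0, amplitude=6.0, width_log=0.5,
        ),
        TemporalProgram(
            "cp_tlr_myd88", TLR_MYD88_GENES,
            ("CP",), peak_time_h=24.0, amplitude=4.0, width_log=0.5,
        ),
        TemporalProgram(
            "perilesional_wave", STR_WAVE_GENES,
            ("STR", "lesion"), peak_time_h=96.0, amplitude=6.0, width_log=0.5,
        ),
        TemporalProgram(
            "cp_leukocyte_biphasic", LEUKOCYTE_GENES,
            ("CP",), peak_time_h=24.0, amplitude=4.0, width_log=0.4,
            second_peak_time_h=96.0, second_amplitude=5.0,
        ),
    ]


def default_gene_sets(universe: list[str] | None = None,
                      rng: np.random.Generator | None = None) -> GeneSetCatalog:
    """Anatomical marker sets, pathway sets, and decoys for enrichment.

    The anatomical sets cover the eight scoring regions.  The
    ``Toll-like receptor signaling pathway`` set unions the CP wave and
    TLR/MyD88 genes (as a KEGG-style pathway would); ``GO:0002755`` is
    the MyD88-dependent TLR signaling set used for the CP time course.
    Decoy sets of housekeeping genes give the enrichment stage a null.
    """
    baseline = default_baseline()
    if universe is None:
        universe = baseline["symbol"].tolist()
    sets: dict[str, list[str]] = {}
    for region in SCORING_REGIONS:
        sets[f"{region}_markers"] = list(_REGION_MARKERS[region])
    sets["Toll-like receptor signaling pathway"] = (
        CP_WAVE_GENES[:5] + TLR_MYD88_GENES
    )
    sets["GO:0002755 MyD88-dependent toll-like receptor signaling"] = list(
        TLR_MYD88_GENES
    )
    sets["Phagosome"] = STR_WAVE_GENES[:6]
    hk = [g for g in universe if g.startswith("Hk")]
    rng = rng or np.random.default_rng(2755)
    for i in range(4):
        pick = rng.choice(len(hk), size=12, replace=False)
        sets[f"Decoy pathway {i + 1}"] = [hk[j] for j in sorted(pick)]
    return GeneSetCatalog(sets=sets, universe=list(universe),
                          provenance="synthetic marker catalog")


def anatomical_set_names() -> dict[str, str]:
    """Map scoring-region label -> its anatomical gene-set name."""
    return {r: f"{r}_markers" for r in SCORING_REGIONS}


def default_spot_design(seed: int = 0) -> CohortDesign:
    """The transcriptomics cohort: control + five post-injection times."""
    return CohortDesign(
        time_points_h=(None, 2.0, 12.0, 24.0, 48.0, 96.0),
        animals_per_timepoint=1,
        genotypes=("wildtype",),
        seed=seed,
    )


def default_histology_design(seed: int = 0) -> CohortDesign:
    """Wildtype temporal histology cohort (36 h added for ICAM1)."""
    return CohortDesign(
        time_points_h=(2.0, 12.0, 24.0, 36.0, 48.0, 96.0),
        animals_per_timepoint=3,
        genotypes=("wildtype", "sham"),
        seed=seed,
    )


def default_knockout_design(genotype: str, seed: int = 0) -> CohortDesign:
    """Knockout series: sham / wildtype-blood / knockout-blood at 24 h."""
    return CohortDesign(
        time_points_h=(24.0,),
        animals_per_timepoint=6,
        genotypes=("sham", "wildtype", genotype),
        seed=seed,
    )
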
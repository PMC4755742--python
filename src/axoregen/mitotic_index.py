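"""Mitotic-index estimation from sectioned tissue.

Mitotic cells are counted in full physical cross-sections while the
proliferating (SOX2+PCNA+) denominator is counted in single optical
planes, so the denominator must be scaled to the section thickness:
N_P = N_PCNA · l_s / l_c with l_s the section thickness and l_c the mean
cell length along the AP axis.  Per-replicate errors use the standard
error of the mean with finite-population correction (the sections sampled
are a sizeable fraction of all sections in the region); the population
error combines the mean intra-replicate error and the inter-replicate
s.e.m. additively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SectionRecord",
    "CellGeometry",
    "RegionSpec",
    "ReplicateResult",
    "MitoticIndexResult",
    "proliferating_cells_per_section",
    "section_mitotic_index",
    "replicate_mitotic_index",
    "population_mitotic_index",
    "estimate_mitotic_index",
    "areal_mitotic_density",
]


@dataclass(frozen=True)
class SectionRecord:
    """Counts and geometry for one physical cross-section."""

    replicate: str
    section: str
    n_pcna: int  # SOX2+PCNA+ cells in one optical plane
    n_mitotic: int  # SOX2+PCNA+ mitotic cells in the full section
    section_thickness_um: float
    ap_position_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pcna < 0 or self.n_mitotic < 0:
            raise ValueError("counts must be nonnegative")
        if self.section_thickness_um <= 0:
            raise ValueError("section thickness must be positive")


@dataclass(frozen=True)
class CellGeometry:
    """Mean AP cell (nucleus) length per replicate, μm."""

    mean_cell_length_um: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mean_cell_length_um.values()):
            raise ValueError("cell lengths must be positive")

    def for_replicate(self, replicate: str) -> float:
        """Replicate's own mean length, or the pooled mean if absent
        (mean cell length is approximately equal across populations)."""
        if replicate in self.mean_cell_length_um:
            return self.mean_cell_length_um[replicate]
        return float(np.mean(list(self.mean_cell_length_um.values())))


@dataclass(frozen=True)
class RegionSpec:
    """AP bounds of the cell population under study, μm."""

    l_min: float
    l_max: float

    def __post_init__(self) -> None:
        if self.l_max <= self.l_min:
            raise ValueError("l_max must exceed l_min")

    def n_sections_total(self, section_thickness_um: float) -> int:
        """Total number of sections spanning the region, rounded to the
        nearest integer (non-integer ratios warn)."""
        raw = (self.l_max - self.l_min) / section_thickness_um
        if abs(raw - round(raw)) > 1e-9:
            warnings.warn(
                f"region length / section thickness = {raw:.3f} is not an "
                "integer; rounding to nearest",
                stacklevel=2,
            )
        return int(round(raw))

    def contains(self, ap_position_um: float) -> bool:
        return self.l_min <= ap_position_um <= self.l_max


@dataclass(frozen=True)
class ReplicateResult:
    replicate: str
    mi: float
    dmi: float
    n_sections: int
    n_sections_total: int
    n_excluded: int = 0
    single_section: bool = False


@dataclass(frozen=True)
class MitoticIndexResult:
    """Population mitotic index with the two-level (intra + inter) error."""

    mi: float
    dmi: float
    replicates: tuple[ReplicateResult, ...] = field(default=())
    single_replicate: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def proliferating_cells_per_section(
    n_pcna: int, section_thickness_um: float, cell_length_um: float
) -> float:
    """Estimated proliferating cells in a full section: N_PCNA · l_s / l_c."""
    if section_thickness_um <= 0 or cell_length_um <= 0:
        raise ValueError("geometry lengths must be positive")
    if n_pcna < 0:
        raise ValueError("count must be nonnegative")
    return n_pcna * section_thickness_um / cell_length_um


def section_mitotic_index(n_mitotic: int, n_proliferating: float) -> float:
    """Per-section mitotic index N_M / N_P.

    A section with no proliferating cells cannot form an index: with
    mitotic cells present that is an inconsistency (error); without, the
    section is simply uninformative and callers exclude it.
    """
    if n_proliferating < 0 or n_mitotic < 0:
        raise ValueError("counts must be nonnegative")
    if n_proliferating == 0:
        if n_mitotic > 0:
            raise ValueError("mitotic cells counted but no proliferating cells")
        raise ValueError("empty section: exclude rather than score")
    return n_mitotic / n_proliferating


def finite_population_sem(values: Sequence[float], n_total: int) -> float:
    """s.e.m. with finite-population correction:
    sqrt((N − n) / (N − 1)) · sd / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need >= 2 values for a standard error")
    if n > n_total:
        raise ValueError(f"sampled {n} sections but region only holds {n_total}")
    if n_total == 1:
        return 0.0
    fpc = math.sqrt((n_total - n) / (n_total - 1))
    return fpc * float(arr.std(ddof=1)) / math.sqrt(n)


def replicate_mitotic_index(
    sections: Sequence[SectionRecord],
    region: RegionSpec,
    geometry: CellGeometry,
) -> ReplicateResult:
    """Mean per-section mitotic index of one replicate with its
    finite-population-corrected s.e.m.

    Sections outside the region bounds or with zero proliferating count
    are excluded (the latter logged in ``n_excluded``).
    """
    if not sections:
        raise ValueError("no sections supplied")
    reps = {s.replicate for s in sections}
    if len(reps) != 1:
        raise ValueError(f"sections from multiple replicates: {sorted(reps)}")
    replicate = next(iter(reps))
    l_c = geometry.for_replicate(replicate)

    in_region = [s for s in sections if region.contains(s.ap_position_um)]
    if not in_region:
        raise ValueError("no sections inside the region bounds")
    thicknesses = {s.section_thickness_um for s in in_region}
    if len(thicknesses) != 1:
        raise ValueError("sections must share one thickness within a replicate")
    l_s = next(iter(thicknesses))

    mis, excluded = [], 0
    for s in in_region:
        n_p = proliferating_cells_per_section(s.n_pcna, l_s, l_c)
        if n_p == 0:
            if s.n_mitotic > 0:
                raise ValueError(
                    f"section {s.section}: mitotic cells but zero PCNA count"
                )
            excluded += 1
            continue
        mis.append(section_mitotic_index(s.n_mitotic, n_p))
    if not mis:
        raise ValueError("all sections excluded (zero proliferating counts)")

    ns_total = region.n_sections_total(l_s)
    ns = len(mis)
    if ns > ns_total:
        raise ValueError(f"{ns} usable sections exceed region capacity {ns_total}")
    if ns == 1:
        return ReplicateResult(
            replicate, float(mis[0]), float("nan"), 1, ns_total, excluded, True
        )
    dmi = finite_population_sem(mis, ns_total)
    return ReplicateResult(
        replicate, float(np.mean(mis)), dmi, ns, ns_total, excluded
    )


def population_mitotic_index(
    replicates: Sequence[ReplicateResult],
) -> MitoticIndexResult:
    """Combine replicates: mi = mean over replicates; the 1σ error adds
    the mean intra-replicate error and the inter-replicate s.e.m.
    (additive combination as published; see ``quadrature=`` on
    :func:`estimate_mitotic_index` for the conventional alternative)."""
    return _combine_replicates(replicates, quadrature=False)


def _combine_replicates(
    replicates: Sequence[ReplicateResult], quadrature: bool
) -> MitoticIndexResult:
    if not replicates:
        raise ValueError("no replicates supplied")
    mis = np.array([r.mi for r in replicates], dtype=float)
    intra = np.array([r.dmi for r in replicates], dtype=float)
    n = mis.size
    if n == 1:
        r = replicates[0]
        return MitoticIndexResult(
            mi=float(mis[0]),
            dmi=float(r.dmi),
            replicates=tuple(replicates),
            single_replicate=True,
        )
    mean_intra = float(np.nanmean(intra))
    inter = float(mis.std(ddof=1)) / math.sqrt(n)
    if quadrature:
        dmi = math.sqrt(mean_intra**2 + inter**2)
    else:
        dmi = mean_intra + inter
    return MitoticIndexResult(
        mi=float(mis.mean()), dmi=dmi, replicates=tuple(replicates)
    )


def estimate_mitotic_index(
    sections: pd.DataFrame | Sequence[SectionRecord],
    region: RegionSpec,
    geometry: CellGeometry,
    quadrature: bool = False,
) -> MitoticIndexResult:
    """Full estimator: per-replicate indices then the population combine.

    Accepts a DataFrame with columns replicate, section, ap_position_um,
    n_pcna, n_mitotic, section_thickness_um, or a sequence of
    :class:`SectionRecord`.  ``quadrature=True`` combines intra- and
    inter-replicate errors in quadrature instead of additively
    (sensitivity analysis only).
    """
    if isinstance(sections, pd.DataFrame):
        records = [
            SectionRecord(
                replicate=str(row["replicate"]),
                section=str(row["section"]),
                n_pcna=int(row["n_pcna"]),
                n_mitotic=int(row["n_mitotic"]),
                section_thickness_um=float(row["section_thickness_um"]),
                ap_position_um=float(row.get("ap_position_um", 0.0)),
            )
            for _, row in sections.iterrows()
        ]
    else:
        records = list(sections)
    by_rep: dict[str, list[SectionRecord]] = {}
    for rec in records:
        by_rep.setdefault(rec.replicate, []).append(rec)
    rep_results = [
        replicate_mitotic_index(recs, region, geometry)
        for _, recs in sorted(by_rep.items())
    ]
    return _combine_replicates(rep_results, quadrature=quadrature)


def areal_mitotic_density(ph3_count: int, area_um2: float) -> float:
    """PH3+ cells per μm² from whole-mount maximum-intensity projections."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if ph3_count < 0:
        raise ValueError("count must be nonnegative")
    return ph3_count / area_um2
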
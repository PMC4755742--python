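"""Mitotic-spindle orientation and cleavage-plane statistics.

Division orientation is read out as the absolute projection of the unit
spindle vector on the unit anterior-posterior (AP) axis vector,
Proj = |S · AP| ∈ [0, 1] (1 = division parallel to the axis).  For
uniformly random 3D orientations |cos θ| is exactly Uniform(0, 1), so a
region's divisions are called oriented when the mean projection of its N
cells exceeds 0.5 + 1.96/sqrt(12 N) — a one-sided normal test at level
0.025 against that uniform null (sd of Uniform(0,1) is 1/sqrt(12)).

Cleavage planes are analysed in 2D longitudinal sections: the cleavage
direction is the spindle rotated 90° in the section plane, and the
reported angle is the acute angle between it and the apical surface,
folded to [0, 90]° (90° = "vertical" cleavage, associated with symmetric
proliferative divisions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_stats import mann_whitney_u

__all__ = [
    "SpindleMeasurement",
    "ProjectionRecord",
    "OrientationTestResult",
    "CleavageMeasurement",
    "spindle_projection",
    "assign_zone",
    "orientation_test",
    "orientation_threshold",
    "cleavage_angle",
    "compare_angle_distributions",
    "projections_from_coordinates",
    "projections_from_dataframe",
]


@dataclass(frozen=True)
class SpindleMeasurement:
    """3D spindle-pole and AP-axis coordinates for one mitotic cell (μm).

    A, B are the spindle poles; C, D lie in the middle of the central
    canal in the first and last optical section of the cell's z-stack,
    so each measurement carries its own AP axis.  ``ap_position_um`` is
    the cell's position relative to the amputation plane (negative =
    anterior).
    """

    cell_id: str
    group: str
    day: int
    A: tuple[float, float, float]
    B: tuple[float, float, float]
    C: tuple[float, float, float]
    D: tuple[float, float, float]
    ap_position_um: float = 0.0

    def __post_init__(self) -> None:
        if np.allclose(self.A, self.B):
            raise ValueError("spindle poles A and B coincide")
        if np.allclose(self.C, self.D):
            raise ValueError("axis points C and D coincide")


@dataclass(frozen=True)
class ProjectionRecord:
    cell_id: str
    projection: float
    in_zone: bool | None = None


@dataclass(frozen=True)
class OrientationTestResult:
    """Outcome of the orientation uniformity test for one cell group."""

    n: int
    mean_projection: float
    threshold: float
    oriented: bool
    level: float = 0.025


def spindle_projection(m: SpindleMeasurement) -> ProjectionRecord:
    """Absolute projection of the unit spindle vector on the unit AP axis.

    The absolute value folds the arbitrary pole/axis labelling: Proj is
    invariant to swapping A with B or C with D.
    """
    S = np.asarray(m.B, dtype=float) - np.asarray(m.A, dtype=float)
    AP = np.asarray(m.D, dtype=float) - np.asarray(m.C, dtype=float)
    S = S / np.linalg.norm(S)
    AP = AP / np.linalg.norm(AP)
    proj = float(abs(np.dot(S, AP)))
    return ProjectionRecord(cell_id=m.cell_id, projection=min(proj, 1.0))


def assign_zone(ap_position_um: float, zone_bounds: tuple[float, float]) -> bool:
    """True if the position falls inside the closed interval
    [l_min, l_max] (boundary ties count as inside)."""
    l_min, l_max = zone_bounds
    if l_max < l_min:
        raise ValueError("zone bounds must be ordered (l_min, l_max)")
    return l_min <= ap_position_um <= l_max


def orientation_threshold(n: int) -> float:
    """Critical mean projection 0.5 + 1.96/sqrt(12 N) for N cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 0.5 + 1.96 / math.sqrt(12 * n)


def orientation_test(projections: Sequence[float]) -> OrientationTestResult:
    """One-sided test of AP-oriented division against the uniform null.

    Under random orientation Proj ~ Uniform(0, 1); the sample mean of N
    draws lies below 0.5 + 1.96·(1/sqrt(12))/sqrt(N) with probability
    0.975 (normal approximation; no small-N exact correction).
    """
    arr = np.asarray(projections, dtype=float)
    if arr.size == 0:
        raise ValueError("empty projection sample")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("projections must lie in [0, 1]")
    n = int(arr.size)
    thr = orientation_threshold(n)
    mean = float(arr.mean())
    return OrientationTestResult(
        n=n, mean_projection=mean, threshold=thr, oriented=mean > thr
    )


@dataclass(frozen=True)
class CleavageMeasurement:
    """2D spindle and apical-surface segments from a longitudinal section."""

    cell_id: str
    group: str
    spindle: tuple[tuple[float, float], tuple[float, float]]
    apical: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if np.allclose(self.spindle[0], self.spindle[1]):
            raise ValueError("degenerate spindle segment")
        if np.allclose(self.apical[0], self.apical[1]):
            raise ValueError("degenerate apical segment")


def _acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Acute (line-line) angle between two 2D directions, degrees."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = abs(float(np.dot(u, v)))
    return math.degrees(math.acos(min(c, 1.0)))


def cleavage_angle(m: CleavageMeasurement) -> float:
    """Angle in [0, 90]° between the cleavage plane and the apical surface.

    The cleavage plane lies orthogonal to the spindle; in the 2D section
    its trace is the spindle direction rotated by 90°, so the cleavage
    angle and the spindle-apical angle are complementary.
    """
    s = np.asarray(m.spindle[1], dtype=float) - np.asarray(m.spindle[0], dtype=float)
    a = np.asarray(m.apical[1], dtype=float) - np.asarray(m.apical[0], dtype=float)
    cleave = np.array([-s[1], s[0]])  # 90° rotation in the section plane
    return _acute_angle_deg(cleave, a)


@dataclass(frozen=True)
class AngleGroupSummary:
    n: int
    median: float
    iqr: float
    sd: float


@dataclass(frozen=True)
class AngleComparison:
    u_statistic: float
    p_value: float
    group_a: AngleGroupSummary
    group_b: AngleGroupSummary


def _summarize_angles(angles: np.ndarray) -> AngleGroupSummary:
    q75, q25 = np.percentile(angles, [75, 25])
    sd = float(angles.std(ddof=1)) if angles.size > 1 else 0.0
    return AngleGroupSummary(
        n=int(angles.size), median=float(np.median(angles)), iqr=float(q75 - q25), sd=sd
    )


def compare_angle_distributions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> AngleComparison:
    """Mann-Whitney U comparison of two cleavage-angle distributions,
    with per-group dispersion summaries (median, IQR, s.d.)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    u, p = mann_whitney_u(a, b)
    return AngleComparison(
        u_statistic=u,
        p_value=p,
        group_a=_summarize_angles(a),
        group_b=_summarize_angles(b),
    )


_COORD_COLS = [
    "ax", "ay", "az", "bx", "by", "bz", "cx", "cy", "cz", "dx", "dy", "dz",
]


def projections_from_coordinates(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, D: np.ndarray
) -> np.ndarray:
    """Vectorized |S·AP| for stacked (n, 3) pole/axis coordinate arrays."""
    S = np.asarray(B, float) - np.asarray(A, float)
    AP = np.asarray(D, float) - np.asarray(C, float)
    ns = np.linalg.norm(S, axis=1)
    na = np.linalg.norm(AP, axis=1)
    if np.any(ns == 0) or np.any(na == 0):
        raise ValueError("coincident pole or axis points")
    proj = np.abs(np.einsum("ij,ij->i", S / ns[:, None], AP / na[:, None]))
    return np.minimum(proj, 1.0)


def projections_from_dataframe(
    df: pd.DataFrame, zone_bounds: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Compute per-cell projections (and optional zone flags) from a table
    with columns cell_id, group, day, ax..dz, ap_position_um."""
    missing = [c for c in ["cell_id", *_COORD_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    coords = df[_COORD_COLS].to_numpy(dtype=float)
    proj = projections_from_coordinates(
        coords[:, 0:3], coords[:, 3:6], coords[:, 6:9], coords[:, 9:12]
    )
    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"].astype(str).values,
            "group": df["group"].astype(str).values if "group" in df else "",
            "day": df["day"].astype(int).values if "day" in df else 0,
            "projection": proj,
            "ap_position_um": (
                df["ap_position_um"].astype(float).values
                if "ap_position_um" in df
                else 0.0
            ),
        }
    )
    if zone_bounds is not None:
        out["in_zone"] = [
            assign_zone(p, zone_bounds) for p in out["ap_position_um"]
        ]
    return out
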
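"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: cumulative
labeling timecourses from an agent-based cell-population simulator,
spindle-orientation coordinate tables (uniform or axially concentrated),
nCounter-style count matrices with spike-in controls, and per-section
count tables for the mitotic-index estimator.

The labeling simulator doubles as the brute-force oracle for the
closed-form labeling curve.  Because the model assumes fixed phase
lengths for every cell, the two daughters of a division are born
simultaneously at age 0 and an entire clone stays perfectly synchronised
forever; the simulator therefore evolves each founder's clone exactly
(division count, shared age, shared label status are deterministic given
the founder's initial age) instead of time-stepping individual agents.
This is the same stochastic process an event-driven simulation realises,
computed without discretisation error, and is fast enough for
100,000-founder oracle runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import nbinom as nbinom_dist

from .cell_cycle import CellCycleParams, LabelingTimecourse
from .mitotic_index import RegionSpec, SectionRecord
from .nanostring import CountMatrix

__all__ = [
    "SimConfig",
    "simulate_labeling_experiment",
    "labeled_fraction_oracle",
    "sample_spindle_orientations",
    "kappa_for_mean_projection",
    "simulate_nanostring_counts",
    "simulate_section_counts",
]


# ---------------------------------------------------------------------------
# agent-based labeling simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated cumulative-labeling experiment.

    Parameters
    ----------
    params : CellCycleParams
        Ground-truth cell-cycle parameters.
    sampling_times : tuple of float
        Hours since labeling onset at which the labeled fraction is read.
    n_cells : int
        Founder cells for oracle-mode runs (one large population).
    n_replicates, cells_per_replicate : int
        If ``n_replicates`` >= 2, each timepoint is instead measured on
        that many independent small populations (animals), and the
        timecourse carries their mean and s.d. — the design of a real
        experiment with ~5 animals per timepoint.
    seed : int
        Seed for all randomness; recorded in the truth record.
    """

    params: CellCycleParams
    sampling_times: tuple[float, ...]
    n_cells: int = 100_000
    n_replicates: int = 0
    cells_per_replicate: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sampling_times) == 0:
            raise ValueError("need at least one sampling time")
        if any(t < 0 for t in self.sampling_times):
            raise ValueError("sampling times must be >= 0")
        if self.n_cells < 1:
            raise ValueError("population must be positive")


def _sample_steady_state_ages(
    rng: np.random.Generator, n: int, T_C: float, r: float, stratified: bool = False
) -> np.ndarray:
    """Ages at labeling onset from the steady-state age density.

    Exponentially growing populations are enriched for young cells:
    density ∝ r^(−a/T_C) on [0, T_C); uniform when r = 1.

    ``stratified`` draws one age per equal-probability stratum of the
    inverse CDF (jittered within strata) — a variance-reduction scheme
    for oracle runs that leaves the marginal distribution exact while
    shrinking the Monte-Carlo error of population averages from
    O(1/sqrt(n)) to O(1/n).
    """
    if stratified:
        u = (np.arange(n) + rng.random(n)) / n
        u = rng.permutation(u)
    else:
        u = rng.random(n)
    if r == 1:
        return u * T_C
    # inverse CDF of c * r^(-a/T_C): F(a) = (1 - r^(-a/T_C)) / (1 - 1/r)
    return -T_C * np.log(1.0 - u * (1.0 - 1.0 / r)) / np.log(r)


def _simulate_population(
    rng: np.random.Generator,
    params: CellCycleParams,
    n_cells: int,
    times: np.ndarray,
    stratified: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled and counted totals at each sampling time.

    Counting rule: quiescent cells count (unlabeled); for r = 1 the
    newborn postmitotic daughter is excluded from numerator and
    denominator (its rounded, neuronal nucleus is not scored), so the
    counted pool is constant; for r = 2 every descendant counts.

    ``stratified`` (oracle runs) stratifies the age draw and fixes the
    proliferative founder count at round(GF·n) instead of Bernoulli
    draws, so the recorded fractions estimate the model mean with far
    sub-binomial Monte-Carlo error.
    """
    p = params
    if stratified:
        n_prolif = int(round(p.GF * n_cells))
    else:
        n_prolif = int((rng.random(n_cells) < p.GF).sum())
    n_quiescent = n_cells - n_prolif
    ages = _sample_steady_state_ages(rng, n_prolif, p.T_C, p.r, stratified=stratified)

    # hours until the founder clone first transits S under the label
    in_s = (ages >= p.T_G1) & (ages < p.T_G1 + p.T_S)
    t_to_s = np.where(in_s, 0.0, (p.T_G1 - ages) % p.T_C)

    labeled = np.empty_like(times)
    counted = np.empty_like(times)
    for j, t in enumerate(times):
        if p.r == 1:
            w = np.ones_like(ages)
        else:
            divisions = np.floor((ages + t) / p.T_C)
            w = p.r**divisions
        lab = w[t_to_s <= t].sum()
        tot = w.sum() + n_quiescent
        labeled[j] = lab
        counted[j] = tot
    return labeled, counted


def simulate_labeling_experiment(
    config: SimConfig,
) -> tuple[LabelingTimecourse, dict]:
    """Simulate a cumulative-labeling experiment.

    Returns the timecourse (population label ``synthetic``) and a truth
    record with the generating parameters, seed, and per-time counted
    population sizes.  In oracle mode (``n_replicates`` < 2) the sd
    column holds the binomial standard error of the recorded fraction;
    in replicate mode it is the empirical s.d. across replicates.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sampling_times, dtype=float)
    p = config.params

    if config.n_replicates >= 2:
        # cross-sectional design: every timepoint is measured on its own
        # set of animals (harvesting is destructive), so readings are
        # independent across timepoints
        mean = np.empty(times.size)
        sd = np.empty(times.size)
        counted = np.zeros(times.size)
        for j, t in enumerate(times):
            fracs = np.empty(config.n_replicates)
            for i in range(config.n_replicates):
                lab, tot = _simulate_population(
                    rng, p, config.cells_per_replicate, np.array([t])
                )
                fracs[i] = lab[0] / tot[0]
                counted[j] += tot[0]
            mean[j] = fracs.mean()
            # sigma of the recorded value (the replicate mean): s.d./sqrt(n)
            sd[j] = fracs.std(ddof=1) / np.sqrt(config.n_replicates)
        # a sigma of exactly 0 (all replicates identical) cannot weight a fit
        sd = np.maximum(sd, 1e-4)
        n_animals = (config.n_replicates,) * times.size
    else:
        lab, counted = _simulate_population(rng, p, config.n_cells, times)
        mean = lab / counted
        sd = np.sqrt(np.maximum(mean * (1 - mean), 1e-12) / counted)
        sd = np.maximum(sd, 1e-6)
        n_animals = (1,) * times.size

    timecourse = LabelingTimecourse(
        population="synthetic",
        time_h=tuple(times.tolist()),
        fraction=tuple(np.clip(mean, 0, 1).tolist()),
        sd=tuple(sd.tolist()),
        n_animals=n_animals,
    )
    truth = {
        "params": p.as_dict(),
        "seed": config.seed,
        "counted": counted.tolist(),
        "mode": "replicates" if config.n_replicates >= 2 else "oracle",
    }
    return timecourse, truth


def labeled_fraction_oracle(
    params: CellCycleParams,
    times: Sequence[float],
    n_cells: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated labeled fractions and counted population sizes — the
    brute-force check of the closed-form curve R(t) = g(t) R'(t).

    Uses the stratified (variance-reduced) sampler: the returned
    fractions carry Monte-Carlo error well below the binomial standard
    error of an equally sized count."""
    rng = np.random.default_rng(seed)
    lab, tot = _simulate_population(
        rng, params, n_cells, np.asarray(times, float), stratified=True
    )
    return lab / tot, tot


# ---------------------------------------------------------------------------
# spindle orientations
# ---------------------------------------------------------------------------


def _sample_watson_axial(
    rng: np.random.Generator, n: int, kappa: float, axis: np.ndarray
) -> np.ndarray:
    """Unit vectors from an axially symmetric Watson-type density
    ∝ exp(κ (u·axis)²); κ = 0 is the uniform sphere."""
    if kappa == 0:
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    cos = np.empty(n)
    have = 0
    while have < n:  # rejection with envelope at |c| = 1
        m = max(2 * (n - have), 64)
        c = rng.uniform(-1, 1, m)
        acc = rng.random(m) < np.exp(kappa * (c**2 - 1.0))
        got = c[acc][: n - have]
        cos[have : have + got.size] = got
        have += got.size
    phi = rng.uniform(0, 2 * np.pi, n)
    sin = np.sqrt(np.maximum(1 - cos**2, 0))
    local = np.column_stack([sin * np.cos(phi), sin * np.sin(phi), cos])
    # rotate local z onto the requested axis
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(axis, z):
        return local
    if np.allclose(axis, -z):
        return -local
    v = np.cross(z, axis)
    s, c0 = np.linalg.norm(v), float(np.dot(z, axis))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c0) / s**2)
    return local @ R.T


def sample_spindle_orientations(
    n: int,
    kappa: float = 0.0,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    seed: int = 0,
    group: str = "synthetic",
    day: int = 0,
    spindle_length_um: float = 8.0,
    ap_position_range: tuple[float, float] = (0.0, 500.0),
) -> pd.DataFrame:
    """Synthetic spindle/axis coordinate table for ``n`` mitotic cells.

    κ = 0 gives directions uniform on the sphere, so the projection
    statistic is exactly Uniform(0, 1); κ > 0 concentrates spindles
    axially around ``axis``.  Output columns match the orientation
    reader: cell_id, group, day, ax..dz, ap_position_um.  Pole pairs are
    randomly translated; each cell carries its own AP-axis points C, D.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    dirs = _sample_watson_axial(rng, n, kappa, axis)
    centers = rng.uniform(0, 200, (n, 3))
    half = dirs * (spindle_length_um / 2.0)
    A = centers - half
    B = centers + half
    C = rng.uniform(0, 50, (n, 3))
    D = C + axis / np.linalg.norm(axis) * 20.0
    ap = rng.uniform(*ap_position_range, n)
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n)],
            "group": group,
            "day": day,
            "ax": A[:, 0], "ay": A[:, 1], "az": A[:, 2],
            "bx": B[:, 0], "by": B[:, 1], "bz": B[:, 2],
            "cx": C[:, 0], "cy": C[:, 1], "cz": C[:, 2],
            "dx": D[:, 0], "dy": D[:, 1], "dz": D[:, 2],
            "ap_position_um": ap,
        }
    )


def _watson_mean_abs_cos(kappa: float) -> float:
    if kappa == 0:
        return 0.5
    num = (np.exp(kappa) - 1.0) / (2.0 * kappa)
    den, _ = quad(lambda c: np.exp(kappa * c * c), 0.0, 1.0)
    return num / den


def kappa_for_mean_projection(target_mean: float) -> float:
    """Concentration κ whose Watson-type axial law has the requested mean
    absolute projection (numeric inversion; target in (0.5, 1))."""
    if not (0.5 < target_mean < 1.0):
        raise ValueError("target mean must lie in (0.5, 1)")
    return float(brentq(lambda k: _watson_mean_abs_cos(k) - target_mean, 1e-9, 700.0))


# ---------------------------------------------------------------------------
# nCounter-style count matrices
# ---------------------------------------------------------------------------


def _nb_draws(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = m + α m²)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return nbinom_dist.rvs(size, p, random_state=rng)


def simulate_nanostring_counts(
    n_genes: int = 100,
    n_true_de: int = 20,
    log2fc: float = 2.0,
    dispersion: float = 0.05,
    group_sizes: tuple[int, int] = (3, 3),
    group_names: tuple[str, str] = ("day0", "day6"),
    n_negative: int = 8,
    background_mean: float = 12.0,
    housekeeping_mean: float = 2000.0,
    sample_factor_sd: float = 0.15,
    baseline_range: tuple[float, float] = (50.0, 5000.0),
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """Synthetic nCounter run with spike-in controls and known DE truth.

    Endogenous genes draw NB counts around log-uniform baseline means;
    the first ``n_true_de`` genes change by ±``log2fc`` in the second
    group (alternating up/down).  Six positive probes sit at the standard
    titration means, negatives are Poisson background, the housekeeping
    probe has a constant mean, and every sample carries a log-normal
    scale factor (hybridization efficiency) the normalization chain must
    undo.  The truth record lists DE genes with their directions.
    """
    if min(group_sizes) < 2:
        raise ValueError("need >= 2 samples per group")
    if n_true_de > n_genes:
        raise ValueError("n_true_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_a, n_b = group_sizes
    n_samples = n_a + n_b
    samples = [f"{group_names[0]}_{i+1}" for i in range(n_a)] + [
        f"{group_names[1]}_{i+1}" for i in range(n_b)
    ]
    groups = {s: (group_names[0] if i < n_a else group_names[1]) for i, s in enumerate(samples)}
    factors = np.exp(rng.normal(0.0, sample_factor_sd, n_samples))

    genes = [f"gene{i:04d}" for i in range(n_genes)]
    base = np.exp(
        rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]), n_genes)
    )
    direction = np.zeros(n_genes)  # +1 up in group B, -1 down, 0 null
    direction[:n_true_de] = np.where(np.arange(n_true_de) % 2 == 0, 1.0, -1.0)

    rows = {}
    for g_idx, gene in enumerate(genes):
        mean_a = base[g_idx]
        mean_b = base[g_idx] * 2.0 ** (log2fc * direction[g_idx])
        means = np.concatenate([np.full(n_a, mean_a), np.full(n_b, mean_b)]) * factors
        rows[gene] = _nb_draws(rng, means, dispersion)

    pos_means = np.array([128.0, 32.0, 8.0, 2.0, 0.5, 0.125]) * 100.0
    for i, m in enumerate(pos_means):
        rows[f"POS_{chr(65 + i)}"] = rng.poisson(m * factors)
    for i in range(n_negative):
        rows[f"NEG_{chr(65 + i)}"] = rng.poisson(background_mean, n_samples)
    rows["Rpl4"] = _nb_draws(rng, housekeeping_mean * factors, dispersion / 2)

    counts = pd.DataFrame(rows, index=samples).T.astype(float)
    probe_class = pd.Series(
        {
            **{g: "endogenous" for g in genes},
            **{f"POS_{chr(65 + i)}": "positive" for i in range(6)},
            **{f"NEG_{chr(65 + i)}": "negative" for i in range(n_negative)},
            "Rpl4": "housekeeping",
        }
    ).reindex(counts.index)
    truth = {
        "seed": seed,
        "de_genes": {
            genes[i]: ("up" if direction[i] > 0 else "down")
            for i in range(n_true_de)
        },
        "log2fc": log2fc,
        "dispersion": dispersion,
        "sample_factors": dict(zip(samples, factors.tolist())),
    }
    return CountMatrix(counts=counts, probe_class=probe_class, groups=groups), truth


# ---------------------------------------------------------------------------
# section counts
# ---------------------------------------------------------------------------


def simulate_section_counts(
    true_mi: float,
    n_sections: int = 8,
    cells_per_section: float = 40.0,
    l_s: float = 50.0,
    l_c: float = 12.5,
    region: RegionSpec | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[SectionRecord]:
    """Per-section counts with a known true mitotic fraction.

    The optical-plane PCNA count is Poisson with mean
    ``cells_per_section · l_c / l_s`` (the geometric thinning the
    estimator inverts); the full-section mitotic count is Binomial over
    the implied proliferating cells at rate ``true_mi``.  Sections are
    spread evenly across the region, mirroring the practice of scoring
    non-consecutive sections (so ``n_sections`` may be smaller than the
    number of sections the region holds).
    """
    if not (0 <= true_mi <= 1):
        raise ValueError("true_mi must lie in [0, 1]")
    if region is None:
        region = RegionSpec(0.0, n_sections * l_s)
    rng = np.random.default_rng(seed)
    span = region.l_max - region.l_min
    records: list[SectionRecord] = []
    for rep in range(n_replicates):
        for k in range(n_sections):
            pos = region.l_min + (k + 0.5) * span / n_sections
            n_pcna = int(rng.poisson(cells_per_section * l_c / l_s))
            n_p = int(round(n_pcna * l_s / l_c))
            n_m = int(rng.binomial(n_p, true_mi)) if n_p > 0 else 0
            records.append(
                SectionRecord(
                    replicate=f"rep{rep + 1}",
                    section=f"rep{rep + 1}_s{k + 1}",
                    n_pcna=n_pcna,
                    n_mitotic=n_m,
                    section_thickness_um=l_s,
                    ap_position_um=pos,
                )
            )
    return records
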
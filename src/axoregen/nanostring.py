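"""nCounter count normalization, NB differential expression, concordance.

The normalization chain follows standard nCounter practice: (1) scale
each sample by the geometric mean of its spike-in positive-control
probes; (2) call each gene present/absent by a one-tailed Student's
t-test against the negative-control probes, blanketing absent genes to
1; (3) subtract the negative-control background (mean + 3 s.d.),
flooring at 1; (4) scale to the housekeeping probe to correct for input
material.  Differential expression then uses a two-group negative-
binomial exact conditional test (the classic exact-test style: per-gene
method-of-moments dispersions shrunk toward a parametric mean-dispersion
trend, p from outcomes as or more extreme conditional on the two-group
total), with Benjamini-Hochberg adjustment.

The concordance analysis scores a developmental reference gene set (genes
high or low in the embryonic stem zone + pre-neural tube relative to the
neural tube) against regeneration DE calls, and tests the association by
Fisher's exact test.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .core_stats import (
    ContingencyTable2x2,
    bh_adjust,
    fisher_exact_2x2,
    geometric_mean,
    one_tailed_t_test,
)

__all__ = [
    "CountMatrix",
    "DEResult",
    "ChickReference",
    "ConcordanceResult",
    "positive_control_normalize",
    "detection_call",
    "background_subtract",
    "housekeeping_normalize",
    "normalize",
    "nb_differential_test",
    "concordance_analysis",
    "volcano_table",
    "read_count_table",
    "read_rcc_dir",
]

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")


@dataclass
class CountMatrix:
    """Probes × samples count table with probe-class annotations.

    Parameters
    ----------
    counts : DataFrame
        Nonnegative counts, index = probe ids, columns = sample ids.
    probe_class : Series
        Per-probe class, one of ``endogenous | positive | negative |
        housekeeping``, indexed like ``counts``.
    groups : mapping, optional
        Sample id -> group label (e.g. day0/day1/day6).
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.index.equals(self.probe_class.index):
            self.probe_class = self.probe_class.reindex(self.counts.index)
            if self.probe_class.isna().any():
                raise ValueError("every probe needs a class annotation")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")

    def probes_of(self, cls: str) -> pd.Index:
        return self.counts.index[self.probe_class == cls]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups.get(s) == group]

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(samples)].copy(),
            probe_class=self.probe_class.copy(),
            groups={s: g for s, g in self.groups.items() if s in set(samples)},
        )

    def copy_with(self, counts: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(
            counts=counts, probe_class=self.probe_class.copy(), groups=dict(self.groups)
        )


# ---------------------------------------------------------------------------
# normalization chain
# ---------------------------------------------------------------------------


def positive_control_normalize(
    matrix: CountMatrix,
) -> tuple[CountMatrix, pd.Series]:
    """Scale each sample by its spike-in positive-control geometric mean.

    factor_s = mean_over_samples(geomean_positives) / geomean_positives(s);
    every count in sample s is multiplied by factor_s.
    """
    pos = matrix.probes_of("positive")
    if len(pos) < 2:
        raise ValueError("need >= 2 positive control probes")
    geo = matrix.counts.loc[pos].apply(lambda col: geometric_mean(col.values))
    factors = geo.mean() / geo
    normalized = matrix.counts.mul(factors, axis=1)
    return matrix.copy_with(normalized), factors.rename("pos_factor")


def detection_call(
    matrix: CountMatrix,
    samples: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Present/absent call per endogenous + housekeeping gene.

    Each gene's counts across the chosen samples are tested against the
    pooled negative-control counts of the same samples with a one-tailed
    Student's t-test (mean gene > mean negatives); genes with p >= alpha
    are flagged absent and downstream blanketed to 1.
    """
    cols = list(samples) if samples is not None else list(matrix.counts.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 samples for the detection t-test")
    neg = matrix.probes_of("negative")
    if len(neg) < 2:
        raise ValueError("need >= 2 negative control probes")
    neg_pool = matrix.counts.loc[neg, cols].values.ravel()
    tested = matrix.counts.index[matrix.probe_class.isin(["endogenous", "housekeeping"])]
    rows = []
    for gene in tested:
        p = one_tailed_t_test(matrix.counts.loc[gene, cols].values, neg_pool)
        rows.append({"gene": gene, "p_detect": p, "present": p < alpha})
    return pd.DataFrame(rows).set_index("gene")


def background_subtract(
    matrix: CountMatrix,
    flags: pd.DataFrame,
    pooled: bool = False,
) -> CountMatrix:
    """Subtract negative-control background (mean + 3 s.d.), floor at 1.

    Background is computed per sample from that sample's negative probes
    (sample-specific chemistry); ``pooled=True`` uses one background from
    all negative-probe counts instead.  Genes flagged absent are set to 1
    in every sample.  Negative probes are consumed by the subtraction
    (set to 0), so re-running the chain on an already-subtracted matrix
    finds zero background and changes nothing; positive probes pass
    through unchanged.
    """
    neg = matrix.probes_of("negative")
    counts = matrix.counts.copy()
    if pooled:
        vals = matrix.counts.loc[neg].values.ravel()
        bg = pd.Series(vals.mean() + 3 * vals.std(ddof=1), index=counts.columns)
    else:
        bg = matrix.counts.loc[neg].mean() + 3 * matrix.counts.loc[neg].std(ddof=1)
    target = counts.index[matrix.probe_class.isin(["endogenous", "housekeeping"])]
    sub = counts.loc[target].sub(bg, axis=1).clip(lower=1.0)
    counts.loc[target] = sub
    counts.loc[neg] = 0.0
    absent = flags.index[~flags["present"]]
    counts.loc[counts.index.intersection(absent)] = 1.0
    return matrix.copy_with(counts)


def housekeeping_normalize(
    matrix: CountMatrix, housekeeping: str | None = None
) -> tuple[CountMatrix, pd.Series]:
    """Scale each sample so its housekeeping count equals the
    across-sample mean housekeeping count (input-material correction).

    Only biological probes (endogenous + housekeeping) are rescaled:
    spike-in controls measure chemistry, not input material.
    """
    if housekeeping is None:
        hk = matrix.probes_of("housekeeping")
        if len(hk) != 1:
            raise ValueError("pass housekeeping= when not exactly one housekeeping probe")
        housekeeping = str(hk[0])
    hk_counts = matrix.counts.loc[housekeeping]
    if (hk_counts <= 0).any():
        raise ValueError("housekeeping counts must be positive in all samples")
    factors = hk_counts.mean() / hk_counts
    counts = matrix.counts.copy()
    bio = counts.index[matrix.probe_class.isin(["endogenous", "housekeeping"])]
    counts.loc[bio] = counts.loc[bio].mul(factors, axis=1)
    return matrix.copy_with(counts), factors.rename("hk_factor")


@dataclass
class NormalizationResult:
    matrix: CountMatrix
    pos_factors: pd.Series
    detection: pd.DataFrame
    hk_factors: pd.Series


def normalize(
    matrix: CountMatrix,
    housekeeping: str | None = None,
    samples: Sequence[str] | None = None,
    detection_alpha: float = 0.05,
    pooled_background: bool = False,
) -> NormalizationResult:
    """Run the full four-step chain; returns the normalized matrix plus
    per-step diagnostics (scale factors, detection calls)."""
    if samples is not None:
        matrix = matrix.subset_samples(samples)
    step1, pos_factors = positive_control_normalize(matrix)
    flags = detection_call(step1, alpha=detection_alpha)
    step3 = background_subtract(step1, flags, pooled=pooled_background)
    step4, hk_factors = housekeeping_normalize(step3, housekeeping=housekeeping)
    return NormalizationResult(
        matrix=step4, pos_factors=pos_factors, detection=flags, hk_factors=hk_factors
    )


# ---------------------------------------------------------------------------
# negative-binomial exact test
# ---------------------------------------------------------------------------


def _mom_dispersions(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion from within-group moments.

    For NB, var = mu + alpha mu^2, so alpha = (var - mu) / mu^2 per
    group; groups are combined weighting by degrees of freedom.
    Negative estimates (sub-Poisson sample variance) truncate to 0.
    """
    est = np.zeros(a.shape[0])
    wsum = np.zeros(a.shape[0])
    for grp in (a, b):
        n = grp.shape[1]
        if n < 2:
            continue
        mu = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        df = n - 1
        est += df * np.clip(alpha, 0.0, None)
        wsum += df
    return est / np.maximum(wsum, 1)


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha(mu) = a0 + a1/mu over informative genes,
    coefficients truncated at 0."""
    use = (mu > 0) & (alpha > 0)
    if use.sum() < 2:
        return (float(alpha[use].mean()) if use.any() else 0.0, 0.0)
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


def _shrunk_dispersions(
    a: np.ndarray, b: np.ndarray, floor: float = 1e-8
) -> np.ndarray:
    raw = _mom_dispersions(a, b)
    mu = np.concatenate([a, b], axis=1).mean(axis=1)
    a0, a1 = _dispersion_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-12)
    df = (a.shape[1] - 1) + (b.shape[1] - 1)
    w = df / (df + 4.0)  # few replicates -> lean heavily on the trend
    blended = w * raw + (1 - w) * trend
    # guard against per-gene underestimates with so few replicates: never
    # drop below the trend value (conservative sharing)
    return np.maximum(np.maximum(blended, trend), floor)


def _exact_nb_pvalue(k_a: int, k_b: int, n_a: int, n_b: int, alpha: float) -> float:
    """Exact conditional two-group NB test.

    Conditions on the total k = k_a + k_b; under the null both groups
    share the per-sample mean mu = k / (n_a + n_b).  Group sums are NB
    with mean n mu and size n/alpha (alpha -> 0 falls back to Poisson via
    a large size).  p = sum of P(a) P(k - a) over outcomes no more likely
    than the observed split, normalized by the total.
    """
    k = k_a + k_b
    if k == 0:
        return 1.0
    mu = k / (n_a + n_b)
    size_a = n_a / max(alpha, 1e-12)
    size_b = n_b / max(alpha, 1e-12)
    xs = np.arange(k + 1)
    la = nbinom.logpmf(xs, size_a, size_a / (size_a + n_a * mu))
    lb = nbinom.logpmf(xs[::-1], size_b, size_b / (size_b + n_b * mu))
    joint = la + lb  # log P(a) + log P(k - a)
    obs = joint[k_a]
    m = joint.max()
    probs = np.exp(joint - m)
    p = probs[joint <= obs + 1e-12].sum() / probs.sum()
    return float(min(p, 1.0))


@dataclass
class DEResult:
    """Per-gene differential-expression calls between two sample groups."""

    table: pd.DataFrame  # gene-indexed: mean_a, mean_b, log2fc, p_value, p_adjusted, significant, direction
    group_a: str
    group_b: str
    alpha: float = 0.05

    def significant_genes(self, direction: str | None = None) -> pd.Index:
        t = self.table
        mask = t["significant"]
        if direction is not None:
            mask &= t["direction"] == direction
        return t.index[mask]


def nb_differential_test(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> DEResult:
    """NB exact test per endogenous gene between two sample groups.

    Operates on already-normalized counts (rounded to integers for the
    conditional test).  log2 fold change is log2(mean_b / mean_a) with
    group means floored at 1, so a gene blanketed to 1 everywhere has
    log2FC = 0.  Significance: raw p < ``alpha``; BH-adjusted p reported
    alongside.
    """
    cols_a = matrix.samples_in(group_a)
    cols_b = matrix.samples_in(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    genes = matrix.probes_of("endogenous")
    A = np.round(matrix.counts.loc[genes, cols_a].values).astype(np.int64)
    B = np.round(matrix.counts.loc[genes, cols_b].values).astype(np.int64)
    disp = _shrunk_dispersions(A, B)

    pvals = np.array(
        [
            _exact_nb_pvalue(int(A[i].sum()), int(B[i].sum()), A.shape[1], B.shape[1], disp[i])
            for i in range(len(genes))
        ]
    )
    mean_a = np.maximum(A.mean(axis=1), 1.0)
    mean_b = np.maximum(B.mean(axis=1), 1.0)
    log2fc = np.log2(mean_b / mean_a)
    adj = np.asarray(bh_adjust(pvals).adjusted_p)
    significant = pvals < alpha
    direction = np.where(
        ~significant | (log2fc == 0), "ns", np.where(log2fc > 0, "up", "down")
    )
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": adj,
            "significant": significant,
            "direction": direction,
        },
        index=genes,
    )
    table.index.name = "gene"
    return DEResult(table=table, group_a=group_a, group_b=group_b, alpha=alpha)


# ---------------------------------------------------------------------------
# concordance with the developmental reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChickReference:
    """Developmental direction per reference gene:
    ``high_in_SZPNT`` or ``low_in_SZPNT``."""

    direction: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.direction.values()) - {"high_in_SZPNT", "low_in_SZPNT"}
        if bad:
            raise ValueError(f"unknown directions: {sorted(bad)}")

    def genes(self, direction: str) -> list[str]:
        return [g for g, d in self.direction.items() if d == direction]


@dataclass
class ConcordanceResult:
    n_down_concordant: int
    n_low_total: int
    n_up_concordant: int
    n_high_total: int
    table: ContingencyTable2x2
    fisher_p: float
    unmatched: tuple[str, ...] = ()


def concordance_analysis(
    de_early: DEResult,
    de_late: DEResult,
    ref: ChickReference,
) -> ConcordanceResult:
    """Score regeneration DE calls against the developmental reference.

    A development-low gene is concordant if called significantly down at
    either regeneration timepoint; a development-high gene if called
    significantly up at either.  The 2×2 table (rows low/high, columns
    concordant/not) is tested with Fisher's exact test.  Reference genes
    missing from either DE result are excluded with a warning.
    """
    available = set(de_early.table.index) & set(de_late.table.index)
    unmatched = tuple(sorted(g for g in ref.direction if g not in available))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} reference genes missing from DE results: "
            f"{list(unmatched)[:5]}...",
            stacklevel=2,
        )

    def concordant(gene: str, want: str) -> bool:
        return (
            de_early.table.loc[gene, "direction"] == want
            or de_late.table.loc[gene, "direction"] == want
        )

    low = [g for g in ref.genes("low_in_SZPNT") if g in available]
    high = [g for g in ref.genes("high_in_SZPNT") if g in available]
    n_down = sum(concordant(g, "down") for g in low)
    n_up = sum(concordant(g, "up") for g in high)
    table = ContingencyTable2x2(
        a=n_down, b=len(low) - n_down, c=n_up, d=len(high) - n_up
    )
    return ConcordanceResult(
        n_down_concordant=n_down,
        n_low_total=len(low),
        n_up_concordant=n_up,
        n_high_total=len(high),
        table=table,
        fisher_p=fisher_exact_2x2(table),
        unmatched=unmatched,
    )


def volcano_table(de: DEResult) -> pd.DataFrame:
    """Volcano-plot columns (log2FC vs −log10 p) derived from a DEResult."""
    t = de.table
    out = pd.DataFrame(
        {
            "gene": t.index,
            "log2fc": t["log2fc"].values,
            "neg_log10_p": -np.log10(np.maximum(t["p_value"].values, 1e-300)),
            "class": t["direction"].values,
            "mean_counts": (t["mean_a"].values + t["mean_b"].values) / 2.0,
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_CLASS_MAP = {
    "endogenous": "endogenous",
    "positive": "positive",
    "negative": "negative",
    "housekeeping": "housekeeping",
}


def read_count_table(path: str | Path, groups: Mapping[str, str] | None = None) -> CountMatrix:
    """Read a delimited count table: first column probe id, second column
    probe class, remaining columns samples."""
    df = pd.read_csv(path, sep=None, engine="python")
    probe_col, class_col = df.columns[:2]
    df = df.set_index(probe_col)
    df.index.name = None
    cls = df[class_col].str.lower().map(_CLASS_MAP)
    if cls.isna().any():
        bad = df[class_col][cls.isna()].unique()
        raise ValueError(f"unknown probe classes in {path}: {list(bad)}")
    counts = df.drop(columns=[class_col]).astype(float)
    return CountMatrix(
        counts=counts, probe_class=cls, groups=dict(groups) if groups else {}
    )


def read_rcc_dir(
    directory: str | Path, groups: Mapping[str, str] | None = None
) -> CountMatrix:
    """Read a directory of nCounter RCC files (one sample each).

    Only the ``<Code_Summary>`` block is interpreted: CSV lines
    ``CodeClass,Name,Accession,Count``.  The sample id is the file stem.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.rcc")) + sorted(directory.glob("*.RCC"))
    if not files:
        raise ValueError(f"no .rcc files in {directory}")
    columns: dict[str, pd.Series] = {}
    classes: dict[str, str] = {}
    for f in files:
        text = f.read_text()
        m = re.search(r"<Code_Summary>(.*?)</Code_Summary>", text, re.S)
        if not m:
            raise ValueError(f"{f.name}: no <Code_Summary> block")
        counts: dict[str, float] = {}
        for line in m.group(1).strip().splitlines():
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 4 or parts[0].lower() == "codeclass":
                continue
            code_class, name, _accession, count = parts[0], parts[1], parts[2], parts[3]
            cls = _CLASS_MAP.get(code_class.lower())
            if cls is None:
                continue  # SpikeIn/Binding etc. are out of scope
            counts[name] = float(count)
            prev = classes.get(name)
            if prev is not None and prev != cls:
                raise ValueError(f"probe {name} has conflicting classes across files")
            classes[name] = cls
        columns[f.stem] = pd.Series(counts, name=f.stem)
    counts_df = pd.DataFrame(columns)
    if counts_df.isna().any().any():
        raise ValueError("probe sets differ across RCC files")
    probe_class = pd.Series({g: classes[g] for g in counts_df.index})
    return CountMatrix(
        counts=counts_df,
        probe_class=probe_class,
        groups=dict(groups) if groups else {},
    )
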
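"""nCounter normalization chain, NB exact test, and concordance."""

import numpy as np
import pandas as pd
import pytest

from axoregen.core_stats import geometric_mean
from axoregen.nanostring import (
    ChickReference,
    CountMatrix,
    DEResult,
    background_subtract,
    concordance_analysis,
    detection_call,
    housekeeping_normalize,
    nb_differential_test,
    normalize,
    positive_control_normalize,
    read_count_table,
    read_rcc_dir,
    volcano_table,
)
from axoregen.synthetic_data import simulate_nanostring_counts


def toy_matrix(values: dict, groups=None) -> CountMatrix:
    """values: probe -> (class, [counts per sample])."""
    counts = pd.DataFrame(
        {p: v[1] for p, v in values.items()},
        index=[f"s{i}" for i in range(len(next(iter(values.values()))[1]))],
    ).T.astype(float)
    cls = pd.Series({p: v[0] for p, v in values.items()}).reindex(counts.index)
    return CountMatrix(counts=counts, probe_class=cls, groups=groups or {})


# ---------------------------------------------------------------------------
# normalization steps
# ---------------------------------------------------------------------------


def test_positive_normalize_identical_samples_factors_one():
    m = toy_matrix(
        {
            "POS_A": ("positive", [100, 100]),
            "POS_B": ("positive", [400, 400]),
            "g1": ("endogenous", [10, 10]),
        }
    )
    _, factors = positive_control_normalize(m)
    assert np.allclose(factors.values, 1.0)


def test_positive_normalize_doubled_sample():
    m = toy_matrix(
        {
            "POS_A": ("positive", [100, 200]),
            "POS_B": ("positive", [400, 800]),
            "g1": ("endogenous", [10, 20]),
        }
    )
    out, factors = positive_control_normalize(m)
    assert factors["s0"] / factors["s1"] == pytest.approx(2.0)
    # after normalization both samples carry the same g1 signal
    assert out.counts.loc["g1", "s0"] == pytest.approx(out.counts.loc["g1", "s1"])


def test_positive_normalize_matches_hand_oracle():
    m = toy_matrix(
        {
            "POS_A": ("positive", [100, 150, 120]),
            "POS_B": ("positive", [25, 30, 20]),
            "g1": ("endogenous", [10, 10, 10]),
        }
    )
    _, factors = positive_control_normalize(m)
    geo = [geometric_mean([100, 25]), geometric_mean([150, 30]), geometric_mean([120, 20])]
    expected = np.mean(geo) / np.array(geo)
    assert np.allclose(factors.values, expected)


def test_detection_call_blankets_noise_level_genes():
    rng = np.random.default_rng(1)
    neg = {f"NEG_{i}": ("negative", list(rng.poisson(12, 3))) for i in range(6)}
    m = toy_matrix(
        {
            **neg,
            "POS_A": ("positive", [500, 500, 500]),
            "POS_B": ("positive", [100, 100, 100]),
            "noise": ("endogenous", [12, 11, 13]),
            "expressed": ("endogenous", [1200, 1300, 1100]),
        }
    )
    flags = detection_call(m)
    assert not flags.loc["noise", "present"]
    assert flags.loc["expressed", "present"]
    assert flags.loc["expressed", "p_detect"] < 1e-4


def test_background_subtract_hand_values():
    # negatives with mean 20, sd 10 per sample -> background 50
    m = toy_matrix(
        {
            "NEG_A": ("negative", [10, 10]),
            "NEG_B": ("negative", [30, 30]),
            "NEG_C": ("negative", [20, 20]),
            "hi": ("endogenous", [500, 500]),
            "lo": ("endogenous", [30, 30]),
            "off": ("endogenous", [1000, 1000]),
        }
    )
    flags = pd.DataFrame(
        {"present": [True, True, False]}, index=["hi", "lo", "off"]
    )
    out = background_subtract(m, flags)
    assert np.allclose(out.counts.loc["hi"].values, 450.0)
    assert np.allclose(out.counts.loc["lo"].values, 1.0)  # floored
    assert np.allclose(out.counts.loc["off"].values, 1.0)  # absent -> 1
    # negatives are consumed by the subtraction
    assert np.allclose(out.counts.loc["NEG_A"].values, 0.0)


def test_housekeeping_normalize_scales_to_mean():
    m = toy_matrix(
        {
            "Rpl4": ("housekeeping", [1000, 2000]),
            "g1": ("endogenous", [100, 200]),
        }
    )
    out, factors = housekeeping_normalize(m)
    assert factors["s1"] == pytest.approx(0.75)  # mean 1500 / 2000
    assert out.counts.loc["Rpl4", "s0"] == pytest.approx(out.counts.loc["Rpl4", "s1"])
    assert out.counts.loc["g1", "s0"] == pytest.approx(out.counts.loc["g1", "s1"])
    bad = toy_matrix({"Rpl4": ("housekeeping", [0, 10]), "g1": ("endogenous", [1, 1])})
    with pytest.raises(ValueError):
        housekeeping_normalize(bad)


def test_full_chain_idempotent_on_normalized_matrix():
    """Re-running the chain on its own output changes nothing: all scale
    factors are 1 and no new gene drops out."""
    matrix, _ = simulate_nanostring_counts(n_genes=30, n_true_de=0, seed=7)
    first = normalize(matrix)
    second = normalize(first.matrix)
    assert np.allclose(second.pos_factors.values, 1.0)
    assert np.allclose(second.hk_factors.values, 1.0, atol=1e-9)
    pd.testing.assert_frame_equal(
        first.matrix.counts, second.matrix.counts, rtol=1e-9
    )


def test_chain_invariant_to_sample_rescaling():
    """Uniformly rescaling one sample's raw counts is undone by the
    positive-control step: downstream values change only by one global
    factor (the normalization target follows the mean geomean), and DE
    calls are untouched."""
    matrix, _ = simulate_nanostring_counts(n_genes=25, n_true_de=0, seed=11)
    rescaled = matrix.copy_with(matrix.counts.copy())
    sample = rescaled.counts.columns[2]
    rescaled.counts[sample] *= 3.7
    a = normalize(matrix).matrix.counts
    b = normalize(rescaled).matrix.counts
    mask = (a.values > 1.0) & (b.values > 1.0)  # skip floored/consumed cells
    ratio = b.values[mask] / a.values[mask]
    assert ratio.std() / ratio.mean() < 1e-9  # single global factor
    de_a = nb_differential_test(normalize(matrix).matrix, "day0", "day6")
    de_b = nb_differential_test(normalize(rescaled).matrix, "day0", "day6")
    assert (de_a.table["significant"] == de_b.table["significant"]).all()


# ---------------------------------------------------------------------------
# NB differential test
# ---------------------------------------------------------------------------


def _groups(n_a, n_b, names=("day0", "day6")):
    g = {}
    for i in range(n_a):
        g[f"s{i}"] = names[0]
    for i in range(n_a, n_a + n_b):
        g[f"s{i}"] = names[1]
    return g


def test_nb_test_identical_groups_ns():
    m = toy_matrix(
        {
            "g1": ("endogenous", [200, 210, 190, 200, 210, 190]),
            "g2": ("endogenous", [50, 55, 45, 50, 55, 45]),
        },
        groups=_groups(3, 3),
    )
    de = nb_differential_test(m, "day0", "day6")
    assert (de.table["direction"] == "ns").all()
    assert (de.table["p_value"] > 0.5).all()


def test_nb_test_blanketed_gene_is_null():
    m = toy_matrix(
        {
            "flat": ("endogenous", [1, 1, 1, 1, 1, 1]),
            "real": ("endogenous", [100, 110, 90, 405, 395, 400]),
        },
        groups=_groups(3, 3),
    )
    de = nb_differential_test(m, "day0", "day6")
    assert de.table.loc["flat", "log2fc"] == 0.0
    assert de.table.loc["flat", "direction"] == "ns"
    assert de.table.loc["real", "direction"] == "up"
    assert de.table.loc["real", "log2fc"] == pytest.approx(2.0, abs=0.2)


def test_nb_test_recovers_simulated_fold_changes():
    """Mean 200 vs 800 at dispersion 0.05, n=3 per group: significant
    with log2FC near 2 in nearly every seeded run."""
    hits = 0
    n_runs = 60
    for seed in range(n_runs):
        rng = np.random.default_rng(10_000 + seed)
        size = 1 / 0.05
        a = rng.negative_binomial(size, size / (size + 200.0), 3)
        b = rng.negative_binomial(size, size / (size + 800.0), 3)
        m = toy_matrix(
            {"g": ("endogenous", list(a) + list(b)),
             "null": ("endogenous", [300, 310, 290, 300, 310, 290])},
            groups=_groups(3, 3),
        )
        de = nb_differential_test(m, "day0", "day6")
        row = de.table.loc["g"]
        if row["significant"] and 1.0 < row["log2fc"] < 3.0:
            hits += 1
    assert hits / n_runs >= 0.95


def test_nb_test_requires_replicates():
    m = toy_matrix({"g": ("endogenous", [1, 2, 3])}, groups=_groups(1, 2))
    with pytest.raises(ValueError):
        nb_differential_test(m, "day0", "day6")


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def make_de(directions: dict) -> DEResult:
    idx = list(directions)
    table = pd.DataFrame(
        {
            "mean_a": 100.0,
            "mean_b": 100.0,
            "log2fc": [1.0 if d == "up" else -1.0 if d == "down" else 0.0 for d in directions.values()],
            "p_value": [0.01 if d != "ns" else 0.9 for d in directions.values()],
            "p_adjusted": [0.02 if d != "ns" else 0.95 for d in directions.values()],
            "significant": [d != "ns" for d in directions.values()],
            "direction": list(directions.values()),
        },
        index=pd.Index(idx, name="gene"),
    )
    return DEResult(table=table, group_a="day0", group_b="test")


def test_concordance_toy_hand_tally():
    """6-gene reference with known calls: counts match a hand tally and
    the 'either timepoint' rule is honoured."""
    ref = ChickReference(
        {
            "l1": "low_in_SZPNT",
            "l2": "low_in_SZPNT",
            "l3": "low_in_SZPNT",
            "h1": "high_in_SZPNT",
            "h2": "high_in_SZPNT",
            "h3": "high_in_SZPNT",
        }
    )
    early = make_de(
        {"l1": "down", "l2": "ns", "l3": "up", "h1": "up", "h2": "ns", "h3": "down"}
    )
    late = make_de(
        {"l1": "ns", "l2": "down", "l3": "ns", "h1": "ns", "h2": "ns", "h3": "ns"}
    )
    res = concordance_analysis(early, late, ref)
    # low: l1 (early), l2 (late) -> 2/3; high: h1 (early) -> 1/3
    assert (res.n_down_concordant, res.n_low_total) == (2, 3)
    assert (res.n_up_concordant, res.n_high_total) == (1, 3)
    assert res.table.as_array().tolist() == [[2, 1], [1, 2]]
    assert 0 < res.fisher_p <= 1


def test_concordance_saturated_rows_no_association():
    ref = ChickReference(
        {**{f"l{i}": "low_in_SZPNT" for i in range(5)},
         **{f"h{i}": "high_in_SZPNT" for i in range(5)}}
    )
    calls_e = {f"l{i}": "down" for i in range(5)}
    calls_e.update({f"h{i}": "up" for i in range(5)})
    de = make_de(calls_e)
    res = concordance_analysis(de, de, ref)
    assert res.n_down_concordant == 5 and res.n_up_concordant == 5
    assert res.fisher_p == pytest.approx(1.0)


def test_concordance_warns_on_unmatched_genes():
    ref = ChickReference({"l1": "low_in_SZPNT", "missing": "high_in_SZPNT"})
    de = make_de({"l1": "down"})
    with pytest.warns(UserWarning):
        res = concordance_analysis(de, de, ref)
    assert res.unmatched == ("missing",)
    assert res.n_low_total == 1 and res.n_high_total == 0


# ---------------------------------------------------------------------------
# volcano table and readers
# ---------------------------------------------------------------------------


def test_volcano_table_derivation():
    de = make_de({"a": "up", "b": "ns"})
    de.table.loc["a", "p_value"] = 0.01
    v = volcano_table(de)
    row = v[v["gene"] == "a"].iloc[0]
    assert row["neg_log10_p"] == pytest.approx(2.0)
    assert row["class"] == "up"
    assert v[v["gene"] == "b"].iloc[0]["class"] == "ns"


def test_count_table_reader_roundtrip(tmp_path):
    matrix, _ = simulate_nanostring_counts(n_genes=10, n_true_de=0, seed=3)
    path = tmp_path / "counts.tsv"
    out = matrix.counts.copy()
    out.insert(0, "probe_class", matrix.probe_class)
    out.reset_index(names="probe").to_csv(path, sep="\t", index=False)
    back = read_count_table(path, groups=matrix.groups)
    pd.testing.assert_frame_equal(back.counts, matrix.counts)
    assert (back.probe_class == matrix.probe_class).all()


def test_rcc_reader(tmp_path):
    body = """<Header>
<Header>ignored</Header>
</Header>
<Code_Summary>
CodeClass,Name,Accession,Count
Endogenous,Sox2,NM_1,{sox2}
Endogenous,Pax6,NM_2,{pax6}
Positive,POS_A,ERCC_1,{pos}
Positive,POS_B,ERCC_2,40
Negative,NEG_A,ERCC_3,5
Negative,NEG_B,ERCC_4,7
Housekeeping,Rpl4,NM_3,900
</Code_Summary>
"""
    (tmp_path / "day0_1.rcc").write_text(body.format(sox2=100, pax6=50, pos=160))
    (tmp_path / "day6_1.rcc").write_text(body.format(sox2=300, pax6=25, pos=150))
    m = read_rcc_dir(tmp_path, groups={"day0_1": "day0", "day6_1": "day6"})
    assert m.counts.shape == (7, 2)
    assert m.counts.loc["Sox2", "day0_1"] == 100
    assert m.probe_class["Rpl4"] == "housekeeping"
    assert m.samples_in("day6") == ["day6_1"]
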
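"""Parameter operations, bin tables and the weighted total, against oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from gtxscore import (
    EffectSpec,
    UndefinedParameterError,
    ValidationError,
    ave_ratio,
    basal_expression,
    bin_score,
    bins_from_yaml,
    bins_to_yaml,
    build_call_matrix,
    cv_percent,
    default_bin_tables,
    gene_parameters,
    generate_dataset,
    group_p_value,
    infer_bin_tables,
    positive_chemical,
    positive_condition,
    rank_genes,
    rescore_reference,
    reference_table,
    reverse_change,
    specificity,
    total_score,
)
from gtxscore.reference import PARAMETERS
from gtxscore.scoring import ScoreBinTable


# ---------------------------------------------------------------------------
# Brute-force oracles (independent, loop-based re-implementations)


def oracle_specificity(calls, klass):
    g = sum(1 for c, k in zip(calls, klass) if c == "up" and k == "GTX")
    n = sum(1 for c, k in zip(calls, klass) if c == "up" and k == "NGTX")
    return g / (g + n)


def oracle_ave_ratio(calls, klass, ratios):
    vals = [r for c, k, r in zip(calls, klass, ratios) if c == "up" and k == "GTX"]
    return sum(vals) / len(vals)


def oracle_positive_condition(calls, klass, weights):
    return sum(w for c, k, w in zip(calls, klass, weights) if c == "up" and k == "GTX")


def oracle_positive_chemical(calls, klass, chems):
    return len({ch for c, k, ch in zip(calls, klass, chems) if c == "up" and k == "GTX"})


def oracle_reverse_change(calls, klass):
    n = sum(1 for c, k in zip(calls, klass) if c == "down" and k == "NGTX")
    g = sum(1 for c, k in zip(calls, klass) if c == "down" and k == "GTX")
    return n - g


def oracle_welch_p(a, b):
    """Textbook Welch t test with Welch-Satterthwaite df."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * tdist.sf(abs(tstat), df)


def oracle_cv(x):
    x = list(map(float, x))
    m = sum(x) / len(x)
    sd = math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))
    return 100 * sd / m


def random_row(rng, n_cells=12):
    calls = rng.choice(["up", "down", "none"], size=n_cells, p=[0.35, 0.25, 0.4])
    klass = rng.choice(["GTX", "NGTX"], size=n_cells, p=[0.7, 0.3])
    chems = rng.choice(["DMN", "DEN", "ENU", "AAT"], size=n_cells)
    weights = np.where(chems == "DEN", 0.5, 1.0)
    ratios = np.exp(rng.normal(0.5, 0.8, size=n_cells))
    return calls, klass, chems, weights, ratios


# ---------------------------------------------------------------------------
# Worked examples


def test_specificity_examples():
    calls = ["up"] * 12
    klass = ["GTX"] * 10 + ["NGTX"] * 2
    assert specificity(calls, klass) == pytest.approx(10 / 12)
    assert specificity(["up", "none"], ["GTX", "NGTX"]) == 1.0
    with pytest.raises(UndefinedParameterError):
        specificity(["none", "down"], ["GTX", "NGTX"])


def test_ave_ratio_examples():
    assert ave_ratio(["up", "up"], ["GTX", "GTX"], [2.0, 4.0]) == 3.0
    assert ave_ratio(["up"], ["GTX"], [10.62]) == 10.62
    with pytest.raises(UndefinedParameterError):
        ave_ratio(["up"], ["NGTX"], [3.0])


def test_positive_condition_weighted_counts():
    calls = ["up"] * 13
    klass = ["GTX"] * 13
    weights = [1.0] * 10 + [0.5] * 3
    assert positive_condition(calls, klass, weights) == 11.5
    weights = [1.0] * 14 + [0.5]
    assert positive_condition(["up"] * 15, ["GTX"] * 15, weights) == 14.5
    assert positive_condition(["none"] * 3, ["GTX"] * 3, [1.0] * 3) == 0.0


def test_positive_chemical_counts_distinct():
    chems = ["DMN", "DEN", "ENU", "DPN", "AAT", "DBP", "DMBA"]
    assert positive_chemical(["up"] * 7, ["GTX"] * 7, chems) == 7
    assert positive_chemical(["none"] * 2, ["GTX"] * 2, ["DMN", "DEN"]) == 0
    # both duplicated-DEN cells up -> still one chemical
    assert positive_chemical(["up", "up"], ["GTX", "GTX"], ["DEN", "DEN"]) == 1


def test_reverse_change_examples():
    assert reverse_change(["down", "down"], ["NGTX", "NGTX"]) == 2.0
    assert reverse_change(["down"], ["GTX"]) == -1.0
    assert reverse_change(["up", "none"], ["GTX", "NGTX"]) == 0.0


def test_group_p_value_degenerate_and_identical():
    assert group_p_value([1.0, 1.0], [1.0, 1.0]) == 1.0
    assert group_p_value([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        group_p_value([1.0], [1, 2])


def test_group_p_value_matches_textbook_welch():
    p = group_p_value([5, 6, 7, 8], [1, 2, 2, 1])
    assert p == pytest.approx(oracle_welch_p([5, 6, 7, 8], [1, 2, 2, 1]), abs=1e-12)


def test_basal_examples():
    assert basal_expression([10, 10, 10]) == pytest.approx(1.0)
    assert basal_expression([1, 1]) == pytest.approx(0.0)
    assert basal_expression([6, 8, 10, 9.3]) == pytest.approx(math.log10(8.325))
    with pytest.raises(ValidationError):
        basal_expression([0.0, 0.0])


def test_cv_examples():
    assert cv_percent([90, 110]) == pytest.approx(100 * math.sqrt(200) / 100)
    assert cv_percent([5, 5, 5]) == 0.0
    with pytest.raises(ValidationError):
        cv_percent([4.0])


def test_parameter_oracle_equivalence_random_rows():
    rng = np.random.default_rng(42)
    tested = 0
    for _ in range(300):
        calls, klass, chems, weights, ratios = random_row(rng)
        if not ((calls == "up") & (klass == "GTX")).any():
            continue
        tested += 1
        assert specificity(calls, klass) == pytest.approx(
            oracle_specificity(calls, klass), abs=1e-12
        )
        assert ave_ratio(calls, klass, ratios) == pytest.approx(
            oracle_ave_ratio(calls, klass, ratios), abs=1e-12
        )
        assert positive_condition(calls, klass, weights) == pytest.approx(
            oracle_positive_condition(calls, klass, weights), abs=1e-12
        )
        assert positive_chemical(calls, klass, chems) == oracle_positive_chemical(
            calls, klass, chems
        )
        assert reverse_change(calls, klass) == oracle_reverse_change(calls, klass)
    assert tested > 100


# ---------------------------------------------------------------------------
# Bin tables


def test_default_bin_scores_match_published_examples():
    tabs = default_bin_tables()
    assert bin_score(0.92, tabs["basal"]) == 0
    assert bin_score(3.16, tabs["basal"]) == 5
    assert bin_score(64, tabs["cv_percent"]) == 2


def test_infer_single_pair():
    tabs = infer_bin_tables([("specificity", 1.0, 5)])
    assert bin_score(1.0, tabs["specificity"]) == 5


def test_infer_contradiction_is_infeasible():
    with pytest.raises(ValidationError, match="cv_percent"):
        infer_bin_tables([("cv_percent", 30.0, 4), ("cv_percent", 30.0, 2)])


def test_infer_non_monotone_is_infeasible():
    with pytest.raises(ValidationError, match="monotonicity"):
        infer_bin_tables([("basal", 1.0, 3), ("basal", 2.0, 1)])


def test_bin_table_validation():
    with pytest.raises(ValidationError):
        ScoreBinTable("basal", "higher-better", (1.0, 0.5), (0, 1, 2))
    with pytest.raises(ValidationError):
        ScoreBinTable("basal", "higher-better", (1.0,), (3, 1))  # non-monotone
    tab = ScoreBinTable("specificity", "higher-better", (0.5,), (0, 5))
    with pytest.raises(ValidationError):
        bin_score(1.5, tab)  # outside the [0, 1] specificity domain


def test_bins_yaml_roundtrip(tmp_path):
    tabs = default_bin_tables()
    path = tmp_path / "bins.yaml"
    bins_to_yaml(tabs, path)
    back = bins_from_yaml(path)
    assert back == tabs


def test_score_monotone_in_parameter_direction():
    """Better parameter values never lower the component score or the total."""
    tabs = default_bin_tables()
    rng = np.random.default_rng(3)
    for _ in range(200):
        base = {
            "specificity": rng.uniform(0, 1),
            "ave_ratio": rng.uniform(1, 30),
            "positive_condition": rng.uniform(0, 16),
            "positive_chemical": rng.integers(0, 8),
            "p_value": rng.uniform(0, 1),
            "basal": rng.uniform(0.5, 3.5),
            "reverse_change": rng.integers(-3, 5),
            "cv_percent": rng.uniform(5, 120),
        }
        scores = {p: bin_score(base[p], tabs[p]) for p in PARAMETERS}
        better_spec = dict(base, specificity=min(1.0, base["specificity"] + rng.uniform(0, 0.3)))
        up = {p: bin_score(better_spec[p], tabs[p]) for p in PARAMETERS}
        assert total_score(up) >= total_score(scores)
        better_cv = dict(base, cv_percent=base["cv_percent"] * rng.uniform(0.3, 1.0))
        down = {p: bin_score(better_cv[p], tabs[p]) for p in PARAMETERS}
        assert total_score(down) >= total_score(scores)


# ---------------------------------------------------------------------------
# Totals and ranking


def test_total_score_examples():
    assert total_score([5, 5, 5, 5, 5, 0, 2, 2]) == 32.0
    assert total_score([3, 5, 5, 5, 4, 0, 2, 2]) == 27.0
    assert total_score([0] * 8) == 0.0
    assert total_score([5] * 8) == 37.5
    with pytest.raises(ValidationError):
        total_score([5] * 7)
    with pytest.raises(ValidationError):
        total_score([6] + [0] * 7)


def test_reference_rescore_preserves_printed_order():
    ref = reference_table()
    rr = rescore_reference()
    assert list(rr.index) == list(ref.index)
    np.testing.assert_allclose(rr["recomputed_total"], ref["total_score"])


def test_single_spiked_gene_ranks_first(small_design):
    effects = EffectSpec(responsive_gene_ids=frozenset({"g00042"}))
    ds, _ = generate_dataset(small_design, effects, seed=9)
    scores = rank_genes(ds)
    assert scores.index[0] == "g00042"
    assert scores.loc["g00042", "rank"] == 1


def test_genes_without_up_calls_are_excluded(small_design):
    effects = EffectSpec(noise_sd=0.0)  # nothing departs from control
    ds, _ = generate_dataset(small_design, effects, seed=1)
    scores = rank_genes(ds)
    assert len(scores) == 0
    assert len(scores.attrs["excluded"]["no_up_call"]) == small_design.n_genes


def test_gene_parameters_match_scalar_ops(small_design, small_effects):
    """Vectorized parameter table agrees with the per-row scalar operations."""
    ds, _ = generate_dataset(small_design, small_effects, seed=6)
    calls = build_call_matrix(ds)
    params = gene_parameters(calls, ds)
    for gene_id, row in params.head(5).iterrows():
        sub = calls[calls["gene_id"] == gene_id]
        assert row["specificity"] == pytest.approx(
            specificity(sub["call"], sub["klass"]), abs=1e-12
        )
        assert row["ave_ratio"] == pytest.approx(
            ave_ratio(sub["call"], sub["klass"], sub["ratio"]), abs=1e-12
        )
        assert row["positive_condition"] == pytest.approx(
            positive_condition(sub["call"], sub["klass"], sub["weight"]), abs=1e-12
        )
        assert row["positive_chemical"] == positive_chemical(
            sub["call"], sub["klass"], sub["chemical"]
        )
        assert row["reverse_change"] == reverse_change(sub["call"], sub["klass"])
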
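"""age_stats: hand-computed ages, the permutation null, rank-biserial."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carcineff import age_stats as ag, cohort_io as cio
from carcineff import synthetic_data as sd
from conftest import make_mutations, make_samples


def _cohort(sample_rows, mut_rows):
    return cio.from_frames(make_samples(sample_rows), make_mutations(mut_rows))


# ---------------------------------------------------------------------------
# weighted mean age


def test_weighted_mean_age_hand_value(toy_cancer):
    s = ag.weighted_mean_age(toy_cancer, "TP53")
    # functional TP53 in c1 (61) and c2 (72); c3's synonymous is excluded
    assert s.mean_age == pytest.approx(66.5)
    assert s.n_mutations == 2
    se = np.std([61.0, 72.0], ddof=1) / np.sqrt(2)
    assert s.ci_low == pytest.approx(66.5 - 1.96 * se)
    assert s.ci_high == pytest.approx(66.5 + 1.96 * se)
    missing = ag.weighted_mean_age(toy_cancer, "NOPE")
    assert np.isnan(missing.mean_age) and "no_data" in missing.flags


def test_weighted_mean_age_is_mutation_weighted():
    c = _cohort(
        [("a", "d1", 40.0, "female", "cancer", "x", np.nan),
         ("b", "d2", 70.0, "female", "cancer", "x", np.nan)],
        [("a", "G", "nonsynonymous_snv", "chr1", 1.0, "A", "T", np.nan),
         ("a", "G", "nonsynonymous_snv", "chr1", 2.0, "A", "T", np.nan),
         ("a", "G", "nonsynonymous_snv", "chr1", 3.0, "A", "T", np.nan),
         ("b", "G", "nonsynonymous_snv", "chr1", 4.0, "A", "T", np.nan)],
    )
    s = ag.weighted_mean_age(c, "G")
    # sample a carries weight 3: (3*40 + 70)/4 = 47.5
    assert s.mean_age == pytest.approx(47.5)
    # the cluster-robust SE recognises that a's three ages are one number
    robust = ag.weighted_mean_age(c, "G", cluster_robust=True)
    se = np.sqrt(9 * (40 - 47.5) ** 2 + (70 - 47.5) ** 2) / 4
    assert (robust.ci_high - robust.mean_age) == pytest.approx(1.96 * se)


# ---------------------------------------------------------------------------
# age divergence


def test_age_divergence_hand_value():
    c = _cohort(
        [("a", "d1", 40.0, "f", "cancer", "x", np.nan),
         ("b", "d2", 40.0, "f", "cancer", "x", np.nan),
         ("c", "d3", 60.0, "f", "cancer", "x", np.nan),
         ("d", "d4", 60.0, "f", "cancer", "x", np.nan)],
        [("a", "A", "nonsynonymous_snv", "chr1", 1.0, "A", "T", np.nan),
         ("b", "A", "nonsynonymous_snv", "chr1", 2.0, "A", "T", np.nan),
         ("c", "B", "nonsynonymous_snv", "chr1", 3.0, "A", "T", np.nan),
         ("d", "B", "nonsynonymous_snv", "chr1", 4.0, "A", "T", np.nan)],
    )
    ratio, kw_p = ag.age_divergence(c, ["A", "B"])
    # gene means 40 and 60, grand mean 50, weights equal:
    # between = 100; population age variance = 100 -> ratio 1
    assert ratio == pytest.approx(1.0)
    want_p = stats.kruskal([40.0, 40.0], [60.0, 60.0]).pvalue
    assert kw_p == pytest.approx(want_p)
    with pytest.raises(ValueError, match=">= 2 genes"):
        ag.age_divergence(c, ["A"])


def test_age_divergence_rejects_constant_ages():
    c = _cohort(
        [("a", "d1", 50.0, "f", "cancer", "x", np.nan),
         ("b", "d2", 50.0, "f", "cancer", "x", np.nan)],
        [("a", "A", "indel", "chr1", 1.0, "A", "T", np.nan),
         ("b", "B", "indel", "chr1", 2.0, "A", "T", np.nan)],
    )
    with pytest.raises(ValueError, match="degenerate"):
        ag.age_divergence(c, ["A", "B"])


def test_age_difference_vs_synonymous(toy_cancer):
    # TP53 functional mean 66.5; exome-wide synonymous: c3 at 55
    assert ag.age_difference_vs_synonymous(toy_cancer, "TP53") == pytest.approx(
        66.5 - 55.0
    )
    assert np.isnan(ag.age_difference_vs_synonymous(toy_cancer, "NOPE"))


# ---------------------------------------------------------------------------
# permutation test


def _age_cohort(mode, seed, n=400, n_genes=5):
    genes = [sd.GeneSpec(f"g{i}") for i in range(n_genes)]
    spec = sd.SynthSpec(genes=genes, n_cancer=n, seed=seed)
    cohort, truth = sd.synth_age_cohort(spec, mode=mode, n_planted=2)
    return cohort, truth


def test_permutation_test_is_seeded_and_valid():
    cohort, _ = _age_cohort("null", seed=8)
    genes = [f"g{i}" for i in range(5)]
    a = ag.permutation_test(cohort, genes, n_perm=200, seed=4)
    b = ag.permutation_test(cohort, genes, n_perm=200, seed=4)
    for ra, rb in zip(a, b):
        assert (ra.p_value, ra.perm_quantile) == (rb.p_value, rb.perm_quantile)
        assert 0 < ra.p_value <= 1
        assert 0 <= ra.perm_quantile <= 1
        assert ra.q_value >= ra.p_value - 1e-12  # BH never shrinks the max


def test_permutation_test_detects_planted_old_bias():
    cohort, truth = _age_cohort("old_bias", seed=12, n=800)
    genes = list(truth["gene"])
    res = {r.gene: r for r in ag.permutation_test(cohort, genes, n_perm=500,
                                                  seed=1)}
    tilted = truth.loc[truth["tilted"], "gene"]
    untilted = truth.loc[~truth["tilted"], "gene"]
    for g in tilted:
        assert res[g].delta_age > 0
        assert res[g].p_value < 0.05
    # untilted genes sit below the planted old-bias genes; note they are
    # not centred at zero here because the synonymous reference itself
    # accumulates with age in the biased modes
    assert max(res[g].delta_age for g in untilted) < min(
        res[g].delta_age for g in tilted
    )


def test_permutation_test_young_bias_sign():
    cohort, truth = _age_cohort("young_bias", seed=3, n=800)
    res = {r.gene: r for r in ag.permutation_test(
        cohort, list(truth["gene"]), n_perm=300, seed=2)}
    for _, rec in truth.iterrows():
        if rec["tilted"]:
            assert res[rec["gene"]].delta_age < 0
            # one-sided young quantile is the lower-tail probability
            assert res[rec["gene"]].young_quantile < 0.05


def test_permutation_test_edge_cases():
    cohort, _ = _age_cohort("null", seed=5, n=100)
    with pytest.raises(ValueError, match="n_perm"):
        ag.permutation_test(cohort, ["g0"], n_perm=50, seed=0)
    res = ag.permutation_test(cohort, ["absent_gene"], n_perm=100, seed=0)
    assert "no_data" in res[0].flags and np.isnan(res[0].p_value)


# ---------------------------------------------------------------------------
# rank-biserial


def _brute_force_rank_biserial(x, y):
    wins = sum(1 for a in x for b in y if a > b)
    losses = sum(1 for a in x for b in y if a < b)
    return (wins - losses) / (len(x) * len(y))


def test_rank_biserial_hand_values():
    assert ag.rank_biserial_age_bias([3, 4], [1, 2]).r == pytest.approx(1.0)
    assert ag.rank_biserial_age_bias([1, 2], [3, 4]).r == pytest.approx(-1.0)
    assert ag.rank_biserial_age_bias([1.0], [1.0]).r == pytest.approx(0.0)
    r = ag.rank_biserial_age_bias([1, 3], [2, 2])
    assert r.r == pytest.approx(0.0)
    assert (r.n_with, r.n_without) == (2, 2)
    with pytest.raises(ValueError):
        ag.rank_biserial_age_bias([], [1.0])


def test_rank_biserial_matches_brute_force_random():
    rng = np.random.default_rng(77)
    for _ in range(50):
        x = rng.integers(0, 10, rng.integers(1, 15)).astype(float)
        y = rng.integers(0, 10, rng.integers(1, 15)).astype(float)
        got = ag.rank_biserial_age_bias(x, y).r
        assert got == pytest.approx(_brute_force_rank_biserial(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# SCNA vs SNV bias table


def test_scna_snv_bias_table_matches_direct_computation():
    genes = [sd.GeneSpec("T1", role="tsg"), sd.GeneSpec("O1", role="oncogene")]
    spec = sd.SynthSpec(genes=genes, n_cancer=300, seed=6)
    cohort, truth = sd.synth_scna_table(spec, concordant=True, effect_size=2.0)
    roles = truth[["gene", "role"]]
    table = ag.scna_snv_bias_table(cohort, roles, min_freq=0.05)
    assert set(table.columns) >= {"gene", "role", "snv_bias", "scna_bias"}
    age_of = dict(zip(cohort.samples["sample_id"], cohort.samples["age"]))
    all_ids = set(cohort.samples["sample_id"])
    for _, row in table.iterrows():
        gene = row["gene"]
        scna_class = "scna_del" if row["role"] == "tsg" else "scna_amp"
        snv = cohort.samples_with_gene(gene, cio.FUNCTIONAL_CLASSES)
        scna_any = cohort.samples_with_gene(gene, {"scna_amp", "scna_del"})
        scna = cohort.samples_with_gene(gene, {scna_class})
        pool = all_ids - scna_any
        want_snv = ag.rank_biserial_age_bias(
            [age_of[s] for s in snv & pool],
            [age_of[s] for s in pool - snv],
        ).r
        pool2 = all_ids - snv
        want_scna = ag.rank_biserial_age_bias(
            [age_of[s] for s in scna & pool2],
            [age_of[s] for s in pool2 - scna_any],
        ).r
        assert row["snv_bias"] == pytest.approx(want_snv)
        assert row["scna_bias"] == pytest.approx(want_scna)


def test_scna_snv_bias_concordance_direction():
    # a strong shared tilt makes the two biases agree in sign
    genes = [sd.GeneSpec(f"T{i}", role="tsg") for i in range(6)]
    spec = sd.SynthSpec(genes=genes, n_cancer=600, seed=19)
    cohort, truth = sd.synth_scna_table(spec, concordant=True, effect_size=3.0)
    table = ag.scna_snv_bias_table(cohort, truth[["gene", "role"]])
    strong = truth.set_index("gene").loc[table["gene"], "tilt_snv"].abs() > 1.0
    agree = np.sign(table.loc[strong.to_numpy(), "snv_bias"]) == np.sign(
        table.loc[strong.to_numpy(), "scna_bias"]
    )
    assert agree.all()


def test_scna_snv_bias_min_freq_filters():
    genes = [sd.GeneSpec("T1", role="tsg")]
    spec = sd.SynthSpec(genes=genes, n_cancer=200, seed=4)
    cohort, truth = sd.synth_scna_table(spec, base_prob=0.02)
    table = ag.scna_snv_bias_table(cohort, truth[["gene", "role"]],
                                   min_freq=0.5)
    assert table.empty
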
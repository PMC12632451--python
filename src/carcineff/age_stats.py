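"""Age-distribution statistics for cancer-genome mutations.

The central quantities: per-gene mutation-weighted mean patient ages with
Wald confidence intervals; the cancer-type-level age-divergence ratio
(between-gene variance of mean ages over the cohort age variance) with a
Kruskal–Wallis p-value; the per-gene age difference of non-synonymous
mutations relative to exome-wide synonymous mutations, tested against a
permutation null (ages shuffled among samples, mutation assignments
fixed); and rank-biserial age-bias comparisons between copy-number and
SNV/indel disruptions of the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortTable, FUNCTIONAL_CLASSES

_SCNA_CLASSES = frozenset({"scna_amp", "scna_del"})


@dataclass
class GeneAgeSummary:
    gene: str
    mean_age: float
    ci_low: float
    ci_high: float
    n_mutations: int
    flags: tuple = ()


@dataclass
class AgeBiasResult:
    """Permutation-test result for one gene's age-difference statistic."""

    gene: str
    delta_age: float
    perm_quantile: float
    young_quantile: float
    p_value: float
    q_value: float
    n_perm: int
    seed: int | None
    flags: tuple = ()


@dataclass
class RankBiserial:
    r: float
    n_with: int
    n_without: int


def _mutation_ages(cohort: CohortTable, gene: str | None, classes) -> np.ndarray:
    """One age per qualifying mutation record (its sample's age)."""
    m = cohort.mutations
    sel = m["mclass"].isin(classes)
    if gene is not None:
        sel &= m["gene"] == gene
    age_of = dict(zip(cohort.samples["sample_id"], cohort.samples["age"]))
    return m.loc[sel, "sample_id"].map(age_of).to_numpy(dtype=float)


def weighted_mean_age(
    cohort: CohortTable,
    gene: str,
    classes=FUNCTIONAL_CLASSES,
    cluster_robust: bool = False,
) -> GeneAgeSummary:
    """Mean patient age weighted by the gene's mutation count, with a 95%
    Wald CI.

    Each mutation contributes its sample's age once, so a sample with k
    qualifying mutations carries weight k.  The default SE treats
    per-mutation ages as independent; ``cluster_robust`` clusters on the
    sample (mutations within one sample share an age).
    """
    ages = _mutation_ages(cohort, gene, classes)
    n = len(ages)
    if n == 0:
        return GeneAgeSummary(gene, np.nan, np.nan, np.nan, 0, ("no_data",))
    mean = float(ages.mean())
    if cluster_robust:
        m = cohort.mutations
        sel = (m["gene"] == gene) & m["mclass"].isin(classes)
        counts = m[sel].groupby("sample_id").size()
        age_of = dict(zip(cohort.samples["sample_id"], cohort.samples["age"]))
        a = np.array([age_of[s] for s in counts.index], dtype=float)
        c = counts.to_numpy(dtype=float)
        se = float(np.sqrt(np.sum(c ** 2 * (a - mean) ** 2)) / c.sum())
    else:
        se = float(ages.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GeneAgeSummary(gene, mean, mean - 1.96 * se, mean + 1.96 * se, n)


def age_divergence(cohort: CohortTable, genes, classes=FUNCTIONAL_CLASSES):
    """Degree of age divergence between driver genes, and Kruskal–Wallis p.

    Ratio = mutation-count-weighted between-gene variance of per-gene mean
    mutation ages, divided by the (population) variance of the cohort's
    patient ages.  The Kruskal–Wallis test (midranks, tie-corrected, as in
    scipy) probes whether mutation ages are independent of gene identity.
    """
    per_gene = []
    for gene in genes:
        ages = _mutation_ages(cohort, gene, classes)
        if len(ages):
            per_gene.append((gene, ages))
    if len(per_gene) < 2:
        raise ValueError("age divergence requires >= 2 genes with mutations")
    means = np.array([a.mean() for _, a in per_gene])
    weights = np.array([len(a) for _, a in per_gene], dtype=float)
    grand = np.sum(weights * means) / weights.sum()
    between = np.sum(weights * (means - grand) ** 2) / weights.sum()
    pop_var = cohort.samples["age"].to_numpy(dtype=float).var()
    if pop_var == 0:
        raise ValueError("degenerate cohort: all patient ages equal")
    _, kw_p = stats.kruskal(*[a for _, a in per_gene])
    return float(between / pop_var), float(kw_p)


def age_difference_vs_synonymous(
    cohort: CohortTable, gene: str, classes=FUNCTIONAL_CLASSES
) -> float:
    """Gene's weighted mean mutation age minus the exome-wide synonymous
    weighted mean age.  Returns NaN when either class is empty."""
    gene_ages = _mutation_ages(cohort, gene, classes)
    syn_ages = _mutation_ages(cohort, None, {"synonymous"})
    if len(gene_ages) == 0 or len(syn_ages) == 0:
        return np.nan
    return float(gene_ages.mean() - syn_ages.mean())


def _count_matrix(cohort: CohortTable, genes, classes):
    """(len(genes), n_samples) matrix of qualifying mutation counts."""
    sample_ids = cohort.samples["sample_id"].to_numpy()
    pos = {s: i for i, s in enumerate(sample_ids)}
    C = np.zeros((len(genes), len(sample_ids)))
    m = cohort.mutations
    sel = m["mclass"].isin(classes) & m["gene"].isin(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    for g, s in zip(m.loc[sel, "gene"], m.loc[sel, "sample_id"]):
        C[gidx[g], pos[s]] += 1
    return C


def permutation_test(
    cohort: CohortTable,
    genes,
    n_perm: int = 1000,
    seed: int | None = None,
    classes=FUNCTIONAL_CLASSES,
) -> list[AgeBiasResult]:
    """Permutation test of the no-carcinogenicity age prediction per gene.

    The statistic is the gene's non-synonymous (plus indel) weighted mean
    age minus the exome-wide synonymous weighted mean age.  The null
    distribution permutes patient ages among samples while keeping every
    mutation attached to its sample.  The reported quantile places the
    observed statistic among the permuted ones; the two-sided p-value is
    2 * min(lower, upper tail), floored at 1/(n_perm + 1); q-values are
    Benjamini–Hochberg across the gene list.  The one-sided young-bias
    quantile is reported alongside.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = list(genes)
    ages = cohort.samples["age"].to_numpy(dtype=float)
    C = _count_matrix(cohort, genes, classes)
    # synonymous counts are exome-wide (no gene filter)
    m = cohort.mutations
    sample_ids = cohort.samples["sample_id"].to_numpy()
    pos = {s: i for i, s in enumerate(sample_ids)}
    syn = np.zeros(len(sample_ids))
    for s in m.loc[m["mclass"] == "synonymous", "sample_id"]:
        syn[pos[s]] += 1

    degenerate = np.ptp(ages) == 0 or syn.sum() == 0
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, len(ages)))
    for i in range(n_perm):
        perms[i] = rng.permutation(ages)

    gene_tot = C.sum(axis=1)
    syn_tot = syn.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = (C @ ages) / gene_tot - (syn @ ages) / syn_tot
        null = (C @ perms.T) / gene_tot[:, None] - (perms @ syn)[None, :] / syn_tot

    results = []
    pvals = []
    for i, gene in enumerate(genes):
        flags = ("uninformative",) if degenerate else ()
        if gene_tot[i] == 0:
            results.append(
                AgeBiasResult(gene, np.nan, np.nan, np.nan, np.nan, np.nan,
                              n_perm, seed, ("no_data",))
            )
            pvals.append(np.nan)
            continue
        nd = null[i]
        n_le = int(np.sum(nd <= obs[i]))
        n_ge = int(np.sum(nd >= obs[i]))
        q_low = (1 + n_le) / (n_perm + 1)
        q_high = (1 + n_ge) / (n_perm + 1)
        n_lt = int(np.sum(nd < obs[i]))
        n_eq = int(np.sum(nd == obs[i]))
        quantile = (n_lt + 0.5 * n_eq) / n_perm
        p = min(1.0, max(2 * min(q_low, q_high), 1.0 / (n_perm + 1)))
        results.append(
            AgeBiasResult(gene, float(obs[i]), float(quantile), float(q_low),
                          float(p), np.nan, n_perm, seed, flags)
        )
        pvals.append(p)
    pvals = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(pvals)
    if ok.any():
        qvals = np.full(len(pvals), np.nan)
        qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for res, q in zip(results, qvals):
            res.q_value = float(q) if not np.isnan(q) else np.nan
    return results


def rank_biserial_age_bias(ages_with, ages_without) -> RankBiserial:
    """Rank-biserial correlation between carrier and non-carrier ages.

    r = (#pairs carrier older - #pairs carrier younger) / (n1 n2), with
    ties contributing zero; equivalently 2U/(n1 n2) - 1 with midrank-tied
    Mann–Whitney U.  Positive r means carriers are older.
    """
    x = np.asarray(list(ages_with), dtype=float)
    y = np.asarray(list(ages_without), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both carrier and non-carrier groups must be non-empty")
    U = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    r = 2.0 * U / (len(x) * len(y)) - 1.0
    return RankBiserial(float(r), len(x), len(y))


def scna_snv_bias_table(
    cohort: CohortTable, roles: pd.DataFrame, min_freq: float = 0.05
) -> pd.DataFrame:
    """Paired SCNA vs. SNV/indel age biases per gene, excluding co-occurrence.

    ``roles`` has columns ``gene`` and ``role`` (tsg or oncogene).  For each
    gene the SNV bias is computed among samples with no SCNA in the gene;
    the SCNA bias (deletions for TSGs, amplifications for oncogenes) among
    samples with no non-synonymous SNV/indel in the gene.  A gene is kept
    only when both alteration types occur in at least ``min_freq`` of
    samples.  Returns a DataFrame (possibly empty) with one row per gene.
    """
    m = cohort.mutations
    age_of = dict(zip(cohort.samples["sample_id"], cohort.samples["age"]))
    all_ids = set(cohort.samples["sample_id"])
    n_total = len(all_ids)
    rows = []
    for _, rec in roles.iterrows():
        gene, role = rec["gene"], rec["role"]
        scna_class = "scna_del" if role == "tsg" else "scna_amp"
        snv_ids = cohort.samples_with_gene(gene, FUNCTIONAL_CLASSES)
        any_scna_ids = cohort.samples_with_gene(gene, _SCNA_CLASSES)
        scna_ids = cohort.samples_with_gene(gene, {scna_class})
        if len(snv_ids) < min_freq * n_total or len(scna_ids) < min_freq * n_total:
            continue
        # SNV bias among samples without any SCNA in the gene
        pool = all_ids - any_scna_ids
        carriers = snv_ids & pool
        others = pool - snv_ids
        if not carriers or not others:
            continue
        r_snv = rank_biserial_age_bias(
            [age_of[s] for s in carriers], [age_of[s] for s in others]
        )
        # SCNA bias among samples without any SNV/indel in the gene
        pool2 = all_ids - snv_ids
        carriers2 = scna_ids & pool2
        others2 = pool2 - any_scna_ids
        if not carriers2 or not others2:
            continue
        r_scna = rank_biserial_age_bias(
            [age_of[s] for s in carriers2], [age_of[s] for s in others2]
        )
        rows.append(
            {
                "gene": gene, "role": role,
                "snv_bias": r_snv.r, "scna_bias": r_scna.r,
                "n_snv": len(carriers), "n_scna": len(carriers2),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "role", "snv_bias", "scna_bias", "n_snv", "n_scna"]
    )
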
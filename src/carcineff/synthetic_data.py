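"""Synthetic cohort generators with known ground truth.

Every fixture the estimators and tests need is generated here: matched
cancer/normal cohorts with planted per-gene mutant cell fractions x and
carcinogenic effects w, normal-tissue VAF tables obeying the bulk
observation rules (factor of two, male X, detection floor), age-structured
cohorts with planted young/old biases for calibrating the permutation
test, and SCNA/SNV tables with controllable age-bias concordance.  Truth
tables are always emitted alongside the data, and all generators are
reproducible from (spec, seed).

The inverse of the odds-ratio estimator drives the matched generator: a
gene carried at fraction x in normal cells with effect w is mutated in a
cancer founder with probability y = w x / (1 - x + w x).

Defaults emulate adult-blood-like designs: ages uniform on (36, 90) and
per-sample fraction noise Beta-distributed around x with precision 50, so
the estimators are exercised under over-dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, from_frames


@dataclass
class GeneSpec:
    """Planted truth for one gene."""

    name: str
    coding_length: int = 1500
    x: float | None = 0.01       # true mean mutant cell fraction
    w: float = 1.0               # true carcinogenic effect
    s: float | None = None       # selective effect; drives x when given
    role: str = "tsg"


@dataclass
class SynthSpec:
    """Full specification of a synthetic study."""

    genes: list[GeneSpec] = field(default_factory=list)
    n_cancer: int = 500
    n_normal: int = 500
    age_low: float = 36.0
    age_high: float = 90.0
    beta_precision: float = 50.0
    depth: int | None = None     # binomial read depth; None = noiseless
    x0: float = 0.0              # detection floor on cell fractions
    clone_rate: float = 1e-4     # per-cell acquisition rate when s drives x
    seed: int = 0


def founder_frequency(x: float, w: float) -> float:
    """Cancer-founder mutation frequency implied by (x, w):
    y = w x / (1 - x + w x), the inverse of the odds-ratio map."""
    if not 0.0 < x < 1.0:
        raise ValueError("x must be in (0, 1)")
    if w <= 0:
        raise ValueError("w must be positive")
    return w * x / (1.0 - x + w * x)


def _expected_fraction(gene: GeneSpec, ages, spec: SynthSpec):
    """Per-sample expected fraction: constant x, or the exponential-clone
    expectation v (e^{s t} - 1)/s when the gene is specified through s."""
    if gene.s is None:
        if gene.x is None:
            raise ValueError(f"gene {gene.name}: specify x or s")
        return np.full(len(ages), gene.x)
    s, v = gene.s, spec.clone_rate
    with np.errstate(over="raise"):
        ex = v * ages if s == 0 else v * (np.expm1(s * ages)) / s
    return np.clip(ex, 1e-9, 0.9)


def _sample_frame(prefix, n, ages, tissue, rng):
    return pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i}" for i in range(n)],
            "donor_id": [f"{prefix}d{i}" for i in range(n)],
            "age": ages,
            "sex": rng.choice(["male", "female"], size=n),
            "tissue_state": tissue,
            "cohort_label": "synthetic",
            "burden": np.nan,
        }
    )


def _empty_mutations():
    return pd.DataFrame(
        columns=["sample_id", "gene", "mclass", "chrom", "pos", "ref", "alt", "vaf"]
    )


def _mutation_frame(rows):
    if not rows:
        return _empty_mutations()
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "mclass", "chrom", "pos", "ref",
                       "alt", "vaf"]
    )


def synth_matched_cohort(spec: SynthSpec):
    """Matched cancer/normal cohorts with planted (x, w) per gene.

    Normal samples carry per-gene mutant fractions drawn from a Beta law
    with mean x (or the clone-growth expectation when s is given) and
    precision ``spec.beta_precision``; the fraction is written as a
    diploid-autosome VAF (fraction / 2).  Cancer samples carry Bernoulli(y)
    gene indicators with y from :func:`founder_frequency`.  Fractions below
    the detection floor x0 are unobserved.

    Returns ``(cancer, normal, truth)`` where truth records (gene, x, y, w).
    """
    rng = np.random.default_rng(spec.seed)
    ages_c = rng.uniform(spec.age_low, spec.age_high, spec.n_cancer)
    ages_n = rng.uniform(spec.age_low, spec.age_high, spec.n_normal)
    cancer_samples = _sample_frame("C", spec.n_cancer, ages_c, "cancer", rng)
    normal_samples = _sample_frame("N", spec.n_normal, ages_n, "normal", rng)

    c_rows, n_rows, truth = [], [], []
    for gene in spec.genes:
        ex_n = _expected_fraction(gene, ages_n, spec)
        prec = spec.beta_precision
        frac = rng.beta(ex_n * prec, (1.0 - ex_n) * prec)
        observed = frac >= spec.x0 if spec.x0 > 0 else frac > 0
        for sid, f, ok in zip(normal_samples["sample_id"], frac, observed):
            if ok:
                n_rows.append((sid, gene.name, "nonsynonymous_snv", "chr1",
                               np.nan, np.nan, np.nan, f / 2.0))
        ex_c = _expected_fraction(gene, ages_c, spec)
        y = np.array([founder_frequency(x, gene.w) for x in ex_c])
        hit = rng.random(spec.n_cancer) < y
        for sid in cancer_samples.loc[hit, "sample_id"]:
            c_rows.append((sid, gene.name, "nonsynonymous_snv", "chr1",
                           np.nan, np.nan, np.nan, np.nan))
        truth.append(
            {"gene": gene.name, "x": float(np.mean(ex_n)),
             "y": float(np.mean(y)), "w": gene.w}
        )
    cancer = from_frames(cancer_samples, _mutation_frame(c_rows),
                         ["synthetic matched cohort (cancer arm)"])
    normal = from_frames(normal_samples, _mutation_frame(n_rows),
                         ["synthetic matched cohort (normal arm)"])
    return cancer, normal, pd.DataFrame(truth)


def synth_vaf_table(spec: SynthSpec):
    """Normal cohort whose VAFs carry binomial read noise and a detection
    floor.

    True fractions are drawn as in :func:`synth_matched_cohort`; the VAF is
    fraction / 2 (diploid autosome) resampled as Binomial(depth, vaf)/depth
    when ``spec.depth`` is set; observed VAFs below x0 / 2 are dropped.

    Returns ``(normal, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(spec.age_low, spec.age_high, spec.n_normal)
    samples = _sample_frame("N", spec.n_normal, ages, "normal", rng)
    rows, truth = [], []
    floor_vaf = spec.x0 / 2.0
    for gene in spec.genes:
        ex = _expected_fraction(gene, ages, spec)
        frac = rng.beta(ex * spec.beta_precision, (1.0 - ex) * spec.beta_precision)
        vaf = frac / 2.0
        if spec.depth is not None:
            vaf = rng.binomial(spec.depth, vaf) / spec.depth
        keep = vaf >= floor_vaf if floor_vaf > 0 else vaf > 0
        for sid, vv, ok in zip(samples["sample_id"], vaf, keep):
            if ok:
                rows.append((sid, gene.name, "nonsynonymous_snv", "chr1",
                             np.nan, np.nan, np.nan, vv))
        truth.append({"gene": gene.name, "x": float(np.mean(ex)), "w": gene.w})
    normal = from_frames(samples, _mutation_frame(rows),
                         ["synthetic VAF table"])
    return normal, pd.DataFrame(truth)


def synth_logistic_cohort(
    spec: SynthSpec,
    w: float,
    a: float = 4.0,
    b: float = 0.0,
    c: float = 0.0,
    burden_mean: float = 50.0,
):
    """Samples table drawn from the logistic carcinogenic-effect model.

    Normal units represent single-cell-derived colonies, so mutation
    presence is Bernoulli in both arms, with
    P(mutated) = w^chi / (w^chi + exp(a + b t + c m)) where chi is the
    cancer indicator, t the age and m the exonic burden
    (Poisson(``burden_mean``) per sample).  Ages are uniform on the spec's
    range.  Returns ``(samples, truth)`` where ``samples`` has the columns
    :func:`carcineff.carcino_effect.fit_logistic_effect` expects and
    ``truth`` records (w, a, b, c).
    """
    rng = np.random.default_rng(spec.seed)
    n_c, n_n = spec.n_cancer, spec.n_normal
    ages = rng.uniform(spec.age_low, spec.age_high, n_c + n_n)
    group = np.concatenate([np.ones(n_c, dtype=int), np.zeros(n_n, dtype=int)])
    burden = rng.poisson(burden_mean, n_c + n_n).astype(float)
    lw = np.log(w)
    p = 1.0 / (1.0 + np.exp(a + b * ages + c * burden - lw * group))
    mutated = (rng.random(n_c + n_n) < p).astype(int)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n_c + n_n)],
            "age": ages,
            "burden": burden,
            "group": group,
            "mutated": mutated,
        }
    )
    truth = pd.DataFrame([{"w": w, "a": a, "b": b, "c": c}])
    return samples, truth


def synth_age_cohort(
    spec: SynthSpec,
    mode: str = "null",
    effect_size: float = 2.0,
    n_planted: int | None = None,
    base_prob: float = 0.1,
    syn_rate: tuple = (3.0, 0.05),
):
    """Cancer cohort for calibrating / powering the age-bias permutation test.

    ``null`` mode: per-gene mutation probabilities and the synonymous
    background are independent of age, so permuting ages is exact.
    ``young_bias`` / ``old_bias`` modes tilt the first ``n_planted`` genes'
    mutation probability by a logistic factor in standardised age with the
    given log-odds effect size.  Synonymous background counts are Poisson
    with rate ``syn_rate[0] + syn_rate[1] * age`` (neutral mutations
    accumulate with age) except in null mode, where the rate is the value
    at the mean age for every sample.

    Returns ``(cohort, truth)``; truth marks which genes were tilted.
    """
    if mode not in {"null", "young_bias", "old_bias"}:
        raise ValueError(f"unknown mode: {mode}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cancer
    ages = rng.uniform(spec.age_low, spec.age_high, n)
    samples = _sample_frame("S", n, ages, "cancer", rng)
    z = (ages - ages.mean()) / ages.std()
    if n_planted is None:
        n_planted = len(spec.genes) if mode != "null" else 0
    rows, truth = [], []
    for j, gene in enumerate(spec.genes):
        tilted = mode != "null" and j < n_planted
        logit = np.log(base_prob / (1 - base_prob)) * np.ones(n)
        if tilted:
            sign = -1.0 if mode == "young_bias" else 1.0
            logit = logit + sign * effect_size * z
        p = 1.0 / (1.0 + np.exp(-logit))
        hit = rng.random(n) < p
        for sid in samples.loc[hit, "sample_id"]:
            rows.append((sid, gene.name, "nonsynonymous_snv", "chr1",
                         np.nan, np.nan, np.nan, np.nan))
        truth.append({"gene": gene.name, "tilted": tilted, "mode": mode})
    lam0, lam1 = syn_rate
    lam = (np.full(n, lam0 + lam1 * ages.mean()) if mode == "null"
           else lam0 + lam1 * ages)
    syn_counts = rng.poisson(lam)
    for sid, k in zip(samples["sample_id"], syn_counts):
        for j in range(k):
            rows.append((sid, "syn_background", "synonymous", "chr2",
                         float(j), np.nan, np.nan, np.nan))
    cohort = from_frames(samples, _mutation_frame(rows),
                         [f"synthetic age cohort (mode={mode})"])
    return cohort, pd.DataFrame(truth)


def synth_scna_table(
    spec: SynthSpec,
    concordant: bool = True,
    effect_size: float = 1.5,
    base_prob: float = 0.15,
    cooccurrence: float = 0.0,
):
    """Cohort with SCNA and SNV records and planted age-bias structure.

    Each gene gets a latent age tilt for its SNVs; with ``concordant`` the
    gene's SCNAs (deletion for TSGs, amplification for oncogenes) share the
    same tilt, otherwise their tilt is drawn independently.
    ``cooccurrence`` adds that probability of the other alteration to
    carriers of one.  Returns ``(cohort, truth)`` with the per-gene tilts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cancer
    ages = rng.uniform(spec.age_low, spec.age_high, n)
    samples = _sample_frame("S", n, ages, "cancer", rng)
    z = (ages - ages.mean()) / ages.std()
    rows, truth = [], []
    base_logit = np.log(base_prob / (1 - base_prob))
    for gene in spec.genes:
        tilt_snv = rng.uniform(-effect_size, effect_size)
        tilt_scna = tilt_snv if concordant else rng.uniform(-effect_size, effect_size)
        scna_class = "scna_del" if gene.role == "tsg" else "scna_amp"
        p_snv = 1.0 / (1.0 + np.exp(-(base_logit + tilt_snv * z)))
        p_scna = 1.0 / (1.0 + np.exp(-(base_logit + tilt_scna * z)))
        snv_hit = rng.random(n) < p_snv
        scna_hit = rng.random(n) < p_scna
        if cooccurrence > 0:
            scna_hit |= snv_hit & (rng.random(n) < cooccurrence)
        for sid in samples.loc[snv_hit, "sample_id"]:
            rows.append((sid, gene.name, "nonsynonymous_snv", "chr1",
                         np.nan, np.nan, np.nan, np.nan))
        for sid in samples.loc[scna_hit, "sample_id"]:
            rows.append((sid, gene.name, scna_class, "chr1",
                         np.nan, np.nan, np.nan, np.nan))
        truth.append({"gene": gene.name, "role": gene.role,
                      "tilt_snv": tilt_snv, "tilt_scna": tilt_scna})
    cohort = from_frames(samples, _mutation_frame(rows),
                         ["synthetic SCNA/SNV cohort"])
    return cohort, pd.DataFrame(truth)


def write_fixture_dir(out_dir, cancer=None, normal=None, genes=None, truth=None):
    """Write generated tables as the TSV dialects cohort_io reads."""
    import os

    os.makedirs(out_dir, exist_ok=True)

    def dump(cohort: CohortTable, tag: str):
        s = cohort.samples.rename(
            columns={"age": "age_years", "tissue_state": "tissue",
                     "cohort_label": "cohort"}
        ).copy()
        s["sex"] = s["sex"].map({"male": "M", "female": "F", "unknown": "NA"})
        s.to_csv(os.path.join(out_dir, f"samples_{tag}.tsv"), sep="\t", index=False)
        cohort.mutations.to_csv(
            os.path.join(out_dir, f"mutations_{tag}.tsv"), sep="\t", index=False
        )

    if cancer is not None:
        dump(cancer, "cancer")
    if normal is not None:
        dump(normal, "normal")
    if genes is not None:
        genes.to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t", index=False)
    if truth is not None:
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
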
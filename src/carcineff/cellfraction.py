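"""Mutant-cell-fraction estimation from VAFs in bulk normal tissue.

A variant allele frequency (VAF) in a bulk sample is converted to the
fraction of cells carrying the mutation under the simplifying assumption
of diploidy and heterozygosity: fraction = 2 x VAF.  Two special cases:
when 2 x VAF exceeds one (possible loss of heterozygosity) the fraction is
taken to be the VAF itself, and for the male X chromosome (hemizygous) the
fraction equals the VAF.  Per-gene, per-sample fractions are the sum of the
gene's mutation fractions (mutations in distinct cells) unless the sum
exceeds one, in which case the maximum is used (mutations in the same
cells).  Cohort-level estimates are means across samples, with percentile
bootstrap confidence intervals from resampling donors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, FUNCTIONAL_CLASSES

_X_CHROMS = {"X", "chrX", "x", "chrx"}


@dataclass
class CellFractionEstimate:
    """Cohort-mean fraction of cells carrying a mutation in a gene."""

    gene: str
    mean_fraction: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_samples: int = 0
    n_bootstrap: int = 0
    flags: tuple = ()


def vaf_to_cell_fraction(vaf: float, chrom: str, sex: str) -> float:
    """Convert one mutation's VAF to an estimated fraction of mutant cells.

    Autosomes and female/unknown-sex X: 2*vaf, capped at vaf when 2*vaf > 1
    (interpreted as possible loss of heterozygosity).  Male X: vaf.
    Unknown sex is treated as female (diploid X), the conservative
    factor-of-two choice, with a warning.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    on_x = str(chrom) in _X_CHROMS
    if on_x and sex == "unknown":
        warnings.warn(
            "sex unknown for X-chromosome mutation; assuming diploid X",
            stacklevel=2,
        )
    if on_x and sex == "male":
        return float(vaf)
    doubled = 2.0 * vaf
    return float(vaf) if doubled > 1.0 else float(doubled)


def gene_sample_fraction(fractions) -> float:
    """Combine one gene's per-mutation cell fractions within one sample.

    Sum if the sum is at most one (mutations in distinct cells), else the
    maximum (mutations co-occurring in the same cells).  Empty input -> 0.
    """
    fractions = list(fractions)
    if not fractions:
        return 0.0
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("cell fractions must lie in [0, 1]")
    total = float(np.sum(fractions))
    return total if total <= 1.0 else float(np.max(fractions))


def _per_sample_fractions(
    normal: CohortTable, gene: str, classes=FUNCTIONAL_CLASSES
) -> pd.Series:
    """Per-sample mutant cell fraction for ``gene`` (0 for unmutated samples).

    Indexed by sample_id, covering every sample in the cohort.
    """
    m = normal.mutations
    hits = m[(m["gene"] == gene) & (m["mclass"].isin(classes)) & m["vaf"].notna()]
    sex_of = dict(zip(normal.samples["sample_id"], normal.samples["sex"]))
    per_sample = {}
    for sid, grp in hits.groupby("sample_id"):
        fr = [
            vaf_to_cell_fraction(v, c, sex_of[sid])
            for v, c in zip(grp["vaf"], grp["chrom"])
        ]
        per_sample[sid] = gene_sample_fraction(fr)
    return pd.Series(per_sample).reindex(normal.samples["sample_id"], fill_value=0.0)


def _donor_values(normal: CohortTable, per_sample: pd.Series, per_donor: bool):
    """Reduce per-sample fractions to the unit that is resampled / averaged.

    ``per_donor=True`` averages a donor's (possibly longitudinal) samples
    before the cohort mean; otherwise samples are pooled directly but the
    bootstrap still resamples donors (keeping a donor's samples together).
    """
    donors = normal.samples["donor_id"].to_numpy()
    df = pd.DataFrame({"donor": donors, "frac": per_sample.to_numpy()})
    if per_donor:
        g = df.groupby("donor")["frac"].mean()
        return g.to_numpy(), np.ones(len(g))
    g = df.groupby("donor")["frac"].agg(["sum", "count"])
    return g["sum"].to_numpy(), g["count"].to_numpy()


def cohort_mean_fraction(
    normal: CohortTable, gene: str, classes=FUNCTIONAL_CLASSES, per_donor: bool = False
) -> CellFractionEstimate:
    """Point estimate of the cohort-mean mutant cell fraction for ``gene``.

    Mean over samples of the per-sample fraction; unmutated samples
    contribute zero.  With ``per_donor`` each donor's samples are averaged
    first and the mean runs over donors.
    """
    per_sample = _per_sample_fractions(normal, gene, classes)
    sums, counts = _donor_values(normal, per_sample, per_donor)
    mean = float(sums.sum() / counts.sum()) if counts.sum() else 0.0
    flags = ("unmutated_in_cohort",) if per_sample.sum() == 0 else ()
    return CellFractionEstimate(
        gene=gene, mean_fraction=mean, n_samples=normal.n_samples, flags=flags
    )


def bootstrap_ci(
    normal: CohortTable,
    gene: str,
    B: int = 1000,
    seed: int | None = None,
    classes=FUNCTIONAL_CLASSES,
    per_donor: bool = False,
) -> CellFractionEstimate:
    """Cohort-mean fraction with a 95% percentile bootstrap CI.

    The resampling unit is the donor: a resample draws donors with
    replacement and carries all of each donor's samples.
    """
    if B < 1:
        raise ValueError("number of bootstrap resamples B must be >= 1")
    est = cohort_mean_fraction(normal, gene, classes, per_donor)
    per_sample = _per_sample_fractions(normal, gene, classes)
    sums, counts = _donor_values(normal, per_sample, per_donor)
    rng = np.random.default_rng(seed)
    n = len(sums)
    idx = rng.integers(0, n, size=(B, n))
    boot = sums[idx].sum(axis=1) / counts[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    est.ci_low, est.ci_high = float(lo), float(hi)
    est.n_bootstrap = B
    return est
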
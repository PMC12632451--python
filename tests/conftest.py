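"""Shared fixtures: small hand-built cohorts with known expected values."""

import numpy as np
import pandas as pd
import pytest

from carcineff import cohort_io as cio


def make_samples(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "donor_id", "age", "sex", "tissue_state",
                 "cohort_label", "burden"],
    )


def make_mutations(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "mclass", "chrom", "pos", "ref", "alt",
                 "vaf"],
    )


@pytest.fixture
def toy_normal():
    """Three normal samples (two from one donor) with TP53/DNMT3A hits.

    Hand-computed gene fractions for TP53 (nonsyn+indel classes):
      s1: 2*0.1 + 2*0.3 = 0.8   (autosome, sum <= 1)
      s2: 0.4                   (male X -> fraction = VAF)
      s3: 0                     (no TP53 mutation)
    """
    samples = make_samples([
        ("s1", "d1", 50.0, "male", "normal", "toy", 10.0),
        ("s2", "d1", 55.0, "male", "normal", "toy", 12.0),
        ("s3", "d2", 60.0, "female", "normal", "toy", 300.0),
    ])
    muts = make_mutations([
        ("s1", "TP53", "nonsynonymous_snv", "chr17", 100.0, "A", "T", 0.1),
        ("s1", "TP53", "indel", "chr17", 200.0, "AT", "A", 0.3),
        ("s2", "TP53", "nonsynonymous_snv", "chrX", 300.0, "G", "C", 0.4),
        ("s3", "DNMT3A", "nonsynonymous_snv", "chr2", np.nan, np.nan, np.nan, 0.6),
    ])
    return cio.from_frames(samples, muts, ["toy normal"])


@pytest.fixture
def toy_cancer():
    """Four cancer samples; TP53 mutated in two of four."""
    samples = make_samples([
        ("c1", "e1", 61.0, "female", "cancer", "toy", 40.0),
        ("c2", "e2", 72.0, "male", "cancer", "toy", 55.0),
        ("c3", "e3", 55.0, "male", "cancer", "toy", 38.0),
        ("c4", "e4", 68.0, "female", "cancer", "toy", 61.0),
    ])
    muts = make_mutations([
        ("c1", "TP53", "nonsynonymous_snv", "chr17", 100.0, "A", "T", np.nan),
        ("c2", "TP53", "indel", "chr17", 150.0, "AT", "A", np.nan),
        ("c2", "KRAS", "nonsynonymous_snv", "chr12", 500.0, "G", "A", np.nan),
        ("c3", "TP53", "synonymous", "chr17", 120.0, "C", "T", np.nan),
    ])
    return cio.from_frames(samples, muts, ["toy cancer"])
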
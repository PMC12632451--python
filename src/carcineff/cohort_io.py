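"""Reading, validation and filtering of mutation/sample/gene tables.

The canonical in-memory representation is :class:`CohortTable`, a pair of
pandas DataFrames (samples, mutations) with referential integrity between
them plus a free-text provenance log of every filter applied.  All other
modules consume this container.

Input dialects (tab-separated, header required):

* ``mutations.tsv`` — sample_id, gene, mclass, chrom, and optionally
  pos, ref, alt, vaf ("NA" allowed for vaf).
* ``samples.tsv`` — sample_id, donor_id, age_years, sex (M/F/NA),
  tissue (cancer/normal), cohort, and optionally burden.
* ``genes.tsv`` — gene, coding_length_bp, chrom, start, end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: recognised mutation classes
MUTATION_CLASSES = frozenset(
    {"synonymous", "nonsynonymous_snv", "indel", "scna_amp", "scna_del"}
)
#: classes counted towards a sample's exonic SNV/indel burden
BURDEN_CLASSES = frozenset({"synonymous", "nonsynonymous_snv", "indel"})
#: classes used by default when asking whether a gene is "mutated"
FUNCTIONAL_CLASSES = frozenset({"nonsynonymous_snv", "indel"})

SAMPLE_COLUMNS = ["sample_id", "donor_id", "age", "sex", "tissue_state", "cohort_label"]
MUTATION_COLUMNS = ["sample_id", "gene", "mclass", "chrom"]

_SEX_MAP = {"M": "male", "F": "female", "NA": "unknown", "male": "male",
            "female": "female", "unknown": "unknown"}


class CohortFormatError(ValueError):
    """A table does not conform to the expected TSV dialect."""


class CohortValidationError(ValueError):
    """Tables are well-formed but internally inconsistent."""


@dataclass
class CohortTable:
    """Validated cohort: sample metadata, mutation records, provenance log.

    ``samples`` columns: sample_id, donor_id, age, sex, tissue_state,
    cohort_label, burden (NaN until :func:`compute_burden` runs).
    ``mutations`` columns: sample_id, gene, mclass, chrom, pos, ref, alt, vaf.
    """

    samples: pd.DataFrame
    mutations: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.samples.copy(), self.mutations.copy(), list(self.provenance)
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_donors(self) -> int:
        return self.samples["donor_id"].nunique()

    def samples_with_gene(self, gene: str, classes=FUNCTIONAL_CLASSES) -> set:
        """Sample ids carrying >=1 mutation of the given classes in ``gene``."""
        m = self.mutations
        hit = m[(m["gene"] == gene) & (m["mclass"].isin(classes))]
        return set(hit["sample_id"])


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{what} table is missing required column(s): {', '.join(missing)}"
        )


def _normalise_samples(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(
        df, ["sample_id", "donor_id", "age_years", "sex", "tissue", "cohort"],
        "samples",
    )
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "donor_id": df["donor_id"].astype(str),
            "age": pd.to_numeric(df["age_years"], errors="coerce"),
            "sex": df["sex"].fillna("NA").astype(str).map(lambda s: _SEX_MAP.get(s, None)),
            "tissue_state": df["tissue"].astype(str),
            "cohort_label": df["cohort"].astype(str),
        }
    )
    if out["sex"].isna().any():
        bad = sorted(df.loc[out["sex"].isna(), "sex"].astype(str).unique())
        raise CohortFormatError(f"unrecognised sex value(s): {bad} (expected M/F/NA)")
    bad_tissue = ~out["tissue_state"].isin(["cancer", "normal"])
    if bad_tissue.any():
        raise CohortFormatError(
            "tissue must be 'cancer' or 'normal'; offending values: "
            f"{sorted(out.loc[bad_tissue, 'tissue_state'].unique())}"
        )
    out["burden"] = (
        pd.to_numeric(df["burden"], errors="coerce") if "burden" in df.columns
        else np.nan
    )
    return out


def _normalise_mutations(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, MUTATION_COLUMNS, "mutations")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["gene"] = out["gene"].astype(str)
    out["mclass"] = out["mclass"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for col in ("pos", "ref", "alt", "vaf"):
        if col not in out.columns:
            out[col] = np.nan
    out["vaf"] = pd.to_numeric(out["vaf"].replace("NA", np.nan), errors="coerce")
    bad_class = ~out["mclass"].isin(MUTATION_CLASSES)
    if bad_class.any():
        raise CohortFormatError(
            f"unrecognised mclass value(s): {sorted(out.loc[bad_class, 'mclass'].unique())}"
        )
    bad_vaf = out["vaf"].notna() & ((out["vaf"] < 0) | (out["vaf"] > 1))
    if bad_vaf.any():
        raise CohortFormatError("column vaf contains values outside [0, 1]")
    return out[["sample_id", "gene", "mclass", "chrom", "pos", "ref", "alt", "vaf"]]


def validate_cohort(samples: pd.DataFrame, mutations: pd.DataFrame) -> None:
    """Check invariants: unique sample ids, non-negative ages, referential
    integrity between mutation and sample tables."""
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        raise CohortValidationError(
            f"duplicate sample_id(s) in sample table: {sorted(dup.unique())}"
        )
    if (samples["age"] < 0).any():
        raise CohortValidationError("negative ages in sample table")
    orphans = set(mutations["sample_id"]) - set(samples["sample_id"])
    if orphans:
        raise CohortValidationError(
            f"mutations reference unknown sample_id(s): {sorted(orphans)}"
        )


def from_frames(
    samples: pd.DataFrame, mutations: pd.DataFrame, provenance=None
) -> CohortTable:
    """Build a validated CohortTable from already-normalised frames.

    Rows with missing age are dropped (and counted in provenance) and exact
    duplicate mutation rows are collapsed.
    """
    samples = samples.reset_index(drop=True)
    mutations = mutations.reset_index(drop=True)
    cohort = CohortTable(samples, mutations, list(provenance or []))
    n_unaged = int(cohort.samples["age"].isna().sum())
    if n_unaged:
        keep = cohort.samples["age"].notna()
        cohort.samples = cohort.samples[keep].reset_index(drop=True)
        kept_ids = set(cohort.samples["sample_id"])
        cohort.mutations = cohort.mutations[
            cohort.mutations["sample_id"].isin(kept_ids)
        ].reset_index(drop=True)
        cohort.log(f"dropped {n_unaged} sample(s) with missing age annotation")
    n_before = len(cohort.mutations)
    cohort.mutations = cohort.mutations.drop_duplicates(
        subset=["sample_id", "gene", "mclass", "chrom", "pos", "ref", "alt", "vaf"]
    ).reset_index(drop=True)
    n_dup = n_before - len(cohort.mutations)
    if n_dup:
        cohort.log(f"collapsed {n_dup} duplicate mutation row(s)")
    validate_cohort(cohort.samples, cohort.mutations)
    return cohort


def read_cohort(mutations_path, samples_path, genes_path=None):
    """Read and validate the TSV triplet into a :class:`CohortTable`.

    Returns ``cohort`` or ``(cohort, genes)`` when ``genes_path`` is given.
    Samples with no age annotation are dropped and counted in provenance.
    """
    raw_samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    raw_mutations = pd.read_csv(mutations_path, sep="\t", dtype=str)
    samples = _normalise_samples(raw_samples)
    mutations = _normalise_mutations(raw_mutations)
    cohort = from_frames(
        samples, mutations,
        provenance=[f"read {len(samples)} samples, {len(mutations)} mutations"],
    )
    if genes_path is None:
        return cohort
    genes = read_gene_annotation(genes_path)
    return cohort, genes


def read_gene_annotation(genes_path) -> pd.DataFrame:
    """Read genes.tsv: gene, coding_length_bp, chrom, start, end."""
    genes = pd.read_csv(genes_path, sep="\t")
    _require_columns(genes, ["gene", "coding_length_bp", "chrom", "start", "end"], "genes")
    if (genes["coding_length_bp"] <= 0).any():
        raise CohortValidationError("coding_length_bp must be positive")
    if (genes["start"] > genes["end"]).any():
        raise CohortValidationError("gene start must be <= end")
    return genes


def compute_burden(cohort: CohortTable) -> CohortTable:
    """Populate the per-sample burden (count of exonic SNV/indel records).

    SCNA records are excluded.  Idempotent: recomputing replaces the column.
    """
    out = cohort.copy()
    m = out.mutations
    counts = (
        m[m["mclass"].isin(BURDEN_CLASSES)]
        .groupby("sample_id")
        .size()
        .reindex(out.samples["sample_id"], fill_value=0)
    )
    out.samples = out.samples.assign(burden=counts.to_numpy(dtype=float))
    out.log("computed per-sample mutation burden (SNV/indel classes)")
    return out


def _lower_median(values: np.ndarray) -> float:
    """Lower-interpolation median: deterministic on integer burdens."""
    v = np.sort(np.asarray(values))
    if len(v) == 0:
        raise CohortValidationError("cannot take the median of an empty cohort")
    return float(v[(len(v) - 1) // 2])


def _drop_samples(cohort: CohortTable, keep_mask: np.ndarray, why: str) -> CohortTable:
    out = cohort.copy()
    removed = out.samples.loc[~keep_mask, "sample_id"]
    out.samples = out.samples[keep_mask].reset_index(drop=True)
    kept = set(out.samples["sample_id"])
    out.mutations = out.mutations[out.mutations["sample_id"].isin(kept)].reset_index(
        drop=True
    )
    out.log(f"{why}: removed {len(removed)} sample(s)")
    return out


def filter_by_burden(cohort: CohortTable, factor: float) -> CohortTable:
    """Remove samples whose burden exceeds ``factor`` x the cohort median burden.

    The median is computed over the input cohort, before any removal.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if cohort.n_samples == 0:
        raise CohortValidationError("cannot filter an empty cohort")
    burdens = cohort.samples["burden"].to_numpy(dtype=float)
    if np.isnan(burdens).any():
        raise CohortValidationError("burdens not computed; run compute_burden first")
    cutoff = factor * _lower_median(burdens)
    return _drop_samples(
        cohort, burdens <= cutoff, f"burden filter (> {factor} x median = {cutoff:g})"
    )


def filter_by_burden_ceiling(cohort: CohortTable, ceiling: float) -> CohortTable:
    """Remove samples whose burden exceeds an absolute ceiling."""
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    if cohort.n_samples == 0:
        raise CohortValidationError("cannot filter an empty cohort")
    burdens = cohort.samples["burden"].to_numpy(dtype=float)
    if np.isnan(burdens).any():
        raise CohortValidationError("burdens not computed; run compute_burden first")
    return _drop_samples(
        cohort, burdens <= ceiling, f"burden ceiling filter (> {ceiling:g})"
    )


def _variant_keys(cohort: CohortTable) -> pd.DataFrame:
    """Per-mutation variant identity keyed on (gene, chrom, pos, ref, alt)
    when position columns are populated, else (gene, mclass)."""
    m = cohort.mutations
    keys = pd.Series(
        [
            (g, c, p, r, a) if pd.notna(p) else (g, k)
            for g, c, p, r, a, k in zip(
                m["gene"], m["chrom"], m["pos"], m["ref"], m["alt"], m["mclass"]
            )
        ],
        index=m.index, dtype=object,
    )
    donor_of = dict(zip(cohort.samples["sample_id"], cohort.samples["donor_id"]))
    return pd.DataFrame(
        {"donor_id": m["sample_id"].map(donor_of), "key": keys}
    )


def exclude_shared_mutation_donors(cancer: CohortTable, normal: CohortTable):
    """Remove donors that carry an identical mutation in both their cancer
    and their normal-tissue samples (matched-design contamination guard).

    Returns the filtered ``(cancer, normal)`` pair.  If the two cohorts have
    no donors in common a warning is emitted and both are returned unchanged.
    """
    shared_donors = set(cancer.samples["donor_id"]) & set(normal.samples["donor_id"])
    if not shared_donors:
        warnings.warn(
            "cancer and normal cohorts share no donors; nothing to exclude",
            stacklevel=2,
        )
        return cancer, normal
    ck = _variant_keys(cancer)
    nk = _variant_keys(normal)
    to_remove = set()
    for donor in shared_donors:
        c_set = set(ck.loc[ck["donor_id"] == donor, "key"])
        n_set = set(nk.loc[nk["donor_id"] == donor, "key"])
        if c_set & n_set:
            to_remove.add(donor)
    out = []
    for cohort in (cancer, normal):
        keep = ~cohort.samples["donor_id"].isin(to_remove).to_numpy()
        out.append(
            _drop_samples(
                cohort, keep,
                f"excluded {len(to_remove)} donor(s) sharing a mutation "
                "between cancer and normal tissue",
            )
        )
    return tuple(out)
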
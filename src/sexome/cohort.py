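"""Core cohort tables: ASV counts, taxonomy, sample metadata.

All downstream stages (contaminant filtering, diversity, community state
typing, transfer detection) operate on the three tab-separated tables read
here: an ASV x sample integer count matrix, a per-ASV taxonomy table, and
per-sample metadata describing the couple-paired before/after design.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from sexome.errors import (
    CohortFileError,
    CrossReferenceError,
    DuplicateIdError,
    EmptySampleError,
    InvalidMetadataError,
    NegativeCountError,
    NonIntegerCountError,
    UnknownRankError,
)

#: Sentinel for an unassigned taxonomic rank.  Comparisons are case-sensitive
#: after whitespace trimming; empty strings and NA parse to this sentinel.
UNCLASSIFIED = "unclassified"

#: Taxonomic ranks stored per ASV, most to least inclusive.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

SAMPLE_CLASSES = ("specimen", "extraction_blank", "no_template_control", "mock")
CONTROL_CLASSES = ("extraction_blank", "no_template_control")
SEXES = ("male", "female")
TIMEPOINTS = ("before", "after")

METADATA_COLUMNS = (
    "sample_id",
    "participant_id",
    "couple_id",
    "sex",
    "timepoint",
    "sample_class",
)


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise DuplicateIdError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass(frozen=True)
class AsvCountTable:
    """Non-negative integer read counts, ASVs as rows, samples as columns.

    The single source of truth for every analysis stage.  ``counts`` is an
    integer DataFrame indexed by ASV id with sample ids as columns.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        _check_unique(df.index, "asv_id")
        _check_unique(df.columns, "sample_id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            # accept float input only if every cell is integral
            frac = values != np.floor(values)
            if np.isnan(values).any() or frac.any():
                bad = np.argwhere(np.isnan(values) | frac)[0]
                raise NonIntegerCountError(
                    f"non-integer count at (asv={df.index[bad[0]]!r}, "
                    f"sample={df.columns[bad[1]]!r})"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise NegativeCountError(
                f"negative count at (asv={df.index[bad[0]]!r}, "
                f"sample={df.columns[bad[1]]!r})"
            )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample(self, sample_id: str) -> pd.Series:
        """Count vector of one sample (indexed by ASV)."""
        return self.counts[sample_id]

    def support(self, sample_id: str, min_reads: int = 1) -> frozenset[str]:
        """ASVs detected in a sample at >= ``min_reads`` reads."""
        col = self.counts[sample_id]
        return frozenset(col.index[col >= min_reads])

    def select_asvs(self, asv_ids: Iterable[str]) -> "AsvCountTable":
        keep = [a for a in self.asv_ids if a in set(asv_ids)]
        return AsvCountTable(self.counts.loc[keep])

    def select_samples(self, sample_ids: Iterable[str]) -> "AsvCountTable":
        return AsvCountTable(self.counts[list(sample_ids)])

    def drop_empty_asvs(self) -> "AsvCountTable":
        """Remove ASVs with zero reads in every retained sample."""
        keep = self.counts.sum(axis=1) > 0
        return AsvCountTable(self.counts.loc[keep])


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-ASV rank assignments kingdom -> species.

    Unassigned ranks hold the :data:`UNCLASSIFIED` sentinel.  The species
    column stores the full binomial (e.g. ``"Lactobacillus crispatus"``).
    """

    assignments: pd.DataFrame

    def __post_init__(self):
        df = self.assignments
        _check_unique(df.index, "asv_id")
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise CrossReferenceError(f"taxonomy missing rank columns: {missing}")
        cleaned = df[list(RANKS)].copy()
        for col in RANKS:
            s = cleaned[col].astype("string").str.strip()
            cleaned[col] = s.fillna(UNCLASSIFIED).replace("", UNCLASSIFIED).astype(str)
        object.__setattr__(self, "assignments", cleaned)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.assignments.index)

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise UnknownRankError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.assignments[rank]

    def subset(self, asv_ids: Iterable[str]) -> "TaxonomyTable":
        keep = [a for a in self.asv_ids if a in set(asv_ids)]
        return TaxonomyTable(self.assignments.loc[keep])


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample and its role in the paired design."""

    sample_id: str
    participant_id: str | None
    couple_id: str | None
    sex: str | None
    timepoint: str | None
    sample_class: str

    def __post_init__(self):
        if self.sample_class not in SAMPLE_CLASSES:
            raise InvalidMetadataError(
                f"sample {self.sample_id!r}: unknown sample_class "
                f"{self.sample_class!r}"
            )
        if self.sample_class == "specimen":
            if not (self.participant_id and self.couple_id):
                raise InvalidMetadataError(
                    f"specimen {self.sample_id!r} requires participant and couple"
                )
            if self.sex not in SEXES:
                raise InvalidMetadataError(
                    f"specimen {self.sample_id!r}: sex must be male/female, "
                    f"got {self.sex!r}"
                )
            if self.timepoint not in TIMEPOINTS:
                raise InvalidMetadataError(
                    f"specimen {self.sample_id!r}: timepoint must be "
                    f"before/after, got {self.timepoint!r}"
                )
        else:
            if any(v is not None for v in (self.couple_id, self.sex, self.timepoint)):
                raise InvalidMetadataError(
                    f"control {self.sample_id!r} must have null "
                    f"couple/sex/timepoint"
                )

    @property
    def is_specimen(self) -> bool:
        return self.sample_class == "specimen"

    @property
    def is_negative_control(self) -> bool:
        return self.sample_class in CONTROL_CLASSES


@dataclass(frozen=True)
class CohortDataset:
    """Validated bundle of counts, taxonomy, metadata and optional sequences."""

    counts: AsvCountTable
    taxonomy: TaxonomyTable
    metadata: tuple[SampleRecord, ...]
    sequences: Mapping[str, str] | None = None

    def __post_init__(self):
        records = tuple(self.metadata)
        object.__setattr__(self, "metadata", records)
        _check_unique((r.sample_id for r in records), "metadata sample_id")
        meta_ids = {r.sample_id for r in records}
        count_ids = set(self.counts.sample_ids)
        if meta_ids != count_ids:
            only_counts = sorted(count_ids - meta_ids)
            only_meta = sorted(meta_ids - count_ids)
            raise CrossReferenceError(
                f"metadata/counts sample mismatch: in counts only {only_counts}, "
                f"in metadata only {only_meta}"
            )
        tax_ids = set(self.taxonomy.asv_ids)
        missing_tax = sorted(set(self.counts.asv_ids) - tax_ids)
        if missing_tax:
            raise CrossReferenceError(f"ASVs missing from taxonomy: {missing_tax}")
        if self.sequences is not None:
            missing_seq = sorted(set(self.counts.asv_ids) - set(self.sequences))
            if missing_seq:
                raise CrossReferenceError(
                    f"ASVs missing from sequences: {missing_seq}"
                )
        # reject duplicate (participant, timepoint) specimens: replicate swabs
        # are assumed selected upstream, one sequenced sample each
        seen: set[tuple[str, str]] = set()
        for r in records:
            if r.is_specimen:
                key = (r.participant_id, r.timepoint)
                if key in seen:
                    raise InvalidMetadataError(
                        f"duplicate specimen for participant "
                        f"{r.participant_id!r} at timepoint {r.timepoint!r}"
                    )
                seen.add(key)

    # -- convenient views -------------------------------------------------

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.metadata:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    @property
    def specimen_records(self) -> list[SampleRecord]:
        return [r for r in self.metadata if r.is_specimen]

    @property
    def specimen_ids(self) -> list[str]:
        return [r.sample_id for r in self.specimen_records]

    @property
    def negative_control_ids(self) -> list[str]:
        return [r.sample_id for r in self.metadata if r.is_negative_control]

    @property
    def mock_ids(self) -> list[str]:
        return [r.sample_id for r in self.metadata if r.sample_class == "mock"]

    @property
    def couple_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.specimen_records:
            if r.couple_id not in out:
                out.append(r.couple_id)
        return out

    def specimen_id(self, couple_id: str, sex: str, timepoint: str) -> str:
        """Sample id of the unique specimen for (couple, sex, timepoint)."""
        hits = [
            r.sample_id
            for r in self.specimen_records
            if r.couple_id == couple_id and r.sex == sex and r.timepoint == timepoint
        ]
        if len(hits) != 1:
            raise InvalidMetadataError(
                f"expected exactly one specimen for couple={couple_id!r} "
                f"sex={sex!r} timepoint={timepoint!r}, found {len(hits)}"
            )
        return hits[0]

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "participant_id": r.participant_id,
                "couple_id": r.couple_id,
                "sex": r.sex,
                "timepoint": r.timepoint,
                "sample_class": r.sample_class,
            }
            for r in self.metadata
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def select_asvs(self, asv_ids: Iterable[str]) -> "CohortDataset":
        keep = set(asv_ids)
        seqs = None
        if self.sequences is not None:
            seqs = {a: s for a, s in self.sequences.items() if a in keep}
        return CohortDataset(
            counts=self.counts.select_asvs(keep),
            taxonomy=self.taxonomy.subset(keep),
            metadata=self.metadata,
            sequences=seqs,
        )


# ---------------------------------------------------------------------------
# TSV / FASTA reading and writing
# ---------------------------------------------------------------------------

_NULL_TOKENS = {"", "NA", "na", "NaN", "nan", "None"}


def _parse_null(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in _NULL_TOKENS else s


def _require_file(path: str | os.PathLike, what: str) -> str:
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise CohortFileError(f"{what} file not found: {path}")
    return path


def read_counts(path: str | os.PathLike) -> AsvCountTable:
    """Read an ASV x sample count TSV (first column header ``asv_id``)."""
    path = _require_file(path, "counts")
    df = pd.read_csv(path, sep="\t", index_col="asv_id", dtype=str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            as_float = df[col].astype(float)
        except ValueError as exc:
            raise NonIntegerCountError(
                f"non-numeric count in sample {col!r}: {exc}"
            ) from None
        frac = as_float != np.floor(as_float)
        if frac.any():
            asv = df.index[frac.to_numpy().nonzero()[0][0]]
            raise NonIntegerCountError(
                f"non-integer count at (asv={asv!r}, sample={col!r})"
            )
        numeric[col] = as_float.astype(np.int64)
    return AsvCountTable(numeric)


def read_taxonomy(path: str | os.PathLike) -> TaxonomyTable:
    path = _require_file(path, "taxonomy")
    df = pd.read_csv(path, sep="\t", index_col="asv_id", dtype=str)
    return TaxonomyTable(df)


def read_metadata(path: str | os.PathLike) -> list[SampleRecord]:
    path = _require_file(path, "metadata")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidMetadataError(f"metadata missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]).strip(),
                participant_id=_parse_null(row["participant_id"]),
                couple_id=_parse_null(row["couple_id"]),
                sex=_parse_null(row["sex"]),
                timepoint=_parse_null(row["timepoint"]),
                sample_class=str(row["sample_class"]).strip(),
            )
        )
    return records


def read_sequences(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    path = _require_file(path, "sequences")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_cohort(
    counts_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    sequences_path: str | os.PathLike | None = None,
) -> CohortDataset:
    """Read and cross-validate the cohort tables.

    Raises a distinct error for each failure mode: missing file
    (:class:`CohortFileError`), duplicate ids (:class:`DuplicateIdError`),
    counts/metadata mismatch (:class:`CrossReferenceError`), negative or
    non-integer counts (:class:`NegativeCountError` /
    :class:`NonIntegerCountError`).
    """
    counts = read_counts(counts_path)
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = read_metadata(metadata_path)
    sequences = read_sequences(sequences_path) if sequences_path else None
    return CohortDataset(counts, taxonomy, metadata, sequences)


def write_cohort(dataset: CohortDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write counts/taxonomy/metadata (and sequences if present) as TSV/FASTA.

    Returns a mapping of table name to written path.  Round-trips through
    :func:`read_cohort` cell-for-cell.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
    }
    dataset.counts.counts.rename_axis("asv_id").to_csv(paths["counts"], sep="\t")
    dataset.taxonomy.assignments.rename_axis("asv_id").to_csv(
        paths["taxonomy"], sep="\t"
    )
    meta = dataset.metadata_frame().fillna("NA")
    meta.to_csv(paths["metadata"], sep="\t")
    if dataset.sequences is not None:
        paths["sequences"] = os.path.join(outdir, "sequences.fasta")
        with open(paths["sequences"], "w") as fh:
            for asv in dataset.counts.asv_ids:
                fh.write(f">{asv}\n{dataset.sequences[asv]}\n")
    return paths


# ---------------------------------------------------------------------------
# Abundance primitives
# ---------------------------------------------------------------------------


def to_relative_abundance(table: AsvCountTable) -> pd.DataFrame:
    """Column-normalize counts to proportions (each sample sums to 1).

    Raises :class:`EmptySampleError` naming the first all-zero sample.
    """
    totals = table.counts.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise EmptySampleError(f"all-zero sample column: {empty.index[0]!r}")
    return table.counts / totals


def filter_low_abundance(
    table: AsvCountTable, threshold: float = 0.001
) -> AsvCountTable:
    """Drop ASVs never exceeding ``threshold`` relative abundance.

    An ASV is retained iff its relative abundance strictly exceeds the
    threshold in at least one sample (default 0.1 %).  Counts of retained
    ASVs and the sample set are unchanged; idempotent at fixed threshold.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    rel = to_relative_abundance(table)
    keep = (rel > threshold).any(axis=1)
    return AsvCountTable(table.counts.loc[keep])


def aggregate_by_rank(
    table: AsvCountTable, taxonomy: TaxonomyTable, rank: str = "genus"
) -> pd.DataFrame:
    """Sum counts of ASVs sharing a taxon at ``rank`` (taxon x sample).

    Unassigned ASVs pool under the :data:`UNCLASSIFIED` sentinel; per-sample
    read totals are conserved exactly (integer arithmetic).
    """
    labels = taxonomy.rank(rank).reindex(table.asv_ids)
    missing = labels.index[labels.isna()]
    if len(missing):
        raise CrossReferenceError(
            f"ASVs missing from taxonomy at rank {rank!r}: {list(missing)[:5]}"
        )
    return table.counts.groupby(labels.to_numpy()).sum()
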
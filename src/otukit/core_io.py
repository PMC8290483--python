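"""Typed containers and I/O for OTU count tables, taxonomy, and sample metadata.

The pipeline's universal currency is the :class:`CountTable` — an OTU x sample
matrix of nonnegative integer read counts.  Taxonomy maps each OTU to a ranked
lineage; sample metadata carries the study design (subject, mother linkage,
age in days, age bin, specimen type, amplicon domain).  Everything downstream
(decontamination, diversity, sharing, differential abundance) consumes these
three tables after cross-validation by :func:`align_study`.

TSV is the primary interchange format; BIOM 2.x (HDF5) is supported read-only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountTable",
    "TaxonomyTable",
    "SampleMetadata",
    "AnalysisConfig",
    "StudyBundle",
    "AGE_BINS",
    "CHILD_BINS",
    "MOTHER_BINS",
    "SAMPLE_TYPES",
    "DOMAINS",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "align_study",
    "write_report",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

SAMPLE_TYPES = ("child_stool", "mother_stool", "breast_milk", "blank", "positive_control")
DOMAINS = ("bacteria_16S", "fungi_ITS2")

# Recruitment strata: day-of-life / month-of-life windows, encoded as
# inclusive [lo, hi] bounds in days so age_bin/age_days consistency is a
# data-driven lookup rather than hard-coded logic.  Month windows use
# 30.44 days/month rounded outward.
AGE_BINS: dict[str, tuple[int, int]] = {
    "DOL 0-5": (0, 5),
    "DOL 13-17": (13, 17),
    "DOL 26-35": (26, 35),
    "DOL 83-115": (83, 115),
    "DOL 165-200": (165, 200),
    "MOL 11-13": (334, 426),
    "MOL 22-26": (669, 822),
    "MOL 33-39": (1004, 1218),
    "MOL 57-63": (1735, 1948),
}
CHILD_BINS = tuple(AGE_BINS)
MOTHER_BINS = ("Mother-wk1", "Mother-wk4")


class StudyValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise StudyValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """OTU x sample matrix of nonnegative integer read counts.

    Rows are OTUs, columns are samples; identifier order is preserved and
    identifiers are case-sensitive and duplicate-free.
    """

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = tuple(str(i) for i in self.otu_ids)
        self.sample_ids = tuple(str(i) for i in self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise StudyValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise StudyValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise StudyValidationError("counts must be integers")
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            r, c = np.argwhere(self.counts < 0)[0]
            raise StudyValidationError(
                f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")

    # -- accessors -------------------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=list(self.sample_ids))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def subset_samples(self, ids: Iterable[str]) -> "CountTable":
        """Restrict to the given samples, preserving this table's order."""
        keep = set(ids)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep]
        return CountTable(
            self.otu_ids,
            tuple(self.sample_ids[j] for j in idx),
            self.counts[:, idx],
        )

    def subset_otus(self, ids: Iterable[str]) -> "CountTable":
        keep = set(ids)
        idx = [i for i, o in enumerate(self.otu_ids) if o in keep]
        return CountTable(
            tuple(self.otu_ids[i] for i in idx),
            self.sample_ids,
            self.counts[idx, :],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())


@dataclass
class TaxonomyTable:
    """OTU -> ranked lineage (kingdom..species; missing ranks only at the tail)."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) > len(RANKS):
                raise StudyValidationError(f"lineage for {otu!r} has too many ranks")
            # a resolved rank implies all shallower ranks are resolved
            seen_gap = False
            for label in lin:
                if label == "":
                    seen_gap = True
                elif seen_gap:
                    raise StudyValidationError(
                        f"lineage for {otu!r} resolves a rank below an unresolved one"
                    )
            self.lineages[otu] = lin

    def genus_label(self, otu_id: str) -> str:
        """Deepest-resolved-rank label, used for genus-level aggregation.

        Returns the genus name when resolved; otherwise the deepest resolved
        rank's label carrying its rank prefix (e.g. ``f__Enterobacteriaceae``),
        so OTUs classified above genus stay countable.  Unknown OTUs map to
        ``Unclassified``.
        """
        lin = self.lineages.get(otu_id)
        if not lin:
            return "Unclassified"
        resolved = [(d, label) for d, label in enumerate(lin) if label]
        if not resolved:
            return "Unclassified"
        depth, label = resolved[-1]
        genus_depth = RANKS.index("genus")
        if depth >= genus_depth and lin[genus_depth]:
            return lin[genus_depth]
        return f"{RANK_PREFIXES[depth]}{label}"

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages


_META_COLUMNS = [
    "sample_id",
    "subject_id",
    "mother_subject_id",
    "age_days",
    "age_bin",
    "sample_type",
    "domain",
    "batch",
]


@dataclass
class SampleMetadata:
    """Per-sample study annotations, stored as a validated DataFrame.

    One row per sample with columns ``sample_id, subject_id,
    mother_subject_id, age_days, age_bin, sample_type, domain, batch``.
    Blanks and positive controls carry no age; when both ``age_days`` and a
    child ``age_bin`` are present they must agree with the bin boundary
    lookup in :data:`AGE_BINS`.
    """

    frame: pd.DataFrame
    bin_bounds: Mapping[str, tuple[int, int]] = field(default_factory=lambda: AGE_BINS)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise StudyValidationError(f"metadata missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise StudyValidationError(f"duplicate sample id in metadata: {dup!r}")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise StudyValidationError(f"unknown sample_type values: {sorted(bad_type)}")
        bad_dom = set(df["domain"]) - set(DOMAINS)
        if bad_dom:
            raise StudyValidationError(f"unknown domain values: {sorted(bad_dom)}")
        controls = df["sample_type"].isin(["blank", "positive_control"])
        if df.loc[controls, "age_days"].notna().any():
            bad = df.loc[controls & df["age_days"].notna(), "sample_id"].iloc[0]
            raise StudyValidationError(f"control sample {bad!r} must not carry age_days")
        both = df["age_days"].notna() & df["age_bin"].isin(self.bin_bounds)
        for _, row in df.loc[both].iterrows():
            lo, hi = self.bin_bounds[row["age_bin"]]
            if not lo <= int(row["age_days"]) <= hi:
                raise StudyValidationError(
                    f"sample {row['sample_id']!r}: age_days={int(row['age_days'])} "
                    f"outside bin {row['age_bin']!r} bounds [{lo}, {hi}]"
                )
        self.frame = df.set_index("sample_id", drop=False)
        self.frame.index.name = None

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["sample_id"])

    def subset(self, ids: Iterable[str]) -> "SampleMetadata":
        keep = [s for s in self.frame["sample_id"] if s in set(ids)]
        return SampleMetadata(self.frame.loc[keep].reset_index(drop=True), self.bin_bounds)

    def ids_where(self, **conditions) -> list[str]:
        """Sample ids matching all column=value (or column=list) conditions."""
        mask = pd.Series(True, index=self.frame.index)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.frame[col].isin(list(val))
            else:
                mask &= self.frame[col] == val
        return list(self.frame.loc[mask, "sample_id"])


@dataclass
class AnalysisConfig:
    """Tunable thresholds shared across pipeline stages.

    min_sample_depth
        Samples with fewer total reads are removed during QC (strict "<").
    blank_prevalence_threshold
        An OTU is a contamination candidate only when present in strictly
        more than this fraction of blanks.
    presence_threshold
        Relative-abundance cutoff for the shared-OTU presence calls
        (strictly greater than; default 0.01%).
    """

    min_sample_depth: int = 1000
    blank_prevalence_threshold: float = 0.5
    presence_threshold: float = 0.0001
    n_permutations: int = 999
    n_resample_draws: int = 1
    alpha_level: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_sample_depth < 0:
            raise ValueError("min_sample_depth must be nonnegative")
        if not 0.0 <= self.blank_prevalence_threshold <= 1.0:
            raise ValueError("blank_prevalence_threshold must be in [0, 1]")
        if not 0.0 <= self.presence_threshold < 1.0:
            raise ValueError("presence_threshold must be in [0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_resample_draws < 1:
            raise ValueError("n_resample_draws must be >= 1")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyBundle:
    """A cross-validated (table, metadata, taxonomy) triple over the shared samples."""

    table: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    table_only_ids: tuple[str, ...] = ()
    metadata_only_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read an OTU x sample count table from TSV or BIOM 2.x (HDF5)."""
    if format == "tsv":
        return _read_count_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown count-table format: {format!r}")


def _read_count_tsv(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise StudyValidationError(f"{path}: duplicate sample column {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise StudyValidationError(f"{path}: duplicate OTU row {dup!r}")
    if df.shape[1] == 0:
        raise StudyValidationError(f"{path}: no sample columns in header")
    mat = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise StudyValidationError(
                    f"{path}: non-integer count {raw!r} at OTU {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if v < 0:
                raise StudyValidationError(
                    f"{path}: negative count at OTU {df.index[i]!r}, sample {col!r}"
                )
            mat[i, j] = v
    return CountTable(tuple(map(str, df.index)), tuple(map(str, df.columns)), mat)


def _read_biom(path: str | Path) -> CountTable:
    """Minimal BIOM 2.x reader: HDF5 with CSR data under ``observation/matrix``."""
    import h5py

    with h5py.File(path, "r") as fh:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        data = np.asarray(grp["data"][:])
        indices = np.asarray(grp["indices"][:])
        indptr = np.asarray(grp["indptr"][:])
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr), shape=(len(otu_ids), len(sample_ids)))
    dense = np.asarray(mat.todense())
    if not np.allclose(dense, np.round(dense)):
        raise StudyValidationError(f"{path}: BIOM matrix contains non-integer values")
    return CountTable(tuple(otu_ids), tuple(sample_ids), dense.astype(np.int64))


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Two-column TSV: OTU id, semicolon-delimited lineage with k__/p__/... prefixes."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise StudyValidationError(f"{path}: taxonomy needs 2 columns (otu_id, lineage)")
    lineages: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        otu = str(row.iloc[0])
        if otu in lineages:
            raise StudyValidationError(f"{path}: duplicate taxonomy entry for {otu!r}")
        labels = []
        for part in str(row.iloc[1]).split(";"):
            part = part.strip()
            for pfx in RANK_PREFIXES:
                if part.startswith(pfx):
                    part = part[len(pfx):]
                    break
            labels.append(part)
        lineages[otu] = tuple(labels)
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    rows = []
    for otu, lin in tax.lineages.items():
        parts = [f"{RANK_PREFIXES[d]}{label}" for d, label in enumerate(lin)]
        rows.append((otu, ";".join(parts)))
    pd.DataFrame(rows, columns=["otu_id", "lineage"]).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str, "batch": str})
    if "age_days" in df.columns:
        df["age_days"] = pd.to_numeric(df["age_days"], errors="coerce")
    if "mother_subject_id" in df.columns:
        df["mother_subject_id"] = df["mother_subject_id"].where(
            df["mother_subject_id"].notna(), None
        )
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def align_study(
    table: CountTable, meta: SampleMetadata, tax: TaxonomyTable
) -> StudyBundle:
    """Restrict table and metadata to their shared samples; report the drops."""
    table_ids = set(table.sample_ids)
    meta_ids = set(meta.sample_ids)
    common = table_ids & meta_ids
    if not common:
        raise StudyValidationError(
            "no samples shared between count table and metadata — check identifiers"
        )
    bundle = StudyBundle(
        table=table.subset_samples(common),
        metadata=meta.subset(common),
        taxonomy=tax,
        table_only_ids=tuple(s for s in table.sample_ids if s not in meta_ids),
        metadata_only_ids=tuple(s for s in meta.sample_ids if s not in table_ids),
    )
    return bundle


def write_report(
    result,
    path: str | Path,
    params: Mapping | None = None,
) -> None:
    """Write a stage result as TSV plus a JSON sidecar with parameters.

    ``result`` must expose ``to_frame()`` (or be a DataFrame); the sidecar at
    ``<path>.json`` records parameters, seed and software version with
    deterministic key ordering, so reruns are byte-comparable.
    """
    from . import __version__

    path = Path(path)
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    frame.to_csv(path, sep="\t", index=False)
    sidecar = {
        "parameters": dict(sorted((params or {}).items())),
        "software": "otukit",
        "version": __version__,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
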
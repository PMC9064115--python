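"""Reading, validation and rank handling for taxonomic profile tables.

Profiles are samples x taxa matrices of relative abundances. On disk,
MetaPhlAn-style merged tables store percent values with pipe-delimited,
rank-prefixed lineage strings (``k__Bacteria|p__Firmicutes|...``) as rows
and samples as columns; in memory everything is a fraction in [0, 1] with
samples as rows. 16S OTU count tables are filtered, converted to relative
abundance and collapsed to genus level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
_RANK_TO_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
_PREFIX_TO_RANK = {v: k for k, v in _RANK_TO_PREFIX.items()}
_STRAIN_PREFIX = "t__"

CLOSURE_TOL = 1e-6


class ProfileError(ValueError):
    """Raised for malformed or inconsistent profile data."""


class LineageParseError(ProfileError):
    """Raised when a lineage string cannot be parsed."""


@dataclass(frozen=True)
class TaxonLineage:
    """A taxonomic lineage, contiguous from kingdom down to its deepest rank.

    ``names`` holds one slot per rank in :data:`RANKS`; unpopulated deep
    ranks are ``None``. A trailing strain segment (``t__``) in the source
    string is ignored but preserved in ``source_string``.
    """

    names: tuple[str | None, ...]
    source_string: str

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise LineageParseError(
                f"lineage must carry {len(RANKS)} rank slots, got {len(self.names)}"
            )
        seen_gap = False
        populated = 0
        for name in self.names:
            if name is None:
                seen_gap = True
            else:
                if seen_gap:
                    raise LineageParseError(
                        f"non-contiguous lineage (gap above a populated rank): "
                        f"{self.source_string!r}"
                    )
                populated += 1
        if populated == 0:
            raise LineageParseError(f"empty lineage: {self.source_string!r}")

    @classmethod
    def from_string(cls, text: str) -> "TaxonLineage":
        segments = [seg.strip() for seg in text.strip().split("|")]
        if segments and segments[-1].startswith(_STRAIN_PREFIX):
            segments = segments[:-1]  # strain slot ignored
        names: list[str | None] = [None] * len(RANKS)
        for i, seg in enumerate(segments):
            prefix = seg[:3]
            rank = _PREFIX_TO_RANK.get(prefix)
            if rank is None or rank != RANKS[i]:
                raise LineageParseError(
                    f"segment {i} of {text!r}: expected prefix "
                    f"{_RANK_TO_PREFIX[RANKS[i]]!r}, got {seg!r}"
                )
            name = seg[3:]
            if not name:
                raise LineageParseError(f"empty taxon name in segment {seg!r} of {text!r}")
            names[i] = name
        return cls(names=tuple(names), source_string=text.strip())

    @property
    def is_strain_level(self) -> bool:
        """True when the source row carried a strain (t__) segment."""
        return self.source_string.split("|")[-1].startswith(_STRAIN_PREFIX)

    @property
    def ranks(self) -> dict[str, str]:
        """Ordered mapping rank-name -> taxon-name for populated ranks."""
        return {r: n for r, n in zip(RANKS, self.names) if n is not None}

    @property
    def deepest_rank(self) -> str:
        for rank, name in zip(reversed(RANKS), reversed(self.names)):
            if name is not None:
                return rank
        raise LineageParseError("empty lineage")  # unreachable: __post_init__ checks

    def name_at(self, rank: str) -> str | None:
        return self.names[RANKS.index(rank)]

    def truncate(self, rank: str) -> "TaxonLineage":
        """Ancestor lineage at ``rank``, with a canonical source string."""
        idx = RANKS.index(rank)
        if self.names[idx] is None:
            raise ProfileError(
                f"lineage {self.source_string!r} is not populated at rank {rank!r}"
            )
        names = tuple(self.names[: idx + 1]) + (None,) * (len(RANKS) - idx - 1)
        source = "|".join(
            _RANK_TO_PREFIX[RANKS[i]] + n for i, n in enumerate(names[: idx + 1])
        )
        return TaxonLineage(names=names, source_string=source)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.source_string


@dataclass
class ProfileTable:
    """Samples x taxa relative-abundance matrix at a single taxonomic rank.

    ``values[i, j]`` is the abundance of taxon ``j`` in sample ``i`` as a
    fraction in [0, 1] (or an indicator in {0, 1} when ``is_binary``).
    """

    sample_ids: list[str]
    taxa: list[TaxonLineage]
    values: np.ndarray
    rank: str
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ProfileError("values must be a 2-D samples x taxa matrix")
        n_samples, n_taxa = self.values.shape
        if n_samples != len(self.sample_ids):
            raise ProfileError(
                f"{len(self.sample_ids)} sample ids but {n_samples} matrix rows"
            )
        if n_taxa != len(self.taxa):
            raise ProfileError(f"{len(self.taxa)} taxa but {n_taxa} matrix columns")
        if len(set(self.sample_ids)) != n_samples:
            raise ProfileError("duplicate sample identifiers")
        keys = [t.source_string for t in self.taxa]
        if len(set(keys)) != n_taxa:
            raise ProfileError("duplicate taxon identifiers")
        if self.rank not in RANKS:
            raise ProfileError(f"unknown rank {self.rank!r}")
        for t in self.taxa:
            if t.deepest_rank != self.rank:
                raise ProfileError(
                    f"taxon {t.source_string!r} has deepest rank {t.deepest_rank!r}, "
                    f"table rank is {self.rank!r}"
                )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ProfileError("abundance values must lie in [0, 1]")
        if self.is_binary and not np.all((self.values == 0) | (self.values == 1)):
            raise ProfileError("binary table contains values outside {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def is_closed(self, tol: float = CLOSURE_TOL) -> bool:
        return bool(np.all(np.abs(self.row_sums() - 1.0) <= tol))

    def assert_closed(self, tol: float = CLOSURE_TOL) -> None:
        sums = self.row_sums()
        bad = np.where(np.abs(sums - 1.0) > tol)[0]
        if bad.size:
            sid = self.sample_ids[bad[0]]
            raise ProfileError(
                f"sample {sid!r} row sum {sums[bad[0]]:.6g} deviates from 1 by more than {tol}"
            )

    def select_samples(self, sample_ids: Sequence[str]) -> "ProfileTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ProfileError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return ProfileTable(
            sample_ids=list(sample_ids),
            taxa=list(self.taxa),
            values=self.values[rows, :].copy(),
            rank=self.rank,
            is_binary=self.is_binary,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[t.source_string for t in self.taxa],
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, rank: str | None = None, is_binary: bool = False
    ) -> "ProfileTable":
        taxa = [TaxonLineage.from_string(c) for c in df.columns]
        if rank is None:
            ranks = {t.deepest_rank for t in taxa}
            if len(ranks) != 1:
                raise ProfileError(f"mixed ranks in table: {sorted(ranks)}")
            rank = ranks.pop()
        return cls(
            sample_ids=[str(s) for s in df.index],
            taxa=taxa,
            values=df.to_numpy(dtype=float),
            rank=rank,
            is_binary=is_binary,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write the canonical TSV (samples as rows, taxa as columns, fractions)."""
        df = self.to_dataframe()
        # repr-precision floats so a read round-trip is bitwise identical
        df = df.map(lambda v: repr(float(v)) if v else "0")
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, is_binary: bool = False) -> "ProfileTable":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls.from_dataframe(df, is_binary=is_binary)


@dataclass
class LabeledCohort:
    """A profile table with aligned binary class labels (0=control, 1=case)."""

    profile: ProfileTable
    labels: np.ndarray
    study_id: str
    disease: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.profile.n_samples,):
            raise ProfileError("labels must align 1:1 with profile sample ids")
        classes = set(self.labels.tolist())
        if not classes <= {0, 1}:
            raise ProfileError(f"labels must be 0 (control) or 1 (case), got {classes}")
        if classes != {0, 1}:
            raise ProfileError("both classes must be present in a cohort")

    @property
    def n_case(self) -> int:
        return int(self.labels.sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == 0).sum())

    def with_profile(self, profile: ProfileTable) -> "LabeledCohort":
        """Same samples and labels, different feature representation."""
        if profile.sample_ids != self.profile.sample_ids:
            raise ProfileError("replacement profile must keep the same samples")
        return LabeledCohort(
            profile=profile, labels=self.labels.copy(),
            study_id=self.study_id, disease=self.disease,
        )


def _find_header(lines: list[str]) -> tuple[int, list[str]]:
    """Locate the header row, skipping MetaPhlAn comment lines."""
    for i, line in enumerate(lines):
        stripped = line.rstrip("\n")
        if not stripped.strip():
            continue
        if stripped.startswith("#") and "\t" not in stripped:
            continue  # e.g. "#mpa_v30_..." version banner
        fields = stripped.lstrip("#").split("\t")
        return i, fields
    raise ProfileError("no header row found")


def read_metaphlan_table(
    path: str | Path,
    rank: str = "species",
    renormalize: bool = False,
) -> ProfileTable:
    """Read a merged MetaPhlAn-style abundance table at one taxonomic rank.

    The file is tab-separated with lineage strings in the first column and
    one percent-valued column per sample. Only rows whose deepest populated
    rank equals ``rank`` are kept (so genus rows are never double-counted
    with their species); values are converted to fractions. If the selected
    rows do not sum to 1 per sample (unclassified mass), a warning is issued
    unless ``renormalize`` restores closure explicitly.
    """
    if rank not in RANKS:
        raise ProfileError(f"unknown rank {rank!r}")
    lines = Path(path).read_text().splitlines()
    header_idx, header = _find_header(lines)
    sample_cols = header[1:]
    if sample_cols and sample_cols[0] in ("NCBI_tax_id", "clade_taxid"):
        tax_id_col = True
        sample_cols = sample_cols[1:]
    else:
        tax_id_col = False
    if not sample_cols:
        raise ProfileError("table has no sample columns")
    if len(set(sample_cols)) != len(sample_cols):
        dupes = sorted({s for s in sample_cols if sample_cols.count(s) > 1})
        raise ProfileError(f"duplicate sample columns: {dupes}")

    taxa: list[TaxonLineage] = []
    rows: list[list[float]] = []
    for row_no, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        lineage_text = fields[0].strip()
        if lineage_text.upper() in ("UNKNOWN", "UNCLASSIFIED"):
            warnings.warn(f"skipping unclassified row at line {row_no}")
            continue
        try:
            lineage = TaxonLineage.from_string(lineage_text)
        except LineageParseError as exc:
            raise LineageParseError(f"line {row_no}: {exc}") from exc
        data_fields = fields[2:] if tax_id_col else fields[1:]
        if len(data_fields) != len(sample_cols):
            raise ProfileError(
                f"line {row_no}: expected {len(sample_cols)} values, got {len(data_fields)}"
            )
        if lineage.deepest_rank != rank or lineage.is_strain_level:
            continue  # strain-level rows would double-count their species
        values = []
        for sample, raw in zip(sample_cols, data_fields):
            v = float(raw)
            if v < 0:
                raise ProfileError(
                    f"negative abundance {v} for sample {sample!r} at line {row_no}"
                )
            values.append(v)
        taxa.append(lineage)
        rows.append(values)
    if not taxa:
        raise ProfileError(f"no rows at rank {rank!r} in {path}")
    values = np.array(rows, dtype=float).T / 100.0  # percent on disk -> fraction
    table = ProfileTable(
        sample_ids=list(sample_cols), taxa=taxa, values=np.clip(values, 0.0, 1.0),
        rank=rank,
    )
    if renormalize:
        table = globals()["renormalize"](table)
    elif not table.is_closed():
        warnings.warn(
            f"rows at rank {rank!r} do not sum to 1 (unclassified mass?); "
            "pass renormalize=True to restore closure"
        )
    return table


def aggregate_to_rank(table: ProfileTable, rank: str) -> ProfileTable:
    """Sum species abundances up the lineage to genus, family or order.

    Per-sample total mass is conserved exactly up to float addition order
    (well within 1e-9).
    """
    if rank not in ("genus", "family", "order"):
        raise ProfileError(f"aggregation target must be genus/family/order, got {rank!r}")
    if table.is_binary:
        raise ProfileError("cannot aggregate a binary table; aggregate before binarizing")
    if table.rank != "species":
        raise ProfileError(f"aggregation starts from a species table, got {table.rank!r}")
    missing = [t.source_string for t in table.taxa if t.name_at(rank) is None]
    if missing:
        raise ProfileError(
            f"{len(missing)} species lack an ancestor at rank {rank!r}: {missing[:5]}"
        )
    groups: dict[str, list[int]] = {}
    ancestors: dict[str, TaxonLineage] = {}
    for j, taxon in enumerate(table.taxa):
        anc = taxon.truncate(rank)
        groups.setdefault(anc.source_string, []).append(j)
        ancestors[anc.source_string] = anc
    keys = list(groups)
    values = np.column_stack([table.values[:, groups[k]].sum(axis=1) for k in keys])
    return ProfileTable(
        sample_ids=list(table.sample_ids),
        taxa=[ancestors[k] for k in keys],
        values=np.clip(values, 0.0, 1.0),
        rank=rank,
    )


def renormalize(table: ProfileTable) -> ProfileTable:
    """Divide each row by its sum so rows sum to 1 (within 1e-12)."""
    if table.is_binary:
        raise ProfileError("cannot renormalize a binary table")
    sums = table.row_sums()
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ProfileError(f"sample {table.sample_ids[zero[0]]!r} has zero total abundance")
    return ProfileTable(
        sample_ids=list(table.sample_ids),
        taxa=list(table.taxa),
        values=table.values / sums[:, None],
        rank=table.rank,
    )


def preprocess_16s(
    counts: pd.DataFrame,
    taxonomy: Mapping[str, str | None] | pd.Series,
    min_sample_reads: int = 100,
    min_otu_reads: int = 10,
    min_prevalence_fraction: float = 0.01,
) -> ProfileTable:
    """Filter an OTU count table and collapse it to genus-level profiles.

    Samples with fewer than ``min_sample_reads`` total reads are discarded
    first; then OTUs with fewer than ``min_otu_reads`` total reads and/or
    present in less than ``min_prevalence_fraction`` of the surviving
    samples are removed (all three boundaries strict, matching the filter
    wording). Surviving counts become per-sample relative abundances, OTUs
    un-annotated at genus are dropped, and genera are summed.

    ``counts`` has samples as rows and OTU ids as columns; ``taxonomy`` maps
    OTU id to a pipe-delimited lineage string (None/NaN = un-annotated).
    """
    mat = counts.to_numpy()
    if np.any(mat < 0) or not np.allclose(mat, np.round(mat)):
        raise ProfileError("counts must be nonnegative integers")
    if isinstance(taxonomy, pd.Series):
        taxonomy = taxonomy.to_dict()

    sample_totals = counts.sum(axis=1)
    kept = counts.loc[sample_totals >= min_sample_reads]
    if kept.shape[0] == 0:
        raise ProfileError(f"all samples have fewer than {min_sample_reads} reads")

    otu_totals = kept.sum(axis=0)
    prevalence = (kept > 0).mean(axis=0)
    otu_ok = (otu_totals >= min_otu_reads) & (prevalence >= min_prevalence_fraction)
    kept = kept.loc[:, otu_ok]
    if kept.shape[1] == 0:
        raise ProfileError("all OTUs removed by the read-count/prevalence filters")

    row_sums = kept.sum(axis=1)
    empty = row_sums == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} sample(s) left with zero reads "
            "after OTU filtering"
        )
        kept = kept.loc[~empty]
        row_sums = row_sums[~empty]
        if kept.shape[0] == 0:
            raise ProfileError("all samples empty after OTU filtering")
    rel = kept.div(row_sums, axis=0)

    genus_cols: dict[str, list[str]] = {}
    genus_lineage: dict[str, TaxonLineage] = {}
    for otu in rel.columns:
        raw = taxonomy.get(otu)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or not str(raw).strip():
            continue  # un-annotated
        lineage = TaxonLineage.from_string(str(raw))
        if lineage.name_at("genus") is None:
            continue  # un-annotated at genus level
        genus = lineage.truncate("genus")
        genus_cols.setdefault(genus.source_string, []).append(otu)
        genus_lineage[genus.source_string] = genus
    if not genus_cols:
        raise ProfileError("no OTUs annotated at genus level survive the filters")
    keys = list(genus_cols)
    values = np.column_stack(
        [rel[genus_cols[k]].sum(axis=1).to_numpy() for k in keys]
    )
    return ProfileTable(
        sample_ids=[str(s) for s in rel.index],
        taxa=[genus_lineage[k] for k in keys],
        values=np.clip(values, 0.0, 1.0),
        rank="genus",
    )


METADATA_COLUMNS = ("sample_id", "study_id", "label", "disease")
_LABEL_MAP = {"control": 0, "case": 1, "0": 0, "1": 1}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, study_id, label, disease)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileError(f"metadata is missing columns: {missing}")
    labels = []
    for raw in df["label"]:
        key = str(raw).strip().lower()
        if key not in _LABEL_MAP:
            raise ProfileError(f"label {raw!r} is not control/case or 0/1")
        labels.append(_LABEL_MAP[key])
    df = df.copy()
    df["label"] = labels
    return df


def write_metadata(cohorts: Iterable[LabeledCohort], path: str | Path) -> None:
    rows = []
    for cohort in cohorts:
        for sid, lab in zip(cohort.profile.sample_ids, cohort.labels):
            rows.append(
                {"sample_id": sid, "study_id": cohort.study_id,
                 "label": int(lab), "disease": cohort.disease}
            )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def build_cohort(
    profile: ProfileTable,
    metadata: pd.DataFrame,
    study_id: str | None = None,
) -> LabeledCohort:
    """Align a profile table with metadata rows into a labeled cohort."""
    meta = metadata
    if study_id is not None:
        meta = metadata[metadata["study_id"] == study_id]
        if meta.empty:
            raise ProfileError(f"no metadata rows for study {study_id!r}")
    meta = meta[meta["sample_id"].isin(profile.sample_ids)]
    if meta.empty:
        raise ProfileError("no metadata rows match the profile's samples")
    sub = profile.select_samples(list(meta["sample_id"]))
    diseases = sorted(set(meta["disease"].astype(str)) - {"", "nan"})
    studies = sorted(set(meta["study_id"].astype(str)))
    return LabeledCohort(
        profile=sub,
        labels=meta["label"].to_numpy(dtype=int),
        study_id=studies[0] if len(studies) == 1 else ",".join(studies),
        disease=diseases[0] if diseases else "",
    )
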
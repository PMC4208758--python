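"""Validated tabular containers for the pipeline.

The central object is the :class:`LineageTable`, an integer matrix of
sequence counts with bacterial lineages as rows and blood samples as
columns, accompanied by :class:`SampleMetadata` (host individual, host
species, plot, and plot community richness) and a per-lineage
:class:`LineageAnnotation` table carrying the zoonotic-candidate flag.

All containers are thin wrappers over :class:`pandas.DataFrame` that
validate their invariants on construction and provide TSV round-trip I/O
(plus a minimal BIOM v1.0 JSON import/export for the count table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineageTable",
    "SampleMetadata",
    "LineageAnnotation",
    "PresenceMatrix",
    "ValidationError",
    "read_lineage_table",
    "write_lineage_table",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "load_zoonotic_candidates",
]

VALID_RICHNESS = (1, 2, 3)


class ValidationError(ValueError):
    """An input table violates a container invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ID(s): {dupes}")


@dataclass
class LineageTable:
    """Counts of sequences per (lineage, sample).

    Parameters
    ----------
    data:
        DataFrame with lineage IDs as the index and sample IDs as the
        columns; values are non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "lineage")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric integers")
            if np.any(~np.isfinite(values.astype(float))):
                raise ValidationError("counts contain non-finite entries")
            if np.any(values != np.floor(values)):
                r, c = np.argwhere(values != np.floor(values))[0]
                raise ValidationError(
                    f"non-integer count at lineage {df.index[r]!r}, "
                    f"sample {df.columns[c]!r}"
                )
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at lineage {df.index[r]!r}, "
                    f"sample {df.columns[c]!r}"
                )
        self.data = df.astype(np.int64)

    # -- basic accessors ------------------------------------------------
    @property
    def lineage_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        """Total sequences per sample (column sums)."""
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples map to 0."""
        totals = self.sample_totals().replace(0, np.nan)
        return (self.data / totals).fillna(0.0)

    def to_presence(self) -> "PresenceMatrix":
        return PresenceMatrix((self.data > 0).astype(np.int8))

    def select_lineages(self, lineage_ids: Iterable) -> "LineageTable":
        return LineageTable(self.data.loc[list(lineage_ids)].copy())

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        return isinstance(other, LineageTable) and self.data.equals(other.data)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageTable":
        return read_lineage_table(path)

    def to_tsv(self, path: str | Path) -> None:
        write_lineage_table(self, path)

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "LineageTable":
        """Read a (sparse or dense) BIOM v1.0 JSON table."""
        with open(path) as fh:
            doc = json.load(fh)
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(rows), len(cols)))
        if doc.get("matrix_type", "sparse") == "dense":
            mat[:] = np.asarray(doc["data"])
        else:
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        return cls(pd.DataFrame(mat, index=rows, columns=cols))

    def to_biom_json(self, path: str | Path) -> None:
        values = self.counts()
        nz = np.argwhere(values > 0)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "hostmicro",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(self.shape),
            "rows": [{"id": str(i), "metadata": None} for i in self.lineage_ids],
            "columns": [{"id": str(c), "metadata": None} for c in self.sample_ids],
            "data": [[int(r), int(c), int(values[r, c])] for r, c in nz],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


@dataclass
class PresenceMatrix:
    """Binary occurrence per (lineage, analysis unit)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "lineage")
        _check_unique(self.data.columns, "unit")
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence entries must be 0/1")
        self.data = self.data.astype(np.int8)

    @property
    def lineage_ids(self) -> list:
        return list(self.data.index)

    @property
    def unit_ids(self) -> list:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def richness(self) -> pd.Series:
        """Lineage richness per unit (column sums of presence)."""
        return self.data.sum(axis=0)


_METADATA_COLS = [
    "sample_id",
    "host_individual_id",
    "host_species",
    "plot_id",
    "community_richness",
]


@dataclass
class SampleMetadata:
    """Per-sample host individual, species, plot and community richness."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in _METADATA_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing column(s): {missing}")
        _check_unique(df["sample_id"], "sample")
        richness = df["community_richness"]
        bad = ~richness.isin(VALID_RICHNESS)
        if bad.any():
            raise ValidationError(
                "community_richness must be 1, 2 or 3; offending sample(s): "
                f"{df.loc[bad, 'sample_id'].tolist()}"
            )
        per_plot = df.groupby("plot_id")["community_richness"].nunique()
        if (per_plot > 1).any():
            raise ValidationError(
                "community_richness varies within plot(s): "
                f"{per_plot[per_plot > 1].index.tolist()}"
            )
        n_species = df.groupby("plot_id").agg(
            n=("host_species", "nunique"), r=("community_richness", "first")
        )
        over = n_species[n_species["n"] > n_species["r"]]
        if len(over):
            raise ValidationError(
                "more host species than community_richness in plot(s): "
                f"{over.index.tolist()}"
            )
        df["community_richness"] = richness.astype(int)
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def require_samples(self, sample_ids: Iterable) -> None:
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        return read_metadata(path)

    def to_tsv(self, path: str | Path) -> None:
        write_metadata(self, path)


@dataclass
class LineageAnnotation:
    """Per-lineage zoonotic-candidate flags (immutable through the run)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        for col in ("lineage_id", "zoonotic_candidate"):
            if col not in df.columns:
                raise ValidationError(f"annotation missing column: {col}")
        if "best_match_label" not in df.columns:
            df["best_match_label"] = ""
        _check_unique(df["lineage_id"], "lineage")
        df["zoonotic_candidate"] = _parse_bool(df["zoonotic_candidate"])
        self.data = df

    @property
    def lineage_ids(self) -> list:
        return list(self.data["lineage_id"])

    def zoonotic_flags(self) -> pd.Series:
        return self.data.set_index("lineage_id")["zoonotic_candidate"]

    def n_zoonotic(self) -> int:
        return int(self.data["zoonotic_candidate"].sum())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageAnnotation":
        return read_annotations(path)

    def to_tsv(self, path: str | Path) -> None:
        write_annotations(self, path)


def _parse_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        raise ValidationError(
            f"unparseable boolean value(s): {s[out.isna()].unique().tolist()}"
        )
    return out.astype(bool)


# ---------------------------------------------------------------------------
# TSV dialect: tab-separated, UTF-8, '#'-prefixed comment lines.
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc


def read_lineage_table(path: str | Path, format: str = "tsv") -> LineageTable:
    """Read a lineage-by-sample count matrix.

    ``format='tsv'`` expects a header row of sample IDs with lineage IDs
    in the first column; ``format='biom'`` reads BIOM v1.0 JSON.
    """
    if format == "biom":
        return LineageTable.from_biom_json(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom'")
    df = _read_tsv(path)
    if df.shape[1] < 1:
        raise ValidationError(f"{path}: header row missing (line 1)")
    df = df.set_index(df.columns[0])
    df.index.name = "lineage_id"
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric count ({exc})") from exc
    return LineageTable(numeric)


def write_lineage_table(table: LineageTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "lineage_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = _read_tsv(path)
    if "community_richness" in df.columns:
        df["community_richness"] = pd.to_numeric(df["community_richness"])
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> LineageAnnotation:
    return LineageAnnotation(_read_tsv(path))


def write_annotations(ann: LineageAnnotation, path: str | Path) -> None:
    ann.data.to_csv(path, sep="\t", index=False)


def load_zoonotic_candidates() -> LineageAnnotation:
    """Packaged annotation table of suspected zoonotic, vector-borne lineages.

    Transcribes the published candidate list for the Negev gerbil blood
    survey (13 lineages counting multiplicities: four Capnocytophaga
    canimorsus lineages and two Corynebacterium urealyticum lineages).
    """
    path = Path(__file__).parent / "data" / "table1_annotations.tsv"
    return read_annotations(path)
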
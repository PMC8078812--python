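"""Typed containers and tab-delimited I/O for count tables, taxonomy, and
sample metadata.

All files are plain TSV with a header row.  The canonical count-table dialect
has samples as rows (first column ``sample_id``); a transposed dialect with
OTUs as rows (first column ``otu_id`` or the BIOM-convention ``#OTU ID``) is
auto-detected.  Taxonomy accepts either one rank column per level or a single
Greengenes-style string (``k__Bacteria; p__Firmicutes; ...``).  Unknown or
blank ranks are normalized to the sentinel ``"unknown"`` and are never merged
with named ranks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "unknown"
RANKS = ("phylum", "class", "order", "family", "genus", "species")
METADATA_COLUMNS = (
    "sample_id",
    "pig_id",
    "farm_id",
    "age_point",
    "weight_d26",
    "weight_d35",
    "weight_d48",
    "interval_days",
)


class TableValidationError(ValueError):
    """Raised when an input file violates a container invariant; the message
    names the first offending record."""


@dataclass
class CountTable:
    """Integer sample x OTU count matrix."""

    data: pd.DataFrame  # index: sample_id, columns: otu_id, dtype int64

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise TableValidationError(
                f"duplicate sample id: {df.index[df.index.duplicated()][0]!r}"
            )
        if df.columns.duplicated().any():
            raise TableValidationError(
                f"duplicate OTU id: {df.columns[df.columns.duplicated()][0]!r}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = df.index[(arr != np.round(arr)).any(axis=1)][0]
                raise TableValidationError(f"non-integer counts in sample {bad!r}")
            self.data = df.round().astype(np.int64)
            arr = self.data.to_numpy()
        if (arr < 0).any():
            bad = df.index[(arr < 0).any(axis=1)][0]
            raise TableValidationError(f"negative counts in sample {bad!r}")
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def to_tsv(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class RelAbundanceTable:
    """Row-normalized real matrix on the same axes as a CountTable.

    Rows sum to 1 (all-zero rows stay all-zero)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        if not ok.all():
            bad = self.data.index[~ok][0]
            raise TableValidationError(f"row {bad!r} does not sum to 0 or 1")

    def to_tsv(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class TaxonomyMap:
    """OTU -> six-rank lineage, any rank possibly the sentinel ``unknown``."""

    data: pd.DataFrame  # index: otu_id, columns: RANKS

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise TableValidationError(
                f"duplicate OTU id in taxonomy: {self.data.index[self.data.index.duplicated()][0]!r}"
            )
        for r in RANKS:
            if r not in self.data.columns:
                self.data[r] = UNKNOWN
        self.data = self.data[list(RANKS)].fillna(UNKNOWN)
        self.data = self.data.map(lambda s: UNKNOWN if str(s).strip() == "" else str(s))

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.data[rank]

    def require(self, otu_ids) -> None:
        missing = [o for o in otu_ids if o not in self.data.index]
        if missing:
            raise TableValidationError(f"taxonomy missing for OTU {missing[0]!r}")

    def to_tsv(self, path) -> None:
        self.data.rename_axis("otu_id").to_csv(path, sep="\t")


@dataclass
class SampleMetadata:
    """Per-sample pig / farm / age / weight records."""

    data: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        df = self.data
        for col in METADATA_COLUMNS[1:]:
            if col not in df.columns:
                raise TableValidationError(f"metadata missing required column {col!r}")
        if df.index.duplicated().any():
            raise TableValidationError(
                f"duplicate sample id in metadata: {df.index[df.index.duplicated()][0]!r}"
            )
        dup = df.duplicated(subset=["pig_id", "age_point"])
        if dup.any():
            raise TableValidationError(
                f"pig/age duplicated for sample {df.index[dup][0]!r}"
            )
        bad_age = ~df["age_point"].isin(["d26", "d35"])
        if bad_age.any():
            raise TableValidationError(
                f"invalid age_point for sample {df.index[bad_age][0]!r}"
            )
        for col in ("weight_d26", "weight_d35", "weight_d48"):
            bad = df[col].notna() & (df[col] <= 0)
            if bad.any():
                raise TableValidationError(
                    f"non-positive {col} for sample {df.index[bad][0]!r}"
                )
        bad_n = df["interval_days"].notna() & (df["interval_days"] <= 0)
        if bad_n.any():
            raise TableValidationError(
                f"non-positive interval_days for sample {df.index[bad_n][0]!r}"
            )

    def to_tsv(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers

def read_count_table(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    first = str(df.index.name or "").strip().lower()
    if first in {"#otu id", "otu_id", "otu id", "otuid"}:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df)


_GG_PREFIX = re.compile(r"^[kpcofgs]__")


def _parse_greengenes(s: str) -> dict[str, str]:
    parts = [p.strip() for p in str(s).split(";")]
    out = dict.fromkeys(RANKS, UNKNOWN)
    level_of = {"p": "phylum", "c": "class", "o": "order", "f": "family",
                "g": "genus", "s": "species"}
    for p in parts:
        m = _GG_PREFIX.match(p)
        if not m:
            continue
        level = p[0]
        value = p[3:].strip().strip("[]")
        if level in level_of and value:
            out[level_of[level]] = value
    return out


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    cols = {c.lower(): c for c in df.columns}
    if "taxonomy" in cols:
        parsed = df[cols["taxonomy"]].map(_parse_greengenes)
        tax = pd.DataFrame(list(parsed), index=df.index)
    else:
        tax = df.rename(columns=str.lower)
    return TaxonomyMap(tax)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pig_id": str})
    if "sample_id" not in df.columns:
        raise TableValidationError("metadata missing required column 'sample_id'")
    df = df.set_index("sample_id")
    return SampleMetadata(df)
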
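"""Abundance tables and their sample/taxon metadata.

The central container is :class:`AbundanceTable`, a samples × taxa matrix of
non-negative counts or relative abundances (OTU %), the starting point of the
whole pipeline. Tables are exchanged as delimited text (TSV by default, CSV by
flag) with the first column holding sample identifiers; a ``# unit:`` comment
line on the first row records whether the body is counts or percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMeta",
    "TaxonMeta",
    "TableValidationError",
    "TableParseError",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_taxon_metadata",
    "flag_organelles",
    "drop_organelles",
]

SPECIES = ("magnatum", "macrosporum")
COMPARTMENTS = ("surface", "gleba")

#: Labels that mark organelle pseudo-taxa (matched case-insensitively as
#: substrings of the rank label). These show up in 16S surveys of fungal
#: tissue — host mitochondria amplify with eubacterial primers — and are
#: flagged rather than dropped, because reported truffle communities
#: include them as observed pseudo-taxa.
DEFAULT_ORGANELLE_LABELS = ("Mitochondria", "Chloroplast")

PERCENT_TOL = 1e-6


class TableValidationError(ValueError):
    """A table violates an invariant (negative value, duplicate id, ...)."""


class TableParseError(ValueError):
    """A file could not be parsed into a valid table."""


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: a replicate of one truffle species/compartment."""

    sample_id: str
    species: str
    compartment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise TableValidationError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if self.compartment not in COMPARTMENTS:
            raise TableValidationError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )
        if self.replicate < 1:
            raise TableValidationError("replicate must be a positive integer")

    @property
    def group(self) -> tuple[str, str]:
        return (self.species, self.compartment)


@dataclass(frozen=True)
class TaxonMeta:
    taxon_id: str
    kingdom: str = ""
    phylum: str = ""
    rank_label: str = ""
    organelle_flag: bool = False


@dataclass
class AbundanceTable:
    """Samples × taxa matrix of non-negative counts or OTU percentages.

    Parameters
    ----------
    data
        DataFrame with sample ids on the index and taxon ids on the columns.
    unit
        ``"counts"`` or ``"percent"``. Percent rows must close to 100.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "percent"):
            raise TableValidationError(f"unknown unit {self.unit!r}")
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise TableValidationError("table must have at least one sample and one taxon")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate taxon identifiers: {dups}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise TableValidationError(
                f"missing value at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative value {values[r, c]} at sample {df.index[r]!r}, "
                f"taxon {df.columns[c]!r}"
            )
        if self.unit == "percent":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 100.0) > max(PERCENT_TOL, 1e-9 * 100.0)
            if bad.any():
                i = int(np.argmax(bad))
                raise TableValidationError(
                    f"percent rows must sum to 100: sample {df.index[i]!r} "
                    f"sums to {sums[i]}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise TableValidationError(f"unknown samples: {missing}")
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(), self.unit)

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "AbundanceTable":
        missing = [t for t in taxon_ids if t not in self.data.columns]
        if missing:
            raise TableValidationError(f"unknown taxa: {missing}")
        sub = self.data[list(taxon_ids)].copy()
        if self.unit == "percent":
            # Subsetting breaks closure; re-close each row to 100.
            sums = sub.sum(axis=1)
            if (sums <= 0).any():
                empty = sums.index[(sums <= 0).to_numpy()].tolist()
                raise TableValidationError(
                    f"samples with zero total after taxon subset: {empty}"
                )
            return AbundanceTable(sub * (100.0 / sums).to_numpy()[:, None], "percent")
        return AbundanceTable(sub, "counts")

    def equals(self, other: "AbundanceTable", rtol: float = 1e-9) -> bool:
        return (
            self.unit == other.unit
            and self.samples == other.samples
            and self.taxa == other.taxa
            and np.allclose(self.values, other.values, rtol=rtol, atol=1e-12)
        )


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise TableParseError(
                f"malformed numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        out[col] = coerced
    return pd.DataFrame(out, index=df.index)


def read_abundance_table(
    path: str | Path,
    delimiter: str = "\t",
    orientation: str = "samples_in_rows",
    unit: str | None = None,
) -> AbundanceTable:
    """Parse a delimited abundance matrix into samples-in-rows form.

    A leading ``# unit: counts|percent`` comment line, as written by
    :func:`write_abundance_table`, sets the unit unless ``unit`` overrides it.
    """
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    header_unit = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            tag = line.lstrip("#").strip()
            if tag.startswith("unit:"):
                header_unit = tag.split(":", 1)[1].strip()
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise TableValidationError(f"{path}: duplicate identifiers in header: {dups}")
    raw = pd.read_csv(path, sep=delimiter, index_col=0, skiprows=skip, dtype=object)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise TableParseError(f"{path}: table has no data rows or columns")
    df = _coerce_numeric(raw)
    if orientation == "taxa_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    resolved = unit or header_unit or "counts"
    try:
        return AbundanceTable(df, resolved)
    except TableValidationError as exc:
        raise TableValidationError(f"{path}: {exc}") from exc


def write_abundance_table(
    table: AbundanceTable, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a table as delimited text with a ``# unit:`` header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unit: {table.unit}\n")
        table.data.to_csv(fh, sep=delimiter, index_label="sample_id",
                          float_format="%.10g")
    return path


# alias: this writer is the table-output entry point of the pipeline
write_outputs = write_abundance_table


_META_COLUMNS = ("sample_id", "species", "compartment", "replicate")


def read_sample_metadata(path: str | Path, delimiter: str = "\t") -> list[SampleMeta]:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing metadata columns {missing}")
    records = [
        SampleMeta(
            sample_id=str(row.sample_id),
            species=str(row.species),
            compartment=str(row.compartment),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
    ids = [m.sample_id for m in records]
    if len(set(ids)) != len(ids):
        raise TableValidationError(f"{path}: duplicate sample ids in metadata")
    return records


def write_sample_metadata(meta: Sequence[SampleMeta], path: str | Path,
                          delimiter: str = "\t") -> Path:
    df = pd.DataFrame(
        [(m.sample_id, m.species, m.compartment, m.replicate) for m in meta],
        columns=list(_META_COLUMNS),
    )
    df.to_csv(path, sep=delimiter, index=False)
    return Path(path)


def read_taxon_metadata(path: str | Path, delimiter: str = "\t") -> list[TaxonMeta]:
    df = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    required = ("taxon_id", "kingdom", "phylum", "rank_label")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing metadata columns {missing}")
    return flag_organelles(
        [
            TaxonMeta(
                taxon_id=str(r.taxon_id),
                kingdom=str(r.kingdom),
                phylum=str(r.phylum),
                rank_label=str(r.rank_label),
            )
            for r in df.itertuples()
        ]
    )


def flag_organelles(
    taxa: Iterable[TaxonMeta],
    organelle_labels: Sequence[str] = DEFAULT_ORGANELLE_LABELS,
) -> list[TaxonMeta]:
    """Set ``organelle_flag`` on taxa whose rank label names an organelle.

    Matching is a case-insensitive substring test, so "Mitochondria spp."
    and "mitochondria" both flag. No records are removed: organelle
    pseudo-taxa are part of the observed communities and dropping them is an
    explicit opt-in (:func:`drop_organelles`).
    """
    needles = [lbl.lower() for lbl in organelle_labels]
    out = []
    for t in taxa:
        hay = t.rank_label.lower()
        flagged = any(n in hay for n in needles)
        out.append(replace(t, organelle_flag=flagged))
    return out


def drop_organelles(
    table: AbundanceTable, taxa_meta: Sequence[TaxonMeta]
) -> AbundanceTable:
    """Opt-in removal of flagged organelle pseudo-taxa from a table."""
    flagged = {t.taxon_id for t in taxa_meta if t.organelle_flag}
    keep = [t for t in table.taxa if t not in flagged]
    if not keep:
        raise TableValidationError("dropping organelles would leave no taxa")
    return table.subset_taxa(keep)
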
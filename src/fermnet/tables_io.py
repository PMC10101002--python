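"""Tabular I/O and sample alignment.

All pipeline inputs are plain TSV matrices: taxa-by-sample abundance tables
(one per domain, bacteria and fungi, sharing sample IDs), a
metabolite-by-sample concentration table, and per-sample metadata (group,
fermentation day, environmental covariates).  Alignment between tables is
always by sample-ID string match, never by position, and missing values are
not allowed: "not detected" must be written as an explicit zero.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "fungi")

_REL_TOL = 1e-6


class TableError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise TableError(f"duplicate {what} IDs: {dups}")


@dataclass
class AbundanceTable:
    """A taxa x samples abundance matrix with per-taxon domain labels.

    ``counts`` may hold integer read counts or relative abundances in [0, 1];
    ``is_relative`` records which.  For a relative table every sample column
    sums to 1 within each domain block (bacterial and fungal libraries are
    sequenced and normalized separately).
    """

    counts: pd.DataFrame
    domain_of: pd.Series
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        _check_unique(self.counts.index, "taxon")
        _check_unique(self.counts.columns, "sample")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.lt(0).any(axis=1)
            raise TableError(
                f"negative abundance for taxa: {list(self.counts.index[bad])}"
            )
        self.domain_of = pd.Series(self.domain_of).reindex(self.counts.index)
        if self.domain_of.isna().any():
            missing = list(self.counts.index[self.domain_of.isna()])
            raise TableError(f"taxa without domain label: {missing}")
        unknown = set(self.domain_of.unique()) - set(DOMAINS)
        if unknown:
            raise TableError(f"unknown domain labels: {sorted(unknown)}")
        if self.is_relative:
            for dom in self.domain_of.unique():
                block = self.counts.loc[self.domain_of == dom]
                sums = block.sum(axis=0).to_numpy()
                if not np.allclose(sums, 1.0, atol=_REL_TOL):
                    raise TableError(
                        f"relative table: {dom} columns do not sum to 1 "
                        f"(range {sums.min():.6g}..{sums.max():.6g})"
                    )

    # -- accessors ---------------------------------------------------------

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances, normalized within each domain."""
        if self.is_relative:
            return self.counts.copy()
        out = self.counts.copy()
        for dom in self.domain_of.unique():
            mask = (self.domain_of == dom).to_numpy()
            block = out.loc[mask]
            sums = block.sum(axis=0).replace(0.0, np.nan)
            out.loc[mask] = block.div(sums, axis=1).fillna(0.0)
        return out

    def subset_taxa(self, taxa) -> "AbundanceTable":
        taxa = [t for t in taxa if t in self.counts.index]
        return AbundanceTable(
            self.counts.loc[taxa], self.domain_of.loc[taxa], self.is_relative
        )

    def subset_samples(self, samples) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.loc[:, list(samples)], self.domain_of, self.is_relative
        )

    def __eq__(self, other) -> bool:  # exported-field equality
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.is_relative == other.is_relative
            and self.counts.equals(other.counts)
            and self.domain_of.equals(other.domain_of)
        )


@dataclass
class MetaboliteTable:
    """Metabolite x sample concentrations (unit carried as metadata)."""

    concentrations: pd.DataFrame
    unit: str = "mg/kg"

    def __post_init__(self) -> None:
        self.concentrations = self.concentrations.astype(float)
        _check_unique(self.concentrations.index, "metabolite")
        _check_unique(self.concentrations.columns, "sample")
        if (self.concentrations.to_numpy() < 0).any():
            raise TableError("negative metabolite concentration")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.columns)


@dataclass
class SampleMetadata:
    """Per-sample design information: group, time, numeric covariates.

    ``frame`` is indexed by sample ID and must cover (be a superset of) the
    samples of any table it is analyzed with.
    """

    frame: pd.DataFrame
    group_col: str = "group"
    time_col: str = "time"

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def groups(self, samples=None) -> pd.Series:
        s = self.frame[self.group_col]
        return s.loc[list(samples)] if samples is not None else s

    def require_samples(self, samples) -> None:
        missing = sorted(set(samples) - set(self.frame.index))
        if missing:
            raise TableError(f"metadata missing samples: {missing}")

    def covariates(self) -> pd.DataFrame:
        drop = [c for c in (self.group_col,) if c in self.frame.columns]
        return self.frame.drop(columns=drop).select_dtypes("number")


# -- readers ---------------------------------------------------------------


def _read_numeric_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise TableError(
                f"non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise TableError(
                f"missing value at row {row!r}, column {col!r}; "
                "write an explicit 0 for 'not detected'"
            )
        out[col] = converted
    return out


def read_abundance_table(path, domain: str = "bacteria",
                         is_relative: bool | None = None) -> AbundanceTable:
    """Read a TSV abundance matrix (first column taxon IDs, header samples).

    ``is_relative`` is inferred (all column sums within 1e-6 of 1) when not
    given explicitly.
    """
    df = _read_numeric_matrix(path)
    if is_relative is None:
        sums = df.sum(axis=0).to_numpy()
        is_relative = bool(len(sums) and np.allclose(sums, 1.0, atol=_REL_TOL))
    domain_of = pd.Series(domain, index=df.index)
    return AbundanceTable(df, domain_of, is_relative)


def read_metabolite_table(path, unit: str = "mg/kg") -> MetaboliteTable:
    return MetaboliteTable(_read_numeric_matrix(path), unit=unit)


def read_metadata(path, group_col: str = "group",
                  time_col: str = "time") -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df, group_col=group_col, time_col=time_col)


def read_taxonomy(path) -> pd.Series:
    """Two-column TSV (taxon_id, semicolon-delimited lineage) -> Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=None,
                     names=["taxon_id", "lineage"])
    _check_unique(df.index, "taxon")
    return df["lineage"]


# -- merge -----------------------------------------------------------------


def merge_domains(bact: AbundanceTable, fungi: AbundanceTable,
                  renormalize: str = "none") -> AbundanceTable:
    """Row-concatenate a bacterial and a fungal table on shared samples.

    ``renormalize``: "none" keeps the raw counts; "per_domain" converts to
    relative abundance within each domain separately (each domain's columns
    sum to 1, the default analysis convention since 16S and ITS libraries are
    normalized separately); "global" renormalizes jointly over the union.
    """
    sb, sf = set(bact.sample_ids), set(fungi.sample_ids)
    if sb != sf:
        diff = sorted(sb.symmetric_difference(sf))
        raise TableError(f"sample sets differ between domains: {diff}")
    overlap = set(bact.taxa_ids) & set(fungi.taxa_ids)
    if overlap:
        raise TableError(f"taxon IDs present in both domains: {sorted(overlap)}")
    fungi_aligned = fungi.counts.loc[:, bact.sample_ids]
    if renormalize == "none":
        counts = pd.concat([bact.counts, fungi_aligned])
        is_rel = bact.is_relative and fungi.is_relative
    elif renormalize == "per_domain":
        counts = pd.concat(
            [bact.relative_abundance(),
             fungi.relative_abundance().loc[:, bact.sample_ids]]
        )
        is_rel = True
    elif renormalize == "global":
        counts = pd.concat([bact.relative_abundance(),
                            fungi.relative_abundance().loc[:, bact.sample_ids]])
        counts = counts.div(counts.sum(axis=0), axis=1)
        # global normalization breaks the per-domain sum invariant on purpose
        dom = pd.concat([bact.domain_of, fungi.domain_of])
        out = AbundanceTable.__new__(AbundanceTable)
        out.counts = counts.astype(float)
        out.domain_of = dom
        out.is_relative = False  # columns sum to 1 jointly, flag as plain
        return out
    else:
        raise ValueError(f"unknown renormalize mode: {renormalize!r}")
    dom = pd.concat([bact.domain_of, fungi.domain_of])
    return AbundanceTable(counts, dom, is_rel)


# -- writers ---------------------------------------------------------------


def write_abundance_table(t: AbundanceTable, path) -> None:
    path = Path(path)
    t.counts.to_csv(path, sep="\t")
    doms = t.domain_of.rename("domain")
    doms.to_csv(path.with_suffix(path.suffix + ".domains"), sep="\t",
                header=True, index_label="taxon_id")


def read_written_abundance_table(path, is_relative: bool | None = None) -> AbundanceTable:
    """Inverse of :func:`write_abundance_table` (uses the domain sidecar)."""
    path = Path(path)
    df = _read_numeric_matrix(path)
    doms = pd.read_csv(path.with_suffix(path.suffix + ".domains"),
                       sep="\t", index_col=0)["domain"]
    doms.index = doms.index.astype(str)
    if is_relative is None:
        sums = df.sum(axis=0).to_numpy()
        is_relative = bool(np.allclose(sums, 1.0, atol=_REL_TOL))
    return AbundanceTable(df, doms, is_relative)


def write_results(obj, path) -> None:
    """Serialize a result object: TSV for tables, JSON for fit summaries.

    Dispatches on type; network objects get GraphML plus an edge-list TSV
    (see :mod:`fermnet.network`), model fits a JSON scalar summary plus a
    per-taxon TSV.
    """
    from . import assembly, network  # local import to avoid cycles

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, AbundanceTable):
        write_abundance_table(obj, path)
    elif isinstance(obj, MetaboliteTable):
        obj.concentrations.to_csv(path, sep="\t")
    elif isinstance(obj, SampleMetadata):
        obj.frame.to_csv(path, sep="\t")
    elif isinstance(obj, network.CooccurrenceNetwork):
        network.write_network(obj, path)
    elif isinstance(obj, assembly.NeutralFit):
        assembly.write_neutral_fit(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
    elif isinstance(obj, dict):
        with open(path, "w") as fh:
            json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
    elif dataclasses.is_dataclass(obj):
        with open(path, "w") as fh:
            json.dump(_jsonable(dataclasses.asdict(obj)), fh, indent=2,
                      sort_keys=True, default=str)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj
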
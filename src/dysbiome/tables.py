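"""Count-table container, TSV input/output, and standard preprocessing.

Tables are taxa-as-rows, samples-as-columns everywhere in this package.
The on-disk dialect is plain TSV (UTF-8, no quoting, '.' decimal point):
taxon ids in the first column, sample ids in the header row.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "rarefy",
    "to_relative",
    "aggregate_taxa",
    "top_n_profile",
]

_PROPORTION_TOL = 1e-9


@dataclass
class CountTable:
    """Taxa x samples abundance matrix with a unit tag.

    ``unit`` is either ``"counts"`` (non-negative numbers, typically
    integers) or ``"proportions"`` (each sample column sums to 1).
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "proportions"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated taxon id(s): {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample id(s): {dups}")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            bad = self.data.index[np.isnan(values).any(axis=1)][0]
            raise ValueError(f"missing value in row {bad!r} (ragged or non-numeric input)")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance for taxon {self.data.index[i]!r} "
                f"in sample {self.data.columns[j]!r}"
            )
        if self.unit == "proportions":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.data.columns[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"proportions in sample {bad!r} do not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data[list(sample_ids)].copy(), unit=self.unit)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.unit == other.unit and self.data.equals(other.data)


def read_count_table(path, unit: str = "counts") -> CountTable:
    """Read a taxa x samples TSV (taxon ids first column, sample ids header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicated sample id(s) in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric abundance value in {path}: {exc}") from exc
    if (df.to_numpy() % 1 == 0).all() and unit == "counts":
        df = df.astype(np.int64)
    return CountTable(df, unit=unit)


def write_count_table(table: CountTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = table.data
    if table.unit == "counts" and np.all(np.mod(df.to_numpy(), 1) == 0):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path, treatments: list[str] | None = None) -> pd.DataFrame:
    """Read per-sample metadata keyed by ``sample_id``.

    Requires columns ``individual``, ``treatment`` and ``timepoint_h``;
    ``treatments``, when given, is the declared label set to validate against.
    """
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "individual", "treatment", "timepoint_h"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample id(s) in metadata: {dups}")
    md["timepoint_h"] = pd.to_numeric(md["timepoint_h"])
    if treatments is not None:
        unknown = set(md["treatment"]) - set(treatments)
        if unknown:
            raise ValueError(f"treatment label(s) outside declared set: {sorted(unknown)}")
    return md.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def rarefy(table: CountTable, depth: int = 5400, seed: int | None = None) -> CountTable:
    """Subsample every sample column without replacement to exactly ``depth``.

    Samples whose total count is below ``depth`` are dropped with a warning
    (never padded). Drawing is multivariate hypergeometric (urn subsampling)
    and is performed in canonical (sorted taxon id) order, which makes the
    result invariant to the row order of the input for a fixed seed.
    """
    if table.unit != "counts":
        raise ValueError("rarefaction requires a table in counts")
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    order = np.argsort(np.asarray(table.data.index.astype(str)))
    canonical = table.data.iloc[order]
    counts = canonical.to_numpy().astype(np.int64)
    kept, dropped, columns = [], [], []
    for j, sample in enumerate(canonical.columns):
        total = counts[:, j].sum()
        if total < depth:
            dropped.append(sample)
            continue
        columns.append(sample)
        kept.append(rng.multivariate_hypergeometric(counts[:, j], depth))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    if not columns:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(
        np.column_stack(kept), index=canonical.index, columns=columns
    )
    # restore the caller's row order
    out = out.loc[table.data.index]
    return CountTable(out, unit="counts")


def to_relative(table: CountTable) -> CountTable:
    """Total-sum scale each sample column to proportions."""
    if table.unit != "counts":
        raise ValueError("table is already in proportions (unit mismatch)")
    sums = table.values.sum(axis=0)
    if (sums == 0).any():
        bad = table.data.columns[np.argmax(sums == 0)]
        raise ValueError(f"sample {bad!r} has zero total count")
    return CountTable(table.data / sums, unit="proportions")


def _taxonomy_frame(taxonomy) -> pd.DataFrame:
    if isinstance(taxonomy, pd.DataFrame):
        return taxonomy
    # mapping taxon_id -> {rank: label}
    return pd.DataFrame.from_dict(dict(taxonomy), orient="index")


def aggregate_taxa(table: CountTable, taxonomy, rank: str) -> CountTable:
    """Sum rows sharing the same ``rank`` label; unmapped ids go to "Unassigned"."""
    tax = _taxonomy_frame(taxonomy)
    if rank not in tax.columns:
        raise ValueError(f"unknown rank {rank!r}; taxonomy has {list(tax.columns)}")
    labels = [
        str(tax.at[t, rank]) if (t in tax.index and pd.notna(tax.at[t, rank])) else "Unassigned"
        for t in table.data.index
    ]
    grouped = table.data.groupby(pd.Index(labels, name=rank), sort=True).sum()
    return CountTable(grouped, unit=table.unit)


def top_n_profile(table: CountTable, n: int) -> CountTable:
    """Keep the n taxa of highest mean proportion; pool the rest into "Other".

    Ties in mean proportion are broken by lexicographic taxon id, so the
    selection is deterministic. The "Other" row is always present (zero when
    n covers every taxon).
    """
    if table.unit != "proportions":
        raise ValueError("top_n_profile requires proportions")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    means = table.data.mean(axis=1)
    ranked = sorted(table.data.index, key=lambda t: (-means[t], str(t)))
    keep = ranked[:n]
    rest = ranked[n:]
    top = table.data.loc[keep]
    other = table.data.loc[rest].sum(axis=0)
    other.name = "Other"
    out = pd.concat([top, other.to_frame().T])
    return CountTable(out, unit="proportions")
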
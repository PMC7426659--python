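"""TSV readers and writers for count tables, copy numbers and load tables.

All files are tab-separated UTF-8 with '.' decimals.  Count tables have the
taxon id in the first column and one column per sample; copy-number tables
are two columns (taxon, copy number); load tables follow the long schema
``sample_id, replicate, method, treatment, value, units``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import CopyNumberTable, QuantProfile, TaxonCountTable
from .simulate import LOAD_COLUMNS


def read_count_table(path) -> TaxonCountTable:
    """Read a taxon-by-sample integer count TSV.

    Rejects duplicate ids, empty tables and non-integer or negative cells,
    naming the first offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells in count table")
    frac = values != np.floor(values)
    if frac.any():
        r, c = np.argwhere(frac)[0]
        raise ValueError(
            f"{path}: non-integer count at taxon {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    neg = values < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: negative count at taxon {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return TaxonCountTable(df.astype(np.int64))


def write_count_table(table: TaxonCountTable, path) -> None:
    df = table.counts if isinstance(table, TaxonCountTable) else pd.DataFrame(table)
    df.to_csv(path, sep="\t", index_label="taxon")


def read_copy_numbers(path, default="mean") -> CopyNumberTable:
    """Read a two-column taxon/copy-number TSV.

    ``default`` is the fallback for taxa absent from the table: ``"mean"``
    (table mean, the default), a number, or None (strict; missing taxa
    raise downstream).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (taxon, copy number)")
    series = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str)
    )
    if default == "mean":
        default = float(series.mean())
    return CopyNumberTable(series, default=default)


def write_copy_numbers(table: CopyNumberTable, path) -> None:
    series = table.copy_numbers if isinstance(table, CopyNumberTable) else table
    series.rename("copy_number").to_csv(
        path, sep="\t", index_label="taxon", header=True
    )


def read_load_table(path) -> pd.DataFrame:
    """Read a long-format load table; validates schema and positivity."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LOAD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: load table missing columns {missing}")
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative load values")
    return df[LOAD_COLUMNS]


def write_load_table(df: pd.DataFrame, path) -> None:
    df[LOAD_COLUMNS].to_csv(path, sep="\t", index=False)


def write_profile(profile: QuantProfile, path, sidecar: bool = True) -> None:
    """Write a profile matrix plus a sidecar provenance file.

    The sidecar (``<path>.provenance.tsv``) records the method, seed and
    per-sample realized sampling depth and load.
    """
    path = Path(path)
    profile.abundances.to_csv(path, sep="\t", index_label="taxon")
    if sidecar:
        prov = pd.DataFrame({"sampling_depth": profile.sampling_depth})
        if profile.loads is not None:
            prov["load"] = profile.loads
        prov.insert(0, "method", profile.method)
        prov.insert(1, "seed", profile.seed)
        prov.to_csv(
            path.with_suffix(path.suffix + ".provenance.tsv"),
            sep="\t",
            index_label="sample_id",
        )


def read_profile_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
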
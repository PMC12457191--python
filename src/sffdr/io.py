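"""Reading, validating and harmonizing GWAS summary-statistic tables.

Input files are delimited text (tab or comma, gzip transparently handled)
with one row per SNP and a header.  Default column names are ``snp``,
``chr``, ``pos`` and ``p``; a ``column_map`` renames nonstandard headers.
Matching across studies is by SNP identifier only -- the framework uses
only P values, so no allele harmonization is performed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["read_sumstats", "harmonize_studies", "write_results", "read_results"]

STANDARD_COLUMNS = {"snp": "snp", "chr": "chr", "pos": "pos", "p": "p"}


def read_sumstats(
    path,
    column_map: dict | None = None,
    delimiter: str | None = None,
    clamp_zero: bool = False,
    duplicate_policy: str = "error",
) -> pd.DataFrame:
    """Load one study's summary statistics into a validated table.

    Parameters
    ----------
    path : str or Path
        Delimited text file (``.gz`` accepted) with a header row.
    column_map : dict, optional
        Maps standard names (``snp``, ``chr``, ``pos``, ``p``) to the
        file's actual column names.
    delimiter : str, optional
        Field separator; sniffed from the file when omitted.
    clamp_zero : bool
        Replace ``p == 0`` by the smallest positive float with a warning
        instead of rejecting the file.
    duplicate_policy : {"error", "keep-first"}
        How to treat repeated SNP identifiers.

    Returns
    -------
    DataFrame with columns ``snp``, ``chr``, ``pos`` (NaN when absent in
    the file) and ``p`` in (0, 1]; rows with missing P are dropped.
    """
    names = dict(STANDARD_COLUMNS)
    if column_map:
        names.update(column_map)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", compression="infer")
    else:
        df = pd.read_csv(path, sep=delimiter, compression="infer")
    if names["p"] not in df.columns:
        raise KeyError(
            f"P-value column {names['p']!r} not found in {path}; "
            f"available columns: {list(df.columns)}"
        )
    if names["snp"] not in df.columns:
        raise KeyError(f"SNP identifier column {names['snp']!r} not found in {path}")

    out = pd.DataFrame({"snp": df[names["snp"]].astype(str)})
    for col in ("chr", "pos"):
        out[col] = df[names[col]] if names[col] in df.columns else np.nan
    out["p"] = pd.to_numeric(df[names["p"]], errors="coerce").astype(float)

    n_missing = int(out["p"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} row(s) with missing P value dropped", stacklevel=2)
        out = out.loc[out["p"].notna()].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"no usable rows in {path}")

    zero = out["p"] == 0
    if zero.any():
        if clamp_zero:
            warnings.warn(
                f"{int(zero.sum())} row(s) with p=0 clamped to the smallest "
                "positive float",
                stacklevel=2,
            )
            out.loc[zero, "p"] = np.finfo(float).tiny
        else:
            bad = out.loc[zero, "snp"].iloc[0]
            raise ValueError(
                f"p=0 at SNP {bad!r}; pass clamp_zero=True to accept such rows"
            )
    invalid = (out["p"] < 0) | (out["p"] > 1)
    if invalid.any():
        row = out.loc[invalid].iloc[0]
        raise ValueError(
            f"P value {row['p']} outside (0, 1] at SNP {row['snp']!r}"
        )

    dup = out["snp"].duplicated()
    if dup.any():
        if duplicate_policy == "keep-first":
            out = out.loc[~dup].reset_index(drop=True)
        elif duplicate_policy == "error":
            raise ValueError(
                f"duplicate SNP identifier {out.loc[dup, 'snp'].iloc[0]!r}; "
                "use duplicate_policy='keep-first' to keep the first occurrence"
            )
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    return out


def harmonize_studies(primary: pd.DataFrame, informative: list[pd.DataFrame]) -> pd.DataFrame:
    """Intersect the primary and informative studies by SNP identifier.

    Returns a table with columns ``snp``, ``chr``, ``pos``, ``p`` (primary)
    and ``z_1 .. z_d`` (informative P values), ordered by (chr, pos) when
    positions are available for every retained SNP and by primary-file
    order otherwise.  ``.attrs`` records ``m`` and ``d``.
    """
    if len(informative) < 1:
        raise ValueError("at least one informative study is required")
    table = primary.copy()
    for k, study in enumerate(informative, start=1):
        zmap = study.set_index("snp")["p"]
        table[f"z_{k}"] = table["snp"].map(zmap)
    table = table.loc[table.filter(like="z_").notna().all(axis=1)].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no overlapping SNPs between the primary and informative studies")
    if table["chr"].notna().all() and table["pos"].notna().all():
        table = table.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
    table.attrs["m"] = len(table)
    table.attrs["d"] = len(informative)
    return table


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV, preserving 12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
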
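"""Reading, validating and normalizing expression signatures and matrices.

A *signature* is the per-gene differential-expression evidence a treatment
versus control comparison produces: HGNC-style gene symbol, log2 ratio
(treated over control) and P-value, optionally a moderated t-statistic and a
BH-adjusted P-value.  Signatures travel as plain TSV/CSV files and live in
memory as a :class:`pandas.DataFrame` with columns ``gene``, ``log2_ratio``,
``p_value`` (and optionally ``t_stat``, ``adj_p``).

A two-group *expression matrix* (genes x samples, already on the log scale)
is the raw material for the differential-expression module; it is wrapped in
:class:`ExpressionMatrix` together with the sample-to-group assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATMENT = "treatment"

#: header spellings accepted for each signature column (lower-cased,
#: punctuation stripped)
GENE_ALIASES = {"gene", "symbol", "genesymbol", "genes", "hgnc", "hgncsymbol", "name"}
RATIO_ALIASES = {"log2ratio", "log2fc", "logfc", "lfc", "ratio", "foldchange", "log2"}
P_ALIASES = {"pvalue", "pval", "p"}
ADJP_ALIASES = {"adjp", "adjpval", "padj", "adjpvalue", "fdr", "qvalue", "q"}
T_ALIASES = {"tstat", "t", "tstatistic", "moderatedt"}

SIGNATURE_COLUMNS = ["gene", "log2_ratio", "p_value"]
OPTIONAL_COLUMNS = ["t_stat", "adj_p"]


def _normalize_header(cell: object) -> str:
    s = str(cell).strip().lower()
    return "".join(ch for ch in s if ch.isalnum())


def _detect_sep(path: Path, dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv, csv or auto")
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    return "\t"


def _map_header(cells: list[str]) -> dict[str, int] | None:
    """Map signature column names to positions, or None if no header found."""
    norm = [_normalize_header(c) for c in cells]
    mapping: dict[str, int] = {}
    alias_table = [
        ("gene", GENE_ALIASES),
        ("log2_ratio", RATIO_ALIASES),
        ("p_value", P_ALIASES),
        ("adj_p", ADJP_ALIASES),
        ("t_stat", T_ALIASES),
    ]
    for col, aliases in alias_table:
        for i, cell in enumerate(norm):
            if cell in aliases and i not in mapping.values():
                mapping[col] = i
                break
    if "gene" in mapping or "p_value" in mapping or "log2_ratio" in mapping:
        return mapping
    return None


def dedupe_signature(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols to a single record per gene.

    Keeps the record with the smallest P-value; ties are broken by larger
    |log2 ratio|, then by first occurrence — deterministic regardless of the
    input row order when P-values are distinct.
    """
    order = np.arange(len(df))
    key = df.assign(_o=order, _a=-df["log2_ratio"].abs())
    key = key.sort_values(["p_value", "_a", "_o"], kind="stable")
    kept = key.drop_duplicates("gene", keep="first").sort_values("_o")
    return kept.drop(columns=["_o", "_a"]).reset_index(drop=True)


def read_signature(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read a differential-expression signature from a TSV/CSV text file.

    The file needs at least three columns mappable to gene symbol, log2
    ratio and P-value — by header name when a header is present, by position
    otherwise.  Gene symbols are upper-cased and de-duplicated; rows with
    unparseable numerics or P-values outside [0, 1] are dropped and counted
    in the log.

    Returns a DataFrame with columns ``gene``, ``log2_ratio``, ``p_value``
    plus ``t_stat`` / ``adj_p`` when the file carries them.
    """
    path = Path(path)
    sep = _detect_sep(path, dialect)
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                          comment=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if raw.empty:
        raise ValueError(f"{path}: no records")
    header_map = _map_header(list(raw.iloc[0]))
    if header_map is not None:
        raw = raw.iloc[1:].reset_index(drop=True)
        colmap = header_map
    else:
        if raw.shape[1] < 3:
            raise ValueError(f"{path}: need >= 3 columns (gene, log2 ratio, P-value)")
        colmap = {"gene": 0, "log2_ratio": 1, "p_value": 2}
    if raw.empty:
        raise ValueError(f"{path}: no records")
    for required in SIGNATURE_COLUMNS:
        if required not in colmap:
            raise ValueError(f"{path}: could not locate a {required!r} column")

    out = pd.DataFrame({"gene": raw.iloc[:, colmap["gene"]].astype(str).str.strip().str.upper()})
    for col in ["log2_ratio", "p_value"] + [c for c in OPTIONAL_COLUMNS if c in colmap]:
        out[col] = pd.to_numeric(raw.iloc[:, colmap[col]], errors="coerce")

    n_unparseable = int(out[["log2_ratio", "p_value"]].isna().any(axis=1).sum()
                        + (~np.isfinite(out["log2_ratio"].fillna(0.0))).sum())
    out = out[out["log2_ratio"].notna() & np.isfinite(out["log2_ratio"])
              & out["p_value"].notna()]
    if n_unparseable:
        logger.info("%s: dropped %d record(s) with missing/unparseable numerics",
                    path.name, n_unparseable)
    bad_p = (out["p_value"] < 0) | (out["p_value"] > 1)
    if bad_p.any():
        logger.info("%s: rejected %d record(s) with P-value outside [0, 1]",
                    path.name, int(bad_p.sum()))
        out = out[~bad_p]
    out = out[out["gene"].str.len() > 0]
    if out.empty:
        raise ValueError(f"{path}: no records")
    return dedupe_signature(out.reset_index(drop=True))


def write_signature(sig: pd.DataFrame, path: str | Path) -> None:
    """Write a signature as CSV with a header (spreadsheet-importable)."""
    cols = [c for c in SIGNATURE_COLUMNS + OPTIONAL_COLUMNS if c in sig.columns]
    sig.to_csv(path, columns=cols, index=False)


@dataclass
class ExpressionMatrix:
    """A genes x samples log-expression matrix with a two-group design.

    ``values`` is indexed by gene symbol with one column per sample;
    ``groups`` maps each sample to ``"control"`` or ``"treatment"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"sample(s) without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - {CONTROL, TREATMENT}
        if bad:
            raise ValueError(f"group labels must be 'control' or 'treatment', got {sorted(bad)}")
        counts = self.groups.value_counts()
        for grp in (CONTROL, TREATMENT):
            if counts.get(grp, 0) < 2:
                raise ValueError(
                    f"group {grp!r} has {counts.get(grp, 0)} sample(s); "
                    "at least two replicates per group are required")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values after ingestion")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])


def read_matrix(path: str | Path, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header row
    sample IDs) and attach group labels.

    Rows with missing values are rejected (counted in the log); duplicated
    gene symbols keep the row with the highest mean expression.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%s: rejected %d row(s) with missing entries", path.name, n_missing)
        df = df.dropna()
    if df.empty:
        raise ValueError(f"{path}: no usable rows")
    if df.index.has_duplicates:
        sel = (pd.DataFrame({"gene": df.index,
                             "mean": df.mean(axis=1).to_numpy(),
                             "_o": np.arange(len(df))})
               .sort_values(["mean", "_o"], ascending=[False, True],
                            kind="stable")
               .drop_duplicates("gene", keep="first")
               .sort_values("_o"))
        df = df.iloc[sel["_o"].to_numpy()]
    return ExpressionMatrix(values=df, groups=pd.Series(dict(groups)))


def write_matrix(matrix: ExpressionMatrix, path: str | Path,
                 float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", float_format=float_format,
                         index_label="gene")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample-to-group TSV (sample, label)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, group)")
    first = _normalize_header(df.iloc[0, 0])
    if first in {"sample", "sampleid", "id"}:
        df = df.iloc[1:]
    return {str(r[0]).strip(): str(r[1]).strip().lower()
            for r in df.itertuples(index=False)}
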
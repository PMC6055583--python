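"""Readers/writers for the plain-text side formats.

Layer matrices travel as TSV (see :class:`triomix.layers.OmicsLayer`);
this module covers probe annotation (BED-like TSV, 1-based inclusive
internally, exported BED as 0-based half-open), gene intervals, gene sets
(GMT) and ID-mapping tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "gene"]
GENE_COLUMNS = ["chrom", "start", "end", "gene"]


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end, probe_id, gene (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str, "gene": str})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe annotation missing columns {missing}")
    df["gene"] = df["gene"].fillna("")
    if (df["start"] < 1).any():
        raise ValueError("probe positions must be 1-based (start >= 1)")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r}")
    return df[PROBE_COLUMNS]


def write_probe_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene interval table missing columns {missing}")
    return df[GENE_COLUMNS]


def write_gene_intervals(df: pd.DataFrame, path: str | Path) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str = "probe_id") -> None:
    """Export 1-based inclusive intervals as standard 0-based half-open BED."""
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "name": df[name_col] if name_col in df.columns else ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


# ------------------------------------------------------------------ GMT
def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Standard GMT: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {line_no}: fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"GMT line {line_no}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_id_mapping(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: ensembl_id, gene_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ensembl_id", "gene_name"):
        if col not in df.columns:
            raise ValueError(f"mapping table missing column {col!r}")
    return df[["ensembl_id", "gene_name"]]
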
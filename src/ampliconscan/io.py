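"""Readers and writers for the pipeline's plain-text formats.

Tables are tab-separated; genomic intervals use BED conventions (0-based,
half-open); summaries are JSON.  Every writer has a reader that parses its
output back to an equal structure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import AmpliconRegion

__all__ = [
    "read_clone_table",
    "write_clone_table",
    "read_genes_bed",
    "write_genes_bed",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "read_screen_table",
    "read_dose_response",
    "write_table",
    "read_polymorphic_list",
    "write_polymorphic_list",
    "write_regions_bed",
    "read_regions_bed",
    "write_json",
    "read_json",
    "load_yaml",
    "dump_yaml",
]

CLONE_META = ["clone_id", "chrom", "start", "end"]


class ParseError(ValueError):
    """Malformed input file."""


def read_clone_table(path: str | Path) -> pd.DataFrame:
    """Read a clone-level log2-ratio table.

    Header must start with clone_id, chrom, start, end followed by one
    column per sample.  Rows are sorted by (chrom, start); duplicate clone
    ids are rejected; non-numeric ratios become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "chrom": str})
    if list(df.columns[:4]) != CLONE_META:
        raise ParseError(
            f"{path}: header must start with {CLONE_META}, got {list(df.columns[:4])}"
        )
    dup = df["clone_id"][df["clone_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate clone_id {dup.iloc[0]!r}")
    for col in ("start", "end"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ParseError(f"{path}: start >= end at line {bad[0] + 2}")
    for col in df.columns[4:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_clone_table(df: pd.DataFrame, path: str | Path) -> None:
    # no float_format: shortest-repr floats round-trip exactly
    df.to_csv(path, sep="\t", index=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """BED4 (chrom, start, end, symbol) -> gene annotation frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "symbol": str}, comment="#",
    )
    if df["symbol"].isna().any():
        raise ParseError(f"{path}: BED file needs 4 columns (chrom, start, end, name)")
    dup = df["symbol"][df["symbol"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate gene symbol {dup.iloc[0]!r}")
    if (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: gene with start >= end")
    return df[["symbol", "chrom", "start", "end"]]


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "symbol"]].to_csv(path, sep="\t", index=False, header=False)


def read_matrix(path: str | Path, index_name: str = "id") -> pd.DataFrame:
    """Feature x sample numeric matrix with the feature id in column 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df.apply(pd.to_numeric, errors="coerce")


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "target": str, "oligo": str})
    needed = {"cell_line", "target", "oligo", "replicate", "luminescence"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: screen table needs columns {sorted(needed)}")
    return df


def read_dose_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "drug": str})
    needed = {"cell_line", "drug", "dose_M", "replicate", "viability"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: dose-response table needs columns {sorted(needed)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def read_polymorphic_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_polymorphic_list(clones: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\n" for c in clones))


def write_regions_bed(regions: list[AmpliconRegion], path: str | Path) -> None:
    """Regions as BED5: chrom, start, end, sample list, recurrence."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(r.samples) if r.samples else "."
            score = "" if not np.isfinite(r.recurrence) else f"{r.recurrence:.6g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\n")


def read_regions_bed(path: str | Path) -> list[AmpliconRegion]:
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, score = (line.split("\t") + [""])[:5]
        regions.append(
            AmpliconRegion(
                chrom=chrom, start=int(start), end=int(end),
                samples=[] if name == "." else name.split(","),
                recurrence=float(score) if score else float("nan"),
            )
        )
    return regions


def write_json(obj, path: str | Path) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.bool_,)):
                return bool(o)
            return super().default(o)

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_Encoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
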
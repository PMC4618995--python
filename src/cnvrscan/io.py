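"""Plain-text readers/writers: TSV with provenance comments, BED, GFF3."""
from __future__ import annotations

import json
from typing import Dict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .windows import WindowGrid, DepthMatrix


def write_tsv(df: pd.DataFrame, path, provenance: dict = None, index=False):
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_grid(grid: WindowGrid, path, provenance: dict = None):
    prov = dict(provenance or {})
    prov["window_size"] = grid.window_size
    prov["chrom_lengths"] = json.dumps(grid.chrom_lengths)
    write_tsv(grid.windows, path, provenance=prov)


def read_grid(path) -> WindowGrid:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(": ")
            meta[key] = val
    df = read_tsv(path)
    if "window_size" not in meta or "chrom_lengths" not in meta:
        raise ValidationError("grid TSV lacks window_size / chrom_lengths provenance")
    return WindowGrid(df, int(meta["window_size"]), json.loads(meta["chrom_lengths"]))


def write_matrix(matrix: DepthMatrix, path, provenance: dict = None):
    prov = dict(provenance or {})
    prov["stage"] = matrix.stage
    df = matrix.values.reset_index()
    write_tsv(df, path, provenance=prov)


def read_matrix(path, stage: str = None) -> DepthMatrix:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(": ")
            meta[key] = val
    df = read_tsv(path)
    values = df.set_index(["chrom", "start"])
    return DepthMatrix(values, stage=stage or meta.get("stage", "raw"))


def write_bed(df: pd.DataFrame, path, name_col: str = None, score_col: str = None):
    cols = ["chrom", "start", "end"]
    out = df[cols].copy()
    if name_col and name_col in df.columns:
        out["name"] = df[name_col]
        if score_col and score_col in df.columns:
            out["score"] = df[score_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols=()) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + list(extra_cols)
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :len(names)]
    df.columns = names[:df.shape[1]]
    return df


def read_features(path, default_class: str = "gene") -> pd.DataFrame:
    """Feature records from BED (4th col id, 5th class) or GFF3 (ID attribute).

    GFF3's 1-based closed coordinates are converted to 0-based half-open.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"])
        ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        ids = ids.fillna(pd.Series([f"feat{i}" for i in range(len(df))]))
        out = pd.DataFrame({"chrom": df["chrom"], "start": df["start"] - 1,
                            "end": df["end"], "feature_id": ids,
                            "feature_class": df["type"].where(
                                df["type"] != "gene", default_class)})
        return out
    names = ["chrom", "start", "end", "feature_id", "feature_class"]
    with open(path) as fh:
        first = next((ln for ln in fh if not ln.startswith("#")), "")
    fields = first.rstrip("\n").split("\t")
    header = 0 if len(fields) > 1 and not fields[1].lstrip("-").isdigit() else None
    df = pd.read_csv(path, sep="\t", comment="#", header=header)
    df = df.iloc[:, :len(names)]
    df.columns = names[:df.shape[1]]
    if "feature_id" not in df.columns:
        df["feature_id"] = [f"feat{i}" for i in range(len(df))]
    if "feature_class" not in df.columns:
        df["feature_class"] = default_class
    return df


def read_baf(path) -> pd.DataFrame:
    return read_tsv(path)


def read_go_map(path) -> pd.DataFrame:
    df = read_tsv(path)
    needed = {"gene_id", "term_id"}
    if not needed.issubset(df.columns):
        raise ValidationError("GO map TSV needs gene_id and term_id columns")
    return df
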
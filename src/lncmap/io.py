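"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions (frozen for reproducibility):

* matrices are TSV, features in rows, first column the feature id;
* GMT is the usual ``name <tab> description <tab> member...`` format;
* BED intervals are 0-based half-open with at least chrom/start/end;
* TSS tables carry a 1-based ``tss_position``;
* survival tables carry ``sample_id``, ``time``, ``event`` (1 = observed).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT; duplicate members within a set are dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path,
    descriptions: Optional[Mapping[str, str]] = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3+ columns); returns chrom/start/end (+name if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        cols[3] = "name"
    df.columns = cols
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(peaks: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in peaks.columns:
        cols.append("name")
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"lncrna_id": str, "chrom": str})
    required = {"lncrna_id", "chrom", "strand", "tss_position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    df["tss_position"] = df["tss_position"].astype(int)
    return df


def write_tss(tss: pd.DataFrame, path) -> None:
    tss[["lncrna_id", "chrom", "strand", "tss_position"]].to_csv(
        path, sep="\t", index=False
    )


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_survival(surv: pd.DataFrame, path) -> None:
    surv[["sample_id", "time", "event"]].to_csv(path, sep="\t", index=False)
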
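"""Tab-separated on-disk formats for every pipeline stage.

All genomic coordinates on disk are 1-based inclusive (SEG convention).
Gene identity is by symbol; duplicate symbols are rejected at load.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .copy_number import GeneCN, ProbeRatioMatrix, SEG_COLUMNS
from .expression import ExpressionMatrix

__all__ = [
    "read_probe_table", "write_probe_table",
    "read_annotation", "write_annotation",
    "read_seg", "write_seg",
    "read_expression", "write_expression",
    "read_gene_list", "write_gene_list",
    "read_plate", "write_plate",
    "write_gene_table",
]

_SEG_HEADER = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_probe_table(matrix: ProbeRatioMatrix, path) -> None:
    """Probe TSV: probe_id, chrom, pos, enzyme_set, one column per sample.

    Control samples are recorded in a ``# control_samples:`` header comment.
    """
    path = Path(path)
    df = pd.concat([matrix.probes.reset_index(drop=True),
                    matrix.ratios.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write(f"# control_samples: {','.join(matrix.control_samples)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_probe_table(path) -> ProbeRatioMatrix:
    path = Path(path)
    controls: tuple = ()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# control_samples:"):
            names = first.split(":", 1)[1].strip()
            controls = tuple(n for n in names.split(",") if n)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    meta_cols = ["probe_id", "chrom", "pos", "enzyme_set"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return ProbeRatioMatrix(
        probes=df[meta_cols], ratios=df[sample_cols], control_samples=controls
    )


def write_annotation(annotation: pd.DataFrame, path) -> None:
    """BED-like TSV: chrom, start, end, symbol, role (1-based inclusive)."""
    out = annotation.reset_index()
    out = out[["chrom", "start", "end", "symbol", "role"]]
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "symbol", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        # +2 -> 1-based file line number accounting for the header row
        raise ValueError(
            f"annotation start > end at line {int(bad[0]) + 2} "
            f"(symbol {df.loc[bad[0], 'symbol']})"
        )
    if df["symbol"].duplicated().any():
        dups = sorted(df.loc[df["symbol"].duplicated(), "symbol"].unique())
        raise ValueError(f"duplicate gene symbols in annotation: {dups[:5]}")
    return df.set_index("symbol")[["chrom", "start", "end", "role"]]


def write_seg(segments: pd.DataFrame, path) -> None:
    """Standard SEG format (sample, chrom, loc.start, loc.end, num.mark, seg.mean)."""
    out = segments[SEG_COLUMNS].copy()
    out.columns = _SEG_HEADER
    out.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    df = df[_SEG_HEADER].copy()
    df.columns = SEG_COLUMNS
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"SEG start > end at line {int(bad[0]) + 2}")
    return df


def write_expression(expr: ExpressionMatrix, path, groups_path=None) -> None:
    """Expression TSV: gene, then <sample>_signal and <sample>_call columns.

    The optional ``groups_path`` writes a sample/group manifest TSV.
    """
    cols = {}
    for s in expr.signals.columns:
        cols[f"{s}_signal"] = expr.signals[s]
        cols[f"{s}_call"] = expr.calls[s]
    df = pd.DataFrame(cols, index=expr.signals.index)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    if groups_path is not None:
        rows = [(s, "tumour") for s in expr.tumours] + [
            (s, "normal") for s in expr.normals
        ]
        pd.DataFrame(rows, columns=["sample", "group"]).to_csv(
            groups_path, sep="\t", index=False
        )


def read_expression(path, groups_path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    groups = pd.read_csv(groups_path, sep="\t")
    if not {"sample", "group"} <= set(groups.columns):
        raise ValueError("groups manifest needs 'sample' and 'group' columns")
    samples = list(groups["sample"])
    for s in samples:
        for suffix in ("_signal", "_call"):
            if f"{s}{suffix}" not in df.columns:
                raise ValueError(f"expression table missing column {s}{suffix}")
    signals = pd.DataFrame({s: df[f"{s}_signal"] for s in samples})
    calls = pd.DataFrame({s: df[f"{s}_call"] for s in samples})
    tumours = list(groups.loc[groups["group"] == "tumour", "sample"])
    normals = list(groups.loc[groups["group"] == "normal", "sample"])
    return ExpressionMatrix(signals=signals, calls=calls,
                            tumours=tumours, normals=normals)


def write_gene_list(symbols, path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n")


def read_gene_list(path) -> list:
    symbols = [line.strip() for line in Path(path).read_text().splitlines()
               if line.strip() and not line.startswith("#")]
    seen = {}
    for s in symbols:
        seen[s] = seen.get(s, 0) + 1
    dups = [s for s, c in seen.items() if c > 1]
    if dups:
        warnings.warn(f"duplicate symbols in gene list deduplicated: {dups[:5]}",
                      stacklevel=2)
    return list(dict.fromkeys(symbols))


def write_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, sep="\t", index=False)


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "replicate", "Ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if "calibrator_copies" not in df.columns:
        df["calibrator_copies"] = np.nan
    return df


def write_gene_table(genecn: GeneCN, path) -> None:
    """Gene-level TSV with assigned ratios and (if called) statuses."""
    out = genecn.ratios.copy()
    out.columns = [f"{c}_ratio" for c in out.columns]
    if genecn.status is not None:
        st = genecn.status.copy()
        st.columns = [f"{c}_status" for c in st.columns]
        out = pd.concat([out, st], axis=1)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
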
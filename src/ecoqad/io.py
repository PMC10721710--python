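"""Readers and writers for the pipeline's tabular formats.

Inputs are three plain-text tables: a plot x variable value matrix
(TSV/CSV, plots as rows), a variable metadata table (variable, group,
kind) and a plot metadata table (plot, gradient_position).  Count
matrices may alternatively come from a BIOM v1 (JSON) file.  All outputs
are TSV with a stable float format so that reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable

FLOAT_FMT = "%.10g"


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance(values_path, variables_path, plots_path) -> AbundanceTable:
    """Read the three input tables into a typed AbundanceTable.

    Raises informative errors naming any variable or plot with missing
    metadata, duplicated ids, or non-numeric cells.
    """
    values_path, variables_path, plots_path = map(Path, (values_path, variables_path, plots_path))
    if values_path.suffix.lower() == ".biom":
        values = read_biom_v1(values_path)
    else:
        values = pd.read_csv(values_path, sep=_sep(values_path), index_col=0)
    non_numeric = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]].tolist()
    if non_numeric:
        raise ValueError(f"non-numeric cells in variables: {non_numeric}")
    var_meta = pd.read_csv(variables_path, sep=_sep(variables_path))
    for col in ("variable", "group", "kind"):
        if col not in var_meta.columns:
            raise ValueError(f"variable metadata lacks column {col!r}")
    var_meta = var_meta.set_index("variable")
    plot_meta = pd.read_csv(plots_path, sep=_sep(plots_path))
    for col in ("plot", "gradient_position"):
        if col not in plot_meta.columns:
            raise ValueError(f"plot metadata lacks column {col!r}")
    plot_meta = plot_meta.set_index("plot")
    return AbundanceTable(
        values=values,
        groups=var_meta["group"],
        gradient=plot_meta["gradient_position"],
        kind=var_meta["kind"],
    )


def read_biom_v1(path) -> pd.DataFrame:
    """Minimal BIOM v1 (JSON) count-table reader.

    BIOM stores observations (taxa) as rows and samples as columns; the
    result is transposed to the package's plot x variable orientation.
    Supports both dense and sparse matrix_type.
    """
    with open(path) as fh:
        doc = json.load(fh)
    obs = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"])
    return pd.DataFrame(mat.T, index=pd.Index(samples, name="plot"), columns=obs)


def write_abundance(tbl: AbundanceTable, outdir, prefix: str = "") -> dict[str, Path]:
    """Write a table as the three input TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": outdir / f"{prefix}values.tsv",
        "variables": outdir / f"{prefix}variables.tsv",
        "plots": outdir / f"{prefix}plots.tsv",
    }
    tbl.values.rename_axis("plot").to_csv(paths["values"], sep="\t", float_format=FLOAT_FMT)
    pd.DataFrame({
        "variable": tbl.values.columns,
        "group": tbl.groups.to_numpy(),
        "kind": tbl.kind.to_numpy(),
    }).to_csv(paths["variables"], sep="\t", index=False)
    pd.DataFrame({
        "plot": tbl.values.index,
        "gradient_position": tbl.gradient.to_numpy(),
    }).to_csv(paths["plots"], sep="\t", index=False, float_format=FLOAT_FMT)
    return paths


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
    return path
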
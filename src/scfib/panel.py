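"""Gene panel, Cq plate and expression-matrix data model with delimited-text IO.

The package analyses multiplex single-cell RT-qPCR data: each cell is profiled
for a fixed panel of gene assays and every cell x gene reaction yields either a
quantification cycle (Cq) or no amplification (a non-detect, the "dropout"
channel that carries the per-gene detection frequency downstream).

All on-disk formats are plain delimited text (tab preferred, comma accepted)
so plates and matrices can be hand-edited and diffed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_GROUPS = (
    "epithelial",
    "fibroblast",
    "chemokine_soluble",
    "transcription_factor",
    "proliferation",
    "bcsc",
    "pluripotency",
    "emt",
    "reference",
)

CELL_CLASSES = ("control", "expCAF", "NF", "CAF")

#: normal-tissue vs tumour-activated side of each cell class
CLASS_CONDITION = {"control": "normal", "NF": "normal", "expCAF": "activated", "CAF": "activated"}

#: scales an ExpressionMatrix can declare, in the order transforms produce them
SCALES = (
    "linear_rq",
    "log2_rq",
    "log2_rq_imputed",
    "autoscaled_by_gene",
    "autoscaled_by_cell",
    "mean_centered_by_gene",
)

NON_DETECT_TOKENS = {"", "nd", "na", "nan"}

METADATA_COLUMNS = ["cell_id", "sample_id", "cell_class"]


class PanelError(ValueError):
    """Raised for malformed panels or plates."""


@dataclass(frozen=True)
class GenePanel:
    """A gene assay panel: unique symbols, one functional group per gene.

    ``aliases`` maps alternative symbols (e.g. FSP1 -> S100A4) onto panel
    symbols so marker rules written with either name resolve.
    """

    table: pd.DataFrame  # index: gene_symbol; column: gene_group
    aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise PanelError(f"duplicate gene symbols in panel: {dupes}")
        bad = set(self.table["gene_group"]) - set(GENE_GROUPS)
        if bad:
            raise PanelError(f"unknown gene groups: {sorted(bad)}")

    @property
    def genes(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index or gene in self.aliases

    def resolve(self, gene: str) -> str:
        """Return the panel symbol for ``gene``, following aliases."""
        if gene in self.table.index:
            return gene
        if gene in self.aliases:
            return self.aliases[gene]
        raise KeyError(f"gene {gene!r} not in panel")

    def group_of(self, gene: str) -> str:
        return self.table.loc[self.resolve(gene), "gene_group"]

    def genes_in_group(self, group: str) -> list:
        if group not in GENE_GROUPS:
            raise PanelError(f"unknown gene group {group!r}")
        return list(self.table.index[self.table["gene_group"] == group])


@dataclass
class CqPlate:
    """Raw instrument-style Cq matrix (cells x assays) with cell metadata.

    Non-detects are stored as NaN. Detected Cq values are finite and > 0.
    """

    cq: pd.DataFrame  # index cell_id, columns gene symbols, NaN = non-detect
    cells: pd.DataFrame  # index cell_id; columns sample_id, cell_class
    panel: GenePanel

    def __post_init__(self) -> None:
        if self.cq.index.duplicated().any():
            dupes = self.cq.index[self.cq.index.duplicated()].unique().tolist()
            raise PanelError(f"duplicate cell_ids: {dupes}")
        unknown = [g for g in self.cq.columns if g not in self.panel]
        if unknown:
            raise PanelError(f"assays not in panel: {unknown}")
        vals = self.cq.to_numpy(dtype=float)
        detected = ~np.isnan(vals)
        if np.any(vals[detected] <= 0) or np.any(~np.isfinite(vals[detected])):
            raise PanelError("detected Cq values must be finite and > 0")
        if not self.cq.index.equals(self.cells.index):
            raise PanelError("cq rows and cell metadata rows do not align")

    @property
    def assays(self) -> list:
        return list(self.cq.columns)

    @property
    def n_cells(self) -> int:
        return len(self.cq)


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values on a declared scale with a detection mask.

    ``provenance`` is the ordered list of transforms that produced the current
    values; the detection mask is fixed at Cq conversion and never altered by
    scaling transforms (imputation fills values but leaves the mask alone).
    """

    values: pd.DataFrame  # index cell_id, columns genes
    detected: pd.DataFrame  # same shape, bool
    cells: pd.DataFrame  # index cell_id; sample_id, cell_class (+ optional dataset)
    scale: str
    provenance: list = field(default_factory=list)
    panel: GenePanel | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.detected.shape:
            raise PanelError("detection mask shape must equal value shape")
        if self.scale not in SCALES:
            raise PanelError(f"unknown scale {self.scale!r}")
        if self.scale == "linear_rq" and len(self.values):
            vals = self.values.to_numpy(dtype=float)
            det = self.detected.to_numpy(dtype=bool)
            if np.any(vals[det] < 0):
                raise PanelError("linear RQ values must be >= 0")
            if np.any(vals[~det] != 0):
                raise PanelError("non-detect linear RQ values must be exactly 0")

    @property
    def genes(self) -> list:
        return list(self.values.columns)

    @property
    def cell_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def copy_with(self, values: pd.DataFrame, scale: str, step: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            detected=self.detected.copy(),
            cells=self.cells.copy(),
            scale=scale,
            provenance=[*self.provenance, step],
            panel=self.panel,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.columns]
        if missing:
            raise PanelError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(
            values=self.values.loc[:, list(genes)].copy(),
            detected=self.detected.loc[:, list(genes)].copy(),
            cells=self.cells.copy(),
            scale=self.scale,
            provenance=list(self.provenance),
            panel=self.panel,
        )

    def subset_cells(self, cell_ids: Sequence) -> "ExpressionMatrix":
        idx = list(cell_ids)
        return ExpressionMatrix(
            values=self.values.loc[idx].copy(),
            detected=self.detected.loc[idx].copy(),
            cells=self.cells.loc[idx].copy(),
            scale=self.scale,
            provenance=list(self.provenance),
            panel=self.panel,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    """Auto-detect tab vs comma, preferring tab."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_default_panel() -> GenePanel:
    """Load the packaged 43-gene fibroblast activation panel.

    The panel covers epithelial, fibroblast/activation, chemokine and soluble
    factor, transcription factor, proliferation, breast cancer stem-cell-like
    (BCSC), pluripotency, EMT and reference groups. Genes not named in the
    study's body text were reconstructed from canonical group members to reach
    the published assay count of 43.
    """
    ref = resources.files("scfib").joinpath("data/default_panel.tsv")
    with resources.as_file(ref) as path:
        return read_panel(path)


def read_panel(path) -> GenePanel:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    required = {"gene_symbol", "gene_group"}
    if not required.issubset(df.columns):
        raise PanelError(f"panel file needs columns {sorted(required)}")
    aliases = {}
    if "aliases" in df.columns:
        for sym, al in zip(df["gene_symbol"], df["aliases"]):
            if isinstance(al, str) and al.strip():
                for a in al.split(","):
                    aliases[a.strip()] = sym
    table = df.set_index("gene_symbol")[["gene_group"]]
    return GenePanel(table=table, aliases=aliases)


def read_cq_plate(path, panel: GenePanel, sentinel: str = "ND") -> CqPlate:
    """Read a delimited Cq plate: metadata columns then one column per assay.

    Non-detects are encoded as empty fields or the sentinel token
    (case-insensitive). Row order is preserved.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise PanelError(f"plate file missing metadata columns: {missing_meta}")
    gene_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    unknown = [g for g in gene_cols if g not in panel]
    if unknown:
        raise PanelError(f"assays not in panel: {unknown}")
    if df["cell_id"].duplicated().any():
        dupes = df["cell_id"][df["cell_id"].duplicated()].unique().tolist()
        raise PanelError(f"duplicate cell_ids: {dupes}")

    tokens = NON_DETECT_TOKENS | {sentinel.lower()}
    cq = pd.DataFrame(index=df["cell_id"], columns=gene_cols, dtype=float)
    for col in gene_cols:
        parsed = np.empty(len(df))
        for i, raw in enumerate(df[col]):
            s = raw.strip()
            if s.lower() in tokens:
                parsed[i] = np.nan
            else:
                try:
                    parsed[i] = float(s)
                except ValueError:
                    raise PanelError(
                        f"unparseable Cq {raw!r} at row {i + 2}, column {col!r}"
                    ) from None
        cq[col] = parsed
    cells = df.set_index("cell_id")[["sample_id", "cell_class"]]
    return CqPlate(cq=cq, cells=cells, panel=panel)


def write_cq_plate(plate: CqPlate, path, sentinel: str = "ND") -> None:
    path = Path(path)
    out = plate.cells.reset_index()
    cq = plate.cq.reset_index(drop=True)
    for col in plate.cq.columns:
        out[col] = [sentinel if np.isnan(v) else repr(float(v)) for v in cq[col]]
    out.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV with a JSON sidecar (``<path>.meta.json``).

    The sidecar records scale, provenance, cell metadata and the non-detect
    coordinates so that :func:`read_matrix` round-trips the object exactly.
    Values are written with full ``repr`` precision.
    """
    path = Path(path)
    df = matrix.values.copy()
    df.insert(0, "cell_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format=None)
    det = matrix.detected.to_numpy(dtype=bool)
    nd_rows, nd_cols = np.nonzero(~det)
    meta = {
        "scale": matrix.scale,
        "provenance": list(matrix.provenance),
        "genes": list(matrix.values.columns),
        "cells": matrix.cells.reset_index().to_dict(orient="list"),
        "non_detects": [[int(r), int(c)] for r, c in zip(nd_rows, nd_cols)],
    }
    with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def read_matrix(path, panel: GenePanel | None = None) -> ExpressionMatrix:
    path = Path(path)
    with open(str(path) + ".meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    df = df.set_index("cell_id")
    df.index.name = "cell_id"
    values = df[meta["genes"]].astype(float) if len(df) else pd.DataFrame(
        columns=meta["genes"], index=df.index, dtype=float
    )
    detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    for r, c in meta["non_detects"]:
        detected.iloc[r, c] = False
    cells = pd.DataFrame(meta["cells"])
    cells = cells.set_index("cell_id") if len(cells.columns) else pd.DataFrame(
        index=values.index
    )
    return ExpressionMatrix(
        values=values,
        detected=detected,
        cells=cells,
        scale=meta["scale"],
        provenance=list(meta["provenance"]),
        panel=panel,
    )
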
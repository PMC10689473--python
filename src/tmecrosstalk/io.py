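"""Readers and writers for the pipeline's external formats.

Count matrices travel as Matrix Market ``.mtx`` plus ``features.tsv`` /
``barcodes.tsv`` (Cell Ranger dialect), per-cell metadata as ``cells.csv``,
gene sets as GMT, receptor-ligand pairs and ECM edges as two-column TSV,
CODEX segmented cells as CSV with ``x``/``y``/``channel_*`` columns, and
interaction graphs as GraphML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml


class FormatError(ValueError):
    """An on-disk artifact violates the format contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CountMatrix:
    """Sparse non-negative integer UMI matrix, genes x cells.

    Parameters
    ----------
    values
        Sparse matrix of shape ``(n_genes, n_cells)`` with non-negative
        integer entries.
    gene_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative count entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.cell_ids[i] for i in idx],
        )


@dataclasses.dataclass
class GeneSetCollection:
    """Named, ordered gene lists (GMT semantics)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def __len__(self) -> int:
        return len(self.sets)


@dataclasses.dataclass
class RLDatabase:
    """Curated receptor-ligand pairs; directional (receptor, ligand)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for pair in self.pairs:
            if pair in seen:
                raise FormatError(f"duplicate receptor-ligand pair {pair}")
            seen.add(pair)

    @property
    def receptors(self) -> set[str]:
        return {r for r, _ in self.pairs}

    @property
    def ligands(self) -> set[str]:
        return {l for _, l in self.pairs}

    def partners_of_receptor(self, receptor: str) -> list[str]:
        return [l for r, l in self.pairs if r == receptor]

    def partners_of_ligand(self, ligand: str) -> list[str]:
        return [r for r, l in self.pairs if l == ligand]

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Count matrix trio
# ---------------------------------------------------------------------------

def _read_id_file(path: Path, column: int = 0) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[column])
    return ids


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate symbols with .1/.2 suffixes (Cell Ranger style)."""
    counts: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in counts:
            counts[s] += 1
            out.append(f"{s}.{counts[s]}")
        else:
            counts[s] = 0
            out.append(s)
    return out


def read_counts(path: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read matrix.mtx + features.tsv + barcodes.tsv (+ optional cells.csv).

    The matrix is oriented genes x cells regardless of the on-disk
    orientation, inferred from the lengths of the id files. Missing metadata
    columns are filled with the sentinel ``"NA"``.
    """
    path = Path(path)
    mtx_path = path / "matrix.mtx"
    feat_path = path / "features.tsv"
    bc_path = path / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FormatError(f"missing input file: {p}")

    genes = _dedupe_symbols(_read_id_file(feat_path))
    barcodes = _read_id_file(bc_path)
    if len(set(barcodes)) != len(barcodes):
        dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
        raise FormatError(f"duplicate barcode ids in {bc_path}: {dupes[:5]}")

    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    if mat.shape == (len(genes), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(genes)):
        mat = mat.T.tocsr()
    else:
        raise FormatError(
            f"matrix shape {mat.shape} in {mtx_path} matches neither "
            f"{len(genes)} genes x {len(barcodes)} cells nor its transpose"
        )
    counts = CountMatrix(mat, genes, barcodes)

    cells_path = path / "cells.csv"
    meta_cols = ["sample", "patient", "tissue_class", "coarse_type"]
    if cells_path.exists():
        cells = pd.read_csv(cells_path, dtype=str)
        if "cell_id" not in cells.columns:
            raise FormatError(f"cells.csv lacks a cell_id column: {cells_path}")
        if set(cells["cell_id"]) != set(barcodes):
            raise FormatError(
                f"cell ids in {cells_path} do not match {bc_path}"
            )
        cells = cells.set_index("cell_id").loc[barcodes].reset_index()
    else:
        cells = pd.DataFrame({"cell_id": barcodes})
    for col in meta_cols:
        if col not in cells.columns:
            cells[col] = "NA"
    return counts, cells


def write_counts(path: str | Path, counts: CountMatrix,
                 cells: pd.DataFrame | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", counts.values.tocoo(), field="integer")
    (path / "features.tsv").write_text(
        "".join(f"{g}\n" for g in counts.gene_ids))
    (path / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in counts.cell_ids))
    if cells is not None:
        cells.to_csv(path / "cells.csv", index=False)


# ---------------------------------------------------------------------------
# Gene sets, receptor-ligand pairs, edge lists, orthologs
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has no genes")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gene_sets(path: str | Path, sets: GeneSetCollection | Mapping[str, Sequence[str]]) -> None:
    items = sets.items() if hasattr(sets, "items") else sets
    with open(path, "w") as fh:
        for name, genes in items:
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_rl(path: str | Path) -> RLDatabase:
    """Parse a two-column receptor/ligand TSV (header optional)."""
    pairs: list[tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"receptor", "receptor_gene"}:
                continue
            pair = (fields[0], fields[1])
            if pair in seen:
                raise FormatError(f"{path}:{lineno}: duplicate pair {pair}")
            seen.add(pair)
            pairs.append(pair)
    return RLDatabase(pairs)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of undirected gene-gene edges (e.g. an ECM network)."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            edges.append((fields[0], fields[1]))
    return edges


def read_orthologs(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source symbols to target symbols.

    Only one-to-one rows are kept; symbols involved in one-to-many or
    many-to-one mappings are dropped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"ortholog file {path}: expected 2 columns")
            rows.append((fields[0], fields[1]))
    src_counts: dict[str, int] = {}
    tgt_counts: dict[str, int] = {}
    for s, t in rows:
        src_counts[s] = src_counts.get(s, 0) + 1
        tgt_counts[t] = tgt_counts.get(t, 0) + 1
    return {
        s: t for s, t in rows if src_counts[s] == 1 and tgt_counts[t] == 1
    }


# ---------------------------------------------------------------------------
# CODEX segmented cells
# ---------------------------------------------------------------------------

def read_codex(path: str | Path) -> pd.DataFrame:
    """Read a CODEX segmented-cell CSV.

    Requires ``cell_id``, ``x``, ``y`` and at least one ``channel_*``
    intensity column; a ``cell_type`` column is optional.
    """
    table = pd.read_csv(path)
    for col in ("cell_id", "x", "y"):
        if col not in table.columns:
            raise FormatError(f"CODEX table {path} lacks column {col!r}")
    channels = [c for c in table.columns if c.startswith("channel_")]
    if not channels:
        raise FormatError(f"CODEX table {path} has no channel_* columns")
    if table["cell_id"].duplicated().any():
        raise FormatError(f"CODEX table {path} has duplicate cell ids")
    if not np.isfinite(table[["x", "y"]].to_numpy(dtype=float)).all():
        raise FormatError(f"CODEX table {path} has non-finite coordinates")
    if (table[channels].to_numpy(dtype=float) < 0).any():
        raise FormatError(f"CODEX table {path} has negative intensities")
    return table


# ---------------------------------------------------------------------------
# Graph export and configuration
# ---------------------------------------------------------------------------

def write_graphml(path: str | Path, edges: pd.DataFrame) -> None:
    """Export interaction edges as a bipartite GraphML graph.

    Epithelial genes form one node class ("epithelium"), (partner gene,
    TME type) pairs the other; edge attributes carry patient support.
    """
    import networkx as nx

    graph = nx.Graph()
    for _, row in edges.iterrows():
        a = f"EP:{row['epithelial_gene']}"
        b = f"{row['tme_type']}:{row['partner_gene']}"
        graph.add_node(a, side="epithelium", gene=row["epithelial_gene"])
        graph.add_node(b, side="tme", gene=row["partner_gene"],
                       cell_type=row["tme_type"])
        graph.add_edge(a, b, n_patients=int(row["n_patients"]),
                       direction=row["direction"])
    nx.write_graphml(graph, path)


_CONFIG_SCHEMA: dict[str, type] = {
    "seed": int,
    "n_features": int,
    "n_pcs": int,
    "knn_k": int,
    "umap_neighbors": int,
    "alpha": float,
    "lfc_min": float,
    "top_frac": float,
}


def load_config(path: str | Path) -> dict:
    """Load and type-check the pipeline YAML configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    for key, value in cfg.items():
        expected = _CONFIG_SCHEMA.get(key)
        if expected is int and not isinstance(value, int):
            raise FormatError(f"config key {key!r} must be an integer")
        if expected is float and not isinstance(value, (int, float)):
            raise FormatError(f"config key {key!r} must be numeric")
    return cfg
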
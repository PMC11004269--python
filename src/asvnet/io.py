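"""Readers and writers for the tabular and network formats the pipeline touches.

Tables travel as TSV (taxa-as-rows feature table, taxonomy, sample metadata);
networks are exported as Cytoscape-friendly edge-list CSV or GraphML with all
edge (rho, p, sign) and node (domain, module, zi, pi, role) attributes, and
both exports round-trip losslessly through the matching reader.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger("asvnet")

EDGE_ATTRS = ("rho", "p", "sign")
NODE_ATTRS = ("domain", "module", "zi", "pi", "role")


class FormatError(ValueError):
    """Raised on malformed input files or unsupported output formats."""


# ---------------------------------------------------------------------------
# feature table


def read_asv_table(path, transpose: bool = False) -> pd.DataFrame:
    """Read a TSV count table (taxa as rows, first column taxon ids).

    Cells must be non-negative integers; duplicates in either axis and
    negative or non-numeric cells raise :class:`FormatError` naming the
    offending coordinates.  ``transpose=True`` accepts the samples-as-rows
    dialect.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.index.name = "taxon_id"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate taxon ids in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for taxon, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise FormatError(
                        f"non-numeric count at row {taxon!r}, column {sample!r}: {cell!r}"
                    ) from None
        raise
    neg = counts < 0
    if neg.to_numpy().any():
        taxon = counts.index[neg.any(axis=1)][0]
        sample = counts.columns[neg.loc[taxon]][0]
        raise FormatError(
            f"negative count at row {taxon!r}, column {sample!r}: "
            f"{counts.loc[taxon, sample]}"
        )
    return counts.astype("int64")


def write_asv_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# taxonomy / metadata


def read_taxonomy(path) -> pd.DataFrame:
    """Read a TSV taxonomy table indexed by taxon id; requires a ``domain``
    column with values bacteria/fungi, other rank columns are kept as-is."""
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    tax.index = tax.index.astype(str)
    tax.index.name = "taxon_id"
    if tax.index.duplicated().any():
        raise FormatError(f"duplicate taxon ids in taxonomy {path}")
    if "domain" not in tax.columns:
        raise FormatError(f"taxonomy {path} lacks required 'domain' column")
    bad = set(tax["domain"]) - {"bacteria", "fungi"}
    if bad:
        raise FormatError(f"unknown domain labels in {path}: {sorted(bad)}")
    return tax


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read per-sample metadata (treatment labels, covariates, traits).

    If a count ``table`` is given, every one of its samples must appear;
    missing ones are reported by id.  Unknown columns are preserved as opaque
    covariates.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    if meta.index.duplicated().any():
        raise FormatError(f"duplicate sample ids in metadata {path}")
    if "treatment" not in meta.columns:
        raise FormatError(f"metadata {path} lacks required 'treatment' column")
    if table is not None:
        missing = [s for s in table.columns if s not in meta.index]
        if missing:
            raise FormatError(
                f"metadata {path} is missing samples present in the count table: {missing}"
            )
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# networks


def write_network(net: nx.Graph, path, format: str = "edge-csv") -> None:
    """Export a signed co-occurrence network.

    ``edge-csv`` writes source,target,rho,p,sign rows (Cytoscape import);
    ``graphml`` additionally carries node attributes (domain, module, zi, pi,
    role) where present.
    """
    path = Path(path)
    if format == "edge-csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("source", "target") + EDGE_ATTRS)
            for u, v, d in sorted(net.edges(data=True)):
                w.writerow([u, v, repr(float(d["rho"])), repr(float(d["p"])), d["sign"]])
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise FormatError(
            f"unknown network format {format!r}; supported: 'edge-csv', 'graphml'"
        )
    logger.info("wrote %d-node %d-edge network to %s (%s)",
                net.number_of_nodes(), net.number_of_edges(), path, format)


def read_network(path, format: str = "edge-csv") -> nx.Graph:
    """Inverse of :func:`write_network` (edge-csv loses isolated nodes and
    node attributes by construction; graphml is fully lossless)."""
    if format == "edge-csv":
        g = nx.Graph()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                g.add_edge(
                    row["source"],
                    row["target"],
                    rho=float(row["rho"]),
                    p=float(row["p"]),
                    sign=row["sign"],
                )
        return g
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    raise FormatError(f"unknown network format {format!r}; supported: 'edge-csv', 'graphml'")


def networks_equal(a: nx.Graph, b: nx.Graph, rel_tol: float = 1e-12) -> bool:
    """True when node set, edge set and numeric attributes agree (numbers to
    12 significant digits)."""
    if set(a.nodes) != set(b.nodes) or set(map(frozenset, a.edges)) != set(
        map(frozenset, b.edges)
    ):
        return False

    def attrs_match(da: dict, db: dict) -> bool:
        if set(da) != set(db):
            return False
        for k, va in da.items():
            vb = db[k]
            if isinstance(va, float) or isinstance(vb, float):
                if not math.isclose(float(va), float(vb), rel_tol=rel_tol, abs_tol=1e-300):
                    return False
            elif str(va) != str(vb):
                return False
        return True

    return all(attrs_match(a.nodes[n], b.nodes[n]) for n in a.nodes) and all(
        attrs_match(a.edges[u, v], b.edges[u, v]) for u, v in a.edges
    )
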
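"""Typed gene knowledge graph, labeled link sets, and node feature tables.

The interactome is modelled as a directed multigraph whose edges carry a
relation label (activation, inhibition, expression regulation, binding, ...).
Parallel edges between the same ordered gene pair are allowed as long as
their relation labels differ.  The stored graph never contains self-loops:
inverse relations and per-node self-loops are added explicitly by
:func:`augment_graph` before message passing, so that information can flow
along both edge directions and every node retains its own state.

All tabular I/O is plain TSV (optionally gzip-compressed); gene identifiers
are opaque strings and no symbol-to-accession mapping is attempted.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Relation label reserved for the self-loops added by :func:`augment_graph`.
SELF_RELATION = "__self__"

#: Suffix appended to a relation label to name its inverse.
INVERSE_SUFFIX = "__inv"


class GraphParseError(ValueError):
    """A graph/link/feature file violated its declared dialect."""


@dataclass
class KnowledgeGraph:
    """Directed, edge-typed gene multigraph ``G = (V, E, R)``.

    Parameters
    ----------
    nodes
        Gene identifiers, in first-appearance order.
    edges
        ``(source, relation, target)`` triples.
    relations
        Relation vocabulary in first-appearance order.
    meta
        Free-form provenance (duplicate counts, community labels of
        synthetic graphs, ...).  Never consulted by the algorithms.
    """

    nodes: tuple[str, ...]
    edges: list[tuple[str, str, str]]
    relations: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        rel_set = set(self.relations)
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            s, r, t = e
            if s not in node_set or t not in node_set:
                raise ValueError(f"edge {e} has an endpoint outside the node set")
            if r not in rel_set:
                raise ValueError(f"edge {e} uses unknown relation {r!r}")
            if e in seen:
                raise ValueError(f"duplicate edge triple {e}")
            seen.add(e)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    @property
    def is_augmented(self) -> bool:
        return SELF_RELATION in self.relations


@dataclass
class LinkDataset:
    """Labeled ordered gene pairs; label 1 = interaction, 0 = no interaction."""

    records: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a, b, y in self.records:
            if y not in (0, 1):
                raise ValueError(f"label must be 0/1, got {y!r} for pair ({a}, {b})")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a}, {b}) in link dataset")
            seen.add((a, b))

    @property
    def n_positive(self) -> int:
        return sum(y for _, _, y in self.records)

    @property
    def n_negative(self) -> int:
        return len(self.records) - self.n_positive

    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.records]

    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.records], dtype=int)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.records:
            out.add(a)
            out.add(b)
        return out

    def subset(self, idx: Sequence[int]) -> "LinkDataset":
        return LinkDataset([self.records[i] for i in idx])


@dataclass
class NodeFeatureTable:
    """Per-gene input feature vectors ``h_i^(0)``.

    The vector is the concatenation of three blocks: an ontology-embedding
    block and cancer-specific expression and mutation-rate blocks.
    ``block_dims`` records the split; ``missing`` maps each gene to the
    blocks for which it had no data (those entries are zero-filled).
    """

    genes: tuple[str, ...]
    X: np.ndarray  # (n_genes, total_dim), float64
    block_dims: tuple[int, int, int]
    missing: dict[str, tuple[str, ...]] = field(default_factory=dict)

    BLOCK_NAMES = ("ontology", "expression", "mutation")

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.genes), sum(self.block_dims)):
            raise ValueError(
                f"feature matrix shape {self.X.shape} inconsistent with "
                f"{len(self.genes)} genes x block dims {self.block_dims}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains non-finite values")

    @property
    def dim(self) -> int:
        return int(self.X.shape[1])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index()

    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.genes)}
            object.__setattr__(self, "_idx", idx)
        return idx

    def vector(self, gene: str) -> np.ndarray:
        return self.X[self._index()[gene]]

    def matrix(self, order: Sequence[str]) -> np.ndarray:
        """Feature matrix with rows in the requested gene order."""
        idx = self._index()
        try:
            rows = [idx[g] for g in order]
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise KeyError(f"gene {exc.args[0]!r} absent from feature table") from None
        return self.X[rows]


# ---------------------------------------------------------------------------
# I/O


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def load_graph(path, dialect: str = "srt", has_header: bool = False) -> KnowledgeGraph:
    """Read a 3-column edge-list TSV into a :class:`KnowledgeGraph`.

    ``dialect`` gives the column order as a permutation of ``"s"`` (source),
    ``"r"`` (relation) and ``"t"`` (target); the canonical layout is
    ``"srt"``.  Duplicate identical triples are dropped with a logged count
    (recorded in ``graph.meta["n_duplicates"]``).
    """
    if sorted(dialect) != ["r", "s", "t"]:
        raise ValueError(f"dialect must be a permutation of 'srt', got {dialect!r}")
    col = {c: i for i, c in enumerate(dialect)}
    nodes: dict[str, None] = {}
    relations: dict[str, None] = {}
    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    n_dup = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and has_header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            triple = (parts[col["s"]], parts[col["r"]], parts[col["t"]])
            if triple in seen:
                n_dup += 1
                continue
            seen.add(triple)
            nodes.setdefault(triple[0], None)
            nodes.setdefault(triple[2], None)
            relations.setdefault(triple[1], None)
            edges.append(triple)
    if not edges:
        raise GraphParseError(f"{path}: no edges found (empty graph)")
    if n_dup:
        logger.info("load_graph(%s): dropped %d duplicate triples", path, n_dup)
    return KnowledgeGraph(
        nodes=tuple(nodes),
        edges=edges,
        relations=tuple(relations),
        meta={"n_duplicates": n_dup},
    )


def write_graph(graph: KnowledgeGraph, path) -> None:
    with _open_text(path, "wt") as fh:
        for s, r, t in graph.edges:
            fh.write(f"{s}\t{r}\t{t}\n")


def load_links(
    path,
    positive_token: str = "1",
    negative_token: str = "0",
    has_header: bool = False,
    dedup: bool = False,
) -> LinkDataset:
    """Read a labeled link TSV (gene_a, gene_b, label).

    Unknown label tokens raise, naming the token and line.  Duplicated pairs
    raise by default (silent dedup could hide label conflicts); pass
    ``dedup=True`` to keep the first occurrence instead.
    """
    records: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and has_header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            a, b, tok = parts
            if tok == positive_token:
                y = 1
            elif tok == negative_token:
                y = 0
            else:
                raise GraphParseError(
                    f"{path}: line {lineno}: unknown label token {tok!r}"
                )
            if (a, b) in seen:
                if dedup:
                    continue
                raise GraphParseError(f"{path}: line {lineno}: duplicate pair ({a}, {b})")
            seen.add((a, b))
            records.append((a, b, y))
    return LinkDataset(records)


def write_links(links: LinkDataset, path) -> None:
    with _open_text(path, "wt") as fh:
        for a, b, y in links.records:
            fh.write(f"{a}\t{b}\t{y}\n")


def write_features(table: NodeFeatureTable, path) -> None:
    """Write a feature TSV whose header names the blocks (ontology_0, ...)."""
    names: list[str] = []
    for bname, bdim in zip(NodeFeatureTable.BLOCK_NAMES, table.block_dims):
        names.extend(f"{bname}_{j}" for j in range(bdim))
    with _open_text(path, "wt") as fh:
        fh.write("gene\t" + "\t".join(names) + "\n")
        for i, g in enumerate(table.genes):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in table.X[i]) + "\n")


def load_features(path) -> NodeFeatureTable:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene":
            raise GraphParseError(f"{path}: feature header must start with 'gene'")
        dims = [0, 0, 0]
        for name in header[1:]:
            block = name.rsplit("_", 1)[0]
            if block not in NodeFeatureTable.BLOCK_NAMES:
                raise GraphParseError(f"{path}: unknown feature block column {name!r}")
            dims[NodeFeatureTable.BLOCK_NAMES.index(block)] += 1
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise GraphParseError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(parts)}"
                )
            genes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return NodeFeatureTable(
        genes=tuple(genes), X=np.array(rows, dtype=float), block_dims=tuple(dims)
    )


# ---------------------------------------------------------------------------
# Assembly and augmentation


def _block_dim(block: Mapping[str, Sequence[float]], name: str) -> int:
    dims = {len(np.atleast_1d(v)) for v in block.values()}
    if len(dims) > 1:
        raise ValueError(f"{name} block has inconsistent vector lengths: {sorted(dims)}")
    return dims.pop() if dims else 0


def assemble_features(
    ontology_block: Mapping[str, Sequence[float]],
    expression_block: Mapping[str, Sequence[float]],
    mutation_block: Mapping[str, Sequence[float]],
    genes: Iterable[str],
) -> NodeFeatureTable:
    """Concatenate ontology ‖ expression ‖ mutation per-gene blocks.

    A gene missing from a block receives a zero vector for that block; the
    affected blocks are recorded per gene in the returned table's
    ``missing`` report.
    """
    genes = tuple(dict.fromkeys(genes))
    if not genes:
        raise ValueError("assemble_features: empty gene set")
    blocks = (ontology_block, expression_block, mutation_block)
    dims = tuple(
        _block_dim(b, n) for b, n in zip(blocks, NodeFeatureTable.BLOCK_NAMES)
    )
    X = np.zeros((len(genes), sum(dims)))
    missing: dict[str, tuple[str, ...]] = {}
    for i, g in enumerate(genes):
        offset = 0
        absent: list[str] = []
        for block, bdim, bname in zip(blocks, dims, NodeFeatureTable.BLOCK_NAMES):
            if g in block:
                X[i, offset : offset + bdim] = np.atleast_1d(block[g])
            elif bdim:
                absent.append(bname)
            offset += bdim
        if absent:
            missing[g] = tuple(absent)
    if missing:
        logger.info(
            "assemble_features: %d/%d genes zero-filled in at least one block",
            len(missing),
            len(genes),
        )
    return NodeFeatureTable(genes=genes, X=X, block_dims=dims, missing=missing)


def augment_graph(graph: KnowledgeGraph) -> KnowledgeGraph:
    """Add inverse relations and per-node self-loops for message passing.

    For every relation ``r`` an inverse relation ``r__inv`` holds every edge
    reversed, and a dedicated self relation holds one loop per node, so the
    augmented vocabulary has ``2|R| + 1`` relations and
    ``2|E| + |V|`` edges.  Augmenting an already-augmented graph raises.
    """
    if graph.is_augmented:
        raise ValueError("graph is already augmented (self relation present)")
    edges = list(graph.edges)
    for s, r, t in graph.edges:
        edges.append((t, r + INVERSE_SUFFIX, s))
    for v in graph.nodes:
        edges.append((v, SELF_RELATION, v))
    relations = (
        tuple(graph.relations)
        + tuple(r + INVERSE_SUFFIX for r in graph.relations)
        + (SELF_RELATION,)
    )
    return KnowledgeGraph(
        nodes=graph.nodes, edges=edges, relations=relations, meta=dict(graph.meta)
    )


def collapse_relations(graph: KnowledgeGraph, label: str = "any") -> KnowledgeGraph:
    """Collapse every relation to a single untyped label.

    This is the relation-blind ablation: a graph convolution run on the
    collapsed graph cannot use edge types or (before augmentation)
    distinguish them, which is exactly what the typed encoder is supposed
    to exploit.  Edges identical up to relation are merged.
    """
    if graph.is_augmented:
        raise ValueError("collapse the stored graph before augmentation")
    merged: dict[tuple[str, str, str], None] = {}
    for s, _, t in graph.edges:
        merged.setdefault((s, label, t), None)
    return KnowledgeGraph(
        nodes=graph.nodes,
        edges=list(merged),
        relations=(label,),
        meta=dict(graph.meta),
    )
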
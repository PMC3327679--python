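"""Tables, containers and file formats shared by every pipeline stage.

All tables are tab-separated with a header row and '.' as the decimal
point, matching common array-export dialects.  Missing values are read
from empty cells or the token ``NA`` and always written back as ``NA``.
Networks are exported in Cytoscape SIF plus a companion node-attribute
table; write followed by read reproduces the object exactly.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMeta",
    "TwoColorArray",
    "TwoColorArraySet",
    "TargetMap",
    "AnnotationCatalog",
    "Network",
    "NetworkNode",
    "NetworkEdge",
    "read_expression_table",
    "write_expression_table",
    "read_target_map",
    "write_target_map",
    "read_catalog",
    "read_edge_list",
    "write_sif",
    "read_sif",
]

LAYERS = ("mRNA", "miRNA", "protein")
CONDITIONS = ("sensitive", "resistant")
DYES = ("Cy3", "Cy5", "none")
NODE_KINDS = ("gene", "miRNA", "protein")
EDGE_KINDS = ("mirna_target", "gene_gene")
DIRECTIONS = ("up", "down", "none")

NA_TOKEN = "NA"


# ---------------------------------------------------------------------------
# sample metadata


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation.

    condition
        Which cell line the sample (or, for log-ratio columns, the
        numerator of the ratio) comes from: ``sensitive`` or
        ``resistant``.
    bio_rep, tech_rep
        1-based biological / technical replicate indices.
    dye
        For log-ratio columns, the dye carrying the *resistant* channel:
        ``Cy5`` means the stored ratio is already oriented
        resistant-over-sensitive, ``Cy3`` means it is dye-swapped (the
        sign must be flipped to reach the common orientation).  Single
        channel data uses ``none``.
    """

    name: str
    condition: str
    bio_rep: int
    tech_rep: int
    dye: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.name!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.dye not in DYES:
            raise ValueError(
                f"sample {self.name!r}: dye must be one of {DYES}, got {self.dye!r}"
            )
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError(
                f"sample {self.name!r}: replicate indices are 1-based positive integers"
            )


class ExpressionMatrix:
    """A features x samples table of log2 values for one omics layer.

    Values may be log2 intensities (single channel) or log2 ratios
    (two-color); missing entries are NaN.
    """

    def __init__(
        self,
        layer: str,
        feature_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        values: np.ndarray,
    ) -> None:
        if layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {layer!r}")
        feature_ids = [str(f) for f in feature_ids]
        dupes = _duplicates(feature_ids)
        if dupes:
            raise ValueError(f"duplicate feature ids: {sorted(dupes)}")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(feature_ids), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(feature_ids)} features x {len(samples)} samples"
            )
        names = [s.name for s in samples]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate sample names: {sorted(_duplicates(names))}")
        self.layer = layer
        self.feature_ids = list(feature_ids)
        self.samples = list(samples)
        self.values = values

    # -- convenience -------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([s.condition == condition for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_names()
        )

    def subset_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep]
        return ExpressionMatrix(
            self.layer,
            [self.feature_ids[i] for i in idx],
            self.samples,
            self.values[idx, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.layer == other.layer
            and self.feature_ids == other.feature_ids
            and self.samples == other.samples
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix(layer={self.layer!r}, "
            f"{self.n_features} features x {self.n_samples} samples)"
        )


# ---------------------------------------------------------------------------
# two-color raw arrays


@dataclass
class TwoColorArray:
    """One two-color hybridization: foreground/background per channel.

    ``condition_of_channel1`` records which cell line was labelled with
    ``dye_of_channel1``; channel 2 carries the other condition with the
    other dye.  Dye swaps are therefore explicit in the metadata rather
    than a convention of column order.
    """

    fg1: np.ndarray
    bg1: np.ndarray
    fg2: np.ndarray
    bg2: np.ndarray
    dye_of_channel1: str
    condition_of_channel1: str
    bio_rep: int = 1
    tech_rep: int = 1

    def __post_init__(self) -> None:
        self.fg1 = np.asarray(self.fg1, dtype=float)
        self.bg1 = np.asarray(self.bg1, dtype=float)
        self.fg2 = np.asarray(self.fg2, dtype=float)
        self.bg2 = np.asarray(self.bg2, dtype=float)
        n = len(self.fg1)
        for name in ("bg1", "fg2", "bg2"):
            if len(getattr(self, name)) != n:
                raise ValueError("all four channel vectors must have equal length")
        for name in ("fg1", "bg1", "fg2", "bg2"):
            v = getattr(self, name)
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"{name}: intensities must be non-negative")
        if self.dye_of_channel1 not in ("Cy3", "Cy5"):
            raise ValueError("dye_of_channel1 must be Cy3 or Cy5")
        if self.condition_of_channel1 not in CONDITIONS:
            raise ValueError(f"condition_of_channel1 must be one of {CONDITIONS}")

    @property
    def dye_of_channel2(self) -> str:
        return "Cy5" if self.dye_of_channel1 == "Cy3" else "Cy3"

    @property
    def condition_of_channel2(self) -> str:
        return (
            "resistant" if self.condition_of_channel1 == "sensitive" else "sensitive"
        )


@dataclass
class TwoColorArraySet:
    """A set of two-color arrays sharing one feature panel."""

    layer: str
    feature_ids: list[str]
    arrays: list[TwoColorArray]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        dupes = _duplicates(self.feature_ids)
        if dupes:
            raise ValueError(f"duplicate feature ids: {sorted(dupes)}")
        n = len(self.feature_ids)
        for i, arr in enumerate(self.arrays):
            if len(arr.fg1) != n:
                raise ValueError(
                    f"array {i}: {len(arr.fg1)} values for {n} features"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)


# ---------------------------------------------------------------------------
# target map, catalogs


class TargetMap:
    """Scored miRNA -> gene predicted-target relation.

    Scores follow the mirSVR convention: more negative means stronger
    predicted repression.  Duplicate (miRNA, gene) rows collapse to the
    most negative (strongest) score.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        best: dict[tuple[str, str], float] = {}
        for mirna, gene, score in edges:
            score = float(score)
            if not np.isfinite(score):
                raise ValueError(f"non-finite score for pair ({mirna}, {gene})")
            key = (str(mirna), str(gene))
            if key not in best or score < best[key]:
                best[key] = score
        self._edges = best

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(m, g, s) for (m, g), s in sorted(self._edges.items())]

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._edges

    def score(self, mirna: str, gene: str) -> float:
        return self._edges[(mirna, gene)]

    def targets_of(self, mirna: str, score_max: float = np.inf) -> list[tuple[str, float]]:
        return [
            (g, s)
            for (m, g), s in sorted(self._edges.items())
            if m == mirna and s <= score_max
        ]

    def filtered(self, score_max: float) -> "TargetMap":
        return TargetMap((m, g, s) for (m, g), s in self._edges.items() if s <= score_max)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetMap):
            return NotImplemented
        return self._edges == other._edges


class AnnotationCatalog:
    """category_id -> (human readable name, set of gene ids)."""

    def __init__(self, categories: Mapping[str, tuple[str, set[str]]]) -> None:
        for cid, (name, genes) in categories.items():
            if not genes:
                raise ValueError(f"category {cid!r} has an empty gene set")
        self.categories = {
            str(cid): (str(name), set(map(str, genes)))
            for cid, (name, genes) in categories.items()
        }

    def __len__(self) -> int:
        return len(self.categories)

    def items(self):
        return sorted(self.categories.items())

    def genes(self, cid: str) -> set[str]:
        return self.categories[cid][1]


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True, order=True)
class NetworkNode:
    id: str
    node_kind: str
    mrna_direction: str = "none"
    protein_direction: str = "none"

    def __post_init__(self) -> None:
        if self.node_kind not in NODE_KINDS:
            raise ValueError(f"node_kind must be one of {NODE_KINDS}")
        for d in (self.mrna_direction, self.protein_direction):
            if d not in DIRECTIONS:
                raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass(frozen=True, order=True)
class NetworkEdge:
    source: str
    edge_kind: str
    target: str

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise ValueError(f"edge_kind must be one of {EDGE_KINDS}")


@dataclass
class Network:
    """Expression-annotated miRNA-gene network.

    Node fill (mRNA direction) and border (protein direction) colors of
    the published figures are carried as plain attributes.
    """

    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        dupes = _duplicates(ids)
        if dupes:
            raise ValueError(f"duplicate node ids: {sorted(dupes)}")
        known = set(ids)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e} references a node not in the network")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges of the same kind")

    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}

    def canonical(self) -> "Network":
        return Network(sorted(self.nodes), sorted(self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return sorted(self.nodes) == sorted(other.nodes) and sorted(
            self.edges
        ) == sorted(other.edges)

    def to_networkx(self):
        """Export as a networkx DiGraph (for layout / graph algorithms)."""
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(
                n.id,
                node_kind=n.node_kind,
                mrna_direction=n.mrna_direction,
                protein_direction=n.protein_direction,
            )
        for e in self.edges:
            g.add_edge(e.source, e.target, edge_kind=e.edge_kind)
        return g


# ---------------------------------------------------------------------------
# readers / writers


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[], comment=None
    )


def read_expression_table(path, layer: str, meta: Sequence[SampleMeta]) -> ExpressionMatrix:
    """Read a tab-delimited expression table (first column = feature id).

    Every sample column in the file must be described in ``meta``;
    columns are reordered to follow ``meta``.  Empty cells and ``NA``
    become missing values.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a feature-id column plus sample columns")
    feature_ids = df.iloc[:, 0].tolist()
    dupes = _duplicates(feature_ids)
    if dupes:
        raise ValueError(f"{path}: duplicate feature ids: {sorted(dupes)}")
    by_name = {m.name: m for m in meta}
    file_samples = list(df.columns[1:])
    unknown = [s for s in file_samples if s not in by_name]
    if unknown:
        raise ValueError(f"{path}: samples absent from metadata: {unknown}")
    missing = [m.name for m in meta if m.name not in file_samples]
    if missing:
        raise ValueError(f"{path}: samples in metadata but not in file: {missing}")
    ordered = [m.name for m in meta]
    raw = df[ordered].replace({"": np.nan, NA_TOKEN: np.nan})
    try:
        values = raw.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(layer, feature_ids, list(meta), values)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.17g")


def read_target_map(path) -> TargetMap:
    """Read a (miRNA, gene, score) table; duplicates keep the most negative score."""
    df = _read_tsv(path)
    if df.shape[0] == 0:
        return TargetMap()
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns (miRNA, gene, score)")
    edges = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row[2])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric score on line {i}") from exc
        edges.append((str(row[0]), str(row[1]), score))
    return TargetMap(edges)


def write_target_map(tm: TargetMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tscore\n")
        for m, g, s in tm.edges:
            fh.write(f"{m}\t{g}\t{s:.17g}\n")


def read_catalog(path) -> AnnotationCatalog:
    """Read a long-format catalog: columns (category_id, name, gene_id)."""
    df = _read_tsv(path)
    if df.shape[0] == 0:
        return AnnotationCatalog({})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns (category_id, name, gene_id)")
    cats: dict[str, tuple[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        cid, name, gene = str(row[0]), str(row[1]), str(row[2])
        if cid not in cats:
            cats[cid] = (name, set())
        cats[cid][1].add(gene)
    return AnnotationCatalog(cats)


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a two-column gene-gene interaction edge list."""
    df = _read_tsv(path)
    if df.shape[0] == 0:
        return []
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_a, gene_b)")
    return [(str(r[0]), str(r[1])) for r in df.itertuples(index=False)]


def write_sif(network: Network, path) -> None:
    """Write a network as SIF plus a node-attribute table.

    The SIF file has one ``source<TAB>edge_kind<TAB>target`` line per
    edge; the attribute table (``<path>`` with suffix ``.nodes.tsv``)
    carries id, node_kind and the two expression directions, including
    isolated nodes, so read-back reconstructs the network exactly.
    """
    path = str(path)
    with open(path, "w") as fh:
        for e in sorted(network.edges):
            fh.write(f"{e.source}\t{e.edge_kind}\t{e.target}\n")
    with open(_node_table_path(path), "w") as fh:
        fh.write("id\tnode_kind\tmrna_direction\tprotein_direction\n")
        for n in sorted(network.nodes):
            fh.write(
                f"{n.id}\t{n.node_kind}\t{n.mrna_direction}\t{n.protein_direction}\n"
            )


def read_sif(path) -> Network:
    """Read back a network written by :func:`write_sif`."""
    path = str(path)
    nodes: list[NetworkNode] = []
    with open(_node_table_path(path)) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: malformed node attribute table")
        for line in fh:
            nid, kind, mdir, pdir = line.rstrip("\n").split("\t")
            nodes.append(NetworkNode(nid, kind, mdir, pdir))
    edges: list[NetworkEdge] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            source, kind, target = line.split("\t")
            edges.append(NetworkEdge(source, kind, target))
    return Network(nodes, edges)


def _node_table_path(sif_path: str) -> str:
    root, _ = os.path.splitext(sif_path)
    return root + ".nodes.tsv"
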
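"""Assembly of expression-annotated miRNA-target networks.

The post-transcriptional network links DE miRNAs to anti-correlated DE
target mRNAs; the pre-translational network links them to DE proteins
of predicted target genes.  Gene-gene pathway edges (e.g. KEGG-derived,
supplied as an edge list) are overlaid on the genes present.  Node
attributes carry the mRNA direction (figure "fill color") and protein
direction ("border color"); rendering itself is out of scope — SIF plus
the attribute table is the artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffexpr import DifferentialResults
from .integrate import PairLink, _de_directions
from .io_tables import Network, NetworkEdge, NetworkNode

__all__ = ["GeneSetSelection", "build_network", "extract_subnetwork", "read_gene_sets"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetSelection:
    """A named gene set used to cut pathway subnetworks."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_sets(path) -> list[GeneSetSelection]:
    """Read (set_name, gene_id) rows into selections, one per set name."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (set_name, gene_id)")
    sets: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        sets.setdefault(str(row[0]), set()).add(str(row[1]))
    return [GeneSetSelection(name, frozenset(genes)) for name, genes in sorted(sets.items())]


def _direction_of(results, feature_id: str) -> str:
    if results is None:
        return "none"
    frame = results.frame if isinstance(results, DifferentialResults) else results
    if feature_id not in frame.index:
        return "none"
    status = frame.loc[feature_id, "status"]
    return status if status in ("up", "down") else "none"


def build_network(
    pairs: list[PairLink],
    gene_gene_edges: list[tuple[str, str]] | None = None,
    de_genes=None,
    de_proteins=None,
    mirna_results=None,
) -> Network:
    """Assemble a network from miRNA->target links plus pathway edges.

    One node per miRNA and per gene; miRNA->gene edges of kind
    ``mirna_target``; gene-gene edges retained only when both endpoints
    are present (dropped edges are counted in the log).  Gene nodes are
    annotated with their mRNA and protein DE direction; miRNA nodes use
    the mRNA slot for their own direction (they have no protein layer).
    """
    mirna_ids = sorted({p.mirna_id for p in pairs})
    gene_ids = sorted({p.gene_id for p in pairs})
    nodes = [
        NetworkNode(
            m, "miRNA",
            mrna_direction=_direction_of(mirna_results, m),
            protein_direction="none",
        )
        for m in mirna_ids
    ]
    nodes += [
        NetworkNode(
            g, "gene",
            mrna_direction=_direction_of(de_genes, g),
            protein_direction=_direction_of(de_proteins, g),
        )
        for g in gene_ids
    ]
    present = {n.id for n in nodes}
    edges = sorted(
        {NetworkEdge(p.mirna_id, "mirna_target", p.gene_id) for p in pairs}
    )
    dropped = 0
    if gene_gene_edges:
        gg = set()
        for a, b in gene_gene_edges:
            if a in present and b in present:
                gg.add(NetworkEdge(a, "gene_gene", b))
            else:
                dropped += 1
        edges += sorted(gg)
    if dropped:
        logger.info("build_network: dropped %d gene-gene edges outside node set", dropped)
    return Network(nodes, edges)


def extract_subnetwork(network: Network, selection: GeneSetSelection) -> Network:
    """Induced subnetwork on a gene set plus adjacent miRNAs.

    Keeps the selection's genes, every miRNA adjacent to at least one
    retained gene, and all edges joining retained nodes.  Isolated
    miRNAs never appear; the operation is idempotent.
    """
    genes = {
        n.id for n in network.nodes if n.node_kind != "miRNA" and n.id in selection.gene_ids
    }
    mirnas = {
        e.source
        for e in network.edges
        if e.edge_kind == "mirna_target" and e.target in genes
    }
    mirnas &= {n.id for n in network.nodes if n.node_kind == "miRNA"}
    keep = genes | mirnas
    nodes = [n for n in network.nodes if n.id in keep]
    edges = [e for e in network.edges if e.source in keep and e.target in keep]
    return Network(nodes, edges)
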
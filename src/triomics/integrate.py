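"""Cross-layer integration and regulatory-loop classification.

The centrepiece is the (miRNA, mRNA, protein) triplet taxonomy: for a
differentially expressed miRNA and a predicted target gene that is
differentially expressed at both the mRNA and protein layers, the three
direction signs define a feed-forward-style loop:

* type A (coherent) — miRNA and mRNA anti-correlated, protein follows
  the mRNA: the signature of target degradation propagating to protein.
* type B (incoherent) — miRNA and mRNA co-expressed, protein opposite:
  translational repression without mRNA decay.
* type C (incoherent) — all three co-expressed: the expression pattern
  does not support miRNA action on the target.
* unclassified — miRNA/mRNA anti-correlated but protein opposite to the
  mRNA; no mechanism in the taxonomy produces it.

Signs are taken from log fold changes (resistant vs sensitive), so the
whole classification is invariant under swapping which condition is
called "up" (negating all three signs preserves the type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DifferentialResults
from .io_tables import TargetMap

__all__ = [
    "PairLink",
    "RegulatoryLoop",
    "CoreGene",
    "MirnaCluster",
    "pair_links",
    "mrna_protein_core",
    "classify_loop",
    "enumerate_loops",
    "loop_table",
    "loop_type_counts",
    "cluster_mirnas",
]


@dataclass(frozen=True)
class PairLink:
    """A predicted miRNA->target pair between two DE feature lists."""

    mirna_id: str
    gene_id: str
    relation: str  # "anti" | "co"
    layer_of_target: str  # "mRNA" | "protein"
    score: float


@dataclass(frozen=True)
class RegulatoryLoop:
    mirna_id: str
    gene_id: str
    s_mirna: int
    s_mrna: int
    s_protein: int
    loop_type: str  # "A" | "B" | "C" | "unclassified"
    coherence: str  # "coherent" | "incoherent" | "none"


@dataclass(frozen=True)
class CoreGene:
    """Gene differentially expressed at both the mRNA and protein layer."""

    gene_id: str
    mrna_logfc: float
    protein_logfc: float
    concordant: bool


@dataclass(frozen=True)
class MirnaCluster:
    chromosome: str
    members: tuple[str, ...]
    span_kb: float


# ---------------------------------------------------------------------------
# helpers


def _de_directions(results: DifferentialResults | pd.DataFrame) -> pd.DataFrame:
    """Normalize input to a frame of significant features with logFC/status."""
    frame = results.frame if isinstance(results, DifferentialResults) else results
    sig = frame[frame["status"].isin(["up", "down"])]
    return sig[["logFC", "status"]]


def _sign(x: float) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    raise ValueError("zero/undefined sign: feature has logFC == 0")


# ---------------------------------------------------------------------------
# pairing


def pair_links(
    de_mirnas: DifferentialResults | pd.DataFrame,
    de_targets: DifferentialResults | pd.DataFrame,
    target_map: TargetMap,
    mode: str = "sign",
    target_layer: str = "mRNA",
    score_max: float = -0.1,
    mirna_profiles: pd.DataFrame | None = None,
    target_profiles: pd.DataFrame | None = None,
    r_min: float = 0.7,
) -> list[PairLink]:
    """Link DE miRNAs to their predicted DE targets.

    Only pairs present in ``target_map`` with score <= ``score_max`` are
    emitted.  In ``sign`` mode (default) the relation is ``anti`` iff
    the miRNA and target log fold changes have opposite signs.  In
    ``correlation`` mode, per-pair Pearson correlation across matched
    biological-replicate columns (``mirna_profiles`` /
    ``target_profiles``, features x replicates) decides: anti iff
    r <= -r_min, co iff r >= r_min; pairs in between are dropped.
    """
    if mode not in ("sign", "correlation"):
        raise ValueError(f"mode must be 'sign' or 'correlation', got {mode!r}")
    mir = _de_directions(de_mirnas)
    tgt = _de_directions(de_targets)
    if mode == "correlation":
        if mirna_profiles is None or target_profiles is None:
            raise ValueError("correlation mode requires replicate profiles")
        shared = [c for c in mirna_profiles.columns if c in target_profiles.columns]
        if len(shared) < 4:
            raise ValueError(
                f"correlation mode needs >= 4 matched samples, got {len(shared)}"
            )
    links: list[PairLink] = []
    tgt_ids = set(tgt.index)
    for mirna_id in mir.index:
        for gene_id, score in target_map.targets_of(mirna_id, score_max=score_max):
            if gene_id not in tgt_ids:
                continue
            if mode == "sign":
                s_m = _sign(mir.loc[mirna_id, "logFC"])
                s_t = _sign(tgt.loc[gene_id, "logFC"])
                relation = "anti" if s_m != s_t else "co"
            else:
                x = mirna_profiles.loc[mirna_id, shared].to_numpy(dtype=float)
                y = target_profiles.loc[gene_id, shared].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 4:
                    raise ValueError(
                        f"pair ({mirna_id}, {gene_id}): fewer than 4 matched samples"
                    )
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                if r <= -r_min:
                    relation = "anti"
                elif r >= r_min:
                    relation = "co"
                else:
                    continue
            links.append(PairLink(mirna_id, gene_id, relation, target_layer, score))
    return sorted(links, key=lambda l: (l.mirna_id, l.gene_id))


# ---------------------------------------------------------------------------
# mRNA-protein core


def mrna_protein_core(
    de_genes: DifferentialResults | pd.DataFrame,
    de_proteins: DifferentialResults | pd.DataFrame,
    protein_to_gene: dict[str, str] | None = None,
) -> list[CoreGene]:
    """Genes significantly altered at both the mRNA and the protein layer.

    ``protein_to_gene`` maps protein feature ids to gene ids (identity
    when the antibody panel is already gene-indexed).  Concordance is
    agreement of fold-change signs across the two layers.
    """
    genes = _de_directions(de_genes)
    prots = _de_directions(de_proteins)
    core: list[CoreGene] = []
    for prot_id in prots.index:
        gene_id = protein_to_gene.get(prot_id, prot_id) if protein_to_gene else prot_id
        if gene_id not in genes.index:
            continue
        m = float(genes.loc[gene_id, "logFC"])
        p = float(prots.loc[prot_id, "logFC"])
        core.append(CoreGene(gene_id, m, p, concordant=_sign(m) == _sign(p)))
    return sorted(core, key=lambda c: c.gene_id)


# ---------------------------------------------------------------------------
# loop classification


def classify_loop(s_mirna: int, s_mrna: int, s_protein: int) -> tuple[str, str]:
    """Classify a sign triplet into loop type and coherence.

    See the module docstring for the taxonomy.  Signs must be +1/-1.
    """
    for s in (s_mirna, s_mrna, s_protein):
        if s not in (1, -1):
            raise ValueError(f"signs must be +1 or -1, got {s!r}")
    if s_mrna == -s_mirna:
        if s_protein == s_mrna:
            return "A", "coherent"
        return "unclassified", "none"
    # miRNA and mRNA co-expressed
    if s_protein == -s_mirna:
        return "B", "incoherent"
    return "C", "incoherent"


def enumerate_loops(
    de_mirnas: DifferentialResults | pd.DataFrame,
    de_genes: DifferentialResults | pd.DataFrame,
    de_proteins: DifferentialResults | pd.DataFrame,
    target_map: TargetMap,
    score_max: float = -0.1,
    protein_to_gene: dict[str, str] | None = None,
) -> list[RegulatoryLoop]:
    """Enumerate all (miRNA, mRNA, protein) triplets and classify them.

    A loop exists for every predicted (miRNA, gene) pair whose miRNA,
    mRNA and protein are all differentially expressed.  One-to-many
    protein->gene mappings expand to one triplet per mapped protein, but
    duplicate (miRNA, gene) triplets are collapsed (they would carry
    identical signs or be ambiguous; the first protein in id order
    wins).
    """
    mir = _de_directions(de_mirnas)
    genes = _de_directions(de_genes)
    prots = _de_directions(de_proteins)
    gene_to_prot: dict[str, str] = {}
    for prot_id in sorted(prots.index):
        gene_id = protein_to_gene.get(prot_id, prot_id) if protein_to_gene else prot_id
        gene_to_prot.setdefault(gene_id, prot_id)
    loops: list[RegulatoryLoop] = []
    seen: set[tuple[str, str]] = set()
    for mirna_id in mir.index:
        s_mir = _sign(mir.loc[mirna_id, "logFC"])
        for gene_id, _score in target_map.targets_of(mirna_id, score_max=score_max):
            if gene_id not in genes.index or gene_id not in gene_to_prot:
                continue
            if (mirna_id, gene_id) in seen:
                continue
            seen.add((mirna_id, gene_id))
            s_mrna = _sign(genes.loc[gene_id, "logFC"])
            s_prot = _sign(prots.loc[gene_to_prot[gene_id], "logFC"])
            loop_type, coherence = classify_loop(s_mir, s_mrna, s_prot)
            loops.append(
                RegulatoryLoop(
                    mirna_id, gene_id, s_mir, s_mrna, s_prot, loop_type, coherence
                )
            )
    return sorted(loops, key=lambda l: (l.mirna_id, l.gene_id))


def loop_table(loops: list[RegulatoryLoop]) -> pd.DataFrame:
    cols = [
        "mirna_id", "gene_id", "s_mirna", "s_mrna", "s_protein",
        "loop_type", "coherence",
    ]
    if not loops:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([l.__dict__ for l in loops])[cols]


def loop_type_counts(loops: list[RegulatoryLoop]) -> dict[str, int]:
    counts = {"A": 0, "B": 0, "C": 0, "unclassified": 0}
    for l in loops:
        counts[l.loop_type] += 1
    return counts


# ---------------------------------------------------------------------------
# genomic clustering of miRNAs


def cluster_mirnas(
    coords: list[tuple[str, str, float]],
    max_gap_kb: float = 1000.0,
) -> list[MirnaCluster]:
    """Single-linkage genomic clustering of miRNAs per chromosome.

    ``coords`` holds (mirna_id, chromosome, position in bp).  Sorted
    positions on one chromosome join a cluster while consecutive gaps
    are strictly below ``max_gap_kb`` kilobases; a gap of exactly the
    threshold splits.  Singleton clusters are reported.
    """
    ids = [c[0] for c in coords]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate mirna ids: {dupes}")
    by_chrom: dict[str, list[tuple[float, str]]] = {}
    for mirna_id, chrom, pos in coords:
        pos = float(pos)
        if pos < 0:
            raise ValueError(f"{mirna_id}: negative position {pos}")
        by_chrom.setdefault(str(chrom), []).append((pos, mirna_id))
    clusters: list[MirnaCluster] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        start = 0
        for i in range(1, len(entries) + 1):
            if i == len(entries) or entries[i][0] - entries[i - 1][0] >= max_gap_kb * 1000.0:
                block = entries[start:i]
                span_kb = (block[-1][0] - block[0][0]) / 1000.0
                clusters.append(
                    MirnaCluster(chrom, tuple(m for _, m in block), span_kb)
                )
                start = i
    return clusters
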
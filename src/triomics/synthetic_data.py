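"""Synthetic three-layer array study with known ground truth.

Emulates the study design end-to-end: two-color 44K-style gene arrays
and a two-color antibody panel (dye-swapped technical replicates),
single-channel miRNA arrays, 3 biological x 4 technical replicates per
condition, planted differentially expressed features, planted
miRNA-mRNA-protein loops of every type, planted low-signal features and
a scored target-prediction table with decoys.

Signal model (per feature f, array a, channel):

    intensity = B + S_f * 2^delta,   B ~ N(background_mu, background_sd^2)

with per-feature brightness S_f exponential across features (the
normexp assumption) and log2 deviation

    delta = +-logFC/2 (by condition) + bio effect + technical noise,

bio ~ N(0, noise_sd^2/2) per (feature, condition, biological replicate),
technical ~ N(0, noise_sd^2) per (feature, array, channel).  The
reported local background equals B, so at noise_sd -> 0 the planted
fold changes are recovered exactly.  Planted DE features draw a shifted
exponential brightness (>= signal_alpha) so that recovery tests measure
the pipeline rather than detectability; planted low-signal features
have foreground below background in a fixed fraction of arrays and no
others do, making the filter ground truth exact.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .integrate import RegulatoryLoop, classify_loop
from .io_tables import (
    ExpressionMatrix,
    SampleMeta,
    TargetMap,
    TwoColorArray,
    TwoColorArraySet,
    read_target_map,
    write_target_map,
)

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticBundle", "generate", "write_fixture", "read_fixture"]

LOOP_TYPES = ("A", "B", "C", "unclassified")

# gene-sign pattern relative to the miRNA sign, per loop type
_TYPE_PATTERN = {
    "A": (-1, -1),
    "B": (+1, -1),
    "C": (+1, +1),
    "unclassified": (-1, +1),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: platform sizes echo the 44K gene array, the
    ~800-probe miRNA array and the 725-antibody panel; replicate layout,
    planted loop counts (38/34/28), fold-change magnitude and noise
    follow the emulated study scenario."""

    n_genes: int = 10000
    n_mirnas: int = 800
    n_proteins: int = 725
    n_bio: int = 3
    n_tech: int = 4
    dye_swap: bool = True
    n_de_genes: int = 400
    n_de_mirnas: int = 47
    n_de_proteins: int = 150
    logfc_magnitude: float = 1.5
    noise_sd: float = 0.25
    loops_per_type: dict = field(
        default_factory=lambda: {"A": 38, "B": 34, "C": 28, "unclassified": 0}
    )
    target_score_range: tuple[float, float] = (-1.0, -0.2)
    n_decoy_targets: int = 400
    background_mu: float = 100.0
    background_sd: float = 20.0
    signal_alpha: float = 1000.0
    low_signal_fraction: float = 0.9
    n_low_signal: int = 200
    n_gene_gene_edges: int = 200
    n_catalog_categories: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins must be <= n_genes (panel is gene-mapped)")
        if self.noise_sd < 0 or self.logfc_magnitude <= 0:
            raise ValueError("noise_sd must be >= 0 and logfc_magnitude > 0")
        if not 0 <= self.low_signal_fraction <= 1:
            raise ValueError("low_signal_fraction must be in [0, 1]")
        if self.background_sd <= 0 or self.signal_alpha <= 0:
            raise ValueError("background_sd and signal_alpha must be > 0")
        unknown = set(self.loops_per_type) - set(LOOP_TYPES)
        if unknown:
            raise ValueError(f"unknown loop types: {sorted(unknown)}")
        n_loops = self.total_loops()
        if self.n_de_mirnas < 1 and n_loops > 0:
            raise ValueError("planted loops require at least one DE miRNA")
        if n_loops > min(self.n_proteins, self.n_de_genes, self.n_de_proteins):
            raise ValueError(
                f"{n_loops} planted loops need distinct genes that are on the "
                f"protein panel ({self.n_proteins}) and DE at both layers "
                f"(n_de_genes={self.n_de_genes}, n_de_proteins={self.n_de_proteins})"
            )
        if self.n_de_genes > self.n_genes or self.n_de_mirnas > self.n_mirnas:
            raise ValueError("more DE features requested than features")
        if self.n_de_proteins > self.n_proteins:
            raise ValueError("n_de_proteins exceeds the panel size")
        if self.n_low_signal > self.n_genes - self.n_de_genes:
            raise ValueError("not enough null genes to plant low-signal features")

    def total_loops(self) -> int:
        return sum(self.loops_per_type.get(t, 0) for t in LOOP_TYPES)


@dataclass
class SyntheticTruth:
    """Planted ground truth: DE status and log fold change per layer,
    the planted loop list and the planted low-signal feature set."""

    de_status: dict[str, dict[str, str]]
    true_logfc: dict[str, dict[str, float]]
    planted_loops: list[RegulatoryLoop]
    planted_low_signal: set[str]

    def de_features(self, layer: str) -> set[str]:
        return {f for f, s in self.de_status[layer].items() if s != "ns"}


@dataclass
class SyntheticBundle:
    config: SimConfig
    mrna_arrays: TwoColorArraySet
    mirna_fg: ExpressionMatrix
    mirna_bg: ExpressionMatrix
    protein_arrays: TwoColorArraySet
    target_map: TargetMap
    truth: SyntheticTruth
    gene_gene_edges: list[tuple[str, str]]
    catalog_rows: list[tuple[str, str, str]]


# ---------------------------------------------------------------------------
# truth construction


def _plant_truth(config: SimConfig, rng: np.random.Generator) -> tuple[SyntheticTruth, list[str], list[str]]:
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mirnas = [f"miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    panel = genes[: config.n_proteins]

    n_loops = config.total_loops()
    de_mirna_ids = list(rng.choice(mirnas, size=config.n_de_mirnas, replace=False))
    loop_genes = list(rng.choice(panel, size=n_loops, replace=False))

    mirna_sign = {m: (1 if i % 2 == 0 else -1) for i, m in enumerate(de_mirna_ids)}

    loops: list[RegulatoryLoop] = []
    gene_sign_mrna: dict[str, int] = {}
    gene_sign_prot: dict[str, int] = {}
    k = 0
    for loop_type in LOOP_TYPES:
        for _ in range(config.loops_per_type.get(loop_type, 0)):
            mirna_id = de_mirna_ids[k % len(de_mirna_ids)]
            gene_id = loop_genes[k]
            s_m = mirna_sign[mirna_id]
            rel_mrna, rel_prot = _TYPE_PATTERN[loop_type]
            s_mrna, s_prot = rel_mrna * s_m, rel_prot * s_m
            lt, coh = classify_loop(s_m, s_mrna, s_prot)
            assert lt == loop_type  # construction consistent with the classifier
            loops.append(
                RegulatoryLoop(mirna_id, gene_id, s_m, s_mrna, s_prot, lt, coh)
            )
            gene_sign_mrna[gene_id] = s_mrna
            gene_sign_prot[gene_id] = s_prot
            k += 1

    # remaining DE genes (mRNA layer) outside the loop set
    pool = [g for g in genes if g not in gene_sign_mrna]
    extra_genes = list(rng.choice(pool, size=config.n_de_genes - n_loops, replace=False))
    for g in extra_genes:
        gene_sign_mrna[g] = int(rng.choice([-1, 1]))

    # remaining DE proteins on the panel outside the loop set
    prot_pool = [g for g in panel if g not in gene_sign_prot]
    extra_prots = list(
        rng.choice(prot_pool, size=config.n_de_proteins - n_loops, replace=False)
    )
    for g in extra_prots:
        gene_sign_prot[g] = int(rng.choice([-1, 1]))

    # planted low-signal features among null genes
    null_genes = [g for g in genes if g not in gene_sign_mrna]
    low_signal = set(rng.choice(null_genes, size=config.n_low_signal, replace=False))

    mag = config.logfc_magnitude
    de_status = {
        "mRNA": {g: ("up" if s > 0 else "down") for g, s in gene_sign_mrna.items()},
        "miRNA": {m: ("up" if s > 0 else "down") for m, s in mirna_sign.items()},
        "protein": {g: ("up" if s > 0 else "down") for g, s in gene_sign_prot.items()},
    }
    true_logfc = {
        "mRNA": {g: float(s * mag) for g, s in gene_sign_mrna.items()},
        "miRNA": {m: float(s * mag) for m, s in mirna_sign.items()},
        "protein": {g: float(s * mag) for g, s in gene_sign_prot.items()},
    }
    for layer, ids in (("mRNA", genes), ("miRNA", mirnas), ("protein", panel)):
        for f in ids:
            de_status[layer].setdefault(f, "ns")
            true_logfc[layer].setdefault(f, 0.0)
    truth = SyntheticTruth(de_status, true_logfc, loops, low_signal)
    return truth, genes, mirnas


# ---------------------------------------------------------------------------
# expression machinery


def _brightness(
    rng: np.random.Generator, features: list[str], de: set[str], alpha: float
) -> np.ndarray:
    s = rng.exponential(scale=alpha, size=len(features))
    is_de = np.array([f in de for f in features])
    s[is_de] = alpha * (1.0 + rng.exponential(scale=1.0, size=int(is_de.sum())))
    return s


def _deltas(
    rng: np.random.Generator,
    features: list[str],
    logfc: np.ndarray,
    config: SimConfig,
    n_arrays: int,
) -> dict[str, np.ndarray]:
    """Per-condition log2 deviations, one matrix column per array slot."""
    n = len(features)
    bio = {
        c: rng.normal(0.0, config.noise_sd / math.sqrt(2.0), size=(n, config.n_bio))
        for c in ("sensitive", "resistant")
    }
    out = {}
    for c, half in (("sensitive", -0.5), ("resistant", +0.5)):
        cols = []
        for b in range(config.n_bio):
            for _t in range(n_arrays // config.n_bio):
                tech = rng.normal(0.0, config.noise_sd, size=n)
                cols.append(half * logfc + bio[c][:, b] + tech)
        out[c] = np.column_stack(cols)
    return out


def _two_color_set(
    rng: np.random.Generator,
    layer: str,
    features: list[str],
    truth: SyntheticTruth,
    config: SimConfig,
    low_signal: set[str] | None = None,
) -> TwoColorArraySet:
    n = len(features)
    n_arrays = config.n_bio * config.n_tech
    logfc = np.array([truth.true_logfc[layer][f] for f in features])
    de = truth.de_features(layer)
    s_f = _brightness(rng, features, de, config.signal_alpha)
    delta = _deltas(rng, features, logfc, config, n_arrays)

    low_mask = np.array([f in (low_signal or set()) for f in features])
    s_f[low_mask] = 0.0
    n_below = math.ceil(config.low_signal_fraction * n_arrays)
    below = np.zeros((n, n_arrays), dtype=bool)
    for i in np.where(low_mask)[0]:
        below[i, rng.permutation(n_arrays)[:n_below]] = True

    arrays: list[TwoColorArray] = []
    k = 0
    for b in range(1, config.n_bio + 1):
        for t in range(1, config.n_tech + 1):
            swapped = config.dye_swap and t % 2 == 0
            cond1 = "resistant" if swapped else "sensitive"
            cond2 = "sensitive" if swapped else "resistant"
            channels = {}
            for ch, cond in ((1, cond1), (2, cond2)):
                bg_true = np.maximum(
                    rng.normal(config.background_mu, config.background_sd, size=n), 0.0
                )
                signal = s_f * np.exp2(delta[cond][:, k])
                fg = bg_true + signal
                # planted low-signal features dip below the local background
                dip = below[:, k]
                fg[dip] = np.maximum(
                    bg_true[dip]
                    - np.abs(rng.normal(0.0, config.background_sd / 2, size=int(dip.sum()))),
                    0.0,
                )
                lift = low_mask & ~dip
                fg[lift] = bg_true[lift] + np.abs(
                    rng.normal(0.0, config.background_sd / 2, size=int(lift.sum()))
                ) + 1e-6
                channels[ch] = (fg, bg_true)
            arrays.append(
                TwoColorArray(
                    fg1=channels[1][0],
                    bg1=channels[1][1],
                    fg2=channels[2][0],
                    bg2=channels[2][1],
                    dye_of_channel1="Cy3",
                    condition_of_channel1=cond1,
                    bio_rep=b,
                    tech_rep=t,
                )
            )
            k += 1
    return TwoColorArraySet(layer, list(features), arrays)


def _single_channel_set(
    rng: np.random.Generator,
    features: list[str],
    truth: SyntheticTruth,
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    n = len(features)
    logfc = np.array([truth.true_logfc["miRNA"][f] for f in features])
    de = truth.de_features("miRNA")
    s_f = _brightness(rng, features, de, config.signal_alpha)
    n_arrays = config.n_bio * config.n_tech
    delta = _deltas(rng, features, logfc, config, n_arrays)

    samples: list[SampleMeta] = []
    fg_cols, bg_cols = [], []
    for cond in ("sensitive", "resistant"):
        k = 0
        for b in range(1, config.n_bio + 1):
            for t in range(1, config.n_tech + 1):
                bg_true = np.maximum(
                    rng.normal(config.background_mu, config.background_sd, size=n), 0.0
                )
                fg = bg_true + s_f * np.exp2(delta[cond][:, k])
                fg_cols.append(fg)
                bg_cols.append(bg_true)
                samples.append(
                    SampleMeta(
                        name=f"{cond}_b{b}_t{t}",
                        condition=cond,
                        bio_rep=b,
                        tech_rep=t,
                        dye="none",
                    )
                )
                k += 1
    fg = ExpressionMatrix("miRNA", features, samples, np.column_stack(fg_cols))
    bg = ExpressionMatrix("miRNA", features, samples, np.column_stack(bg_cols))
    return fg, bg


# ---------------------------------------------------------------------------
# target map, pathway edges, catalog


def _build_target_map(
    rng: np.random.Generator,
    truth: SyntheticTruth,
    genes: list[str],
    mirnas: list[str],
    config: SimConfig,
) -> TargetMap:
    lo, hi = config.target_score_range
    planted = {(l.mirna_id, l.gene_id) for l in truth.planted_loops}
    edges = [
        (m, g, float(rng.uniform(lo, hi))) for m, g in sorted(planted)
    ]
    de_mirnas = truth.de_features("miRNA")
    dual_de = truth.de_features("mRNA") & truth.de_features("protein")
    n_decoys = 0
    attempts = 0
    seen = set(planted)
    while n_decoys < config.n_decoy_targets and attempts < config.n_decoy_targets * 50:
        attempts += 1
        m = mirnas[int(rng.integers(len(mirnas)))]
        g = genes[int(rng.integers(len(genes)))]
        if (m, g) in seen:
            continue
        # decoys must not silently complete an unplanted loop
        if m in de_mirnas and g in dual_de:
            continue
        seen.add((m, g))
        edges.append((m, g, float(rng.uniform(lo, hi))))
        n_decoys += 1
    return TargetMap(edges)


def _build_gene_gene(
    rng: np.random.Generator, truth: SyntheticTruth, genes: list[str], config: SimConfig
) -> list[tuple[str, str]]:
    de_genes = sorted(truth.de_features("mRNA"))
    edges = set()
    while len(edges) < config.n_gene_gene_edges:
        a = de_genes[int(rng.integers(len(de_genes)))]
        b = de_genes[int(rng.integers(len(de_genes)))]
        if a != b and (a, b) not in edges and (b, a) not in edges:
            edges.add((a, b))
    return sorted(edges)


def _build_catalog(
    rng: np.random.Generator, truth: SyntheticTruth, genes: list[str], config: SimConfig
) -> list[tuple[str, str, str]]:
    """Long-format catalog rows; CAT01 is genuinely enriched in up-genes."""
    rows: list[tuple[str, str, str]] = []
    up = sorted(g for g, s in truth.de_status["mRNA"].items() if s == "up")
    enriched = list(rng.choice(up, size=min(30, len(up)), replace=False))
    enriched += list(rng.choice(genes, size=10, replace=False))
    for g in sorted(set(enriched)):
        rows.append(("CAT01", "planted enriched set", g))
    for c in range(2, config.n_catalog_categories + 1):
        members = rng.choice(genes, size=int(rng.integers(20, 80)), replace=False)
        for g in sorted(members):
            rows.append((f"CAT{c:02d}", f"random set {c}", g))
    return rows


# ---------------------------------------------------------------------------
# public API


def generate(config: SimConfig | None = None) -> SyntheticBundle:
    """Generate the full three-layer study with ground truth.

    Fully reproducible from ``config.seed``; infeasible loop counts are
    rejected before any data is produced (SimConfig validation).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    truth, genes, mirnas = _plant_truth(config, rng)
    panel = genes[: config.n_proteins]
    mrna = _two_color_set(rng, "mRNA", genes, truth, config, truth.planted_low_signal)
    mirna_fg, mirna_bg = _single_channel_set(rng, mirnas, truth, config)
    protein = _two_color_set(rng, "protein", panel, truth, config)
    target_map = _build_target_map(rng, truth, genes, mirnas, config)
    gene_gene = _build_gene_gene(rng, truth, genes, config)
    catalog = _build_catalog(rng, truth, genes, config)
    return SyntheticBundle(
        config, mrna, mirna_fg, mirna_bg, protein, target_map, truth, gene_gene, catalog
    )


# ---------------------------------------------------------------------------
# fixture files


def _write_two_color(arrset: TwoColorArraySet, prefix: str, out_dir: str) -> None:
    data = {"feature_id": arrset.feature_ids}
    meta_rows = []
    for k, arr in enumerate(arrset.arrays, start=1):
        for name, vec in (
            ("fg1", arr.fg1), ("bg1", arr.bg1), ("fg2", arr.fg2), ("bg2", arr.bg2)
        ):
            data[f"a{k}_{name}"] = vec
        meta_rows.append(
            {
                "array_id": f"a{k}",
                "bio_rep": arr.bio_rep,
                "tech_rep": arr.tech_rep,
                "dye_of_channel1": arr.dye_of_channel1,
                "condition_of_channel1": arr.condition_of_channel1,
            }
        )
    pd.DataFrame(data).to_csv(
        os.path.join(out_dir, f"{prefix}_arrays.tsv"),
        sep="\t", index=False, na_rep="NA", float_format="%.17g",
    )
    pd.DataFrame(meta_rows).to_csv(
        os.path.join(out_dir, f"{prefix}_arrays_meta.tsv"), sep="\t", index=False
    )


def _read_two_color(prefix: str, in_dir: str, layer: str) -> TwoColorArraySet:
    df = pd.read_csv(
        os.path.join(in_dir, f"{prefix}_arrays.tsv"), sep="\t",
        float_precision="round_trip",
    )
    meta = pd.read_csv(os.path.join(in_dir, f"{prefix}_arrays_meta.tsv"), sep="\t")
    features = df["feature_id"].astype(str).tolist()
    arrays = []
    for row in meta.itertuples(index=False):
        aid = row.array_id
        arrays.append(
            TwoColorArray(
                fg1=df[f"{aid}_fg1"].to_numpy(float),
                bg1=df[f"{aid}_bg1"].to_numpy(float),
                fg2=df[f"{aid}_fg2"].to_numpy(float),
                bg2=df[f"{aid}_bg2"].to_numpy(float),
                dye_of_channel1=row.dye_of_channel1,
                condition_of_channel1=row.condition_of_channel1,
                bio_rep=int(row.bio_rep),
                tech_rep=int(row.tech_rep),
            )
        )
    return TwoColorArraySet(layer, features, arrays)


def _write_matrix_with_meta(matrix: ExpressionMatrix, stem: str, out_dir: str) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(
        os.path.join(out_dir, f"{stem}.tsv"), sep="\t", na_rep="NA", float_format="%.17g"
    )
    pd.DataFrame(
        [
            {
                "name": s.name, "condition": s.condition,
                "bio_rep": s.bio_rep, "tech_rep": s.tech_rep, "dye": s.dye,
            }
            for s in matrix.samples
        ]
    ).to_csv(os.path.join(out_dir, f"{stem}_samples.tsv"), sep="\t", index=False)


def _read_matrix_with_meta(stem: str, in_dir: str, layer: str) -> ExpressionMatrix:
    from .io_tables import read_expression_table

    meta_df = pd.read_csv(os.path.join(in_dir, f"{stem}_samples.tsv"), sep="\t")
    meta = [
        SampleMeta(
            name=str(r.name_) if hasattr(r, "name_") else str(r[0]),
            condition=str(r.condition),
            bio_rep=int(r.bio_rep),
            tech_rep=int(r.tech_rep),
            dye=str(r.dye),
        )
        for r in meta_df.itertuples(index=False)
    ]
    return read_expression_table(os.path.join(in_dir, f"{stem}.tsv"), layer, meta)


def write_fixture(bundle: SyntheticBundle, out_dir: str, overwrite: bool = False) -> None:
    """Write every fixture file the pipeline consumes, plus the truth.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (use overwrite=True)")
    os.makedirs(out_dir, exist_ok=True)
    _write_two_color(bundle.mrna_arrays, "mrna", out_dir)
    _write_two_color(bundle.protein_arrays, "protein", out_dir)
    _write_matrix_with_meta(bundle.mirna_fg, "mirna_fg", out_dir)
    _write_matrix_with_meta(bundle.mirna_bg, "mirna_bg", out_dir)
    write_target_map(bundle.target_map, os.path.join(out_dir, "target_map.tsv"))
    with open(os.path.join(out_dir, "gene_gene.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in bundle.gene_gene_edges:
            fh.write(f"{a}\t{b}\n")
    with open(os.path.join(out_dir, "catalog.tsv"), "w") as fh:
        fh.write("category_id\tname\tgene_id\n")
        for cid, name, gene in bundle.catalog_rows:
            fh.write(f"{cid}\t{name}\t{gene}\n")
    truth = bundle.truth
    rows = []
    for layer in ("mRNA", "miRNA", "protein"):
        for fid in sorted(truth.de_status[layer]):
            rows.append(
                {
                    "layer": layer, "feature_id": fid,
                    "status": truth.de_status[layer][fid],
                    "true_logfc": truth.true_logfc[layer][fid],
                }
            )
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "truth_de.tsv"), sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame([l.__dict__ for l in truth.planted_loops]).to_csv(
        os.path.join(out_dir, "truth_loops.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "truth_low_signal.txt"), "w") as fh:
        for fid in sorted(truth.planted_low_signal):
            fh.write(fid + "\n")
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        cfg = dataclasses.asdict(bundle.config)
        cfg["target_score_range"] = list(cfg["target_score_range"])
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_fixture(in_dir: str) -> SyntheticBundle:
    """Read back a fixture directory into an in-memory bundle."""
    with open(os.path.join(in_dir, "config.yaml")) as fh:
        raw = yaml.safe_load(fh)
    raw["target_score_range"] = tuple(raw["target_score_range"])
    config = SimConfig(**raw)
    mrna = _read_two_color("mrna", in_dir, "mRNA")
    protein = _read_two_color("protein", in_dir, "protein")
    mirna_fg = _read_matrix_with_meta("mirna_fg", in_dir, "miRNA")
    mirna_bg = _read_matrix_with_meta("mirna_bg", in_dir, "miRNA")
    target_map = read_target_map(os.path.join(in_dir, "target_map.tsv"))
    gg = pd.read_csv(os.path.join(in_dir, "gene_gene.tsv"), sep="\t")
    gene_gene = [(str(a), str(b)) for a, b in zip(gg["gene_a"], gg["gene_b"])]
    cat = pd.read_csv(os.path.join(in_dir, "catalog.tsv"), sep="\t")
    catalog_rows = [
        (str(c), str(n), str(g))
        for c, n, g in zip(cat["category_id"], cat["name"], cat["gene_id"])
    ]
    truth_df = pd.read_csv(os.path.join(in_dir, "truth_de.tsv"), sep="\t")
    de_status: dict[str, dict[str, str]] = {"mRNA": {}, "miRNA": {}, "protein": {}}
    true_logfc: dict[str, dict[str, float]] = {"mRNA": {}, "miRNA": {}, "protein": {}}
    for row in truth_df.itertuples(index=False):
        de_status[row.layer][str(row.feature_id)] = str(row.status)
        true_logfc[row.layer][str(row.feature_id)] = float(row.true_logfc)
    loops_df = pd.read_csv(os.path.join(in_dir, "truth_loops.tsv"), sep="\t")
    loops = [
        RegulatoryLoop(
            str(r.mirna_id), str(r.gene_id), int(r.s_mirna), int(r.s_mrna),
            int(r.s_protein), str(r.loop_type), str(r.coherence),
        )
        for r in loops_df.itertuples(index=False)
    ]
    with open(os.path.join(in_dir, "truth_low_signal.txt")) as fh:
        low = {line.strip() for line in fh if line.strip()}
    truth = SyntheticTruth(de_status, true_logfc, loops, low)
    return SyntheticBundle(
        config, mrna, mirna_fg, mirna_bg, protein, target_map, truth, gene_gene, catalog_rows
    )
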
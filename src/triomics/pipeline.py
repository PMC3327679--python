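"""Config-driven orchestration: preprocess -> DE -> enrichment ->
integration -> loops -> networks, with a deterministic run manifest.

Each layer follows its platform's route:

* mRNA (two-color): low-signal filter, background subtraction, lowess
  (MA) normalization per array, channel split, technical-replicate
  collapse, moderated t at FDR <= 0.01 and |logFC| >= 1.
* miRNA (single channel): low-signal filter, variance-stabilizing
  transform, collapse, moderated t at FDR <= 0.1.
* protein (two-color antibody panel): normexp background correction,
  rank-invariant normalization per array, channel split, collapse,
  moderated t at FDR <= 0.1.

Outputs are tab-delimited tables plus SIF networks; the manifest
records the config hash, seed and per-stage row counts, so identical
inputs and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, integrate, netbuild, preprocess
from .diffexpr import LAYER_THRESHOLDS, DifferentialResults, ModeratedTTest
from .io_tables import (
    ExpressionMatrix,
    TwoColorArraySet,
    write_expression_table,
    write_sif,
)
from .netbuild import GeneSetSelection
from .synthetic_data import SimConfig, SyntheticBundle, generate, read_fixture, write_fixture

__all__ = ["PipelineConfig", "run", "run_bundle", "demo", "recovery_report"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    ``input_dir`` must hold a fixture-layout directory (see
    :mod:`triomics.synthetic_data`); thresholds default to the
    layer-specific study values; ``score_max`` is the mirSVR-style
    cutoff on predicted target scores (more negative = stronger).
    """

    input_dir: str
    output_dir: str
    fdr_mrna: float = 0.01
    min_abs_logfc_mrna: float = 1.0
    fdr_mirna: float = 0.1
    fdr_protein: float = 0.1
    pairing_mode: str = "sign"
    score_max: float = -0.1
    low_signal_max_fraction: float = 0.6
    lowess_span: float = 0.3
    normexp_offset: float = 16.0
    seed: int = 0
    log_level: str = "INFO"

    def thresholds(self) -> dict[str, diffexpr.SelectionThresholds]:
        return {
            "mRNA": diffexpr.SelectionThresholds(self.fdr_mrna, self.min_abs_logfc_mrna),
            "miRNA": diffexpr.SelectionThresholds(self.fdr_mirna, 0.0),
            "protein": diffexpr.SelectionThresholds(self.fdr_protein, 0.0),
        }

    def config_hash(self) -> str:
        """Hash of the analysis settings (paths and logging excluded)."""
        fields = dataclasses.asdict(self)
        for key in ("input_dir", "output_dir", "log_level"):
            fields.pop(key)
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-layer preprocessing


def _two_color_fg_bg(arrset: TwoColorArraySet) -> tuple[np.ndarray, np.ndarray]:
    """Feature x array foreground/background matrices for the filter.

    A feature counts as below background on an array iff both channels
    are below their local background; this is encoded by taking the
    per-array maximum of (fg - bg) over the two channels.
    """
    diff = np.column_stack(
        [np.maximum(a.fg1 - a.bg1, a.fg2 - a.bg2) for a in arrset.arrays]
    )
    return diff, np.zeros_like(diff)


def preprocess_two_color(
    arrset: TwoColorArraySet,
    config: PipelineConfig,
    use_normexp: bool,
) -> tuple[ExpressionMatrix, preprocess.FilterReport]:
    """Filter, background-correct, normalize and collapse one two-color set."""
    fg, bg = _two_color_fg_bg(arrset)
    report = preprocess.filter_low_signal(
        arrset.feature_ids, fg, bg, max_fraction=config.low_signal_max_fraction
    )
    keep_idx = [i for i, f in enumerate(arrset.feature_ids) if f in report.kept]
    features = [arrset.feature_ids[i] for i in keep_idx]

    M_cols, A_cols = [], []
    floor = 0.5  # minimum background-subtracted intensity before log
    for arr in arrset.arrays:
        if use_normexp:
            params1 = preprocess.estimate_normexp_params(
                arr.fg1, arr.bg1, offset=config.normexp_offset
            )
            params2 = preprocess.estimate_normexp_params(
                arr.fg2, arr.bg2, offset=config.normexp_offset
            )
            ch1 = preprocess.normexp_correct(arr.fg1, arr.bg1, params1)[keep_idx]
            ch2 = preprocess.normexp_correct(arr.fg2, arr.bg2, params2)[keep_idx]
        else:
            ch1 = np.maximum((arr.fg1 - arr.bg1)[keep_idx], floor)
            ch2 = np.maximum((arr.fg2 - arr.bg2)[keep_idx], floor)
        A = 0.5 * (np.log2(ch1) + np.log2(ch2))
        if use_normexp:
            try:
                M_norm = preprocess.rank_invariant_normalize(ch1, ch2)
            except ValueError as exc:
                # small/volatile panels can leave too few rank-invariant
                # features; the advised fallback is plain lowess
                logger.warning("rank-invariant normalization failed (%s); "
                               "falling back to lowess", exc)
                M = np.log2(ch2 / ch1)
                M_norm = preprocess.lowess_normalize(M, A, span=config.lowess_span)
        else:
            M = np.log2(ch2 / ch1)
            M_norm = preprocess.lowess_normalize(M, A, span=config.lowess_span)
        M_cols.append(M_norm)
        A_cols.append(A)

    kept_set = TwoColorArraySet(
        arrset.layer,
        features,
        [
            dataclasses.replace(
                a,
                fg1=a.fg1[keep_idx], bg1=a.bg1[keep_idx],
                fg2=a.fg2[keep_idx], bg2=a.bg2[keep_idx],
            )
            for a in arrset.arrays
        ],
    )
    channels = preprocess.two_color_to_channels(
        kept_set, np.column_stack(M_cols), np.column_stack(A_cols)
    )
    collapsed = preprocess.collapse_replicates(channels)
    return collapsed, report


def preprocess_single_channel(
    fg: ExpressionMatrix,
    bg: ExpressionMatrix,
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, preprocess.FilterReport]:
    report = preprocess.filter_low_signal(
        fg.feature_ids, fg.values, bg.values,
        max_fraction=config.low_signal_max_fraction,
    )
    kept = fg.subset_features(report.kept)
    normalized = preprocess.vsn_like_normalize(kept)
    collapsed = preprocess.collapse_replicates(normalized)
    return collapsed, report


# ---------------------------------------------------------------------------
# full run


def run_bundle(
    bundle: SyntheticBundle,
    config: PipelineConfig,
    gene_sets: list[GeneSetSelection] | None = None,
) -> dict:
    """Run the full analysis on an in-memory bundle; write all outputs.

    Returns the manifest dictionary (also written as manifest.json).
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # --- preprocessing ---------------------------------------------------
    layers: dict[str, ExpressionMatrix] = {}
    reports = {}
    layers["mRNA"], reports["mRNA"] = preprocess_two_color(
        bundle.mrna_arrays, config, use_normexp=False
    )
    layers["protein"], reports["protein"] = preprocess_two_color(
        bundle.protein_arrays, config, use_normexp=True
    )
    layers["miRNA"], reports["miRNA"] = preprocess_single_channel(
        bundle.mirna_fg, bundle.mirna_bg, config
    )
    for layer, matrix in layers.items():
        write_expression_table(
            matrix, os.path.join(out, f"normalized_{layer}.tsv")
        )
        manifest["stages"][f"preprocess_{layer}"] = {
            "features_in": len(reports[layer].kept) + len(reports[layer].removed),
            "features_kept": len(reports[layer].kept),
            "samples": matrix.n_samples,
        }

    # --- differential expression -----------------------------------------
    thresholds = config.thresholds()
    results: dict[str, DifferentialResults] = {}
    for layer, matrix in layers.items():
        res = ModeratedTTest(matrix).fit(thresholds=thresholds[layer])
        res.save(os.path.join(out, f"differential_{layer}.tsv"))
        results[layer] = res
        manifest["stages"][f"diffexpr_{layer}"] = {
            "tested": int(res.frame["tested"].sum()),
            "up": res.n_up(),
            "down": res.n_down(),
        }

    # --- enrichment -------------------------------------------------------
    if bundle.catalog_rows:
        from .io_tables import AnnotationCatalog

        cats: dict[str, tuple[str, set[str]]] = {}
        for cid, name, gene in bundle.catalog_rows:
            cats.setdefault(cid, (name, set()))[1].add(gene)
        catalog = AnnotationCatalog(cats)
        universe = set(results["mRNA"].frame.index)
        for direction in ("up", "down"):
            selected = set(
                results["mRNA"].frame.index[results["mRNA"].frame["status"] == direction]
            )
            rows = enrichment.enrich(catalog, selected, universe, direction)
            enrichment.enrichment_table(rows).to_csv(
                os.path.join(out, f"enrichment_mRNA_{direction}.tsv"),
                sep="\t", index=False, na_rep="NA", float_format="%.17g",
            )
            manifest["stages"][f"enrichment_{direction}"] = {"categories": len(rows)}

    # --- integration ------------------------------------------------------
    links = integrate.pair_links(
        results["miRNA"], results["mRNA"], bundle.target_map,
        mode=config.pairing_mode, target_layer="mRNA", score_max=config.score_max,
    )
    pd.DataFrame([l.__dict__ for l in links]).to_csv(
        os.path.join(out, "pair_links.tsv"), sep="\t", index=False
    )
    core = integrate.mrna_protein_core(results["mRNA"], results["protein"])
    pd.DataFrame([c.__dict__ for c in core]).to_csv(
        os.path.join(out, "core_genes.tsv"), sep="\t", index=False
    )
    loops = integrate.enumerate_loops(
        results["miRNA"], results["mRNA"], results["protein"],
        bundle.target_map, score_max=config.score_max,
    )
    integrate.loop_table(loops).to_csv(
        os.path.join(out, "loops.tsv"), sep="\t", index=False
    )
    counts = integrate.loop_type_counts(loops)
    manifest["stages"]["integration"] = {
        "pair_links": len(links),
        "anti_links": sum(1 for l in links if l.relation == "anti"),
        "core_genes": len(core),
        "loops": counts,
    }

    # --- networks ---------------------------------------------------------
    anti = [l for l in links if l.relation == "anti"]
    network = netbuild.build_network(
        anti, bundle.gene_gene_edges,
        de_genes=results["mRNA"], de_proteins=results["protein"],
        mirna_results=results["miRNA"],
    )
    write_sif(network, os.path.join(out, "post_transcriptional.sif"))
    manifest["stages"]["network"] = {
        "nodes": len(network.nodes),
        "edges": len(network.edges),
    }
    for selection in gene_sets or []:
        sub = netbuild.extract_subnetwork(network, selection)
        slug = "".join(c if c.isalnum() else "_" for c in selection.name)
        write_sif(sub, os.path.join(out, f"subnetwork_{slug}.sif"))
        manifest["stages"][f"subnetwork_{selection.name}"] = {
            "nodes": len(sub.nodes),
            "edges": len(sub.edges),
        }

    manifest["loop_counts"] = counts
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run(config: PipelineConfig) -> dict:
    """Load a fixture directory and run the full analysis."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    required = os.path.join(config.input_dir, "target_map.tsv")
    if not os.path.isfile(required):
        raise FileNotFoundError(f"integration stage input missing: {required}")
    bundle = read_fixture(config.input_dir)
    gene_sets_path = os.path.join(config.input_dir, "gene_sets.tsv")
    gene_sets = (
        netbuild.read_gene_sets(gene_sets_path)
        if os.path.isfile(gene_sets_path)
        else None
    )
    return run_bundle(bundle, config, gene_sets=gene_sets)


def demo(seed: int = 1, out_dir: str = "triomics_demo", sim: SimConfig | None = None) -> dict:
    """Generate a synthetic study and analyse it in one call."""
    sim = sim or SimConfig(seed=seed)
    bundle = generate(sim)
    fixture_dir = os.path.join(out_dir, "fixture")
    write_fixture(bundle, fixture_dir, overwrite=True)
    config = PipelineConfig(
        input_dir=fixture_dir, output_dir=os.path.join(out_dir, "results"), seed=seed
    )
    manifest = run(config)
    manifest["recovery"] = recovery_report(
        bundle, os.path.join(out_dir, "results", "loops.tsv")
    )
    with open(os.path.join(out_dir, "results", "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def recovery_report(bundle: SyntheticBundle, loops_path: str) -> dict:
    """Compare recovered loops with the planted truth.

    Reports the fraction of planted loops recovered with the correct
    type, the fraction of reported loops that were never planted, and
    per-type recovered counts.
    """
    df = pd.read_csv(loops_path, sep="\t")
    recovered = {
        (str(r.mirna_id), str(r.gene_id)): str(r.loop_type)
        for r in df.itertuples(index=False)
    }
    planted = {
        (l.mirna_id, l.gene_id): l.loop_type for l in bundle.truth.planted_loops
    }
    n_correct = sum(
        1 for pair, t in planted.items() if recovered.get(pair) == t
    )
    spurious = [pair for pair in recovered if pair not in planted]
    counts = {t: 0 for t in ("A", "B", "C", "unclassified")}
    for t in recovered.values():
        counts[t] += 1
    planted_counts = {t: 0 for t in ("A", "B", "C", "unclassified")}
    for t in planted.values():
        planted_counts[t] += 1
    return {
        "planted": len(planted),
        "recovered_correct_type": n_correct,
        "recovery_rate": n_correct / len(planted) if planted else float("nan"),
        "reported": len(recovered),
        "spurious": len(spurious),
        "spurious_rate": len(spurious) / len(recovered) if recovered else 0.0,
        "recovered_counts": counts,
        "planted_counts": planted_counts,
    }
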
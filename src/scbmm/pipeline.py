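"""End-to-end orchestration: QC -> curation -> DE -> networks -> velocity.

`run_pipeline` drives the whole chain on a list of per-timepoint count
matrices (read from bundles or freshly simulated), writes every stage's
artifacts under an output directory, and — when planted truth is
available — scores recovery of DE genes, ligand-receptor channels and
per-gene gamma into ``report.json``.  All parameters live in
:class:`PipelineConfig`, which is snapshotted to ``config.json`` so each
run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import core_io
from .core_io import CountMatrix, lognormalize
from .annotation_curation import CurationLog, drop_small_types, drop_discordant
from .communication_network import (
    LRDatabase,
    build_links,
    delta_network,
    expressed_genes_by_type,
    network_from_links,
)
from .differential_expression import count_de_by_direction, de_by_timepoint
from .enrichment import GeneSetCollection, enrich_min_genes_gate, hypergeom_enrich
from .velocity import estimate_velocity

__all__ = ["PipelineConfig", "concat_timepoints", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable knob of the chain, with the standard defaults."""

    # QC / normalization
    gene_min_cells: int = 3
    mito_nmads: float = 3.0
    lognorm_scale: float = 10_000.0
    # curation
    min_cells_per_sample: int = 5
    small_type_policy: str = "any"
    min_label_frac_in_cluster: float = 0.10
    # differential expression
    de_min_cells: int = 5
    de_min_pct: float = 0.10
    de_min_fold: float = 1.5
    de_alpha: float = 0.05
    reference_timepoint: str = "D0"
    # conserved markers
    marker_min_pct: float = 0.75
    marker_min_pct_diff: float = 0.50
    marker_min_fold: float = 2.0
    # communication networks
    lr_threshold: float = 0.20
    # enrichment
    enrichment_min_genes: int = 20
    # velocity
    velocity_k: int = 25
    velocity_n_pcs: int = 20
    velocity_extreme_quantile: float = 0.02
    # misc
    seed: int = 0

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def concat_timepoints(matrices: list[CountMatrix]) -> CountMatrix:
    """Stack per-timepoint matrices on their shared gene set.

    Genes are intersected (order of the first matrix); cells are
    concatenated.  Raw-count layers (spliced/unspliced) are carried
    through when every matrix has them.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    shared = matrices[0].gene_ids
    for m in matrices[1:]:
        shared = shared[shared.isin(m.gene_ids)]
    subs = [m.subset(genes=m.gene_ids.get_indexer(shared)) for m in matrices]

    counts = sp.vstack([m.counts for m in subs]).tocsr()
    cell_meta = pd.concat([m.cell_meta for m in subs])
    # re-establish ordered timepoint categories across samples
    if cell_meta["timepoint"].notna().any():
        cats = core_io._timepoint_categories(cell_meta["timepoint"].astype(str))
        cell_meta["timepoint"] = pd.Categorical(
            cell_meta["timepoint"].astype(str), categories=cats, ordered=True
        )
    layers = {}
    common_layers = set(subs[0].layers)
    for m in subs[1:]:
        common_layers &= set(m.layers)
    for lname in common_layers:
        layers[lname] = sp.vstack([m.layers[lname] for m in subs]).tocsr()

    return CountMatrix(
        counts=counts,
        cell_meta=cell_meta,
        gene_meta=subs[0].gene_meta.copy(),
        layers=layers,
    )


def _score_de_recovery(de_results: dict, truth, all_genes, alpha_genes_tested) -> dict:
    """Recall of planted DE genes and count of null-gene false positives."""
    truth_df = truth.de_truth
    if truth_df.empty:
        return {}
    planted = set(zip(truth_df["cell_type"], truth_df["timepoint"], truth_df["gene"]))
    planted_slots = set(zip(truth_df["cell_type"], truth_df["timepoint"]))
    # ligand/receptor channel genes are switched on/off by design, so a
    # significant call on them is planted signal, not a false positive
    channel_genes = set(truth.active_channels["ligand"]) | set(
        truth.active_channels["receptor"]
    )

    hits = 0
    false_pos = 0
    for (ct, tp), de in de_results.items():
        sig = set(de.significant_rows()["gene"]) if de.reason is None else set()
        for g in sig:
            if (ct, tp, g) in planted:
                hits += 1
            elif (ct, tp) in planted_slots and g not in channel_genes:
                false_pos += 1
    recall = hits / len(planted) if planted else float("nan")
    return {
        "n_planted": len(planted),
        "n_recovered": hits,
        "recall": recall,
        "n_false_positives_in_planted_slots": false_pos,
    }


def _score_channel_recovery(link_tables: dict, truth, lrdb: LRDatabase) -> dict:
    """Sensitivity on planted active channels; link rate on inactive ones."""
    active = set(
        map(
            tuple,
            truth.active_channels[
                ["ligand", "receptor", "sender", "receiver", "timepoint"]
            ].itertuples(index=False, name=None),
        )
    )
    if not active:
        return {}
    observed = set()
    universe = set()
    types_by_tp: dict[str, set[str]] = {}
    for tp, lt in link_tables.items():
        for row in lt.links.itertuples(index=False):
            observed.add(
                (row.ligand, row.receptor, row.sender_type, row.receiver_type, row.timepoint)
            )
        senders = set(lt.links["sender_type"]) | set(lt.links["receiver_type"])
        types_by_tp[tp] = senders

    # candidate channel space: every (pair, sender, receiver, timepoint)
    types_all = sorted(set().union(*types_by_tp.values())) if types_by_tp else []
    for tp in link_tables:
        for _, pair in lrdb.pairs.iterrows():
            for s in types_all:
                for r in types_all:
                    universe.add((pair["ligand"], pair["receptor"], s, r, tp))

    inactive = universe - active
    tp_hits = len(active & observed)
    fp = len(inactive & observed)
    return {
        "n_active_channels": len(active),
        "sensitivity": tp_hits / len(active),
        "n_inactive_channels": len(inactive),
        "inactive_link_rate": fp / len(inactive) if inactive else 0.0,
    }


def _score_gamma_recovery(fit, truth) -> dict:
    if not truth.gamma_truth:
        return {}
    rel_errs = []
    for g, g_true in truth.gamma_truth.items():
        if g in fit.gamma and g_true > 0:
            rel_errs.append(abs(fit.gamma[g] - g_true) / g_true)
    if not rel_errs:
        return {"n_recovered": 0}
    return {
        "n_recovered": len(rel_errs),
        "n_planted": len(truth.gamma_truth),
        "median_relative_error": float(np.median(rel_errs)),
    }


def run_pipeline(
    matrices: list[CountMatrix],
    lrdb: LRDatabase | None,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    truth=None,
    collection: GeneSetCollection | None = None,
) -> dict:
    """Run QC, curation, DE, networks, enrichment and velocity; write artifacts.

    Returns the report dict (also written to ``report.json``).  Outputs
    are deterministic given (matrices, config): no timestamps are
    recorded.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "config.json")

    log_lines: list[dict] = []

    def log(event: str, **kv) -> None:
        log_lines.append({"event": event, **kv})

    # ---- per-sample QC --------------------------------------------------
    # The gene filter is evaluated per sample (per-sample detected-gene
    # counts are logged), but a gene is retained downstream when it
    # passes in at least one sample, so the merged matrix is the union
    # of per-sample gene sets rather than their intersection.
    qc_matrices = []
    kept_genes: set[str] = set()
    for cm in matrices:
        tp = str(cm.cell_meta["timepoint"].iloc[0])
        cm1, rep_g = core_io.filter_genes_min_cells(cm, config.gene_min_cells)
        kept_genes.update(cm1.gene_ids)
        cm2, rep_m = core_io.filter_cells_mito(cm, config.mito_nmads)
        log("qc", timepoint=tp, cells_before=cm.n_cells, cells_after=cm2.n_cells,
            genes_before=cm.n_genes, genes_after_this_sample=cm1.n_genes,
            mito_threshold=rep_m.mito_threshold)
        qc_matrices.append(cm2)
    qc_matrices = [
        m.subset(genes=np.asarray(m.gene_ids.isin(kept_genes))) for m in qc_matrices
    ]

    combined = concat_timepoints(qc_matrices)
    combined = lognormalize(combined, config.lognorm_scale)

    # ---- curation -------------------------------------------------------
    curation = CurationLog()
    n_before = combined.n_cells
    combined, curation = drop_small_types(
        combined, config.min_cells_per_sample, config.small_type_policy, curation
    )
    combined, curation = drop_discordant(
        combined, config.min_label_frac_in_cluster, curation
    )
    log("curation", cells_before=n_before, cells_after=combined.n_cells,
        n_actions=len(curation.actions))
    curation.to_json(outdir / "curation_log.json")

    timepoints = [str(t) for t in combined.cell_meta["timepoint"].cat.categories]
    cell_types = sorted(
        str(t) for t in combined.cell_meta["cell_type"].dropna().unique()
    )

    # ---- differential expression ---------------------------------------
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    de_results: dict[tuple[str, str], object] = {}
    de_counts_rows = []
    for ct in cell_types:
        for tp in timepoints:
            if tp == config.reference_timepoint:
                continue
            de = de_by_timepoint(
                combined, ct, tp,
                reference_timepoint=config.reference_timepoint,
                min_cells=config.de_min_cells,
                min_pct=config.de_min_pct,
                min_fold=config.de_min_fold,
                alpha=config.de_alpha,
            )
            de_results[(ct, tp)] = de
            safe_ct = ct.replace("/", "_").replace(" ", "_")
            de.write(de_dir / f"de_{safe_ct}_{tp}.tsv")
            counts = count_de_by_direction(de)
            de_counts_rows.append(
                {"cell_type": ct, "timepoint": tp, **counts,
                 "skipped": de.reason or ""}
            )
            log("de", cell_type=ct, timepoint=tp, **counts, skipped=de.reason or "")
    pd.DataFrame(de_counts_rows).to_csv(outdir / "de_counts.tsv", sep="\t", index=False)

    # ---- communication networks ----------------------------------------
    report: dict = {}
    networks = {}
    link_tables = {}
    if lrdb is not None:
        net_dir = outdir / "networks"
        net_dir.mkdir(exist_ok=True)
        expressed_by_tp = {}
        for tp in timepoints:
            expressed = expressed_genes_by_type(combined, tp, config.lr_threshold)
            expressed_by_tp[tp] = expressed
            links = build_links(expressed, lrdb, tp, gene_universe=combined.gene_ids)
            net = network_from_links(links, nodes=sorted(expressed))
            link_tables[tp] = links
            networks[tp] = net
            net.write(net_dir / f"network_{tp}.tsv")
            links.write(net_dir / f"links_{tp}.tsv")
            log("commnet", timepoint=tp, n_links=len(links),
                coverage=links.coverage.get("coverage"))
        ref_tp = config.reference_timepoint
        if ref_tp in networks:
            delta_rows = []
            for tp in timepoints:
                if tp == ref_tp:
                    continue
                for (s, r), d in sorted(delta_network(networks[tp], networks[ref_tp]).items()):
                    delta_rows.append(
                        {"timepoint": tp, "sender": s, "receiver": r, "delta": d}
                    )
            pd.DataFrame(
                delta_rows, columns=["timepoint", "sender", "receiver", "delta"]
            ).to_csv(net_dir / "delta_vs_reference.tsv", sep="\t", index=False)

        # ---- enrichment of DE sets and LR lists -------------------------
        if collection is not None:
            enr_dir = outdir / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            universe = set(combined.gene_ids)
            for (ct, tp), de in sorted(de_results.items()):
                genes = list(de.significant_rows()["gene"]) if de.reason is None else []
                if not enrich_min_genes_gate(genes, config.enrichment_min_genes):
                    continue
                table = hypergeom_enrich(genes, collection, universe)
                safe_ct = ct.replace("/", "_").replace(" ", "_")
                table.write(enr_dir / f"enrich_de_{safe_ct}_{tp}.tsv")

    # ---- velocity -------------------------------------------------------
    if "spliced" in combined.layers and "unspliced" in combined.layers:
        fit = estimate_velocity(
            combined,
            k=min(config.velocity_k, combined.n_cells - 1),
            n_pcs=config.velocity_n_pcs,
            extreme_quantile=config.velocity_extreme_quantile,
        )
        fit.write_gamma(outdir / "gamma.tsv")
        fit.write_magnitudes(outdir / "velocity_magnitude.tsv")
        log("velocity", n_fitted_genes=len(fit.fitted_genes))
    else:
        fit = None

    # ---- recovery scoring ----------------------------------------------
    if truth is not None:
        report["de_recovery"] = _score_de_recovery(
            de_results, truth, combined.gene_ids, None
        )
        if lrdb is not None:
            report["channel_recovery"] = _score_channel_recovery(
                link_tables, truth, lrdb
            )
        if fit is not None:
            report["gamma_recovery"] = _score_gamma_recovery(fit, truth)

    report["n_cells_final"] = combined.n_cells
    report["n_genes_final"] = combined.n_genes
    report["cell_types"] = cell_types
    report["timepoints"] = timepoints

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    with open(outdir / "log.jsonl", "w") as fh:
        for line in log_lines:
            fh.write(json.dumps(line, sort_keys=True, default=str) + "\n")
    return report
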
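"""End-to-end orchestration: simulate/load → preprocess → XPN → DE →
enrichment → PPI/hubs → crosstalk, with every stage artifact on disk.

A single :class:`RunConfig` (serialisable to YAML) carries every threshold
and seed, so one file reproduces a whole run. The machine-readable summary
(``summary.json``) is written with sorted keys and no timestamps: rerunning
the same config and seed yields a byte-identical file. Timestamps go to the
plain-text log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import networks
from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    read_sample_annotation,
    write_sample_annotation,
)
from .crosstalk import build_pathway_network
from .diffexpr import call_differential
from .enrichment import enrich
from .preprocess import intersect_gene_universe, quantile_normalize
from .simulate import (
    SimulationConfig,
    generate_pathways_and_ppi,
    generate_two_platform_dataset,
)
from .xpn import XpnConfig, cross_platform_discrepancy, xpn_normalize

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_contrasts"]

logger = logging.getLogger("crosspath")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulation`` is set (synthetic run) or the four input paths
    are (matrices A/B, sample annotation, gene sets, PPI edges). Thresholds
    default to the conventional choices: raw p 0.05 and BH 0.05 for the DE
    call, BH 0.1 for selecting the PPI gene list, 0.1 for enrichment and
    0.05 for crosstalk.
    """

    output_dir: str = "crosspath_run"
    seed: int = 0
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    matrix_a_path: str | None = None
    matrix_b_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    ppi_edges_path: str | None = None
    xpn: XpnConfig = field(default_factory=XpnConfig)
    de_raw_threshold: float = 0.05
    de_bh_threshold: float = 0.05
    ppi_gene_bh_threshold: float = 0.1
    enrichment_threshold: float = 0.1
    enrichment_column: str = "p"
    crosstalk_threshold: float = 0.05
    welch: bool = False

    def __post_init__(self) -> None:
        for name in ("de_raw_threshold", "de_bh_threshold",
                     "ppi_gene_bh_threshold", "enrichment_threshold",
                     "crosstalk_threshold"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.simulation is None:
            needed = [self.matrix_a_path, self.matrix_b_path,
                      self.annotation_path, self.gene_sets_path,
                      self.ppi_edges_path]
            if any(p is None for p in needed):
                raise ValueError("without a simulation block, all five input "
                                 "paths must be provided")

    # -- YAML round-trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = payload["simulation"]
            sim["pathway_size_range"] = list(sim["pathway_size_range"])
            sim["baseline_range"] = list(sim["baseline_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = payload.pop("simulation", None)
        xpn_cfg = payload.pop("xpn", None)
        config = cls(
            simulation=None if sim is None else SimulationConfig(
                **{**sim,
                   "pathway_size_range": tuple(sim["pathway_size_range"]),
                   "baseline_range": tuple(sim["baseline_range"])}
            ) if isinstance(sim, dict) else sim,
            xpn=XpnConfig(**xpn_cfg) if isinstance(xpn_cfg, dict) else (xpn_cfg or XpnConfig()),
            **payload,
        )
        return config


def summarize_contrasts(
    de_tables: dict[str, pd.DataFrame], flag_column: str = "significant_raw"
) -> pd.DataFrame:
    """Per-contrast significant counts: total, up, down (up + down = total).

    Direction among flagged genes comes from the fold change (fc > 1 up,
    fc < 1 down); a flagged gene with fc exactly 1 counts as neither, in
    which case up + down may fall short of total — with continuous data
    this does not occur.
    """
    if not de_tables:
        raise ValueError("need at least one contrast")
    rows = []
    for contrast, table in de_tables.items():
        flagged = table.loc[table[flag_column].astype(bool)]
        up = int((flagged["fc"] > 1).sum())
        down = int((flagged["fc"] < 1).sum())
        rows.append((contrast, int(len(flagged)), up, down))
    return pd.DataFrame(rows, columns=["contrast", "total", "up", "down"])


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return decorator


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the machine-readable summary dict.

    Writes, under ``config.output_dir``: the input artifacts (simulated or
    copies of the loaded ones), normalized matrices, the XPN model, DE
    tables per contrast, enrichment tables, the PPI subnetwork (SIF +
    GraphML) with hubs, crosstalk pairs tables and pathway networks, the
    DE-overlay concordance summary, a parameter dump (``params.yaml``), a
    log file and ``summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    config.to_yaml(out / "params.yaml")
    summary: dict = {"seed": config.seed, "stages": []}

    # -- inputs ----------------------------------------------------------
    truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)

        @_stage("simulate")
        def _simulate():
            mat_a, mat_b, annotation, tr = generate_two_platform_dataset(sim)
            sets, ppi = generate_pathways_and_ppi(sim, tr)
            return mat_a, mat_b, annotation, tr, sets, ppi

        matrix_a, matrix_b, annotation, truth, gene_sets, ppi = _simulate()
        truth.to_json(out / "truth.json")
    else:
        @_stage("load")
        def _load():
            mat_a = ExpressionMatrix.from_tsv(config.matrix_a_path, platform_id="A")
            mat_b = ExpressionMatrix.from_tsv(config.matrix_b_path, platform_id="B")
            annotation = read_sample_annotation(config.annotation_path)
            sets = GeneSetCollection.from_gmt(config.gene_sets_path)
            ppi = InteractionNetwork.from_tsv(config.ppi_edges_path)
            return mat_a, mat_b, annotation, sets, ppi

        matrix_a, matrix_b, annotation, gene_sets, ppi = _load()

    write_sample_annotation(annotation, out / "annotation.tsv")
    gene_sets.to_gmt(out / "gene_sets.gmt")
    ppi.to_tsv(out / "ppi_edges.tsv")
    matrix_a.to_tsv(out / "matrix_a_raw.tsv")
    matrix_b.to_tsv(out / "matrix_b_raw.tsv")

    # -- preprocess ------------------------------------------------------
    @_stage("preprocess")
    def _preprocess():
        qa = quantile_normalize(matrix_a)
        qb = quantile_normalize(matrix_b)
        return intersect_gene_universe(qa, qb)

    norm_a, norm_b = _preprocess()
    summary["n_common_genes"] = len(norm_a.gene_ids)

    # -- cross-platform normalization ------------------------------------
    @_stage("xpn")
    def _xpn():
        cfg = dataclasses.replace(config.xpn, seed=config.seed)
        _, pre_mean = cross_platform_discrepancy(norm_a, norm_b)
        xa, xb, model = xpn_normalize(norm_a, norm_b, cfg)
        _, post_mean = cross_platform_discrepancy(xa, xb)
        return xa, xb, model, pre_mean, post_mean

    xpn_a, xpn_b, xpn_model, pre_disc, post_disc = _xpn()
    xpn_a.to_tsv(out / "matrix_a_normalized.tsv")
    xpn_b.to_tsv(out / "matrix_b_normalized.tsv")
    xpn_model.to_json(out / "xpn_model.json")
    summary["xpn_discrepancy_before"] = round(pre_disc, 10)
    summary["xpn_discrepancy_after"] = round(post_disc, 10)

    # -- differential expression per platform contrast -------------------
    @_stage("diffexpr")
    def _de():
        tables = {}
        for label, matrix in (("A", xpn_a), ("B", xpn_b)):
            ann = annotation[annotation["platform"] == label]
            tables[f"tumor_vs_normal_{label}"] = call_differential(
                matrix, ann,
                raw_threshold=config.de_raw_threshold,
                bh_threshold=config.de_bh_threshold,
                welch=config.welch,
            )
        return tables

    de_tables = _de()
    for contrast, table in de_tables.items():
        table.to_csv(out / f"de_{contrast}.tsv", sep="\t", index=False,
                     float_format="%.6g")
    contrast_summary = summarize_contrasts(de_tables, "significant_raw")
    contrast_summary_bh = summarize_contrasts(de_tables, "significant_bh")
    contrast_summary.to_csv(out / "contrast_summary_raw.tsv", sep="\t", index=False)
    contrast_summary_bh.to_csv(out / "contrast_summary_bh.tsv", sep="\t", index=False)
    summary["contrasts_raw"] = contrast_summary.to_dict(orient="records")
    summary["contrasts_bh"] = contrast_summary_bh.to_dict(orient="records")

    universe = set(xpn_a.gene_ids)

    # -- enrichment per contrast -----------------------------------------
    @_stage("enrichment")
    def _enrich():
        tables = {}
        for contrast, de in de_tables.items():
            query = set(de.loc[de["significant_raw"], "gene"]) & universe
            if not query:
                tables[contrast] = pd.DataFrame(
                    columns=["set_name", "overlap", "set_size", "p", "p_bh",
                             "significant"])
                continue
            tables[contrast] = enrich(
                query, gene_sets, universe,
                threshold=config.enrichment_threshold,
                significance_column=config.enrichment_column,
            )
        return tables

    enrich_tables = _enrich()
    summary["enrichment"] = {}
    for contrast, table in enrich_tables.items():
        table.to_csv(out / f"enrichment_{contrast}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        summary["enrichment"][contrast] = {
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
            "top_set": table.iloc[0]["set_name"] if len(table) else None,
        }

    # -- PPI subnetwork and hubs (per contrast) --------------------------
    @_stage("ppi")
    def _ppi():
        results = {}
        for contrast, de in de_tables.items():
            genes = set(de.loc[de["p_bh"] < config.ppi_gene_bh_threshold, "gene"])
            if not genes:
                results[contrast] = (None, [])
                continue
            sub = networks.build_ppi_subnetwork(ppi, genes)
            de_sub = de.copy()
            de_sub["direction"] = de_sub["direction"].where(
                de_sub["p_bh"] < config.ppi_gene_bh_threshold, "none")
            k = min(5, max(1, sub.n_nodes))
            hubs = networks.top_hubs(sub, k, de_table=de_sub) if sub.n_nodes else []
            results[contrast] = (sub, hubs)
        return results

    ppi_results = _ppi()
    summary["ppi"] = {}
    for contrast, (sub, hubs) in ppi_results.items():
        if sub is not None:
            sub.to_sif(out / f"ppi_subnetwork_{contrast}.sif")
            sub.to_graphml(out / f"ppi_subnetwork_{contrast}.graphml")
            hub_df = pd.DataFrame(
                [(h.gene, h.degree, h.direction, h.p_bh, h.tied) for h in hubs],
                columns=["gene", "degree", "direction", "p_bh", "tied"],
            )
            hub_df.to_csv(out / f"hubs_{contrast}.tsv", sep="\t", index=False,
                          float_format="%.6g")
        summary["ppi"][contrast] = {
            "n_nodes": sub.n_nodes if sub is not None else 0,
            "n_edges": sub.n_edges if sub is not None else 0,
            "hubs": [
                {"gene": h.gene, "degree": h.degree, "direction": h.direction}
                for h in hubs
            ],
        }

    # -- DE overlay concordance ------------------------------------------
    @_stage("overlay")
    def _overlay():
        (name_a, de_a), (name_b, de_b) = list(de_tables.items())[:2]
        annotated, concordance = networks.overlay_expression(
            ppi, de_a, de_b, label_a=name_a, label_b=name_b)
        return annotated, concordance

    if len(de_tables) >= 2:
        annotated_net, concordance = _overlay()
        annotated_net.to_graphml(out / "global_network_overlay.graphml")
        concordance.to_csv(out / "overlay_concordance.tsv", sep="\t", index=False)
        summary["overlay"] = {
            row.quantity: int(row.count) for row in concordance.itertuples(index=False)
        }

    # -- pathway crosstalk per contrast ----------------------------------
    @_stage("crosstalk")
    def _crosstalk():
        results = {}
        for contrast, de in de_tables.items():
            degs = set(de.loc[de["significant_raw"], "gene"])
            enriched = enrich_tables[contrast]
            names = list(enriched.loc[enriched["significant"], "set_name"])
            if len(names) < 2 or not degs or ppi.n_edges == 0:
                results[contrast] = None
                continue
            results[contrast] = build_pathway_network(
                ppi, degs, gene_sets.subset(names),
                threshold=config.crosstalk_threshold,
            )
        return results

    crosstalk_results = _crosstalk()
    summary["crosstalk"] = {}
    for contrast, result in crosstalk_results.items():
        if result is None:
            summary["crosstalk"][contrast] = {
                "tested_pairs": 0, "interacting_pairs": 0,
                "description": "no interactions",
            }
            continue
        result.pairs.to_csv(out / f"crosstalk_{contrast}_pairs.tsv", sep="\t",
                            index=False, float_format="%.6g")
        result.network.to_sif(out / f"crosstalk_{contrast}.sif", relation="crosstalk")
        summary["crosstalk"][contrast] = {
            "tested_pairs": int(len(result.pairs)),
            "interacting_pairs": int(result.network.n_edges),
            "description": result.describe(),
        }

    # -- truth-based scoring (synthetic runs only) -----------------------
    if truth is not None:
        scoring = {}
        for contrast, de in de_tables.items():
            called = set(de.loc[de["significant_bh"], "gene"])
            true_de = set(truth.de_genes)
            tp = len(called & true_de)
            fp = len(called - true_de)
            scoring[contrast] = {
                "n_called": len(called),
                "true_positives": tp,
                "false_positives": fp,
                "fdr": round(fp / max(len(called), 1), 6),
                "sensitivity": round(tp / max(len(true_de), 1), 6),
            }
        summary["truth_scoring"] = scoring

    summary["stages"] = ["simulate" if config.simulation else "load",
                         "preprocess", "xpn", "diffexpr", "enrichment",
                         "ppi", "overlay", "crosstalk"]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
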
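"""End-to-end pipeline: reads table + tree -> filtered matrices, stratum
networks, phylogenetic signal, host specificity, carrier communities and
assemblage summaries, all written to an output directory with a manifest
recording every seed and filter parameter."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    carrier_network,
    community_stats,
    filtering,
    phylo_metrics,
    sample_io,
    specificity,
    taxon_network,
)

log = logging.getLogger("micronet")


@dataclasses.dataclass
class PipelineConfig:
    reads: str  # sample x taxon TSV/CSV
    tree: str | None = None  # Newick over the genus catalogue
    distance_matrix: str | None = None  # alternative to tree: square TSV, NJ is run
    replicate_b: str | None = None  # optional second PCR replicate table
    out_dir: str = "results/pipeline"
    percentile: float = 10.0
    iterate_filters: bool = False
    damping: float = 0.85
    resolution: float = 1.0
    seed: int = 0
    carriers: tuple[str, str] = ("tick", "vole")
    biotopes: tuple[str, str] = ("forest", "ecotone")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("carriers", "biotopes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage in order and return the output directory.

    Stages: read (and optionally merge replicates) -> filter -> per-stratum
    genus networks with WD/BNC/CC/PR/communities and the power-law fit ->
    Pagel's lambda of prevalence and of the network indexes -> per-biotope
    host-specificity tables -> per-biotope carrier networks, communities and
    PD summaries -> Sørensen matrix and shared/exclusive accounting.
    Any stage failure aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    for path_attr in ("reads", "tree", "distance_matrix", "replicate_b"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config.{path_attr}: no such file {p!r}")

    # --- sample_io ---------------------------------------------------------
    stage("sample_io")
    matrix = sample_io.read_table(config.reads)
    if config.replicate_b:
        rep_b = sample_io.read_table(config.replicate_b)
        matrix = sample_io.merge_replicates(matrix, rep_b)

    if config.tree:
        tree = phylo_metrics.parse_newick(Path(config.tree).read_text())
    elif config.distance_matrix:
        dist = phylo_metrics.read_distance_matrix(config.distance_matrix)
        tree = phylo_metrics.neighbor_joining(dist)
    else:
        raise ValueError("config must provide a tree or a distance_matrix")

    # --- filtering ---------------------------------------------------------
    stage("filtering")
    filtered, report = filtering.apply_filters(
        matrix, percentile=config.percentile, iterate=config.iterate_filters
    )
    report.to_json(out / "filter_report.json")
    sample_io.write_table(filtered, out / "filtered_reads.tsv")
    pres = filtered.presence()

    # --- taxon networks per stratum ---------------------------------------
    stage("taxon_network")
    tip_set = set(phylo_metrics.tip_labels(tree))
    networks: dict[tuple[str, str], taxon_network.CooccurrenceNetwork] = {}
    net_rows = []
    lambda_rows = []
    for carrier in config.carriers:
        for biotope in config.biotopes:
            sub = filtered.subset(carrier=carrier, biotope=biotope)
            if not sub.sample_ids:
                continue
            net = taxon_network.build_network(sub.presence(), (carrier, biotope))
            metrics = taxon_network.annotate(
                net, damping=config.damping, resolution=config.resolution, seed=config.seed
            )
            networks[(carrier, biotope)] = net
            name = f"{carrier}_{biotope}"
            metrics.to_csv(out / f"node_metrics_{name}.tsv", sep="\t")
            taxon_network.export_graph(net, out / f"network_{name}.gexf")
            wd = metrics["WD"][metrics["WD"] > 0]
            try:
                pl = taxon_network.fit_power_law(wd)
                gamma, ks = pl.gamma, pl.ks_distance
            except ValueError:
                gamma = ks = float("nan")
            net_rows.append(
                {
                    "stratum": name,
                    "n_nodes": len(net.nodes),
                    "n_links": net.n_links,
                    "n_communities": int(metrics["community"].nunique()),
                    "powerlaw_gamma": gamma,
                    "powerlaw_ks": ks,
                }
            )

            # --- phylo_metrics: lambda of prevalence and of the indexes ----
            prev = phylo_metrics.prevalence(filtered, carrier=carrier, biotope=biotope)
            traits = {"prevalence": {g: v for g, v in prev.items() if v > 0}}
            for index_name in ("BNC", "CC", "PR"):
                traits[index_name] = metrics[index_name].to_dict()
            for trait_name, values in traits.items():
                usable = {g: v for g, v in values.items() if g in tip_set}
                try:
                    fit = phylo_metrics.pagels_lambda(tree, usable)
                    lam, ident = fit.lambda_hat, fit.identifiable
                except ValueError:
                    lam, ident = float("nan"), False
                lambda_rows.append(
                    {"stratum": name, "trait": trait_name, "lambda": lam, "identifiable": ident}
                )
    pd.DataFrame(net_rows).to_csv(out / "network_summary.tsv", sep="\t", index=False)
    stage("phylo_metrics")
    pd.DataFrame(lambda_rows).to_csv(out / "pagels_lambda.tsv", sep="\t", index=False)

    # --- specificity per biotope (pooled-biotope network for WD) ----------
    stage("specificity")
    for biotope in config.biotopes:
        sub = filtered.subset(biotope=biotope)
        if not sub.sample_ids:
            continue
        pooled_net = taxon_network.build_network(sub.presence(), (None, biotope))
        table = specificity.specificity_table(filtered, pooled_net, biotope)
        table.to_csv(out / f"specificity_{biotope}.tsv", sep="\t", index=False)

    # --- carrier networks and community summaries per biotope -------------
    stage("carrier_network")
    conc_report = {}
    for biotope in config.biotopes:
        sub = filtered.subset(biotope=biotope)
        if len(sub.sample_ids) < 2:
            continue
        cnet = carrier_network.build_carrier_network(
            sub.presence(), sub.meta["carrier"], biotope=biotope
        )
        carrier_network.detect_carrier_communities(cnet, seed=config.seed, resolution=config.resolution)
        carrier_network.export_graph(cnet, out / f"carrier_network_{biotope}.gexf")
        pd.Series(cnet.communities, name="community").rename_axis("sample_id").to_csv(
            out / f"carrier_communities_{biotope}.tsv", sep="\t"
        )
        summaries = community_stats.summarize_communities(cnet, sub.presence(), tree)
        community_stats.summaries_to_frame(summaries).to_csv(
            out / f"community_summary_{biotope}.tsv", sep="\t", index=False
        )
        for carrier in config.carriers:
            mine = [s for s in summaries if s.carrier == carrier]
            if len(mine) >= 2:
                conc_report[f"{carrier}_{biotope}"] = community_stats.pd_concentration(mine)

    # --- community_stats ---------------------------------------------------
    stage("community_stats")
    community_stats.sorensen_matrix(filtered).to_csv(out / "sorensen.tsv", sep="\t")
    shared = community_stats.shared_exclusive(filtered)
    report_json = {
        "shared_exclusive": shared,
        "pd_concentration": conc_report,
        "network_summary": net_rows,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2, default=float) + "\n")

    manifest["n_samples"] = len(filtered.sample_ids)
    manifest["n_taxa"] = len(filtered.taxa)
    manifest["networks"] = [f"{c}_{b}" for c, b in networks]
    manifest["numpy_version"] = np.__version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out
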
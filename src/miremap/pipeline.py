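"""End-to-end orchestration: synthetic simulate -> quantify -> DE calling ->
interaction DB -> network -> stats -> enrichment, plus the packaged-fixture
analysis path and a human-readable report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import de_calling, enrichment, interaction_db, network_builder, network_stats
from . import synthetic_data as synth
from .de_calling import DEConfig
from .exceptions import MiremapError
from .interaction_db import PromoterConfig
from .smallrna_quant import QuantConfig

log = logging.getLogger("miremap")


@dataclass
class PipelineConfig:
    outdir: Path = Path("miremap_out")
    seed: int = 0
    alpha: float = 0.05
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    de: DEConfig = field(default_factory=DEConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    quantify_reads: bool = False  # regenerate reads and recount (slow at depth >~1e5)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"outdir", "seed", "alpha", "quantify_reads"}
        kwargs: dict[str, Any] = {k: v for k, v in raw.items() if k in known}
        if "outdir" in kwargs:
            kwargs["outdir"] = Path(kwargs["outdir"])
        if "synthetic" in raw:
            kwargs["synthetic"] = synth.SyntheticConfig(**{
                k: (tuple(map(tuple, v)) if k == "hub_spec"
                    else tuple(v) if isinstance(v, list) else v)
                for k, v in raw["synthetic"].items()
            })
        if "de" in raw:
            kwargs["de"] = DEConfig(**raw["de"])
        if "quant" in raw:
            kwargs["quant"] = QuantConfig(**raw["quant"])
        if "promoter" in raw:
            kwargs["promoter"] = PromoterConfig(**raw["promoter"])
        cfg = cls(**kwargs)
        if "seed" in raw and "synthetic" not in raw:
            cfg.synthetic.seed = cfg.seed
        return cfg


def _stage(name: str, t0: float) -> float:
    t1 = time.monotonic()
    log.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage on a synthetic instance; returns the summary dict.

    Artifacts (tables, GraphML, summary JSON) land under ``cfg.outdir``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = cfg.synthetic
    t0 = time.monotonic()

    # --- simulate -----------------------------------------------------------
    loci = synth.generate_mirna_annotation(scfg)
    truth = synth.generate_truth(scfg, loci)
    ct_table, count_table = synth.generate_expression(scfg, truth)
    gene_fc = synth.generate_gene_fold_changes(scfg, truth)
    tf_table, peaks, mti_table = synth.generate_interactions(scfg, truth, loci)
    synth.write_gff3(loci, out / "mirna_loci.gff3")
    ct_table.to_csv(out / "openarray_ct.tsv", sep="\t", index=False)
    count_table.to_csv(out / "seq_counts.tsv", sep="\t", index=False)
    gene_fc.to_csv(out / "gene_fc.tsv", sep="\t", index=False)
    tf_table.to_csv(out / "tf_mirna.tsv", sep="\t", index=False)
    synth.write_bed(peaks, out / "peaks.bed")
    mti_table.to_csv(out / "mti.tsv", sep="\t", index=False)
    truth.write_manifest(out / "truth.json")
    t0 = _stage("simulate", t0)

    # --- quantify (optional regeneration of reads; else use the count table)
    if cfg.quantify_reads:
        from .smallrna_quant import match_and_count, ReadRecord

        mature = synth.generate_mature_sequences(scfg)
        counts = {r.mirna: r.count for r in count_table.itertuples() if r.sample == "KO"}
        reads = synth.generate_reads(counts, mature, scfg)
        records = [ReadRecord(*r) for r in reads]
        report = match_and_count(records, mature, cfg=cfg.quant)
        (out / "quant_report.json").write_text(
            json.dumps({k: v for k, v in report.counts.items()}, sort_keys=True)
        )
        t0 = _stage("quantify", t0)

    # --- DE calling ---------------------------------------------------------
    array_fc = de_calling.normalize_openarray(ct_table, cfg.de)
    seq_fc = de_calling.seq_fold_changes(count_table)
    calls_array = de_calling.call_de(array_fc, cfg.de, platform="openarray")
    calls_seq = de_calling.call_de(seq_fc, cfg.de, platform="seq")
    gene_calls = de_calling.call_de_genes(gene_fc, cfg.de, platform="microarray",
                                          id_col="gene")
    gene_calls = [
        de_calling.DECall(c.molecule.upper(), c.fc, c.direction, c.platform)
        for c in gene_calls
    ]
    de_calling.de_calls_frame(calls_seq).to_csv(out / "de_seq.tsv", sep="\t", index=False)
    de_calling.de_calls_frame(calls_array).to_csv(out / "de_array.tsv", sep="\t", index=False)
    t0 = _stage("decall", t0)

    # --- intersect ----------------------------------------------------------
    loci_by_name = {l.name: l for l in loci}
    demirs, conflicts = de_calling.intersect_platforms(calls_seq, calls_array, loci_by_name)
    t0 = _stage("intersect", t0)

    # --- interaction DB -----------------------------------------------------
    curated_tf = interaction_db.read_tf_mirna_tsv(out / "tf_mirna.tsv")
    chip_tf = interaction_db.infer_tf_mirna_from_peaks(peaks, loci, cfg.promoter)
    mti_records = interaction_db.read_mti_tsv(out / "mti.tsv")
    merged = interaction_db.merge_sources(curated_tf + chip_tf + mti_records)
    interaction_db.write_interactions_tsv(merged, out / "interactions_merged.tsv")
    t0 = _stage("build-db", t0)

    # --- networks -----------------------------------------------------------
    tf_net = network_builder.build_tf_mirna_network(merged, demirs)
    mti_net = network_builder.build_mti_network(merged, demirs, gene_calls)
    network_builder.validate_network(mti_net)
    counts_table = network_builder.per_mirna_target_counts(merged, mti_net, demirs)
    counts_table.to_csv(out / "per_mirna_counts.tsv", sep="\t", index=False)
    network_builder.export_network(
        network_builder.compose(tf_net, mti_net),
        out / "network.graphml", out / "network_edges.tsv",
    )
    t0 = _stage("network", t0)

    # --- stats --------------------------------------------------------------
    hub_up = network_stats.find_hubs(mti_net, "regulator", "up")
    hub_down = network_stats.find_hubs(mti_net, "regulator", "down")
    chrom, cstart, cend, _ = scfg.cluster_spec
    regions = [network_stats.RegionSpec("cluster", chrom)]
    region_table = network_stats.chromosomal_clustering(demirs, regions)
    cot_table, cot_union = (pd.DataFrame(), set())
    if truth.reference_targets:
        cot_table, cot_union = network_stats.co_targeting(
            merged, truth.reference_targets, demirs
        )
    t0 = _stage("stats", t0)

    # --- enrichment ---------------------------------------------------------
    universe = [g.upper() for g in scfg.gene_names]
    down_set = [g for g, d in truth.gene_direction.items() if d == "down"]
    up_set = [g for g, d in truth.gene_direction.items() if d == "up"]
    collection = [
        enrichment.GeneSet("planted_down", "genes planted down",
                           frozenset(g.upper() for g in down_set)),
        enrichment.GeneSet("planted_up", "genes planted up",
                           frozenset(g.upper() for g in up_set)),
    ] if (down_set and up_set) else []
    targeted = sorted({v for _, v, d in mti_net.edges(data=True) if d.get("kind") == "mti"})
    results = (enrichment.run_collection(targeted, collection, universe, cfg.alpha)
               if targeted and collection else [])
    if results:
        enrichment.results_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    t0 = _stage("enrich", t0)

    summary = {
        "mode": "synthetic",
        "seed": cfg.seed,
        "n_mirnas": scfg.n_mirnas,
        "n_demirs": len(demirs),
        "n_demirs_up": sum(1 for d in demirs if d.direction == "up"),
        "n_demirs_down": sum(1 for d in demirs if d.direction == "down"),
        "n_conflicts": len(conflicts),
        "n_tf_edges": tf_net.number_of_edges(),
        "n_mti_edges": mti_net.number_of_edges(),
        "hub_up": {"degree": hub_up.max_degree, "mirnas": sorted(hub_up.hubs)},
        "hub_down": {"degree": hub_down.max_degree, "mirnas": sorted(hub_down.hubs)},
        "regions": region_table.to_dict(orient="records"),
        "cotargeting": {"n_mirnas": int(len(cot_table)), "union_size": len(cot_union)},
        "top_enrichment": ([{"set": r.set_name, "p": r.p_value} for r in results[:3]]
                           if results else []),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def run_fixtures(outdir: str | Path | None = None, de: DEConfig | None = None) -> dict:
    """Analyse the packaged published reference tables end to end.

    Directions are re-derived from the printed fold changes via the DE
    thresholds and the cross-platform intersection; network-level counts
    come from the per-miRNA DE-target statistics.
    """
    de = de or DEConfig()
    table1, table2 = synth.load_paper_fixtures()
    loci = synth.fixture_loci(table1)

    calls_seq = de_calling.call_de(
        table1.rename(columns={"seq_fc_value": "fc"}), de, platform="seq",
        id_col="mirna")
    calls_array = de_calling.call_de(
        table1.rename(columns={"array_fc_value": "fc"}), de, platform="openarray",
        id_col="mirna")
    demirs, conflicts = de_calling.intersect_platforms(calls_seq, calls_array, loci)

    regions = [network_stats.RegionSpec("chr12", "chr12")]
    region_table = network_stats.chromosomal_clustering(demirs, regions)

    de_by_dir = table2.groupby("direction")["n_de_targets"].sum().to_dict()
    up_rows = table2[table2["direction"] == "up"]
    down_rows = table2[table2["direction"] == "down"]
    hub_up = network_stats.hub_report_from_degrees(
        dict(zip(up_rows["mirna"], up_rows["n_de_targets"])), "regulator", "up")
    hub_down = network_stats.hub_report_from_degrees(
        dict(zip(down_rows["mirna"], down_rows["n_de_targets"])), "regulator", "down")

    summary = {
        "mode": "fixtures",
        "n_demirs": len(demirs),
        "n_demirs_up": sum(1 for d in demirs if d.direction == "up"),
        "n_demirs_down": sum(1 for d in demirs if d.direction == "down"),
        "n_conflicts": len(conflicts),
        "n_mti_edges": int(table2["n_de_targets"].sum()),
        "n_mti_edges_up": int(de_by_dir.get("up", 0)),
        "n_mti_edges_down": int(de_by_dir.get("down", 0)),
        "n_mirnas_with_de_targets": int((table2["n_de_targets"] > 0).sum()),
        "n_mirnas_without_de_targets": int((table2["n_de_targets"] == 0).sum()),
        "hub_up": {"degree": hub_up.max_degree, "mirnas": sorted(hub_up.hubs)},
        "hub_down": {"degree": hub_down.max_degree, "mirnas": sorted(hub_down.hubs)},
        "regions": region_table.to_dict(orient="records"),
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_REPORT_KEYS = (
    "n_demirs_up", "n_demirs_down", "n_demirs", "n_tf_edges", "n_mti_edges",
)


def report(summary: dict) -> str:
    """Render a summary dict as markdown; numeric lines use a fixed
    ``- key: value`` shape so :func:`parse_report` can round-trip them."""
    for key in ("mode", "n_demirs"):
        if key not in summary:
            raise MiremapError(f"summary missing required field {key!r}")
    lines = [f"# miremap run report ({summary['mode']} mode)", ""]
    for key in _REPORT_KEYS:
        if key in summary:
            lines.append(f"- {key}: {summary[key]}")
    for side in ("hub_up", "hub_down"):
        if side in summary and summary[side]["mirnas"]:
            names = ", ".join(summary[side]["mirnas"])
            lines.append(f"- {side}: {names} ({summary[side]['degree']})")
    for row in summary.get("regions", []):
        lines.append(
            f"- region {row['region']}: {row['n_up']} up / {row['n_down']} down"
        )
    if summary.get("n_mti_edges", 0) == 0:
        lines.append("")
        lines.append("The reconstructed miRNA-target network is empty.")
    for item in summary.get("top_enrichment", []):
        lines.append(f"- enriched: {item['set']} (p={item['p']:.3g})")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> dict:
    """Recover the numeric counts from a rendered report."""
    out: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("- ") and ": " in line:
            key, _, value = line[2:].partition(": ")
            if key in _REPORT_KEYS:
                out[key] = int(value)
    return out
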
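"""End-to-end orchestrator: counts -> networks -> comparison -> annotation.

Stages, in order, per region:

1. per (dataset, condition): CPM filter, median-of-ratios normalization,
   signed wTO network, hard threshold;
2. per condition: sign-consistent consensus integration across datasets;
3. differential link classification between the two condition networks;
4. k-core hubs and Louvain clusters per condition network;
5. per-cluster enrichment and RWR-based lncRNA assignment per condition;
6. statistical evaluation (Fisher on core lncRNA counts, permutation
   overlap of assignments between conditions);
7. per-dataset differential expression and the all-dataset intersection.

Each stage logs its edge/node bookkeeping; ``write_outputs`` writes every
intermediate as TSV with a provenance header carrying the config hash.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, consensus, diffconet, io, preprocess, topology, wtonet
from .config import PipelineConfig
from .containers import ConsensusNetwork, CountMatrix, GeneCatalog, WtoNetwork
from .synthdata import GroundTruth, generate_study
from .topology import CorenessMap, Partition
from .validation import FisherResult, OverlapTest, core_lncrna_enrichment, \
    permutation_overlap_test

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Bundle of every stage's output for one region."""

    config: PipelineConfig
    wto_nets: dict[tuple[str, str], WtoNetwork]        # (dataset, condition)
    consensus_nets: dict[str, ConsensusNetwork]        # condition
    diff_links: pd.DataFrame
    coreness: dict[str, CorenessMap]
    partitions: dict[str, Partition]
    enrichment: dict[str, pd.DataFrame]
    assignments: dict[str, pd.DataFrame]
    de_tables: dict[str, pd.DataFrame]
    consensus_degs: pd.Series
    core_fisher: FisherResult | None
    overlap_tests: dict[str, OverlapTest]
    stage_log: list[str] = field(default_factory=list)
    catalog: GeneCatalog | None = None
    truth: GroundTruth | None = None

    def accepted_lncrnas(self, condition: str) -> pd.DataFrame:
        tab = self.assignments[condition]
        return tab.loc[tab["accepted"]]


def _stage(result_log: list[str], msg: str) -> None:
    log.info(msg)
    result_log.append(msg)


def run_pipeline(config: PipelineConfig,
                 matrices: list[CountMatrix] | None = None,
                 catalog: GeneCatalog | None = None,
                 category_sets: dict[str, set[str]] | None = None,
                 truth: GroundTruth | None = None) -> PipelineResult:
    """Run every stage; synthetic study generated when no matrices given."""
    config.validate()
    stage_log: list[str] = []
    if matrices is None:
        matrices, catalog, category_sets, truth = generate_study(config.synth)
        _stage(stage_log, f"synthdata: {len(matrices)} count matrices, "
               f"{config.synth.n_genes} genes")
    if catalog is None or category_sets is None:
        raise ValueError("catalog and category_sets required with user data")

    conditions = sorted({m.condition for m in matrices})
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conditions}")

    # stage 1: per-dataset networks
    wto_nets: dict[tuple[str, str], WtoNetwork] = {}
    normalized: dict[tuple[str, str], CountMatrix] = {}
    for cm in matrices:
        key = (cm.dataset_id, cm.condition)
        try:
            filt = preprocess.cpm_filter(cm, config.cpm_min, config.cpm_frac)
            norm, _ = preprocess.median_of_ratios_normalize(filt)
            normalized[key] = norm
            net = wtonet.wto_from_counts(norm, cutoff=config.wto_cutoff)
        except Exception as exc:
            raise RuntimeError(f"stage wto failed on {key}: {exc}") from exc
        wto_nets[key] = net
        _stage(stage_log, f"wto {key}: {len(filt.genes)} genes -> "
               f"{net.n_edges} edges, {len(net.nodes)} nodes after "
               f"|w|>={config.wto_cutoff}")

    # stage 2: consensus per condition
    consensus_nets: dict[str, ConsensusNetwork] = {}
    for cond in conditions:
        nets = [wto_nets[k] for k in sorted(wto_nets) if k[1] == cond]
        ids = [k[0] for k in sorted(wto_nets) if k[1] == cond]
        cn = consensus.integrate(nets, input_ids=ids)
        consensus_nets[cond] = cn
        _stage(stage_log, f"consensus {cond}: {cn.n_edges} edges, "
               f"{len(cn.nodes)} nodes from {len(nets)} inputs")

    # stage 3: differential link classification
    cond_a, cond_b = conditions
    diff = diffconet.classify_links(consensus_nets[cond_a],
                                    consensus_nets[cond_b],
                                    cutoff=config.diff_cutoff)
    counts = diffconet.category_counts(diff)
    _stage(stage_log, "diff links: " + ", ".join(
        f"{c}={counts[c]}" for c in counts.index))

    # stage 4: topology per condition
    coreness, partitions = {}, {}
    for cond in conditions:
        cmap = topology.kcore_decomposition(consensus_nets[cond])
        part = topology.louvain_clusters(
            consensus_nets[cond], resolution=config.louvain_resolution,
            min_links=config.min_cluster_links, seed=config.seed)
        coreness[cond] = cmap
        partitions[cond] = part
        _stage(stage_log, f"topology {cond}: {len(cmap.core_set)} core hubs, "
               f"{len(part.clusters)} clusters kept")

    # stage 5: enrichment + lncRNA assignment per condition
    enrichment, assignments = {}, {}
    background = set.union(*(set(n.nodes) for n in consensus_nets.values()))
    for cond in conditions:
        enr, asg = annotate.annotate_lncrnas(
            consensus_nets[cond], partitions[cond], catalog, category_sets,
            background, r=config.rwr_restart, percentile=config.assign_percentile,
            tol=config.rwr_tol, alpha=config.enrich_alpha,
            min_term_size=config.min_term_size)
        enrichment[cond] = enr
        assignments[cond] = asg
        _stage(stage_log, f"annotate {cond}: "
               f"{int(enr['significant'].sum()) if len(enr) else 0} enriched "
               f"terms, {int(asg['accepted'].sum()) if len(asg) else 0} "
               "accepted lncRNA assignments")

    # stage 6: statistical evaluation
    lnc = catalog.lncrna
    core_counts = {}
    for cond in conditions:
        core = coreness[cond].core_set
        core_counts[cond] = (len(core & lnc), len(core - lnc))
    try:
        fisher = core_lncrna_enrichment(core_counts[cond_b], core_counts[cond_a])
    except ValueError:
        fisher = None
    overlap_tests: dict[str, OverlapTest] = {}
    pools = {c: set(consensus_nets[c].nodes) & lnc for c in conditions}
    shared_cats = set()
    for c in conditions:
        if len(assignments[c]):
            acc = assignments[c].loc[assignments[c]["accepted"]]
            shared_cats |= set(acc["category"])
    for cat in sorted(shared_cats):
        sets = {}
        for c in conditions:
            tab = assignments[c]
            if len(tab):
                acc = tab.loc[tab["accepted"] & (tab["category"] == cat)]
                sets[c] = set(acc["lncrna"])
            else:
                sets[c] = set()
        if sets[cond_a] and sets[cond_b]:
            overlap_tests[cat] = permutation_overlap_test(
                sets[cond_a], sets[cond_b], pools[cond_a], pools[cond_b],
                n_perm=config.n_perm, seed=config.seed)
    _stage(stage_log, f"validation: core counts {core_counts}, "
           f"{len(overlap_tests)} category overlap tests")

    # stage 7: differential expression + intersection rule
    de_tables: dict[str, pd.DataFrame] = {}
    datasets = sorted({m.dataset_id for m in matrices})
    for ds in datasets:
        key_a, key_b = (ds, cond_a), (ds, cond_b)
        if key_a not in normalized or key_b not in normalized:
            continue
        na, nb = normalized[key_a], normalized[key_b]
        shared = sorted(set(na.genes) & set(nb.genes))
        de_tables[ds] = preprocess.differential_expression(
            na.subset_genes(shared), nb.subset_genes(shared),
            fdr_threshold=config.de_fdr, lfc_threshold=config.de_lfc)
    degs = preprocess.consensus_degs(list(de_tables.values())) \
        if de_tables else pd.Series(dtype=object)
    _stage(stage_log, f"de: {len(degs)} consensus DEGs across "
           f"{len(de_tables)} datasets")

    return PipelineResult(
        config=config, wto_nets=wto_nets, consensus_nets=consensus_nets,
        diff_links=diff, coreness=coreness, partitions=partitions,
        enrichment=enrichment, assignments=assignments, de_tables=de_tables,
        consensus_degs=degs, core_fisher=fisher, overlap_tests=overlap_tests,
        stage_log=stage_log, catalog=catalog, truth=truth)


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every intermediate table with a provenance header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = [f"config_hash={result.config.config_hash}"]
    result.config.to_yaml(outdir / "config.yaml")
    for (ds, cond), net in result.wto_nets.items():
        io.write_edges(net, outdir / f"wto_{ds}_{cond}.tsv",
                       h + [f"dataset={ds} condition={cond}"])
    for cond, cn in result.consensus_nets.items():
        io.write_table(cn.edges, outdir / f"consensus_{cond}.tsv",
                       h + [f"input={i}" for i in cn.input_ids])
    io.write_table(result.diff_links, outdir / "diff_links.tsv", h)
    for cond in result.consensus_nets:
        io.write_table(result.coreness[cond].to_frame(),
                       outdir / f"coreness_{cond}.tsv", h)
        io.write_table(result.partitions[cond].to_frame(),
                       outdir / f"clusters_{cond}.tsv", h)
        io.write_table(result.enrichment[cond],
                       outdir / f"enrichment_{cond}.tsv", h)
        io.write_table(result.assignments[cond],
                       outdir / f"assignments_{cond}.tsv", h)
    for ds, tab in result.de_tables.items():
        io.write_table(tab, outdir / f"de_{ds}.tsv", h)
    io.write_table(result.consensus_degs.rename_axis("gene").reset_index(),
                   outdir / "consensus_degs.tsv", h)
    stats_rows = []
    if result.core_fisher is not None:
        stats_rows.append(("core_lncrna_fisher_or", result.core_fisher.odds_ratio))
        stats_rows.append(("core_lncrna_fisher_p", result.core_fisher.p_value))
    for cat, ot in result.overlap_tests.items():
        stats_rows.append((f"overlap_{cat}", ot.observed))
        stats_rows.append((f"overlap_{cat}_p", ot.p_value))
    io.write_table(pd.DataFrame(stats_rows, columns=["statistic", "value"]),
                   outdir / "validation_stats.tsv",
                   h + [f"permutation_seed={result.config.seed}"])
    with open(outdir / "stage_log.txt", "w") as fh:
        fh.write("\n".join(result.stage_log) + "\n")
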
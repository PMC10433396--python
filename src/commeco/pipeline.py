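"""One-command orchestration: simulate (optional) -> diversity -> assembly
-> per-group networks, with a manifest that makes every stochastic output
reproducible from the global seed.

Stage seeds are derived from the global seed by fixed offsets so any stage
can be re-run in isolation and still match a full run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from commeco import diversity as dv
from commeco import network as net
from commeco.assembly import pairwise_assembly, summarize_processes
from commeco.io import (
    CountMatrix,
    SampleGroups,
    ValidationError,
    read_count_table,
    read_metadata,
    read_newick,
    write_edge_list,
    write_table,
)
from commeco.synthetic import SyntheticScenario, generate_dataset

log = logging.getLogger("commeco")

# fixed per-stage seed offsets
SEED_OFFSETS = {"simulate": 0, "assembly": 101, "network": 202, "rarefy": 303}


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Either the three input paths or a simulate block must be given.
    Defaults follow the conventional analysis settings: 999 null draws and
    permutations for the phylogenetic null models, 1,000 permutations for
    network p-values, 0.5% dominance filter, |rho| > 0.6 and q < 0.01 edge
    gates.
    """

    out_dir: str = "run"
    seed: int = 0
    counts: str | None = None
    tree: str | None = None
    metadata: str | None = None
    simulate: dict | None = None          # SyntheticScenario kwargs
    n_null: int = 999
    beta_metric: str = "both"             # braycurtis | unifrac | both
    network_threshold: float = 0.005
    network_rho: float = 0.6
    network_q: float = 0.01
    network_perms: int = 1000
    # per-group networks need >= 4 samples per group; the 4x3 study design
    # leaves correlations undefined, so the default pools all samples
    network_scope: str = "all_samples"    # all_samples | per_group
    pcoa_axes: int = 2

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name: str):
    start = time.time()

    def _done(**info):
        log.info("stage=%s elapsed=%.2fs %s", name, time.time() - start,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    return _done


def run_all(config: RunConfig) -> Path:
    """Run every stage and write all tables plus a manifest under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- inputs -------------------------------------------------------------
    done = _stage("inputs")
    if config.simulate is not None:
        scenario = SyntheticScenario(seed=config.seed + SEED_OFFSETS["simulate"],
                                     **config.simulate)
        ds = generate_dataset(scenario, out / "data", force=True)
        counts, tree, groups = ds.counts, ds.tree, ds.groups
    else:
        if not (config.counts and config.metadata):
            raise ValidationError("provide counts+metadata paths or a simulate block")
        counts = read_count_table(config.counts)
        groups = read_metadata(config.metadata)
        tree = read_newick(config.tree) if config.tree else None
    needs_tree = config.beta_metric in ("unifrac", "both")
    if tree is None and needs_tree:
        raise ValidationError("UniFrac/assembly stages need a tree; none given")
    groups.check_counts(counts)
    done(samples=counts.shape[0], taxa=counts.shape[1])

    # -- alpha diversity ----------------------------------------------------
    done = _stage("alpha")
    alpha = dv.alpha_table(counts)
    write_table(alpha, out / "alpha.tsv", index_label="sample_id")
    write_table(dv.alpha_group_summary(alpha, groups), out / "alpha_groups.tsv",
                index_label="group")
    done(samples=len(alpha))

    # -- beta diversity + ordination ----------------------------------------
    done = _stage("beta")
    dms = {}
    if config.beta_metric in ("braycurtis", "both"):
        dms["braycurtis"] = dv.bray_curtis(counts)
    if needs_tree:
        dms["unifrac"] = dv.unweighted_unifrac(counts, tree)
    for name, dm in dms.items():
        write_table(dm.to_data_frame(), out / f"dm_{name}.tsv",
                    index_label="sample_id")
        ord_ = dv.pcoa(dm, k=config.pcoa_axes)
        coords = ord_.coordinates.copy()
        write_table(coords, out / f"pcoa_{name}.tsv", index_label="sample_id")
    done(metrics=",".join(dms))

    # -- assembly -----------------------------------------------------------
    done = _stage("assembly")
    pairs = pairwise_assembly(counts, tree, groups, n_null=config.n_null,
                              seed=config.seed + SEED_OFFSETS["assembly"])
    write_table(pairs, out / "pairwise_assembly.tsv")
    summary = summarize_processes(pairs, scope="within_group")
    write_table(summary, out / "process_summary.tsv")
    done(pairs=len(pairs), nulls=config.n_null)

    # -- networks -----------------------------------------------------------
    done = _stage("network")
    scopes: dict[str, CountMatrix] = {}
    if config.network_scope == "all_samples":
        scopes["all"] = counts
    else:
        for g in groups.group_labels():
            scopes[g] = counts.select_samples(groups.members(g))
    summaries = []
    for name, sub in scopes.items():
        if sub.shape[0] < 5:
            log.warning("network scope %s has only %d samples; "
                        "correlation networks are fragile below 5",
                        name, sub.shape[0])
        edges, graph, summary = net.infer_network(
            sub, threshold=config.network_threshold,
            rho_threshold=config.network_rho, q_threshold=config.network_q,
            n_perm=config.network_perms,
            seed=config.seed + SEED_OFFSETS["network"],
        )
        write_table(edges, out / f"edges_{name}.tsv")
        sif = [(u, d["sign"], v) for u, v, d in graph.edges(data=True)]
        write_edge_list(sif, out / f"edges_{name}.sif")
        import networkx as nx
        nx.write_graphml(graph, out / f"network_{name}.graphml")
        row = summary.to_frame()
        row.insert(0, "scope", name)
        summaries.append(row)
    write_table(pd.concat(summaries, ignore_index=True), out / "network_summary.tsv")
    done(scopes=len(scopes))

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas
    import scipy
    import skbio

    import commeco
    return {m.__name__: m.__version__
            for m in (commeco, numpy, scipy, pandas, skbio, networkx)}
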
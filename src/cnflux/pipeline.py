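"""End-to-end orchestration: flux arm, cluster arm, and scenario runs.

The flux arm runs constrain -> prune -> sample(low) -> sample(high) ->
shift test -> group summaries; the cluster arm runs enrichment -> C/N flags
-> metabolite sets -> connectivity -> topology; the scenario runner sweeps
each configured uptake scenario.  Every output TSV starts with a provenance
header (config hash, seeds, package version) as comment lines; bodies are
byte-reproducible for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clusters import (
    build_category_map,
    cluster_metabolite_sets,
    connectivity_graph,
    enrich,
    flag_cn_clusters,
    graph_topology,
    read_clusters_tsv,
    read_gene_terms_tsv,
    write_edges_tsv,
    write_enrichment_tsv,
    write_graphml,
)
from .fba import prune_blocked
from .model import apply_constraints, load_model, read_constraints_tsv
from .sampling import read_samples_tsv, sample, validate_samples, write_samples_tsv
from .scenarios import ScenarioSpec, run_scenario, scenario_summary
from .shifttest import (
    summarize_groups,
    test_all,
    write_group_summary_tsv,
    write_results_tsv,
)

__all__ = ["PipelineConfig", "run_flux_arm", "run_cluster_arm", "run_scenarios"]


@dataclass
class PipelineConfig:
    model_path: str
    outdir: str
    model_format: str | None = None
    constraints: dict[str, str] = field(default_factory=dict)  # condition -> TSV
    samples: dict[str, str] = field(default_factory=dict)  # condition -> TSV bypass
    sampler: dict = field(default_factory=lambda: {"n_points": 2000, "seed": 0})
    test: dict = field(default_factory=lambda: {"n_repeats": 100, "alpha": 0.05})
    clusters_tsv: str | None = None
    terms_tsv: str | None = None
    connectivity_threshold: float = 0.9
    scenarios: list[dict] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance_lines(cfg: PipelineConfig, **extra) -> str:
    fields = {"config": cfg.digest(), "cnflux": __version__, **extra}
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def _write_tsv(write_fn, path: Path, cfg: PipelineConfig, **extra) -> None:
    import io

    buf = io.StringIO()
    write_fn(buf)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(cfg, **extra))
        fh.write(buf.getvalue())


def run_flux_arm(cfg: PipelineConfig) -> dict:
    """Constrain, prune, sample both carbon conditions, test, summarize."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.sampler.get("seed", 0))

    if cfg.samples:  # planted/bypass mode: sample matrices supplied directly
        low = read_samples_tsv(cfg.samples["low"])
        high = read_samples_tsv(cfg.samples["high"])
        model = load_model(cfg.model_path, cfg.model_format)
    else:
        model = load_model(cfg.model_path, cfg.model_format)
        sets = {}
        for i, cond in enumerate(("low", "high")):
            cs = read_constraints_tsv(cfg.constraints[cond])
            constrained = apply_constraints(model, cs, block_others=True)
            pruned, _, _ = prune_blocked(constrained)
            n_points = int(cfg.sampler.get("n_points", 2000))
            step_count = int(
                cfg.sampler.get("step_count", 2 * len(pruned.reactions))
            )
            s = sample(pruned, n_points, step_count, seed + i)
            s.meta["condition"] = cond
            report = validate_samples(pruned, s)
            if report.n_offending:
                raise RuntimeError(
                    f"stage sample({cond}): {report.n_offending} infeasible rows"
                )
            write_samples_tsv(s, outdir / f"samples_{cond}.tsv")
            sets[cond] = s
        low, high = sets["low"], sets["high"]

    results, skipped = test_all(
        low,
        high,
        n_repeats=int(cfg.test.get("n_repeats", 100)),
        alpha=float(cfg.test.get("alpha", 0.05)),
        seed=seed,
        subsample=cfg.test.get("subsample"),
    )
    _write_tsv(
        lambda fh: write_results_tsv(results, fh), outdir / "shift_test.tsv", cfg,
        seed=seed,
    )
    cmap = build_category_map()
    tested_in_model = [r for r in results if model.has_reaction(r.reaction_id)]
    summaries = summarize_groups(tested_in_model, model, cmap)
    _write_tsv(
        lambda fh: write_group_summary_tsv(summaries, fh),
        outdir / "group_summary.tsv", cfg, seed=seed,
    )
    significant = [r.reaction_id for r in results if r.significant]
    return {
        "n_tested": len(results),
        "n_significant": len(significant),
        "significant": significant,
        "skipped": skipped,
        "groups": {
            s.group: {"pct_up": s.pct_up, "pct_down": s.pct_down}
            for s in summaries
        },
    }


def run_cluster_arm(cfg: PipelineConfig) -> dict:
    """Enrichment, C/N flagging, connectivity and topology for both sides."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = load_model(cfg.model_path, cfg.model_format)
    clusters = read_clusters_tsv(cfg.clusters_tsv)
    gene_terms = read_gene_terms_tsv(cfg.terms_tsv)
    alpha = float(cfg.test.get("alpha", 0.05))

    records = enrich(clusters, gene_terms, alpha=alpha)
    _write_tsv(lambda fh: write_enrichment_tsv(records, fh),
               outdir / "enrichment.tsv", cfg)
    cmap = build_category_map()
    flags = flag_cn_clusters(records, cmap, alpha=alpha)
    flagged = {cid for cid, f in flags.items() if f}
    from .clusters import ClusterSet

    subset = (
        ClusterSet({cid: clusters.clusters[cid] for cid in sorted(flagged)})
        if flagged
        else None
    )
    report: dict = {
        "n_clusters": len(clusters.clusters),
        "n_flagged": len(flagged),
        "flags": {cid: sorted(f) for cid, f in flags.items()},
        "sides": {},
    }
    for side in ("substrates", "products"):
        if subset is None:
            report["sides"][side] = {"edges": 0, "component_sizes": []}
            _write_tsv(lambda fh: fh.write("cluster_a\tcluster_b\tscore\tside\n"),
                       outdir / f"edges_{side}.tsv", cfg)
            continue
        sets = cluster_metabolite_sets(subset, model, side=side, drop_currency=True)
        cg = connectivity_graph(sets, threshold=cfg.connectivity_threshold, side=side)
        sizes, btw = graph_topology(cg)
        _write_tsv(lambda fh: write_edges_tsv(cg, fh),
                   outdir / f"edges_{side}.tsv", cfg)
        write_graphml(cg, str(outdir / f"connectivity_{side}.graphml"))
        report["sides"][side] = {
            "edges": len(cg.edges),
            "component_sizes": sizes,
            "betweenness": btw,
        }
    return report


def run_scenarios(cfg: PipelineConfig) -> dict:
    """Run every configured uptake scenario; write per-step TSV + summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = load_model(cfg.model_path, cfg.model_format)
    summaries = []
    for raw in cfg.scenarios:
        raw = dict(raw)
        for key in ("open_demands", "closed_demands"):
            if key in raw:
                raw[key] = set(raw[key])
        spec = ScenarioSpec(**raw)
        result = run_scenario(model, spec)
        _write_tsv(
            lambda fh: result.steps.to_csv(fh, sep="\t", index=False,
                                           float_format="%.10g"),
            outdir / f"scenario_{spec.scenario}.tsv", cfg,
        )
        summaries.append(scenario_summary(result))
    with open(outdir / "scenario_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=1)
        fh.write("\n")
    return {"scenarios": summaries}
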
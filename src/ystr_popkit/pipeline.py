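"""End-to-end workflow: summary → distances → ordination → network → richness
→ ancestry, with a reproducibility manifest.

Every stage writes plain-text artifacts into the output directory and is
recorded in ``manifest.json`` together with the effective configuration,
seeds, package version and SHA-256 hashes, so a rerun with the same config
reproduces identical hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .allelic_richness import mean_richness, richness_profile
from .ancestry import fst_ratio_bootstrap, fit_haplogroup_model, predict_haplogroup
from .distance_amova import DistanceOptions, pairwise_differences, rst_matrix
from .forensic_stats import summarize
from .haplotype_io import HaplotypeTable, allele_frequencies, read_table
from .mjnetwork import export_network, median_joining, prepare_network_input
from .ordination import nonmetric_mds, upgma

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for :func:`run_all`; a YAML document with CLI overrides."""

    input_table: str | None = None  # path; None -> simulate
    output_dir: str = "ystr_popkit_out"
    include_dys385: bool = True
    use_encoded_dys389ii: bool = False
    round_microvariants: bool = False
    mds_dims: int = 2
    tree_k: int | None = None
    network_epsilon: float = 0.0
    q_matrix: str | None = None
    bootstrap: int = 100
    seed: int = 0
    stages: tuple[str, ...] = (
        "summary", "distance", "mds", "tree", "network", "richness", "fstruct",
        "predict",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, table: HaplotypeTable | None = None) -> dict:
    """Run the enabled stages and return (and write) the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    options = DistanceOptions(
        include_dys385=config.include_dys385,
        use_encoded_dys389ii=config.use_encoded_dys389ii,
        round_microvariants=config.round_microvariants,
    )
    if table is None:
        if config.input_table:
            table = read_table(config.input_table)
        else:
            from .synthetic_data import study_config, simulate_table

            table, truth = simulate_table(study_config(seed=config.seed))
            truth.to_csv(out / "true_lineages.csv", header=True)
    artifacts: dict[str, str] = {}
    stage_log: list[dict] = []

    def record(stage: str, paths: list[Path], t0: float):
        for p in paths:
            artifacts[p.name] = _sha256(p)
        stage_log.append(
            {"stage": stage, "seconds": round(time.time() - t0, 3),
             "outputs": [p.name for p in paths]}
        )

    multi_pop = len(table.populations) >= 2
    for stage in config.stages:
        t0 = time.time()
        if stage == "summary":
            summary = summarize(table)
            (out / "summary.json").write_text(
                json.dumps(summary.to_dict(), indent=2, default=float)
            )
            summary.per_locus.to_csv(out / "per_locus.csv")
            summary.microvariants.to_csv(out / "microvariants.csv")
            allele_frequencies(table).to_dataframe().to_csv(
                out / "allele_frequencies.csv", index=False
            )
            record(stage, [out / "summary.json", out / "per_locus.csv",
                           out / "microvariants.csv", out / "allele_frequencies.csv"], t0)
        elif stage == "distance":
            if not multi_pop:
                logger.info("single population; skipping distance stage")
                continue
            rst = rst_matrix(table, options)
            rst.to_dataframe().to_csv(out / "rst.csv")
            (out / "rst.phy").write_text(rst.to_phylip())
            pw = pairwise_differences(table, options)
            pw.pixy.to_csv(out / "pairwise_between.csv")
            pw.pix.to_csv(out / "pairwise_within.csv")
            pw.corrected.to_csv(out / "pairwise_corrected.csv")
            record(stage, [out / "rst.csv", out / "rst.phy",
                           out / "pairwise_between.csv", out / "pairwise_within.csv",
                           out / "pairwise_corrected.csv"], t0)
        elif stage == "mds":
            if not multi_pop:
                continue
            rst = rst_matrix(table, options)
            res = nonmetric_mds(rst, k=config.mds_dims)
            res.coordinates.to_csv(out / "mds_coords.csv")
            (out / "mds.json").write_text(json.dumps(
                {"stress": res.stress, "k": res.k, "converged": res.converged,
                 "iterations": res.iterations}))
            record(stage, [out / "mds_coords.csv", out / "mds.json"], t0)
        elif stage == "tree":
            if not multi_pop:
                continue
            dend = upgma(rst_matrix(table, options))
            (out / "tree.nwk").write_text(dend.newick() + "\n")
            k = config.tree_k or min(8, len(dend.labels) - 1) or 1
            cut = dend.cut(max(k, 1))
            with open(out / "clusters.csv", "w") as fh:
                fh.write("label,cluster\n")
                for lab, c in cut.items():
                    fh.write(f"{lab},{c}\n")
            record(stage, [out / "tree.nwk", out / "clusters.csv"], t0)
        elif stage == "network":
            reduced = prepare_network_input(table)
            net = median_joining(reduced, epsilon=config.network_epsilon)
            export_network(net, out / "network.graphml", "graphml")
            export_network(net, out / "network.dot", "dot")
            with open(out / "network_nodes.csv", "w") as fh:
                fh.write("name,kind,size\n")
                for n in net.nodes:
                    fh.write(f"{n.name},{n.kind},{n.size}\n")
            record(stage, [out / "network.graphml", out / "network.dot",
                           out / "network_nodes.csv"], t0)
        elif stage == "richness":
            if not multi_pop:
                continue
            prof = richness_profile(table)
            prof.to_csv(out / "richness.csv", index=False)
            mean_richness(prof).to_csv(out / "richness_mean.csv", index=False)
            record(stage, [out / "richness.csv", out / "richness_mean.csv"], t0)
        elif stage == "fstruct":
            if config.q_matrix:
                from .ancestry import read_qmatrix

                qmat = read_qmatrix(config.q_matrix)
            else:
                from .synthetic_data import simulate_q

                sizes = {p: sum(1 for x in table.profiles if x.population == p)
                         for p in table.populations}
                qmat = simulate_q(sizes, K=3,
                                  alpha={p: 0.5 for p in sizes},
                                  seed=config.seed + 1)
            results = fst_ratio_bootstrap(qmat, B=config.bootstrap,
                                          seed=config.seed + 2)
            with open(out / "fstruct.csv", "w") as fh:
                fh.write("population,fst,fst_max,ratio\n")
                for r in results:
                    fh.write(f"{r.population},{r.fst:.6f},{r.fst_max:.6f},{r.ratio:.6f}\n")
            with open(out / "fstruct_replicates.csv", "w") as fh:
                fh.write("population,replicate,ratio\n")
                for r in results:
                    for b, v in enumerate(r.replicates):
                        fh.write(f"{r.population},{b},{v:.6f}\n")
            record(stage, [out / "fstruct.csv", out / "fstruct_replicates.csv"], t0)
        elif stage == "predict":
            model = fit_haplogroup_model(table)
            with open(out / "predictions.csv", "w") as fh:
                fh.write("sample_id,haplogroup,posterior\n")
                for p in table.profiles:
                    hg, post = predict_haplogroup(p, model)[0]
                    fh.write(f"{p.sample_id},{hg},{post:.6f}\n")
            record(stage, [out / "predictions.csv"], t0)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": stage_log,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
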
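"""End-to-end analysis pipeline: edges in, reproducible report bundle out.

Stages: read network -> transactions -> association-rule mining ->
tissue-bias statistics -> hubs / cancer-specific miRNAs -> neighbor
clusters (if loci supplied) -> permutation tests -> Pajek export.  Every
output is a plain TSV with a ``#`` comment block echoing the configuration,
plus a JSON manifest (config, seed, package/library versions, input and
output checksums) sufficient to reproduce the bundle bit-for-bit.

The bundle is assembled in a temporary directory and moved into place only
on success, so a failed stage never leaves a half-written bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import clusters as clusters_mod
from . import enrichment, mining, nulls
from .network import Direction, read_edge_list, read_loci, to_transactions, write_pajek

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    edges: str | None = None
    loci: str | None = None
    loci_format: str = "BED"
    out_dir: str = "cminet-out"
    min_support: float = 0.3
    min_confidence: float = 0.8
    top_k: int = 5
    max_itemset_size: int = 6
    hub_min_degree: int = 5
    specific_max_degree: int = 2
    cluster_max_gap: int = 50_000
    n_permutations: int = 1000
    rewire_mode: str = "cancer-degree"
    fisher_sidedness: str = "two-sided"
    conflict_policy: str = "error"
    sign_mode: str = "any"
    seed: int = 0

    def validate(self) -> None:
        if self.edges is None:
            raise ValueError("config requires an edges path")
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must be in (0, 1]")
        if not (0 < self.min_confidence <= 1):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.top_k < 0 or self.hub_min_degree < 1 or self.specific_max_degree < 0:
            raise ValueError("threshold out of range")
        if self.cluster_max_gap < 0 or self.n_permutations < 1:
            raise ValueError("threshold out of range")
        if self.rewire_mode not in {"cancer-degree", "double-swap"}:
            raise ValueError(f"unknown rewire_mode {self.rewire_mode!r}")
        if self.fisher_sidedness not in {"two-sided", "greater", "less"}:
            raise ValueError(f"unknown fisher_sidedness {self.fisher_sidedness!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    out_dir: Path
    tissue_bias: Path
    rules: Path
    hubs: Path
    cancer_specific: Path
    clusters: Path | None
    permutation: Path
    pajek_net: Path
    pajek_clu: Path
    manifest: Path
    paths: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_header(config: PipelineConfig) -> str:
    lines = ["# cminet report"]
    for key, value in asdict(config).items():
        lines.append(f"# {key} = {value}")
    return "\n".join(lines) + "\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_config_header(config))
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Raises with a stage-named error on any failure; the output directory is
    only (re)placed after every artifact has been written.
    """
    config.validate()
    out_dir = Path(config.out_dir)

    def stage(name: str):
        logger.info("stage %s: begin", name)
        return name

    # -- read ----------------------------------------------------------
    current = stage("read-edges")
    edges_path = Path(config.edges)
    if not edges_path.exists():
        raise FileNotFoundError(f"[{current}] edges file not found: {edges_path}")
    network = read_edge_list(str(edges_path), conflict_policy=config.conflict_policy)
    logger.info(
        "stage read-edges: %d cancers, %d miRNAs, %d edges",
        len(network.cancers),
        len(network.mirnas),
        network.n_edges,
    )

    loci = None
    if config.loci is not None:
        current = stage("read-loci")
        loci_path = Path(config.loci)
        if not loci_path.exists():
            raise FileNotFoundError(f"[{current}] loci file not found: {loci_path}")
        loci = read_loci(str(loci_path), format=config.loci_format)
        logger.info("stage read-loci: %d loci", len(loci))

    tmp = Path(tempfile.mkdtemp(prefix=".cminet-bundle-", dir=out_dir.parent or "."))
    try:
        # -- tissue bias ------------------------------------------------
        stage("tissue-bias")
        bias = enrichment.tissue_bias_table(network, config.fisher_sidedness)
        _write_tsv(bias, tmp / "tissue_bias.tsv", config)

        # -- rule mining ------------------------------------------------
        stage("rule-mining")
        db = to_transactions(network, sign_mode=config.sign_mode)
        frequent = mining.apriori(
            db, config.min_support, max_len=config.max_itemset_size
        )
        rules = mining.generate_rules(frequent, db, config.min_confidence)
        top = mining.top_rules(rules, config.top_k)
        frame = mining.rules_frame(mining.top_rules(rules, len(rules)))
        frame.insert(0, "rank", range(1, len(frame) + 1))
        frame["in_top_k"] = frame["rank"] <= config.top_k
        _write_tsv(frame, tmp / "rules.tsv", config)
        logger.info(
            "stage rule-mining: %d frequent itemsets, %d rules", len(frequent), len(rules)
        )

        # -- hubs & cancer-specific -------------------------------------
        stage("hubs")
        hubs = enrichment.find_hubs(network, config.hub_min_degree)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "mirna": h.mirna,
                        "degree": h.degree,
                        "n_up": h.n_up,
                        "n_down": h.n_down,
                        "homogeneity": h.homogeneity,
                    }
                    for h in hubs
                ],
                columns=["mirna", "degree", "n_up", "n_down", "homogeneity"],
            ),
            tmp / "hubs.tsv",
            config,
        )
        specific = enrichment.cancer_specific(network, config.specific_max_degree)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "mirna": m,
                        "degree": d,
                        "associations": "; ".join(
                            f"{c}:{dd.value}" for c, dd in sorted(assoc.items())
                        ),
                    }
                    for m, d, assoc in specific
                ],
                columns=["mirna", "degree", "associations"],
            ),
            tmp / "cancer_specific.tsv",
            config,
        )

        # -- clusters -----------------------------------------------------
        cluster_list = None
        if loci is not None:
            stage("clusters")
            cluster_list = clusters_mod.build_clusters(
                loci, max_gap=config.cluster_max_gap
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "cluster_id": i + 1,
                            "chrom": c.chrom,
                            "span_start": c.span[0],
                            "span_end": c.span[1],
                            "members": "; ".join(sorted(c.members)),
                        }
                        for i, c in enumerate(cluster_list)
                    ],
                    columns=["cluster_id", "chrom", "span_start", "span_end", "members"],
                ),
                tmp / "clusters.tsv",
                config,
            )

        # -- permutation tests -------------------------------------------
        stage("permutation")
        perm_rows = []

        def record(result: nulls.EmpiricalPValue) -> None:
            perm_rows.append(
                {
                    "statistic": result.statistic,
                    "observed": result.observed,
                    "n_replicates": result.n_replicates,
                    "n_as_extreme": result.n_as_extreme,
                    "p": result.p,
                    "p_floor": result.p_floor,
                    "tail": result.tail,
                    "mode": result.mode,
                    "seed": result.seed,
                }
            )

        for h in hubs:
            record(
                nulls.permutation_test(
                    network,
                    nulls.mirna_degree_statistic(h.mirna),
                    n_replicates=config.n_permutations,
                    rewire_mode=config.rewire_mode,
                    seed=nulls.derive_seed(config.seed, f"hub:{h.mirna}"),
                )
            )
        for rule in top:
            record(
                nulls.permutation_test(
                    network,
                    nulls.rule_support_statistic(sorted(rule.items)),
                    n_replicates=config.n_permutations,
                    rewire_mode=config.rewire_mode,
                    seed=nulls.derive_seed(config.seed, f"rule:{rule}"),
                )
            )
        if cluster_list:
            for direction in (Direction.DOWN, Direction.UP):
                record(
                    clusters_mod.cluster_coexpression_test(
                        network,
                        cluster_list,
                        direction,
                        n_replicates=config.n_permutations,
                        seed=nulls.derive_seed(
                            config.seed, f"cluster:{direction.value}"
                        ),
                        rewire_mode=config.rewire_mode,
                    )
                )
        _write_tsv(
            pd.DataFrame(
                perm_rows,
                columns=[
                    "statistic",
                    "observed",
                    "n_replicates",
                    "n_as_extreme",
                    "p",
                    "p_floor",
                    "tail",
                    "mode",
                    "seed",
                ],
            ),
            tmp / "permutation.tsv",
            config,
        )

        # -- Pajek export -------------------------------------------------
        stage("pajek-export")
        with open(tmp / "network.net", "w", encoding="utf-8") as net_fh, open(
            tmp / "network.clu", "w", encoding="utf-8"
        ) as clu_fh:
            write_pajek(network, net_fh, clu_fh)

        # -- manifest -----------------------------------------------------
        stage("manifest")
        import numpy, scipy  # versions recorded for provenance

        artifacts = sorted(p.name for p in tmp.iterdir())
        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "versions": {
                "cminet": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "inputs": {
                "edges": {"path": str(edges_path), "sha256": _sha256(edges_path)},
                **(
                    {
                        "loci": {
                            "path": str(config.loci),
                            "sha256": _sha256(Path(config.loci)),
                        }
                    }
                    if config.loci
                    else {}
                ),
            },
            "cluster_stage": "run" if loci is not None else "skipped (no loci input)",
            "outputs": {name: _sha256(tmp / name) for name in artifacts},
        }
        with open(tmp / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise

    return ReportBundle(
        out_dir=out_dir,
        tissue_bias=out_dir / "tissue_bias.tsv",
        rules=out_dir / "rules.tsv",
        hubs=out_dir / "hubs.tsv",
        cancer_specific=out_dir / "cancer_specific.tsv",
        clusters=(out_dir / "clusters.tsv") if loci is not None else None,
        permutation=out_dir / "permutation.tsv",
        pajek_net=out_dir / "network.net",
        pajek_clu=out_dir / "network.clu",
        manifest=out_dir / "manifest.json",
    )
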
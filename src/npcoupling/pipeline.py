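"""End-to-end orchestration: preprocessing -> site/taxon classification ->
regression & enrichment -> signed networks at phylum and genus ranks.

A single configuration (YAML-friendly dict) drives either analysis mode
(paths to three count tables, a taxonomy and a nutrient table) or generator
mode (a synthetic dataset is created in memory). Every threshold the method
uses is surfaced in the config with its standard default. Identical
config + seed yields a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    classify_sites,
    classify_taxa,
    correlate_taxa,
    regress_vs_nmin_ap,
    test_enrichment,
)
from .constants import MARKER_GROUPS
from .exceptions import ConfigError, NPCouplingError, PipelineError
from .network import (
    NetworkParams,
    build_network,
    centrality_and_keystones,
    network_metrics,
    select_candidates,
)
from .preprocess import PreprocessParams, merge_groups, preprocess_table
from .synthetic import GeneratorConfig, generate_dataset
from .tableio import (
    read_count_table,
    read_nutrients,
    read_taxonomy,
    write_network,
    write_report,
)

logger = logging.getLogger("npcoupling")

RANKS = ("phylum", "genus")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``inputs``/``generator`` set."""

    seed: int = 0
    ranks: tuple[str, ...] = RANKS
    inputs: dict | None = None  # {"counts": {group: path}, "taxonomy": p, "nutrients": p}
    generator: GeneratorConfig | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    tn_tp_min: float = 3.0
    nmin_ap_min: float = 0.16
    alpha: float = 0.05
    bonferroni: str = "family"
    network: NetworkParams = field(default_factory=NetworkParams)

    def validate(self) -> None:
        if (self.inputs is None) == (self.generator is None):
            raise ConfigError("config needs exactly one of 'inputs' or 'generator'")
        if self.tn_tp_min <= 0 or self.nmin_ap_min <= 0:
            raise ConfigError("site thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        bad = [r for r in self.ranks if r not in RANKS]
        if bad:
            raise ConfigError(f"unknown ranks: {bad}")
        self.preprocess.validate()
        self.network.validate()
        if self.generator is not None:
            self.generator.validate()
        else:
            for group, path in self.inputs.get("counts", {}).items():
                if group not in MARKER_GROUPS:
                    raise ConfigError(f"unknown marker group {group!r} in inputs")
                if not Path(path).exists():
                    raise ConfigError(f"count table not found: {path}")
            for key in ("taxonomy", "nutrients"):
                if key not in self.inputs:
                    raise ConfigError(f"inputs missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"{key} table not found: {self.inputs[key]}")

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "ranks": list(self.ranks),
            "inputs": self.inputs,
            "generator": dataclasses.asdict(self.generator) if self.generator else None,
            "preprocess": dataclasses.asdict(self.preprocess),
            "tn_tp_min": self.tn_tp_min,
            "nmin_ap_min": self.nmin_ap_min,
            "alpha": self.alpha,
            "bonferroni": self.bonferroni,
            "network": dataclasses.asdict(self.network),
        }
        if out["generator"] is not None:
            out["generator"]["depth_range"] = list(out["generator"]["depth_range"])
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("generator"):
            gen = dict(kwargs["generator"])
            if "depth_range" in gen:
                gen["depth_range"] = tuple(gen["depth_range"])
            kwargs["generator"] = GeneratorConfig(**gen)
        if kwargs.get("preprocess"):
            kwargs["preprocess"] = PreprocessParams(**kwargs["preprocess"])
        if kwargs.get("network"):
            kwargs["network"] = NetworkParams(**kwargs["network"])
        if kwargs.get("ranks"):
            kwargs["ranks"] = tuple(kwargs["ranks"])
        return cls(**{k: v for k, v in kwargs.items() if v is not None or k in ("inputs", "generator")})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Wrap stage bodies so failures carry the stage name."""

    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except NPCouplingError as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def _load(config: PipelineConfig):
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        ds = generate_dataset(gen)
        return ds.counts, ds.taxonomy, ds.nutrients
    counts = {
        group: read_count_table(path, group)
        for group, path in sorted(config.inputs["counts"].items())
    }
    taxonomy = read_taxonomy(config.inputs["taxonomy"])
    nutrients = read_nutrients(config.inputs["nutrients"])
    return counts, taxonomy, nutrients


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    counts, taxonomy, nutrients = _stage("load")(_load)(config)
    for group, table in counts.items():
        missing = table.sites.difference(nutrients.sites)
        if len(missing):
            raise PipelineError(
                "load", f"nutrient table missing site {missing[0]!r} present in {group} counts"
            )

    site_labels = _stage("classify_sites")(classify_sites)(
        nutrients, config.tn_tp_min, config.nmin_ap_min
    )
    n_coupled = int((site_labels["label"] == "coupled").sum())
    logger.info("site classification: %d coupled / %d total", n_coupled, len(site_labels))

    report: dict = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "sites": {
            "n_sites": int(len(site_labels)),
            "n_coupled": n_coupled,
            "n_decoupled": int(len(site_labels)) - n_coupled,
            "coupled_sites": sorted(site_labels.index[site_labels["label"] == "coupled"]),
        },
        "ranks": {},
    }
    if out is not None:
        site_labels.rename_axis("site_id").to_csv(out / "site_labels.tsv", sep="\t")

    prep = dataclasses.replace(config.preprocess, seed=config.seed)
    for rank in config.ranks:
        rank_dir = out / rank if out is not None else None
        if rank_dir is not None:
            rank_dir.mkdir(exist_ok=True)
        aggs, all_labels = {}, {}
        rank_report: dict = {"groups": {}, "networks": {}}
        for group, table in counts.items():
            agg = _stage(f"preprocess:{rank}:{group}")(preprocess_table)(
                table, taxonomy, rank, prep
            )
            logger.info("%s %s: %d major taxa retained", rank, group, len(agg.taxa))
            records = _stage(f"correlate:{rank}:{group}")(correlate_taxa)(
                agg, nutrients, config.alpha, config.bonferroni
            )
            labels = classify_taxa(records, config.alpha)
            regression = _stage(f"regression:{rank}:{group}")(regress_vs_nmin_ap)(
                agg, nutrients, labels, config.alpha
            )
            enrichment = _stage(f"enrichment:{rank}:{group}")(test_enrichment)(
                agg, site_labels, labels, config.alpha
            )
            aggs[group], all_labels[group] = agg, labels
            counts_by_label = labels["label"].value_counts().to_dict()
            rank_report["groups"][group] = {
                "n_taxa": int(len(agg.taxa)),
                "label_counts": {k: int(v) for k, v in sorted(counts_by_label.items())},
                "n_regression_significant": int(regression["significant"].sum()),
                "n_enriched": int(enrichment["enriched"].sum()),
            }
            if rank_dir is not None:
                agg.data.rename_axis("site_id").T.rename_axis("taxon").to_csv(
                    rank_dir / f"abundance_{group}.tsv", sep="\t"
                )
                records.to_csv(rank_dir / f"correlations_{group}.tsv", sep="\t", index=False)
                labels.to_csv(rank_dir / f"labels_{group}.tsv", sep="\t", index=False)
                regression.to_csv(rank_dir / f"regression_{group}.tsv", sep="\t", index=False)
                enrichment.to_csv(rank_dir / f"enrichment_{group}.tsv", sep="\t", index=False)

        merged = _stage(f"merge:{rank}")(merge_groups)(list(aggs.values()))
        merged_labels = pd.concat(
            [
                lab.assign(taxon=[f"{group}|{t}" for t in lab["taxon"]])
                for group, lab in all_labels.items()
            ],
            ignore_index=True,
        )
        for which in ("coupled", "decoupled"):
            cands = select_candidates(
                merged, merged_labels, which, config.network, config.preprocess.major_abund
            )
            net_report: dict = {"n_candidates": len(cands)}
            if len(cands) < 2:
                logger.warning("%s %s network: empty candidate set", rank, which)
                net_report["metrics"] = None
                net_report["keystones"] = []
            else:
                graph = _stage(f"network:{rank}:{which}")(build_network)(
                    merged, cands, config.network
                )
                metrics = network_metrics(graph)
                net_report["metrics"] = metrics
                if graph.number_of_nodes() >= 3:
                    cent = centrality_and_keystones(graph, config.network)
                    net_report["keystones"] = sorted(
                        cent.loc[cent["keystone"], "taxon"].tolist()
                    )
                else:
                    cent = None
                    net_report["keystones"] = []
                if rank_dir is not None:
                    write_network(graph, rank_dir / f"network_{which}.graphml", "graphml")
                    write_network(graph, rank_dir / f"network_{which}_edges.tsv", "edge_tsv")
                    if cent is not None:
                        cent.to_csv(rank_dir / f"network_{which}_nodes.tsv", sep="\t", index=False)
            rank_report["networks"][which] = net_report
        report["ranks"][rank] = rank_report

    if out is not None:
        write_report(report, out / "report.json")
        _write_report_tables(report, out)
    return report


def _write_report_tables(report: dict, out: Path) -> None:
    """Tab-delimited companions to report.json."""
    rows = []
    for rank, rr in report["ranks"].items():
        for which, nr in rr["networks"].items():
            m = nr["metrics"]
            if m is None:
                continue
            flat = {"rank": rank, "network": which, **{k: v for k, v in m.items() if k != "edge_types"}}
            flat.update({f"edges_{k}": v for k, v in m["edge_types"].items()})
            flat["keystones"] = ";".join(nr["keystones"])
            rows.append(flat)
    pd.DataFrame(rows).to_csv(out / "network_metrics.tsv", sep="\t", index=False)
    rows = []
    for rank, rr in report["ranks"].items():
        for group, gr in rr["groups"].items():
            rows.append({"rank": rank, "group": group, **gr["label_counts"]})
    pd.DataFrame(rows).fillna(0).to_csv(out / "label_counts.tsv", sep="\t", index=False)
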
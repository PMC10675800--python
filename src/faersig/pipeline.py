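"""End-to-end orchestration: generate/ingest -> map -> signal -> filter -> cluster.

Each stage persists its intermediate as TSV so the pipeline is resumable and
every stage is independently testable; ``manifest.json`` records row/report
counts at every stage together with the effective configuration.  Any stage
error aborts the run, removes partial outputs, and reports the failing stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import cluster as _cluster
from . import disproportionality as _disp
from . import drug_mapping as _map
from . import faers_tables as _tables
from . import signal_matrix as _sm
from . import synthetic as _syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline aborted at stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``faers_dir`` (directory holding DEMO/DRUG/REAC/INDI
    ``$``-delimited files) or ``synthetic`` (a
    :class:`faersig.synthetic.SyntheticConfig`) must be set.
    """

    out_dir: str | Path
    faers_dir: str | Path | None = None
    synthetic: _syn.SyntheticConfig | None = None
    rules_file: str | Path | None = None      # default: shipped 11-opioid rules
    drugs: Sequence[str] | None = None        # default: labels observed after mapping
    comparator: str = "all_reports"
    alpha: float = _disp.DEFAULT_ALPHA
    ci_level: float = 0.95
    filter: _sm.FilterConfig = field(default_factory=_sm.FilterConfig)
    k_drugs: int = 5
    k_events: int = 7
    standardize: bool = False
    make_heatmap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.faers_dir is None) == (self.synthetic is None):
            raise ValueError("set exactly one of faers_dir or synthetic")
        if self.k_drugs < 1 or self.k_events < 1:
            raise ValueError("k_drugs and k_events must be >= 1")
        if self.faers_dir is not None and not Path(self.faers_dir).is_dir():
            raise ValueError(f"faers_dir {self.faers_dir} does not exist")
        if self.rules_file is not None and not Path(self.rules_file).is_file():
            raise ValueError(f"rules_file {self.rules_file} does not exist")


def _effective_config(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(config.out_dir)
    d["faers_dir"] = str(config.faers_dir) if config.faers_dir else None
    d["rules_file"] = str(config.rules_file) if config.rules_file else None
    if config.synthetic is not None:
        d["synthetic"]["multipliers"] = [
            {"drug": k[0], "event": k[1], "theta": v}
            for k, v in sorted(config.synthetic.multipliers.items())]
    d["drugs"] = list(config.drugs) if config.drugs is not None else None
    return d


def _find_table(directory: Path, kind: str) -> Path:
    hits = sorted(p for p in directory.iterdir()
                  if p.name.upper().startswith(kind) and p.suffix.lower() in (".txt", ".gz"))
    if not hits:
        raise FileNotFoundError(f"no {kind}*.txt file in {directory}")
    return hits[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to
    ``out_dir/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"stages": {}, "outputs": {},
                      "config": _effective_config(config)}

    def emit(name: str, path: Path) -> Path:
        written.append(path)
        manifest["outputs"][name] = str(path)
        return path

    stage = "setup"
    t_start = time.perf_counter()
    try:
        # -- generate -------------------------------------------------------
        if config.synthetic is not None:
            stage = "generate"
            t0 = time.perf_counter()
            gen_dir = out / "synthetic_faers"
            paths, truth = _syn.generate(config.synthetic, gen_dir)
            for kind, p in paths.items():
                written.append(Path(p))
            faers_dir = gen_dir
            manifest["stages"]["generate"] = {
                "n_reports": config.synthetic.n_reports,
                "n_capped_cells": truth.n_capped,
                "seed": config.synthetic.seed,
            }
            logger.info("generate: %d reports (%.2fs)", config.synthetic.n_reports,
                        time.perf_counter() - t0)
        else:
            faers_dir = Path(config.faers_dir)

        # -- ingest ---------------------------------------------------------
        stage = "ingest"
        t0 = time.perf_counter()
        raw = {kind: _tables.read_faers_table(_find_table(faers_dir, kind), kind)
               for kind in _tables.TABLE_KINDS}
        n_rows = {kind: len(tab) for kind, tab in raw.items()}
        if n_rows["DEMO"] == 0:
            raise ValueError(f"no DEMO rows ingested from {faers_dir}; "
                             "cannot build an analysis table")
        table = _tables.build_analysis_table(raw["DEMO"], raw["DRUG"],
                                             raw["REAC"], raw["INDI"])
        long_path = emit("analysis_long", out / "analysis_long.tsv")
        _tables.write_long_table(table, long_path)
        manifest["stages"]["ingest"] = {
            "rows_ingested": n_rows,
            "rows_skipped": {kind: tab.n_skipped for kind, tab in raw.items()},
            "n_reports_after_dedup": table.n_reports,
            "n_orphan_rows": table.n_orphan_rows,
            "n_superseded_rows": table.n_superseded_rows,
        }
        logger.info("ingest: %d reports after dedup (%.2fs)", table.n_reports,
                    time.perf_counter() - t0)

        # -- map ------------------------------------------------------------
        stage = "map"
        t0 = time.perf_counter()
        rules = (_map.load_rules(config.rules_file) if config.rules_file
                 else _map.default_rules())
        index = _disp.ReportIndex(table, rules=rules, drugs=config.drugs)
        n_mapped_reports = int(index.drug_matrix.any(axis=1).sum())
        manifest["stages"]["map"] = {
            "n_rules": len(rules),
            "drugs": index.drugs,
            "n_reports_with_target_drug": n_mapped_reports,
        }
        logger.info("map: %d/%d reports carry a target drug (%.2fs)",
                    n_mapped_reports, table.n_reports, time.perf_counter() - t0)

        # -- signals --------------------------------------------------------
        stage = "signals"
        t0 = time.perf_counter()
        if not index.drugs:
            raise ValueError("no report maps to any target drug; check the rules file")
        signals = _disp.signal_table(index, comparator=config.comparator,
                                     alpha=config.alpha, level=config.ci_level)
        sig_path = emit("signals", out / "signals.tsv")
        signals.to_csv(sig_path, sep="\t", index=False, float_format="%.12g",
                       lineterminator="\n")
        manifest["stages"]["signals"] = {
            "n_pairs": len(signals),
            "n_events": len(index.events),
            "n_significant": int(signals["significant"].sum()),
        }
        logger.info("signals: %d pairs, %d significant (%.2fs)", len(signals),
                    int(signals["significant"].sum()), time.perf_counter() - t0)

        # -- summarize + filter ---------------------------------------------
        stage = "filter"
        t0 = time.perf_counter()
        matrix = _sm.assemble_matrix(signals, index.drugs, index.events)
        _sm.write_matrix_tsv(matrix, emit("matrix", out / "matrix.tsv"))
        _sm.write_summary_tsv(matrix, emit("summary", out / "summary.tsv"))
        by_count = _sm.filter_events(
            matrix, _sm.FilterConfig(min_event_reports=config.filter.min_event_reports,
                                     require_positive_mean=False))
        filtered = _sm.filter_events(matrix, config.filter)
        _sm.write_matrix_tsv(filtered, emit("filtered_matrix", out / "filtered_matrix.tsv"))
        manifest["stages"]["filter"] = {
            "n_events_input": len(matrix.events),
            "n_events_after_count_filter": len(by_count.events),
            "n_events_after_all_filters": len(filtered.events),
            "min_event_reports": config.filter.min_event_reports,
            "require_positive_mean": config.filter.require_positive_mean,
        }
        logger.info("filter: %d -> %d -> %d events (%.2fs)", len(matrix.events),
                    len(by_count.events), len(filtered.events), time.perf_counter() - t0)

        # -- cluster --------------------------------------------------------
        stage = "cluster"
        t0 = time.perf_counter()
        result = _cluster.two_way_cluster(filtered, k_drugs=config.k_drugs,
                                          k_events=config.k_events,
                                          standardize=config.standardize)
        _cluster.write_linkage_tsv(result.drug_tree, emit("drug_linkage", out / "drug_linkage.tsv"))
        _cluster.write_linkage_tsv(result.event_tree, emit("event_linkage", out / "event_linkage.tsv"))
        _cluster.write_clusters_tsv(result.drug_clusters, emit("drug_clusters", out / "drug_clusters.tsv"))
        _cluster.write_clusters_tsv(result.event_clusters, emit("event_clusters", out / "event_clusters.tsv"))
        for name, tree in (("drug_dendrogram", result.drug_tree),
                           ("event_dendrogram", result.event_tree)):
            p = emit(name, out / f"{name}.nwk")
            with open(p, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(_cluster.to_newick(tree) + "\n")
        result.reordered.rename_axis("drug").to_csv(
            emit("reordered_matrix", out / "reordered_matrix.tsv"),
            sep="\t", float_format="%.12g", lineterminator="\n")
        if config.make_heatmap:
            _cluster.write_heatmap(result, emit("heatmap", out / "heatmap.png"))
        manifest["stages"]["cluster"] = {
            "k_drugs": config.k_drugs,
            "k_events": config.k_events,
            "drug_clusters": {lab: cl for lab, cl in sorted(result.drug_clusters.labels.items())},
            "event_clusters": {ev: cl for ev, cl in sorted(result.event_clusters.labels.items())},
        }
        logger.info("cluster: %d drug / %d event clusters (%.2fs)", config.k_drugs,
                    config.k_events, time.perf_counter() - t0)

        manifest["elapsed_stages_s"] = round(time.perf_counter() - t_start, 3)
        man_path = out / "manifest.json"
        manifest_to_write = {k: v for k, v in manifest.items() if k != "elapsed_stages_s"}
        with open(man_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest_to_write, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest_to_write
    except Exception as exc:
        for p in written:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


# -- YAML config ------------------------------------------------------------

def load_config(path: str | Path, out_dir: str | Path | None = None,
                seed: int | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``synthetic`` holds
    ``n_reports``, ``drugs: [{label, prob, variants?}]``,
    ``events: [{term, prob}]``, ``multipliers: [{drug, event, theta}]``,
    ``aggregation``, ``duplicate_rate``, ``concomitant_prob``.  ``out_dir`` and
    ``seed`` arguments override the file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    syn = None
    if "synthetic" in doc:
        s = doc["synthetic"]
        syn = _syn.SyntheticConfig(
            n_reports=int(s["n_reports"]),
            drugs=tuple(_syn.DrugSpec(label=d["label"], prob=float(d["prob"]),
                                      variants=tuple(d["variants"]) if d.get("variants") else None)
                        for d in s["drugs"]),
            events=tuple(_syn.EventSpec(term=e["term"], prob=float(e["prob"]))
                         for e in s["events"]),
            multipliers={(m["drug"], m["event"]): float(m["theta"])
                         for m in s.get("multipliers", [])},
            aggregation=s.get("aggregation", "max"),
            duplicate_rate=float(s.get("duplicate_rate", 0.05)),
            concomitant_prob=float(s.get("concomitant_prob", 0.2)),
            seed=int(s.get("seed", doc.get("seed", 0))),
        )
    filt = _sm.FilterConfig(
        min_event_reports=int(doc.get("min_event_reports", 100_000)),
        require_positive_mean=bool(doc.get("require_positive_mean", True)),
        top_n=doc.get("top_n"),
    )
    eff_seed = seed if seed is not None else int(doc.get("seed", 0))
    if syn is not None and seed is not None:
        syn = dataclasses.replace(syn, seed=seed)
    return PipelineConfig(
        out_dir=Path(out_dir if out_dir is not None else doc.get("out_dir", "faersig_out")),
        faers_dir=doc.get("faers_dir"),
        synthetic=syn,
        rules_file=doc.get("rules_file"),
        drugs=doc.get("drugs"),
        comparator=doc.get("comparator", "all_reports"),
        alpha=float(doc.get("alpha", _disp.DEFAULT_ALPHA)),
        ci_level=float(doc.get("ci_level", 0.95)),
        filter=filt,
        k_drugs=int(doc.get("k_drugs", 5)),
        k_events=int(doc.get("k_events", 7)),
        standardize=bool(doc.get("standardize", False)),
        make_heatmap=bool(doc.get("make_heatmap", False)),
        seed=eff_seed,
    )
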
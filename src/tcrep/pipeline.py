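"""End-to-end analysis pipeline with a reproducible on-disk layout.

``run_all`` composes every stage — load or simulate a cohort, apply the
functionality filter, profile diversity, quantify the tracked clone,
run the group comparisons, tabulate clone sharing and build the CDR3
similarity network — and writes a deterministic result bundle. Rerunning
with the same configuration and inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .diversity import DEFAULT_ALPHA_GRID, diversity_summary, profiles_frame
from .filtering import filter_set
from .io import load_cohort
from .networks import build_network, network_summary, shared_clones, write_graphml
from .repertoire import DEFAULT_TRACKED_CDR3, RepertoireSet, ValidationError
from .simulate import CohortConfig, generate_cohort, write_cohort
from .stats import compare_diversity, compare_tracked_frequency
from .tracking import correlate_with_flow, composition_table, track_clone, tracked_frequency_table

__all__ = ["RunConfig", "run_all", "StageError"]

logger = logging.getLogger("tcrep")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    output_dir: str
    input_dir: Optional[str] = None
    dialect: str = "simple"
    simulate: Optional[CohortConfig] = None
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID
    network_top_n: int = 50
    composition_top_n: int = 10
    tracked_clones: Sequence[str] = (DEFAULT_TRACKED_CDR3,)
    exclude_tracked_from_sharing: bool = True
    include_tracked_in_network: bool = True
    diversity_alpha: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = plain(dataclasses.asdict(self))
        d["alphas"] = [float(a) for a in self.alphas]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if d.get("simulate") is not None:
            d["simulate"] = CohortConfig(**d["simulate"])
        return cls(**d)


def _table_header(stage: str, config: RunConfig) -> str:
    return (
        f"# tcrep v{__version__} | stage={stage} | seed={config.seed} | "
        f"tracked={','.join(config.tracked_clones)}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, stage: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_table_header(stage, config))
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig, outdir: Path) -> RepertoireSet:
    if (config.input_dir is None) == (config.simulate is None):
        raise ValidationError(
            "exactly one of input_dir and simulate must be provided"
        )
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        write_cohort(cohort, outdir / "input")
        rset = cohort.repertoire_set
    else:
        indir = Path(config.input_dir)
        tables = sorted(
            p for p in indir.glob("*.tsv") if p.name != "sample_sheet.tsv"
        )
        sheet = indir / "sample_sheet.tsv"
        rset = load_cohort(
            tables,
            sample_sheet=sheet if sheet.exists() else None,
            dialect=config.dialect,
            tracked_clones=list(config.tracked_clones),
        )
    return rset


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; return a name -> path map of outputs.

    A failing stage aborts with a :class:`StageError` naming the stage;
    outputs written by earlier stages are kept and a ``FAILED`` marker
    file records where the run stopped.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outputs: dict[str, Path] = {}
    stage = "setup"

    def emit(name: str, path: Path) -> None:
        outputs[name] = path

    try:
        (outdir / "run_config.yaml").write_text(config.to_yaml())
        emit("config", outdir / "run_config.yaml")

        stage = "load"
        rset = _load_inputs(config, outdir)
        logger.info("loaded %d repertoires", len(rset))

        stage = "filter"
        filtered, reports = filter_set(rset)
        report_df = pd.DataFrame([dataclasses.asdict(r) for r in reports.values()])
        _write_table(report_df, outdir / "filter_report.tsv", stage, config)
        emit("filter_report", outdir / "filter_report.tsv")
        for animal_id, rep in filtered.repertoires.items():
            if len(rep) == 0:
                raise ValidationError(
                    f"repertoire {animal_id!r} is empty after filtering"
                )

        stage = "diversity"
        _write_table(
            profiles_frame(filtered, config.alphas),
            outdir / "diversity_profiles.tsv", stage, config,
        )
        emit("diversity_profiles", outdir / "diversity_profiles.tsv")
        _write_table(
            diversity_summary(filtered),
            outdir / "diversity_summary.tsv", stage, config,
        )
        emit("diversity_summary", outdir / "diversity_summary.tsv")

        stage = "track"
        tracked_df = tracked_frequency_table(filtered)
        _write_table(tracked_df, outdir / "tracked_clone.tsv", stage, config)
        emit("tracked_clone", outdir / "tracked_clone.tsv")
        _write_table(
            composition_table(filtered, config.composition_top_n),
            outdir / "composition.tsv", stage, config,
        )
        emit("composition", outdir / "composition.tsv")

        stage = "flow_correlation"
        if filtered.flow_frequencies:
            results = track_clone(filtered, config.tracked_clones[0])
            corr = correlate_with_flow(results, filtered.flow_frequencies)
            (outdir / "flow_correlation.json").write_text(
                pd.Series(corr._asdict()).to_json(indent=2)
            )
            emit("flow_correlation", outdir / "flow_correlation.json")
        else:
            logger.info("no flow frequencies supplied; correlation stage skipped")

        stage = "compare"
        cmp_tracked = compare_tracked_frequency(filtered)
        cmp_div = compare_diversity(filtered, alpha=config.diversity_alpha)
        (outdir / "comparison_tracked.json").write_text(
            cmp_tracked.to_json(indent=2, sort_keys=True)
        )
        (outdir / "comparison_diversity.json").write_text(
            cmp_div.to_json(indent=2, sort_keys=True)
        )
        emit("comparison_tracked", outdir / "comparison_tracked.json")
        emit("comparison_diversity", outdir / "comparison_diversity.json")

        stage = "overlap"
        exclude = (
            list(config.tracked_clones)
            if config.exclude_tracked_from_sharing
            else []
        )
        overlap = shared_clones(filtered, exclude=exclude)
        _write_table(overlap.table, outdir / "shared_clones.tsv", stage, config)
        _write_table(
            overlap.degree_histogram, outdir / "sharing_degree_histogram.tsv",
            stage, config,
        )
        emit("shared_clones", outdir / "shared_clones.tsv")
        emit("sharing_degree_histogram", outdir / "sharing_degree_histogram.tsv")

        stage = "network"
        net_exclude = (
            [] if config.include_tracked_in_network else list(config.tracked_clones)
        )
        net = build_network(filtered, top_n=config.network_top_n, exclude=net_exclude)
        write_graphml(net, outdir / "network.graphml")
        _write_table(net.edge_list(), outdir / "network_edges.tsv", stage, config)
        _write_table(net.node_table(), outdir / "network_nodes.tsv", stage, config)
        (outdir / "network_summary.json").write_text(
            network_summary(net).to_json(indent=2, sort_keys=True)
        )
        emit("network", outdir / "network.graphml")
        emit("network_edges", outdir / "network_edges.tsv")
        emit("network_nodes", outdir / "network_nodes.tsv")
        emit("network_summary", outdir / "network_summary.json")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    return outputs
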
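"""End-to-end pipeline: synthetic inputs -> density -> race MC -> clone stats.

Also hosts the published-construct verification table: the bundled fixture
lists genomic-rescue/deletion/mapping coordinate pairs with their published
lengths, which are recomputed from scratch and compared at the printed
precision.
"""

from __future__ import annotations

import csv
import dataclasses
import importlib.resources
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import scipy
import yaml

from . import __version__
from .caretaker_mc import MCConfig, race_probability_mc
from .competition_stats import call_suppressor, summarize_genotype
from .errors import CaretakerError, ConfigError
from .genome_intervals import (
    bin_gene_density,
    interval_length_kb,
    net_length_change,
    parse_flybase_interval,
    parse_sequence_change,
    write_bed,
    write_density_csv,
    write_flybase_tsv,
)
from .synthetic_data import CloneDatasetSpec, GenomeSpec, gen_clone_dataset, gen_genome, write_clone_csv

__all__ = [
    "RunConfig",
    "RunReport",
    "demo_config",
    "load_config",
    "run_pipeline",
    "verify_reference_intervals",
    "default_fixture_path",
]

log = logging.getLogger("caretaker.pipeline")

STAGES = ("synthetic_data", "genome_intervals", "caretaker_mc", "competition_stats")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    genome: GenomeSpec
    clone_specs: list[CloneDatasetSpec]
    mc: MCConfig
    bin_size_bp: int = 40_000
    control_genotype: str | None = None
    alpha_ratio: float = 0.05
    alpha_norm: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.bin_size_bp < 1:
            raise ConfigError("bin_size_bp must be >= 1")
        labels = [s.genotype_label for s in self.clone_specs]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate genotype labels: {labels}")
        if self.control_genotype is not None and self.control_genotype not in labels:
            raise ConfigError(
                f"control genotype {self.control_genotype!r} not among {labels}"
            )


@dataclass
class RunReport:
    config_echo: dict[str, Any]
    versions: dict[str, str]
    stage_status: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def demo_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """A small, fast configuration exercising every stage."""
    genome = GenomeSpec(
        n_genes=800,
        n_hrpg=66,
        arm_names=("2L", "2R", "3L", "3R", "X"),
        arm_length_bp=(2_000_000,) * 5,
        mean_gene_length_bp=2_000,
        seed=seed,
    )
    clones = [
        CloneDatasetSpec(genotype_label="loser_control", n_discs=52,
                         elimination_strength=0.95, seed=seed + 1),
        CloneDatasetSpec(genotype_label="rescued_candidate", n_discs=45,
                         elimination_strength=0.05, seed=seed + 2),
        CloneDatasetSpec(genotype_label="weak_candidate", n_discs=48,
                         elimination_strength=0.90, seed=seed + 3),
    ]
    mc = MCConfig(G=800, H=66, reps=20_000, seed=seed)
    return RunConfig(out_dir=Path(out_dir), seed=seed, genome=genome,
                     clone_specs=clones, mc=mc,
                     control_genotype="loser_control")


def load_config(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a YAML mapping mirroring the dataclass fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        genome_raw = dict(raw["genome"])
        genome_raw["arm_names"] = tuple(genome_raw["arm_names"])
        genome_raw["arm_length_bp"] = tuple(genome_raw["arm_length_bp"])
        genome = GenomeSpec(**genome_raw)
        clones = [CloneDatasetSpec(**c) for c in raw.get("clone_specs", [])]
        mc = MCConfig(**raw["mc"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: bad configuration: {exc}") from exc
    return RunConfig(
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", ".")),
        seed=int(raw.get("seed", 0)),
        genome=genome,
        clone_specs=clones,
        mc=mc,
        bin_size_bp=int(raw.get("bin_size_bp", 40_000)),
        control_genotype=raw.get("control_genotype"),
        alpha_ratio=float(raw.get("alpha_ratio", 0.05)),
        alpha_norm=float(raw.get("alpha_norm", 0.05)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _versions() -> dict[str, str]:
    return {
        "caretaker": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "python": platform.python_version(),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages in order; stop at the first failure.

    Outputs written by completed stages are left intact; the report names
    the failed stage and the error.  Deterministic for a fixed config.
    """
    report = RunReport(config_echo=dataclasses.asdict(config),
                       versions=_versions())
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    annotation = None
    clones = []
    stage = "synthetic_data"
    try:
        log.info("[%s] generating genome and clone datasets", stage)
        annotation = gen_genome(config.genome)
        write_bed(annotation, out / "genome.bed")
        write_flybase_tsv(annotation, out / "genome.tsv")
        for spec in config.clone_specs:
            clones.extend(gen_clone_dataset(spec))
        write_clone_csv(clones, out / "clones.csv")
        report.outputs += [str(out / "genome.bed"), str(out / "genome.tsv"),
                           str(out / "clones.csv")]
        report.stage_status[stage] = "ok"

        stage = "genome_intervals"
        log.info("[%s] computing binned gene density", stage)
        profiles = bin_gene_density(annotation, bin_size_bp=config.bin_size_bp)
        write_density_csv(profiles, out / "density.csv")
        report.outputs.append(str(out / "density.csv"))
        report.stage_status[stage] = "ok"

        stage = "caretaker_mc"
        log.info("[%s] running mutation-race Monte Carlo", stage)
        est = race_probability_mc(config.mc)
        payload = {"config": dataclasses.asdict(config.mc),
                   "estimate": dataclasses.asdict(est)}
        (out / "race.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        report.outputs.append(str(out / "race.json"))
        report.stage_status[stage] = "ok"

        stage = "competition_stats"
        log.info("[%s] summarizing genotypes and calling suppressors", stage)
        by_geno: dict[str, list] = {}
        for spec in config.clone_specs:
            by_geno[spec.genotype_label] = [
                m for m in clones if m.genotype == spec.genotype_label
            ]
        summaries = {g: summarize_genotype(ms) for g, ms in by_geno.items()}
        with open(out / "summary.csv", "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["genotype", "n", "mean_ratio", "sem"])
            for g in sorted(summaries):
                s = summaries[g]
                writer.writerow([g, s.n, repr(s.mean_ratio), repr(s.sem)])
        report.outputs.append(str(out / "summary.csv"))
        if config.control_genotype is not None:
            control = summaries[config.control_genotype]
            calls = []
            for g in sorted(summaries):
                if g == config.control_genotype:
                    continue
                call = call_suppressor(summaries[g], control,
                                       alpha_ratio=config.alpha_ratio,
                                       alpha_norm=config.alpha_norm)
                calls.append(dataclasses.asdict(call))
            (out / "calls.json").write_text(
                json.dumps(calls, indent=2, sort_keys=True) + "\n")
            report.outputs.append(str(out / "calls.json"))
        report.stage_status[stage] = "ok"
    except CaretakerError as exc:
        report.stage_status[stage] = "failed"
        report.failed_stage = stage
        report.error = f"{type(exc).__name__}: {exc}"
        log.error("[%s] failed: %s", stage, exc)

    (out / "report.json").write_text(report.to_json() + "\n")
    return report


def default_fixture_path() -> Path:
    res = importlib.resources.files("caretaker").joinpath(
        "data/reference_constructs.csv")
    return Path(str(res))


def verify_reference_intervals(
    fixture_path: str | Path | None = None,
) -> list[dict[str, Any]]:
    """Recompute published construct lengths from their coordinate pairs.

    Returns one row per fixture entry with the published value, the value
    recomputed from the coordinates, and whether they match exactly at the
    printed precision.  An empty fixture yields an empty table.
    """
    path = Path(fixture_path) if fixture_path is not None else default_fixture_path()
    rows: list[dict[str, Any]] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            kind = rec["kind"]
            expected = float(rec["expected"])
            if kind == "interval":
                iv = parse_flybase_interval(rec["text"])
                computed = interval_length_kb(iv, decimals=int(rec["decimals"]))
            elif kind == "change":
                change = parse_sequence_change(rec["text"], arm=rec["arm"],
                                               position=int(rec["position"]))
                computed = float(net_length_change(change))
            else:
                raise ConfigError(f"{path}: unknown fixture kind {kind!r}")
            rows.append({
                "label": rec["label"],
                "units": rec["units"],
                "published": expected,
                "computed": computed,
                "match": computed == expected,
            })
    return rows
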
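"""Synthetic inputs: genome annotations and twin-spot clone-area datasets.

Everything downstream (density maps, the mutation-race simulation, the
clone statistics) can be exercised without any external download.  All
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .competition_stats import CloneMeasurement, per_disc_ratio
from .errors import ConfigError, InputError
from .genome_intervals import GeneRecord, GenomeAnnotation, GenomicInterval

__all__ = [
    "GenomeSpec",
    "CloneDatasetSpec",
    "gen_genome",
    "gen_clone_dataset",
    "estimate_elimination_strength",
    "write_clone_csv",
    "read_clone_csv",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic diploid genome annotation."""

    n_genes: int
    n_hrpg: int
    arm_names: tuple[str, ...]
    arm_length_bp: tuple[int, ...]
    mean_gene_length_bp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError(f"n_genes must be >= 0, got {self.n_genes}")
        if not 0 <= self.n_hrpg <= self.n_genes:
            raise ConfigError(
                f"need 0 <= n_hrpg <= n_genes, got n_hrpg={self.n_hrpg}, "
                f"n_genes={self.n_genes}"
            )
        if len(self.arm_names) != len(self.arm_length_bp):
            raise ConfigError("arm_names and arm_length_bp must have equal length")
        if self.n_genes > 0 and not self.arm_names:
            raise ConfigError("cannot place genes without arms")
        if len(set(self.arm_names)) != len(self.arm_names):
            raise ConfigError("arm names must be unique")
        for arm, length in zip(self.arm_names, self.arm_length_bp):
            if length < 1:
                raise ConfigError(f"arm {arm!r} length must be >= 1, got {length}")
        if self.mean_gene_length_bp < 1:
            raise ConfigError("mean_gene_length_bp must be >= 1")


@dataclass(frozen=True)
class CloneDatasetSpec:
    """Parameters of a synthetic clone-area dataset for one genotype.

    ``elimination_strength`` (e) attenuates the loser twin relative to its
    winner twin: e = 0 leaves ratios near 1 (rescued), e = 1 forces them
    to 0 (fully eliminated).
    """

    genotype_label: str
    n_discs: int
    elimination_strength: float
    winner_area_log_mean: float = math.log(10_000.0)
    winner_area_log_sd: float = 0.4
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        # n_discs = 0 is tolerated (empty dataset) so that degenerate pipeline
        # configurations fail at the statistics stage, not at generation.
        if self.n_discs < 0:
            raise ConfigError(f"n_discs must be >= 0, got {self.n_discs}")
        if not 0.0 <= self.elimination_strength <= 1.0:
            raise ConfigError(
                f"elimination_strength must be in [0, 1], got "
                f"{self.elimination_strength}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


def gen_genome(spec: GenomeSpec) -> GenomeAnnotation:
    """Generate a genome annotation with non-overlapping genes.

    Genes are assigned to arms with probability proportional to arm length,
    given lengths ~ max(1, Poisson(mean_gene_length_bp)), and placed
    uniformly at random without overlap.  Exactly ``n_hrpg`` genes, sampled
    uniformly without replacement across the whole genome, carry the hRPG
    flag — so hRPGs end up broadly distributed across arms.
    """
    arms = dict(zip(spec.arm_names, spec.arm_length_bp))
    if spec.n_genes == 0:
        return GenomeAnnotation(genes=[], arm_length_bp=arms)

    rng = np.random.default_rng(spec.seed)
    lengths = np.maximum(1, rng.poisson(spec.mean_gene_length_bp, spec.n_genes))
    total_capacity = sum(spec.arm_length_bp)
    if int(lengths.sum()) > total_capacity:
        raise ConfigError(
            f"total gene footprint {int(lengths.sum())} bp does not fit in "
            f"{total_capacity} bp of arm sequence"
        )

    arm_lens = np.asarray(spec.arm_length_bp, dtype=float)
    assignment = rng.choice(len(spec.arm_names), size=spec.n_genes,
                            p=arm_lens / arm_lens.sum())
    per_arm: list[list[int]] = [[] for _ in spec.arm_names]
    for gi, ai in enumerate(assignment):
        per_arm[ai].append(gi)

    # Rebalance deterministically if weighted assignment overfilled an arm.
    def _load(ai: int) -> int:
        return int(sum(lengths[g] for g in per_arm[ai]))

    moved = True
    while moved:
        moved = False
        for ai in range(len(spec.arm_names)):
            while _load(ai) > spec.arm_length_bp[ai]:
                free = [(spec.arm_length_bp[bj] - _load(bj), bj)
                        for bj in range(len(spec.arm_names)) if bj != ai]
                slack, bj = max(free)
                gi = per_arm[ai].pop()
                if lengths[gi] > slack:
                    raise ConfigError(
                        "gene footprint cannot be packed into the arms"
                    )
                per_arm[bj].append(gi)
                moved = True

    genes: list[GeneRecord] = []
    hrpg_idx = set(rng.choice(spec.n_genes, size=spec.n_hrpg, replace=False).tolist())
    for ai, arm in enumerate(spec.arm_names):
        idx = per_arm[ai]
        if not idx:
            continue
        arm_len = spec.arm_length_bp[ai]
        lens = lengths[idx]
        free = arm_len - int(lens.sum())
        # Sorted uniform offsets into the free space keep genes disjoint.
        offsets = np.floor(np.sort(rng.random(len(idx))) * (free + 1)).astype(int)
        cum = np.concatenate([[0], np.cumsum(lens)[:-1]])
        for j, gi in enumerate(idx):
            start = int(offsets[j] + cum[j] + 1)
            end = start + int(lens[j]) - 1
            genes.append(
                GeneRecord(
                    gene_id=f"gene{gi:06d}",
                    interval=GenomicInterval(arm, start, end),
                    is_hrpg=gi in hrpg_idx,
                )
            )
    genes.sort(key=lambda g: g.gene_id)
    return GenomeAnnotation(genes=genes, arm_length_bp=arms)


def gen_clone_dataset(spec: CloneDatasetSpec) -> list[CloneMeasurement]:
    """Generate per-disc loser/winner twin areas for one genotype.

    Winner area W ~ lognormal(log_mean, log_sd); loser area
    L = W * (1 - e) * exp(eps) with eps ~ Normal(0, noise_sd), truncated
    at 0.  Each disc draws from its own spawned substream, so growing
    ``n_discs`` never perturbs earlier discs.
    """
    e = spec.elimination_strength
    out: list[CloneMeasurement] = []
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_discs)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        w = float(rng.lognormal(spec.winner_area_log_mean, spec.winner_area_log_sd))
        eps = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        loser = max(0.0, w * (1.0 - e) * math.exp(eps))
        out.append(
            CloneMeasurement(
                disc_id=f"{spec.genotype_label}_d{i:05d}",
                genotype=spec.genotype_label,
                loser_area=loser,
                winner_area=w,
            )
        )
    return out


def estimate_elimination_strength(
    measurements: Sequence[CloneMeasurement], noise_sd: float
) -> float:
    """Recover e from generated data: 1 - mean(L/W) / exp(noise_sd**2 / 2)."""
    if not measurements:
        raise InputError("no measurements")
    ratios = [per_disc_ratio(m) for m in measurements]
    return 1.0 - float(np.mean(ratios)) / math.exp(noise_sd ** 2 / 2.0)


def write_clone_csv(
    measurements: Iterable[CloneMeasurement], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["disc_id", "genotype", "loser_area", "winner_area"])
        for m in measurements:
            writer.writerow([m.disc_id, m.genotype,
                             repr(m.loser_area), repr(m.winner_area)])


def read_clone_csv(path: str | Path) -> list[CloneMeasurement]:
    out: list[CloneMeasurement] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"disc_id", "genotype", "loser_area", "winner_area"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            out.append(
                CloneMeasurement(
                    disc_id=row["disc_id"],
                    genotype=row["genotype"],
                    loser_area=float(row["loser_area"]),
                    winner_area=float(row["winner_area"]),
                )
            )
    return out
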
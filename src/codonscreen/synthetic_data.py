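"""Synthetic screen records, toy genomes and random coding sequences.

Every pipeline stage in this package can be exercised without external
downloads: this module generates per-cross phenotype counts with planted
deficiency effects, toy genomes with deficiencies / gene groups / a planted
enriched group, and random coding sequences drawn from a codon-usage table —
each with the planted truth recorded so classification can be checked
against it.

Noise model
-----------
A cross starts from ``n`` progeny; the number of eclosed (scored) flies is
Binomial(n, eclosion_p) and the mild/moderate/severe counts are
Multinomial(eclosed, probs).  A planted effect perturbs the affected
transgene(s) by moving category probability mass stepwise along
mild -> moderate -> severe (enhancers) or the reverse (suppressors) until
the mean severity has shifted by ``severity_shift`` score units (one
category step = 2.0 units on the 1/3/5 scale), and multiplies the eclosion
probability by ``lethality_factor``.

Randomness is consumed through named sub-streams (effects, crosses, genome,
groups, cds) derived from the single mandatory seed, so e.g. adding
deficiencies does not perturb the genome draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_engine import (
    SENSE_CODONS,
    CodingSequence,
    CodonUsageTable,
)
from .genome_mapping import DeficiencyRecord, GeneGroup, GeneModel, GenomicInterval
from .screen_scoring import CrossRecord, PhenotypeCounts

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SimulatedGenome",
    "EFFECT_TYPES",
    "stream_rng",
    "shift_severity_probs",
    "simulate_cross",
    "make_effect",
    "draw_effects",
    "simulate_screen",
    "simulate_genome",
    "simulate_cds",
    "true_category",
]

EFFECT_TYPES = (
    "null",
    "general_enhancer",
    "general_suppressor",
    "common_only",
    "rare_only",
)

_CATEGORY_SPACING = 2.0  # score units between adjacent severity categories


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG for a named sub-stream of ``seed``."""
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


@dataclass(frozen=True)
class PlantedEffect:
    """Ground truth for one deficiency in a simulated screen.

    ``severity_shift`` is the intended mean-severity displacement in score
    units for each affected transgene (positive = toward severe);
    ``lethality_factor`` multiplies the eclosion probability.
    """

    df_id: str
    effect_type: str
    severity_shift: float = 0.0
    lethality_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown effect type {self.effect_type!r}")
        if self.lethality_factor <= 0:
            raise ValueError("lethality_factor must be positive")
        if self.effect_type == "null" and (
            self.severity_shift != 0.0 or self.lethality_factor != 1.0
        ):
            raise ValueError("null effects must have zero shift and factor 1")

    def affects(self, transgene: str) -> bool:
        if self.effect_type == "null":
            return False
        if self.effect_type.startswith("general"):
            return True
        return self.effect_type == f"{transgene}_only"


def true_category(effect: PlantedEffect) -> str:
    """Screen category a perfectly powered screen would assign."""
    return {
        "null": "not_modifier",
        "general_enhancer": "enhancer",
        "general_suppressor": "suppressor",
        "common_only": "differential",
        "rare_only": "differential",
    }[effect.effect_type]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated deficiency screen.

    Defaults mirror the screen being emulated: ~30 progeny per common-codon
    cross and ~60 per rare-codon cross, baseline category probabilities
    giving control severities of 3.4 (common) vs 1.7 (rare) — a roughly
    two-fold stronger common-codon phenotype — and an effect mix of 16%
    general enhancers, 7% general suppressors and 3% differential modifiers.
    """

    n_dfs: int
    seed: int
    progeny_common: int = 30
    progeny_rare: int = 60
    baseline_probs_common: tuple[float, float, float] = (0.2, 0.4, 0.4)
    baseline_probs_rare: tuple[float, float, float] = (0.7, 0.25, 0.05)
    eclosion_p: float = 0.8
    effect_mix: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.74,
            "general_enhancer": 0.16,
            "general_suppressor": 0.07,
            "common_only": 0.015,
            "rare_only": 0.015,
        }
    )
    severity_shift: float = 2.0
    lethality_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_dfs < 1:
            raise ValueError("n_dfs must be positive")
        for probs in (self.baseline_probs_common, self.baseline_probs_rare):
            _check_simplex(probs)
        if not (0.0 < self.eclosion_p <= 1.0):
            raise ValueError("eclosion_p must lie in (0, 1]")
        unknown = set(self.effect_mix) - set(EFFECT_TYPES)
        if unknown:
            raise ValueError(f"unknown effect types in mix: {sorted(unknown)}")
        if abs(sum(self.effect_mix.values()) - 1.0) > 1e-9:
            raise ValueError("effect mix proportions must sum to 1")

    def progeny(self, transgene: str) -> int:
        return self.progeny_common if transgene == "common" else self.progeny_rare

    def baseline_probs(self, transgene: str) -> tuple[float, float, float]:
        return (
            self.baseline_probs_common
            if transgene == "common"
            else self.baseline_probs_rare
        )


def _check_simplex(probs) -> None:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (3,) or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{probs!r} is not a 3-category probability vector")


def shift_severity_probs(
    probs: tuple[float, float, float], shift: float
) -> tuple[float, float, float]:
    """Move category mass so the mean severity changes by ``shift`` units.

    Positive shifts move mass mild -> moderate -> severe, negative the
    reverse.  Mass moves one step at a time (each unit of mass moved one
    step changes the mean by the category spacing, 2.0), so arbitrarily
    large shifts saturate at all-severe / all-mild.
    """
    _check_simplex(probs)
    p = list(map(float, probs))
    remaining = abs(float(shift))
    forward = shift >= 0
    while remaining > 1e-12:
        lo, hi = (0, 1) if forward else (2, 1)
        movable = _CATEGORY_SPACING * (p[lo] + p[hi])
        if movable <= 1e-15:
            break
        phi = min(1.0, remaining / movable)
        if forward:
            moved_mild, moved_mod = phi * p[0], phi * p[1]
            p[0] -= moved_mild
            p[1] += moved_mild - moved_mod
            p[2] += moved_mod
        else:
            moved_sev, moved_mod = phi * p[2], phi * p[1]
            p[2] -= moved_sev
            p[1] += moved_sev - moved_mod
            p[0] += moved_mod
        remaining -= phi * movable
        if phi < 1.0:
            break
    return (p[0], p[1], p[2])


def simulate_cross(
    n: int,
    probs: tuple[float, float, float],
    eclosion_p: float,
    rng: np.random.Generator,
) -> tuple[PhenotypeCounts, int]:
    """One cross: Binomial eclosion then Multinomial category counts."""
    if n < 1:
        raise ValueError("n must be positive")
    _check_simplex(probs)
    if not (0.0 < eclosion_p <= 1.0):
        raise ValueError("eclosion_p must lie in (0, 1]")
    eclosed = int(rng.binomial(n, eclosion_p))
    counts = rng.multinomial(eclosed, probs)
    return PhenotypeCounts(int(counts[0]), int(counts[1]), int(counts[2])), eclosed


def make_effect(
    df_id: str,
    effect_type: str,
    severity_shift: float,
    lethality_factor: float = 1.0,
) -> PlantedEffect:
    """Planted effect with the sign convention applied for suppressors."""
    if effect_type == "null":
        return PlantedEffect(df_id, "null")
    shift = -abs(severity_shift) if effect_type == "general_suppressor" else abs(severity_shift)
    return PlantedEffect(df_id, effect_type, shift, lethality_factor)


def draw_effects(cfg: SimulationConfig) -> list[PlantedEffect]:
    """Random effect assignment for every Df, from the configured mix."""
    rng = stream_rng(cfg.seed, "effects")
    types = sorted(cfg.effect_mix)
    probs = np.array([cfg.effect_mix[t] for t in types])
    width = len(str(cfg.n_dfs))
    drawn = rng.choice(len(types), size=cfg.n_dfs, p=probs)
    return [
        make_effect(
            f"Df{i + 1:0{width}d}", types[j], cfg.severity_shift, cfg.lethality_factor
        )
        for i, j in enumerate(drawn)
    ]


def simulate_screen(
    cfg: SimulationConfig, effects: list[PlantedEffect] | None = None
) -> tuple[list[CrossRecord], pd.DataFrame]:
    """Full two-stage screen: control and Df crosses plus the truth table.

    One transgene-only control cross per transgene per stage; every Df is
    crossed to both transgenes at both stages (the screen runner decides
    which secondary records to evaluate).  Returns the records and a truth
    table with columns df_id, effect_type, severity_shift, lethality_factor,
    true_category.
    """
    if effects is None:
        effects = draw_effects(cfg)
    if len(effects) != cfg.n_dfs:
        raise ValueError("one planted effect per Df is required")
    rng = stream_rng(cfg.seed, "crosses")

    records: list[CrossRecord] = []
    for stage in ("primary", "secondary"):
        for transgene in ("common", "rare"):
            counts, eclosed = simulate_cross(
                cfg.progeny(transgene),
                cfg.baseline_probs(transgene),
                cfg.eclosion_p,
                rng,
            )
            records.append(CrossRecord("", transgene, stage, counts, eclosed))
        for eff in effects:
            for transgene in ("common", "rare"):
                probs = cfg.baseline_probs(transgene)
                ecl_p = cfg.eclosion_p
                if eff.affects(transgene):
                    probs = shift_severity_probs(probs, eff.severity_shift)
                    ecl_p = min(1.0, ecl_p * eff.lethality_factor)
                counts, eclosed = simulate_cross(
                    cfg.progeny(transgene), probs, ecl_p, rng
                )
                records.append(
                    CrossRecord(eff.df_id, transgene, stage, counts, eclosed)
                )

    truth = pd.DataFrame(
        {
            "df_id": [e.df_id for e in effects],
            "effect_type": [e.effect_type for e in effects],
            "severity_shift": [e.severity_shift for e in effects],
            "lethality_factor": [e.lethality_factor for e in effects],
            "true_category": [true_category(e) for e in effects],
        }
    )
    return records, truth


# --- toy genomes ------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedGenome:
    """Toy genome with construction bookkeeping as planted truth."""

    genes: list[GeneModel]
    dfs: list[DeficiencyRecord]
    groups: list[GeneGroup]
    known_modifiers: frozenset[str]
    query_genes: frozenset[str]
    enriched_group_id: str
    df_truth: dict[str, frozenset[str]]  # df_id -> gene ids covered, by construction


def simulate_genome(
    n_genes: int,
    n_dfs: int,
    genome_length: int,
    seed: int,
    n_groups: int = 6,
    chrom: str = "chr2L",
) -> SimulatedGenome:
    """Non-overlapping genes, deficiencies each covering >= 1 gene, random
    gene groups with one group planted to be enriched in a designated query
    set, and a random known-modifier list.
    """
    if min(n_genes, n_dfs, genome_length) < 1:
        raise ValueError("sizes must be positive")
    rng = stream_rng(seed, "genome")
    gene_len, min_gap = 200, 20
    if n_genes * (gene_len + min_gap) > genome_length:
        raise ValueError(
            f"genome length {genome_length} too short for {n_genes} genes"
        )

    slack = genome_length - n_genes * (gene_len + min_gap)
    extra_gaps = rng.multinomial(slack, np.full(n_genes, 1.0 / n_genes))
    genes: list[GeneModel] = []
    pos = 0
    width = len(str(n_genes))
    for i in range(n_genes):
        pos += min_gap + int(extra_gaps[i])
        genes.append(
            GeneModel(f"gene{i + 1:0{width}d}", GenomicInterval(chrom, pos, pos + gene_len))
        )
        pos += gene_len

    dfs: list[DeficiencyRecord] = []
    df_truth: dict[str, frozenset[str]] = {}
    dfw = len(str(n_dfs))
    for j in range(n_dfs):
        start_idx = int(rng.integers(0, n_genes))
        span = int(rng.integers(1, min(8, n_genes - start_idx) + 1))
        block = genes[start_idx : start_idx + span]
        left = block[0].interval.start - int(rng.integers(0, min_gap))
        right = block[-1].interval.end + int(rng.integers(0, min_gap))
        df_id = f"Df{j + 1:0{dfw}d}"
        dfs.append(DeficiencyRecord(df_id, GenomicInterval(chrom, max(0, left), right)))
        df_truth[df_id] = frozenset(g.gene_id for g in block)

    grng = stream_rng(seed, "groups")
    all_ids = [g.gene_id for g in genes]
    n_query = max(2, n_genes // 4)
    query = frozenset(
        grng.choice(all_ids, size=n_query, replace=False).tolist()
    )
    group_size = max(3, n_genes // 10)
    groups: list[GeneGroup] = []
    for k in range(n_groups - 1):
        members = grng.choice(all_ids, size=min(group_size, n_genes), replace=False)
        groups.append(GeneGroup(f"group{k + 1}", frozenset(members.tolist())))
    # planted enriched group: drawn almost entirely from the query set
    q_list = sorted(query)
    n_from_query = min(len(q_list), max(2, group_size - 1))
    planted = set(grng.choice(q_list, size=n_from_query, replace=False).tolist())
    outside = sorted(set(all_ids) - query)
    if outside and len(planted) < group_size:
        planted |= set(
            grng.choice(outside, size=group_size - len(planted), replace=False).tolist()
        )
    enriched_id = f"group{n_groups}"
    groups.append(GeneGroup(enriched_id, frozenset(planted)))

    known = frozenset(
        grng.choice(all_ids, size=max(1, n_genes // 10), replace=False).tolist()
    )
    return SimulatedGenome(genes, dfs, groups, known, query, enriched_id, df_truth)


# --- random coding sequences ------------------------------------------------


def simulate_cds(
    n_codons: int,
    table: CodonUsageTable,
    seed: int,
    terminal_stop: bool = False,
    seq_id: str | None = None,
) -> CodingSequence:
    """Random CDS: ATG start, sense codons drawn from the table's genome
    frequencies, no internal stops, optional TAA terminal stop.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be positive")
    rng = stream_rng(seed, "cds")
    freqs = np.array([table.genome_frequency[c] for c in SENSE_CODONS])
    freqs = freqs / freqs.sum()
    draws = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=freqs)
    codons = ["ATG"] + [SENSE_CODONS[i] for i in draws]
    if terminal_stop:
        codons.append("TAA")
    return CodingSequence(seq_id or f"cds_seed{seed}", "".join(codons))
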
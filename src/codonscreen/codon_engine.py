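"""Synonymous codon recoding and codon-usage metrics.

This module manipulates the codon content of a coding sequence without touching
the encoded protein.  It supports recoding every codon to the most common (or
most rare) synonym in a genome-wide usage table, or substituting a chosen
fraction of positions with rare synonyms dispersed along the sequence.  It also
computes the Codon Adaptation Index (CAI, the geometric mean of per-codon
relative adaptiveness values), GC content, and ungapped pairwise nucleotide
identity — the metrics typically used to characterise such recoded transgenes.

Conventions
-----------
* DNA alphabet is canonical internally; RNA input (``U``) is transliterated to
  ``T`` on load.
* CAI includes every sense codon: single-codon families (ATG, TGG) contribute
  w = 1.  Stop codons never contribute.
* Zero-count codons in a usage table are smoothed to 0.5 counts before
  normalisation so every relative adaptiveness is strictly positive and the
  geometric mean is defined.
* Ties at a family's extreme frequency break to the lexicographically smallest
  codon, deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodonUsageError",
    "SequenceError",
    "SENSE_CODONS",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "CODON_TO_AA",
    "CodonUsageTable",
    "CodingSequence",
    "RecodingScheme",
    "RecodedVariant",
    "default_usage_table",
    "load_codon_usage",
    "relative_adaptiveness",
    "compute_cai",
    "gc_content",
    "reverse_complement",
    "translate",
    "recode",
    "nucleotide_identity",
    "read_fasta",
    "write_fasta",
]


class CodonUsageError(ValueError):
    """Malformed or incomplete codon-usage table."""


class SequenceError(ValueError):
    """Coding sequence violating the module's preconditions."""


# --- genetic code -----------------------------------------------------------

_STANDARD_TABLE = _BioCodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, standard genetic code, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

#: amino acid -> sorted tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
    SYNONYMOUS_FAMILIES[CODON_TO_AA[_codon]] += (_codon,)

_VALID_BASES = frozenset("ACGT")


# --- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon usage of an organism, normalised within synonymous families.

    ``usage`` maps each of the 61 sense codons to its relative frequency
    within its synonymous family (frequencies of a family sum to 1).
    ``genome_frequency`` maps each sense codon to its frequency among all
    sense codons of the source table; it is used when sampling random coding
    sequences that mimic the organism.
    """

    organism_label: str
    usage: Mapping[str, float]
    genome_frequency: Mapping[str, float] = field(default_factory=dict)
    genetic_code_id: int = 1

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.usage)
        if missing:
            raise CodonUsageError(f"missing sense codons: {sorted(missing)}")
        extra = set(self.usage) - set(SENSE_CODONS)
        if extra:
            raise CodonUsageError(f"non-sense codons present: {sorted(extra)}")
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            total = sum(self.usage[c] for c in codons)
            if abs(total - 1.0) > 1e-9:
                raise CodonUsageError(
                    f"family {aa} frequencies sum to {total!r}, expected 1"
                )
        if any(self.usage[c] <= 0 for c in SENSE_CODONS):
            raise CodonUsageError("all within-family frequencies must be > 0")


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence (optionally with one terminal stop).

    By default ambiguity codes are rejected; with ``allow_ambiguous=True``
    codons containing non-ACGT characters are tolerated and skipped by
    recoding and CAI.
    """

    id: str
    nucleotides: str
    allow_ambiguous: bool = False

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper().replace("U", "T")
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) < 3 or len(nt) % 3:
            raise SequenceError(
                f"{self.id}: length {len(nt)} is not a positive multiple of 3"
            )
        bad = set(nt) - _VALID_BASES
        if bad and not self.allow_ambiguous:
            raise SequenceError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        codons = self.codons
        for i, codon in enumerate(codons):
            if codon in STOP_CODONS and i != len(codons) - 1:
                raise SequenceError(f"{self.id}: internal stop codon at codon {i}")

    @property
    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]

    @property
    def has_terminal_stop(self) -> bool:
        return self.codons[-1] in STOP_CODONS

    @property
    def coding_codons(self) -> list[str]:
        """Codons excluding a terminal stop, if present."""
        codons = self.codons
        return codons[:-1] if codons[-1] in STOP_CODONS else codons


@dataclass(frozen=True)
class RecodingScheme:
    """How to rewrite synonymous codons.

    ``extremal_common`` / ``extremal_rare`` replace every codon by its
    family's most / least used synonym.  ``fractional_rare`` replaces
    ``round(fraction * R)`` of the R recodable positions (codons whose family
    has more than one member) with the rare synonym; positions are either
    evenly dispersed (deterministic) or drawn from a seeded RNG.
    """

    mode: str
    fraction: float | None = None
    pattern: str = "dispersed_deterministic"
    seed: int | None = None

    _MODES = ("extremal_common", "extremal_rare", "fractional_rare")
    _PATTERNS = ("dispersed_deterministic", "seeded_random")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pattern not in self._PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.mode == "fractional_rare":
            if self.fraction is None or not (0.0 <= self.fraction <= 1.0):
                raise ValueError("fractional_rare requires fraction in [0, 1]")
            if self.pattern == "seeded_random" and self.seed is None:
                raise ValueError("seeded_random pattern requires a seed")
        elif self.fraction is not None:
            raise ValueError("fraction is only meaningful for fractional_rare")


@dataclass(frozen=True)
class RecodedVariant:
    """A synonymous recoding of a source sequence plus its summary metrics."""

    source_id: str
    scheme: RecodingScheme
    nucleotides: str
    cai: float
    gc_content: float
    identity_to_source: float
    warning: str | None = None


# --- codon usage tables -----------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"
_SMOOTH_FLOOR = 0.5


def load_codon_usage(path: str | Path, organism_label: str = "") -> CodonUsageTable:
    """Read a TSV/CSV codon-usage table with columns ``codon`` and ``count``
    (or ``frequency``) and normalise counts within each synonymous family.

    RNA-alphabet codons are transliterated to DNA; stop codons in the input
    are ignored; zero counts are smoothed to a floor of 0.5 before
    normalisation.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "codon" not in df.columns:
        raise CodonUsageError(f"{path}: no 'codon' column")
    value_col = next((c for c in ("count", "frequency") if c in df.columns), None)
    if value_col is None:
        raise CodonUsageError(f"{path}: need a 'count' or 'frequency' column")

    raw: dict[str, float] = {}
    for codon, value in zip(df["codon"], df[value_col]):
        codon = str(codon).strip().upper().replace("U", "T")
        if codon in STOP_CODONS:
            continue
        if codon not in CODON_TO_AA:
            raise CodonUsageError(f"{path}: invalid codon {codon!r}")
        if value < 0:
            raise CodonUsageError(f"{path}: negative value for codon {codon}")
        raw[codon] = float(value)

    missing = set(SENSE_CODONS) - set(raw)
    if missing:
        raise CodonUsageError(f"{path}: missing sense codons {sorted(missing)}")

    smoothed = {c: (v if v > 0 else _SMOOTH_FLOOR) for c, v in raw.items()}
    usage: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(smoothed[c] for c in codons)
        if total <= 0:
            raise CodonUsageError(f"{path}: non-positive total for family {aa}")
        for c in codons:
            usage[c] = smoothed[c] / total
    grand = sum(smoothed.values())
    genome_frequency = {c: smoothed[c] / grand for c in SENSE_CODONS}
    label = organism_label or Path(path).stem
    return CodonUsageTable(label, usage, genome_frequency)


def default_usage_table() -> CodonUsageTable:
    """The packaged synthetic D. melanogaster usage table (see its header)."""
    return load_codon_usage(
        _DATA_DIR / "dmel_codon_usage_synthetic.tsv",
        organism_label="D. melanogaster (synthetic)",
    )


def relative_adaptiveness(table: CodonUsageTable) -> dict[str, float]:
    """Per-codon w values: family frequency divided by the family maximum.

    The most-used codon of every family (all of them, on ties) has w = 1.
    """
    w: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        fmax = max(table.usage[c] for c in codons)
        for c in codons:
            w[c] = table.usage[c] / fmax
    return w


# --- sequence metrics -------------------------------------------------------


def compute_cai(seq: CodingSequence, table: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of w over all sense codons.

    A terminal stop is excluded; Met and Trp contribute w = 1; with a
    permissive sequence, codons containing ambiguity codes are skipped.
    """
    w = relative_adaptiveness(table)
    logs = [math.log(w[c]) for c in seq.coding_codons if c in w]
    if not logs:
        raise SequenceError(f"{seq.id}: no scorable codons")
    return math.exp(math.fsum(logs) / len(logs))


def gc_content(seq: str) -> float:
    """Fraction of G and C bases in a DNA string."""
    if not seq:
        raise SequenceError("empty sequence has no GC content")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: CodingSequence) -> str:
    """Standard-code translation; a terminal stop is rendered as ``*``.

    CodingSequence construction already rejects internal stops with the
    offending codon index.
    """
    out = []
    for codon in seq.codons:
        if codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


# --- recoding ---------------------------------------------------------------


def _family_extreme(table: CodonUsageTable, codon: str, rare: bool) -> str:
    family = SYNONYMOUS_FAMILIES[CODON_TO_AA[codon]]
    if rare:
        extreme = min(table.usage[c] for c in family)
    else:
        extreme = max(table.usage[c] for c in family)
    # lexicographically smallest among ties; families are stored sorted
    return next(c for c in family if table.usage[c] == extreme)


def _dispersed_ranks(n_recodable: int, k: int) -> list[int]:
    """k evenly spaced ranks among n recodable positions, starting at rank 0.

    For k = n/2 this is every second recodable codon; chosen ranks are never
    adjacent unless k forces it (k > ceil(n/2)).
    """
    return [(i * n_recodable) // k for i in range(k)]


def recode(
    seq: CodingSequence, table: CodonUsageTable, scheme: RecodingScheme
) -> RecodedVariant:
    """Rewrite synonymous codons of ``seq`` according to ``scheme``.

    The amino-acid sequence is preserved by construction; a terminal stop and
    (in permissive sequences) ambiguous codons are left untouched.
    """
    codons = seq.codons
    n = len(codons)
    coding_n = len(seq.coding_codons)

    recodable = [
        i
        for i in range(coding_n)
        if codons[i] in CODON_TO_AA
        and len(SYNONYMOUS_FAMILIES[CODON_TO_AA[codons[i]]]) > 1
    ]
    warning = None
    new = list(codons)

    if scheme.mode in ("extremal_common", "extremal_rare"):
        rare = scheme.mode == "extremal_rare"
        for i in range(coding_n):
            if codons[i] in CODON_TO_AA:
                new[i] = _family_extreme(table, codons[i], rare)
    else:  # fractional_rare
        r = len(recodable)
        k = int(scheme.fraction * r + 0.5)
        if r == 0 and scheme.fraction > 0:
            warning = "no recodable positions; sequence returned unchanged"
            k = 0
        if k:
            if scheme.pattern == "dispersed_deterministic":
                ranks = _dispersed_ranks(r, k)
            else:
                rng = np.random.default_rng(scheme.seed)
                ranks = sorted(rng.choice(r, size=k, replace=False).tolist())
            for rank in ranks:
                i = recodable[rank]
                new[i] = _family_extreme(table, codons[i], rare=True)

    nt = "".join(new)
    variant_seq = CodingSequence(f"{seq.id}|{scheme.mode}", nt, seq.allow_ambiguous)
    return RecodedVariant(
        source_id=seq.id,
        scheme=scheme,
        nucleotides=nt,
        cai=compute_cai(variant_seq, table),
        gc_content=gc_content(nt),
        identity_to_source=nucleotide_identity(seq.nucleotides, nt),
        warning=warning,
    )


def nucleotide_identity(a: str, b: str) -> float:
    """Percent identical positions of two equal-length, ungapped sequences."""
    if len(a) != len(b):
        raise SequenceError(
            f"unequal lengths ({len(a)} vs {len(b)}); alignment is out of scope"
        )
    if not a:
        raise SequenceError("empty sequences have no identity")
    matches = sum(x == y for x, y in zip(a.upper(), b.upper()))
    return 100.0 * matches / len(a)


# --- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path, allow_ambiguous: bool = False) -> list[CodingSequence]:
    return [
        CodingSequence(rec.id, str(rec.seq), allow_ambiguous)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)
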
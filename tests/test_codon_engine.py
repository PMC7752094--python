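"""Codon-usage tables, recoding schemes and sequence metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonscreen import (
    CodingSequence,
    CodonUsageError,
    RecodingScheme,
    SequenceError,
    compute_cai,
    gc_content,
    load_codon_usage,
    nucleotide_identity,
    recode,
    relative_adaptiveness,
    translate,
)
from codonscreen.codon_engine import (
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    read_fasta,
    reverse_complement,
    write_fasta,
)
from codonscreen.synthetic_data import simulate_cds

from conftest import random_table


def _write_table(tmp_path, counts, name="usage.tsv"):
    path = tmp_path / name
    lines = ["codon\tcount"] + [f"{c}\t{v}" for c, v in counts.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def _full_counts(**overrides):
    counts = {c: 10.0 for c in SENSE_CODONS}
    counts.update(overrides)
    return counts


class TestLoadCodonUsage:
    def test_counts_normalized_within_family(self, tmp_path):
        path = _write_table(
            tmp_path, _full_counts(GGA=20, GGC=40, GGG=20, GGT=20)
        )
        table = load_codon_usage(path)
        assert table.usage["GGA"] == pytest.approx(0.2)
        assert table.usage["GGC"] == pytest.approx(0.4)
        assert table.usage["GGG"] == pytest.approx(0.2)
        assert table.usage["GGT"] == pytest.approx(0.2)

    def test_per_family_frequencies_returned_unchanged(self, tmp_path):
        counts = {}
        for codons in SYNONYMOUS_FAMILIES.values():
            for c in codons:
                counts[c] = 1.0 / len(codons)
        path = tmp_path / "freq.tsv"
        path.write_text(
            "codon\tfrequency\n"
            + "\n".join(f"{c}\t{v}" for c, v in counts.items())
            + "\n"
        )
        table = load_codon_usage(path)
        for c in SENSE_CODONS:
            assert table.usage[c] == pytest.approx(counts[c])

    def test_missing_codon_named_in_error(self, tmp_path):
        counts = _full_counts()
        del counts["GGG"]
        with pytest.raises(CodonUsageError, match="GGG"):
            load_codon_usage(_write_table(tmp_path, counts))

    def test_rna_codons_transliterated(self, tmp_path):
        counts = {c.replace("T", "U"): 10.0 for c in SENSE_CODONS}
        table = load_codon_usage(_write_table(tmp_path, counts))
        assert set(table.usage) == set(SENSE_CODONS)

    def test_zero_counts_smoothed_positive(self, tmp_path):
        table = load_codon_usage(
            _write_table(tmp_path, _full_counts(GGG=0))
        )
        assert table.usage["GGG"] > 0

    def test_stop_codons_ignored(self, tmp_path):
        counts = _full_counts()
        counts["TAA"] = 5.0
        table = load_codon_usage(_write_table(tmp_path, counts))
        assert "TAA" not in table.usage

    def test_table_invariants(self, dmel_table):
        assert set(dmel_table.usage) == set(SENSE_CODONS)
        for codons in SYNONYMOUS_FAMILIES.values():
            assert sum(dmel_table.usage[c] for c in codons) == pytest.approx(
                1.0, abs=1e-9
            )


class TestRelativeAdaptiveness:
    def test_gly_family_values(self, gly_table):
        w = relative_adaptiveness(gly_table)
        assert w["GGC"] == pytest.approx(1.0)
        assert w["GGA"] == pytest.approx(0.5)
        assert w["GGG"] == pytest.approx(0.5)
        assert w["GGT"] == pytest.approx(0.5)

    def test_single_codon_family_and_uniform_ties(self, uniform_table):
        w = relative_adaptiveness(uniform_table)
        assert w["ATG"] == 1.0
        assert w["TGG"] == 1.0
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_invariant_to_uniform_rescaling(self, tmp_path):
        base = _full_counts(GGA=20, GGC=40, GGG=20, GGT=20, CTG=55)
        t1 = load_codon_usage(_write_table(tmp_path, base, "a.tsv"))
        t2 = load_codon_usage(
            _write_table(tmp_path, {c: 7 * v for c, v in base.items()}, "b.tsv")
        )
        w1, w2 = relative_adaptiveness(t1), relative_adaptiveness(t2)
        for c in SENSE_CODONS:
            assert w1[c] == pytest.approx(w2[c], rel=1e-12)


class TestCai:
    def test_geometric_mean_of_w(self, gly_table):
        # GGAGGA: two codons with w = 0.5 -> geometric mean 0.5
        seq = CodingSequence("g", "GGAGGA")
        assert compute_cai(seq, gly_table) == pytest.approx(0.5)

    def test_most_used_codons_score_one(self, gly_table):
        assert compute_cai(CodingSequence("g", "GGCGGC"), gly_table) == 1.0

    def test_uniform_table_scores_one(self, uniform_table, dmel_table):
        seq = simulate_cds(80, dmel_table, seed=11)
        assert compute_cai(seq, uniform_table) == pytest.approx(1.0)

    def test_terminal_stop_excluded(self, gly_table):
        with_stop = CodingSequence("g", "GGAGGATAA")
        assert compute_cai(with_stop, gly_table) == pytest.approx(0.5)


class TestSequenceValidation:
    @pytest.mark.parametrize("nt", ["ATGG", "AT", "ATGNNN", "atgtga ggc"])
    def test_invalid_sequences_rejected(self, nt):
        with pytest.raises(SequenceError):
            CodingSequence("bad", nt)

    def test_internal_stop_reports_codon_index(self):
        with pytest.raises(SequenceError, match="codon 1"):
            CodingSequence("bad", "ATGTGAGGA")

    def test_rna_input_transliterated(self):
        assert CodingSequence("r", "AUGGGA").nucleotides == "ATGGGA"

    def test_ambiguity_tolerated_when_permissive(self, gly_table):
        seq = CodingSequence("amb", "GGANNNGGA", allow_ambiguous=True)
        assert compute_cai(seq, gly_table) == pytest.approx(0.5)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,expected", [("ATGGGA", "MG"), ("ATGTGA", "M*"), ("ATGAAATTC", "MKF")]
    )
    def test_standard_code(self, nt, expected):
        assert translate(CodingSequence("t", nt)) == expected


class TestGcContent:
    @pytest.mark.parametrize(
        "nt,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("ATAT", 0.0)]
    )
    def test_worked_values(self, nt, expected):
        assert gc_content(nt) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            gc_content("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_reverse_complement_preserves_gc(self, nt):
        assert gc_content(reverse_complement(nt)) == pytest.approx(gc_content(nt))


class TestRecode:
    def test_extremal_common_forced_by_table(self, gly_table):
        seq = CodingSequence("s", "ATGGGA")
        assert recode(seq, gly_table, RecodingScheme("extremal_common")).nucleotides == "ATGGGC"

    def test_extremal_common_cai_is_exactly_one(self, dmel_table):
        seq = simulate_cds(120, dmel_table, seed=5)
        variant = recode(seq, dmel_table, RecodingScheme("extremal_common"))
        assert variant.cai == 1.0

    def test_fraction_zero_is_identity(self, dmel_table):
        seq = simulate_cds(50, dmel_table, seed=7)
        v = recode(seq, dmel_table, RecodingScheme("fractional_rare", fraction=0.0))
        assert v.nucleotides == seq.nucleotides
        assert v.identity_to_source == 100.0

    def test_dispersed_half_substitutes_alternating_positions(self, dmel_table):
        # 1 Met start + 10 recodable codons: exactly 5 substituted, never
        # adjacent among recodable ranks
        seq = CodingSequence("s", "ATG" + "GGA" * 10)
        v = recode(
            seq, dmel_table, RecodingScheme("fractional_rare", fraction=0.5)
        )
        src, new = seq.codons, [v.nucleotides[i : i + 3] for i in range(0, len(v.nucleotides), 3)]
        changed = [i for i, (a, b) in enumerate(zip(src, new)) if a != b]
        assert len(changed) == 5
        assert all(b - a >= 2 for a, b in zip(changed, changed[1:]))

    def test_fraction_one_equals_extremal_rare(self, dmel_table):
        seq = simulate_cds(60, dmel_table, seed=9)
        frac = recode(seq, dmel_table, RecodingScheme("fractional_rare", fraction=1.0))
        rare = recode(seq, dmel_table, RecodingScheme("extremal_rare"))
        assert frac.nucleotides == rare.nucleotides

    def test_seeded_random_is_reproducible(self, dmel_table):
        seq = simulate_cds(60, dmel_table, seed=13)
        scheme = RecodingScheme(
            "fractional_rare", fraction=0.3, pattern="seeded_random", seed=42
        )
        assert (
            recode(seq, dmel_table, scheme).nucleotides
            == recode(seq, dmel_table, scheme).nucleotides
        )

    def test_no_recodable_positions_warns(self, dmel_table):
        seq = CodingSequence("m", "ATGATGTGG")  # Met/Trp only
        v = recode(seq, dmel_table, RecodingScheme("fractional_rare", fraction=0.5))
        assert v.nucleotides == seq.nucleotides
        assert v.warning is not None

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            RecodingScheme("fractional_rare", fraction=1.5)
        with pytest.raises(ValueError):
            RecodingScheme("extremal_common", fraction=0.5)
        with pytest.raises(ValueError):
            RecodingScheme("no_such_mode")

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 60))
    def test_translation_preserved_and_cai_ordered(self, seed, n):
        """For every scheme: same protein, and CAI(rare) <= CAI(s) <= CAI(common)."""
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        codons = ["ATG"] + list(
            rng.choice(SENSE_CODONS, size=n - 1).tolist()
        )
        seq = CodingSequence("p", "".join(codons))
        protein = translate(seq)
        cais = {}
        for mode, fraction in [
            ("extremal_common", None),
            ("extremal_rare", None),
            ("fractional_rare", 0.5),
        ]:
            v = recode(seq, table, RecodingScheme(mode, fraction=fraction))
            assert translate(CodingSequence("v", v.nucleotides)) == protein
            cais[mode] = v.cai
        cai_src = compute_cai(seq, table)
        assert cais["extremal_rare"] <= cai_src + 1e-12
        assert cai_src <= cais["extremal_common"] + 1e-12
        assert cais["extremal_common"] == 1.0


class TestNucleotideIdentity:
    def test_worked_values(self):
        assert nucleotide_identity("ACGT", "ACGT") == 100.0
        assert nucleotide_identity("AAAA", "CCCC") == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SequenceError):
            nucleotide_identity("AAA", "AAAAAA")

    def test_matches_positionwise_oracle(self, dmel_table):
        seq = simulate_cds(100, dmel_table, seed=17)
        common = recode(seq, dmel_table, RecodingScheme("extremal_common"))
        rare = recode(seq, dmel_table, RecodingScheme("extremal_rare"))
        expected = (
            100.0
            * sum(a == b for a, b in zip(common.nucleotides, rare.nucleotides))
            / len(seq.nucleotides)
        )
        assert nucleotide_identity(
            common.nucleotides, rare.nucleotides
        ) == pytest.approx(expected)


class TestFasta:
    def test_round_trip_wrapped_at_60(self, tmp_path, dmel_table):
        seq = simulate_cds(50, dmel_table, seed=23)
        path = tmp_path / "seqs.fasta"
        write_fasta([(seq.id, seq.nucleotides)], path)
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) <= 60
        back = read_fasta(path)
        assert back[0].id == seq.id
        assert back[0].nucleotides == seq.nucleotides
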
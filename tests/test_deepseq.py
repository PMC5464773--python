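"""Read filtering, pair merging, peptide extraction, counting and assignment."""

from collections import Counter

import numpy as np
import pytest

from bh3design import (PUMA_BFL1_DESIGN, PUMA_BH3, PUMA_VARIABLE_POSITIONS,
                       DegenerateCodon)
from bh3design.core import PUMA_BH3_DNA, reverse_complement
from bh3design.deepseq import (ConstructTemplate, ReadPair, SortPool,
                               assign_to_libraries, count_filter,
                               demultiplex_and_filter, enrichment_trajectory,
                               extract_peptide, logo_frequencies, merge_pair,
                               nondesigned_fraction, read_fastq_pairs,
                               validate_barcode_table, write_fastq_pairs)
from bh3design.libdesign import LibraryDesign

BARCODES = {"p1": "ACGTAC", "p2": "CAGACG"}


def _pair(fwd, rev, fq=None, rq=None, rid="r1"):
    fq = fq if fq is not None else (40,) * len(fwd)
    rq = rq if rq is not None else (40,) * len(rev)
    return ReadPair(rid, fwd, tuple(fq), rev, tuple(rq))


class TestDemultiplex:
    def test_exact_barcode_high_quality_kept(self):
        p = _pair("ACGTAC" + "A" * 20, "T" * 20)
        pools, stats = demultiplex_and_filter([p], BARCODES)
        assert len(pools["p1"]) == 1 and stats["kept"] == 1
        assert pools["p1"][0].fwd_seq == "A" * 20  # barcode trimmed

    def test_quality_exactly_20_is_discarded(self):
        fq = (40,) * 3 + (20,) + (40,) * 22
        p = _pair("ACGTAC" + "A" * 20, "T" * 20, fq=fq)
        pools, stats = demultiplex_and_filter([p], BARCODES, min_phred=20)
        assert stats["barcode_low_quality"] == 1 and stats["kept"] == 0

    def test_one_mismatch_barcode_rejected(self):
        p = _pair("ACGTAA" + "A" * 20, "T" * 20)
        _, stats = demultiplex_and_filter([p], BARCODES)
        assert stats["barcode_mismatch"] == 1

    def test_barcode_table_distance_validated(self):
        with pytest.raises(ValueError, match="< 2"):
            validate_barcode_table({"a": "ACGTAC", "b": "ACGTAT"})

    def test_accounting_conserved_on_synthetic_reads(self, rng):
        reads, expected = [], Counter()
        for i in range(2000):
            fate = rng.random()
            if fate < 0.6:
                bc, key = "ACGTAC", "kept"
            elif fate < 0.8:
                bc, key = "GGGGGG", "barcode_mismatch"
            else:
                bc, key = "ACGTAC", "barcode_low_quality"
            fq = [40] * 26
            if key == "barcode_low_quality":
                fq[int(rng.integers(6))] = int(rng.integers(0, 21))
            reads.append(_pair(bc + "A" * 20, "T" * 20, fq=fq, rid=f"r{i}"))
            expected[key] += 1
        _, stats = demultiplex_and_filter(reads, BARCODES)
        for key in expected:
            assert stats[key] == expected[key]
        assert stats["kept"] + stats["barcode_mismatch"] + \
            stats["barcode_low_quality"] == stats["reads_in"]


class TestMergePair:
    def test_identical_fully_overlapping_mates(self):
        amp = "ACGT" * 10
        p = _pair(amp, reverse_complement(amp))
        merged, reason = merge_pair(p, len(amp))
        assert reason == "ok" and merged == amp

    def test_disagreement_resolved_by_quality(self):
        amp = "A" * 40
        rev = reverse_complement("A" * 20 + "C" + "A" * 19)
        p = _pair(amp, rev, fq=[30] * 40, rq=[10] * 40)
        merged, reason = merge_pair(p, 40)
        assert reason == "ok" and merged == amp  # Q30 forward base wins
        p2 = _pair(amp, rev, fq=[10] * 40, rq=[30] * 40)
        merged2, _ = merge_pair(p2, 40)
        assert merged2[20] == "C"  # now the reverse base wins

    def test_equal_quality_disagreement_fails(self):
        amp = "A" * 40
        rev = reverse_complement("A" * 20 + "C" + "A" * 19)
        merged, reason = merge_pair(_pair(amp, rev), 40)
        assert merged is None and reason == "ambiguous-disagreement"

    def test_overlap_too_short(self):
        p = _pair("A" * 30, "T" * 30)
        merged, reason = merge_pair(p, expected_amplicon_length=55)
        assert merged is None and reason == "overlap-too-short"

    def test_overlap_longer_than_read_fails(self):
        p = _pair("A" * 30, "T" * 20)
        merged, reason = merge_pair(p, expected_amplicon_length=25)
        assert merged is None and reason == "overlap-too-long"

    def test_simulated_amplicons_with_injected_errors(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            L = int(rng.integers(60, 101))
            amp = "".join(rng.choice(bases, size=L))
            rlen = 75 if L >= 75 else L
            fwd = list(amp[:rlen])
            rev_region = list(amp[L - rlen:])
            fq, rq = [35] * rlen, [30] * rlen
            # inject a forward-read error in the overlap: reverse is cleaner
            # only where qualities differ, so truth is always recoverable
            overlap_start = L - rlen
            err_i = int(rng.integers(max(overlap_start, 0), rlen))
            truth_base = fwd[err_i]
            fwd[err_i] = rng.choice([b for b in "ACGT" if b != truth_base])
            fq[err_i] = 12
            pair = _pair("".join(fwd), reverse_complement("".join(rev_region)),
                         fq=fq, rq=rq[::-1])
            merged, reason = merge_pair(pair, L)
            assert reason == "ok"
            assert merged == amp  # higher-quality reverse base restores truth


CONSTRUCT = ConstructTemplate("GGTACCGGATCCGGTGGC",
                              "GGCGGCCGCGATTATAAAGATGATGATGATAAATAA", 69)


class TestExtractPeptide:
    def test_wild_type_insert_recovers_puma(self):
        consensus = CONSTRUCT.anchor5 + PUMA_BH3_DNA + CONSTRUCT.anchor3
        pep, reason = extract_peptide(consensus, CONSTRUCT)
        assert reason == "ok" and pep == PUMA_BH3.sequence

    def test_internal_stop_categorized(self):
        insert = PUMA_BH3_DNA[:30] + "TAA" + PUMA_BH3_DNA[33:]
        pep, reason = extract_peptide(
            CONSTRUCT.anchor5 + insert + CONSTRUCT.anchor3, CONSTRUCT)
        assert pep is None and reason == "internal-stop"

    def test_missing_anchor(self):
        pep, reason = extract_peptide("T" * 100, CONSTRUCT)
        assert pep is None and reason == "anchor5-not-found"

    def test_frameshift(self):
        c = ConstructTemplate(CONSTRUCT.anchor5, CONSTRUCT.anchor3, None)
        insert = PUMA_BH3_DNA[:-1]  # 68 nt
        pep, reason = extract_peptide(
            CONSTRUCT.anchor5 + insert + CONSTRUCT.anchor3, c)
        assert pep is None and reason == "frameshift"

    def test_synthetic_constructs_full_recovery(self, puma_design, rng):
        from bh3design.synthetic import _reverse_translate
        for i in range(100):
            seq = puma_design.sample_members(1, seed=i)[0]
            insert = _reverse_translate(puma_design, seq, rng)
            pep, reason = extract_peptide(
                CONSTRUCT.anchor5 + insert + CONSTRUCT.anchor3, CONSTRUCT)
            assert reason == "ok" and pep == seq


class TestCountFilter:
    def test_boundary_is_strictly_fewer_than(self):
        kept, removed = count_filter({"A": 25, "B": 19, "C": 20}, 20)
        assert kept == {"A": 25, "C": 20} and removed == 19

    def test_empty_input(self):
        assert count_filter({}, 20) == ({}, 0)


class TestAssignment:
    def _second_design(self):
        codons = {p: DegenerateCodon("RMA") for p in PUMA_VARIABLE_POSITIONS}
        return LibraryDesign(PUMA_BH3, PUMA_VARIABLE_POSITIONS, codons)

    def test_exact_member_gets_its_library(self, puma_design):
        member = puma_design.sample_members(1, seed=3)[0]
        labels, _ = assign_to_libraries([member], {"Bfl-1": puma_design})
        assert labels[member] == "Bfl-1"

    def test_distance_one_unique_assignment(self, puma_design):
        member = puma_design.sample_members(1, seed=4)[0]
        i = puma_design.template.index_of("3a")
        mutant = member[:i] + "W" + member[i + 1:]
        designs = {"Bfl-1": puma_design, "other-lib": self._second_design()}
        labels, _ = assign_to_libraries([mutant], designs)
        assert labels[mutant] == "Bfl-1"

    def test_tie_is_ambiguous(self, puma_design):
        designs = {"A": puma_design, "B": puma_design}  # same design twice
        member = puma_design.sample_members(1, seed=5)[0]
        labels, _ = assign_to_libraries([member], designs)
        assert labels[member] == "ambiguous"

    def test_far_sequence_is_other(self, puma_design):
        seq = "W" * len(PUMA_BH3)
        labels, _ = assign_to_libraries([seq], {"Bfl-1": puma_design})
        assert labels[seq] == "other"

    def test_length_mismatch_warned_and_other(self, puma_design):
        labels, warn = assign_to_libraries(["QWAR"], {"Bfl-1": puma_design})
        assert labels["QWAR"] == "other"
        assert warn["length_mismatch"] == 1


class TestEnrichment:
    def _pool(self, label_counts, name="r"):
        counts, assignments = {}, {}
        i = 0
        for lab, (n_unique, reads_each) in label_counts.items():
            for j in range(n_unique):
                pep = f"{lab}{i}"
                counts[pep] = reads_each
                assignments[pep] = lab
                i += 1
        return SortPool(name, counts, assignments)

    def test_single_label_pool_fraction_one(self):
        pools = [self._pool({"Bfl-1": (5, 10)}, "a"),
                 self._pool({"Bfl-1": (5, 10)}, "b")]
        traj = enrichment_trajectory(pools)
        assert (traj["read_fraction"] == 1.0).all()

    def test_fractions_sum_to_one(self):
        pools = [self._pool({"Bfl-1": (5, 10), "Mcl-1": (3, 7)}, "a"),
                 self._pool({"Bfl-1": (8, 20), "other": (2, 1)}, "b")]
        traj = enrichment_trajectory(pools)
        sums = traj.groupby("round")[["read_fraction", "unique_fraction"]].sum()
        assert np.allclose(sums.values, 1.0, atol=1e-12)

    def test_read_and_unique_fractions_coincide_for_equal_counts(self):
        pools = [self._pool({"Bfl-1": (4, 5), "Mcl-1": (6, 5)}, "a"),
                 self._pool({"Bfl-1": (4, 5), "Mcl-1": (6, 5)}, "b")]
        traj = enrichment_trajectory(pools)
        assert np.allclose(traj["read_fraction"], traj["unique_fraction"])

    def test_empty_pool_rejected(self):
        pools = [self._pool({"Bfl-1": (5, 10)}, "a"), SortPool("b", {}, {})]
        with pytest.raises(ValueError, match="b"):
            enrichment_trajectory(pools)

    def test_needs_two_pools(self):
        with pytest.raises(ValueError):
            enrichment_trajectory([self._pool({"x": (1, 1)})])


class TestLogoFrequencies:
    def test_single_peptide_is_indicator(self):
        mat = logo_frequencies(["QWA"])
        assert mat.loc[0, "Q"] == 1.0 and mat.loc[1, "W"] == 1.0
        assert np.allclose(mat.sum(axis=1), 1.0)

    def test_two_peptides_split_at_variant_site(self):
        mat = logo_frequencies(["QWA", "QWV"])
        assert mat.loc[2, "A"] == 0.5 and mat.loc[2, "V"] == 0.5
        assert mat.loc[0, "Q"] == 1.0

    def test_hand_tabulated_five_sequences(self):
        peps = ["AC", "AC", "AD", "GC", "GC"]
        mat = logo_frequencies(peps)
        assert mat.loc[0, "A"] == pytest.approx(3 / 5)
        assert mat.loc[0, "G"] == pytest.approx(2 / 5)
        assert mat.loc[1, "C"] == pytest.approx(4 / 5)
        assert mat.loc[1, "D"] == pytest.approx(1 / 5)

    def test_read_weighting(self):
        mat = logo_frequencies(["AC", "GC"], weights=[3, 1])
        assert mat.loc[0, "A"] == pytest.approx(0.75)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            logo_frequencies(["AC", "ACD"])


class TestNondesignedFraction:
    def test_all_members_zero(self, puma_design):
        members = puma_design.sample_members(10, seed=0)
        pool = SortPool("x", {m: 5 for m in members}, {})
        f, se = nondesigned_fraction(pool, puma_design)
        assert f == 0.0

    def test_one_in_ten_off_design(self, puma_design):
        members = puma_design.sample_members(9, seed=1)
        off = "W" * len(PUMA_BH3)
        pool = SortPool("x", {**{m: 5 for m in members}, off: 5}, {})
        f, se = nondesigned_fraction(pool, puma_design)
        assert f == pytest.approx(0.1)


def test_fastq_round_trip(tmp_path):
    pairs = [_pair("ACGT" * 5, "TTTT" * 5, fq=range(20), rq=range(20, 40),
                   rid=f"r{i}") for i in range(5)]
    write_fastq_pairs(pairs, tmp_path / "R1.fastq", tmp_path / "R2.fastq")
    back = read_fastq_pairs(tmp_path / "R1.fastq", tmp_path / "R2.fastq")
    assert back == pairs
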
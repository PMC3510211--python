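"""Substrate data model, I/O, window extraction and redundancy reduction."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cleavesite.substrates import (
    AA_ALPHABET,
    GAP,
    DatasetLoadError,
    ProteaseDataset,
    SubstrateRecord,
    SubstrateValidationError,
    extract_windows,
    make_window,
    read_substrates,
    reduce_redundancy,
    specificity_profile,
    subsite_labels,
    write_substrates,
)


class TestSubstrateRecord:
    def test_positions_sorted_unique_and_in_range(self):
        rec = SubstrateRecord("s", "P", "ACDEFGHIKL", (7, 3, 7))
        assert rec.cleavage_p1_positions == (3, 7)

    @pytest.mark.parametrize("bad_p1", [0, 10, 11])
    def test_p1_must_leave_a_p1_prime_residue(self, bad_p1):
        with pytest.raises(SubstrateValidationError):
            SubstrateRecord("s", "P", "ACDEFGHIKL", (bad_p1,))

    def test_nonstandard_residues_map_to_x(self):
        rec = SubstrateRecord("s", "P", "acdBZu", ())
        assert rec.sequence == "ACDXXX"

    def test_empty_sequence_rejected(self):
        with pytest.raises(SubstrateValidationError):
            SubstrateRecord("s", "P", "", ())

    def test_duplicate_substrate_ids_rejected(self):
        rec = SubstrateRecord("s", "P", "ACDEF", ())
        with pytest.raises(SubstrateValidationError, match="duplicate"):
            ProteaseDataset("P", [rec, SubstrateRecord("s", "P", "GHIKL", ())])


class TestIO:
    def _write(self, tmp_path, fasta_text, table_text):
        fasta = tmp_path / "subs.fasta"
        table = tmp_path / "cleavages.tsv"
        fasta.write_text(fasta_text)
        table.write_text(table_text)
        return fasta, table

    def test_minimal_round_trip(self, tmp_path):
        fasta, table = self._write(
            tmp_path,
            ">s1\nACDEFGHIKL\n",
            "substrate_id\tprotease_id\tp1_positions\ns1\tP\t4\n",
        )
        ds = read_substrates(fasta, table)
        assert ds.n_substrates == 1 and ds.n_sites == 1
        assert ds.get("s1").cleavage_p1_positions == (4,)

    def test_p1_at_sequence_end_rejected(self, tmp_path):
        fasta, table = self._write(
            tmp_path,
            ">s1\nACDEFGHIKL\n",
            "substrate_id\tprotease_id\tp1_positions\ns1\tP\t10\n",
        )
        with pytest.raises(SubstrateValidationError, match="10"):
            read_substrates(fasta, table)

    def test_missing_sequence_names_the_id(self, tmp_path):
        fasta, table = self._write(
            tmp_path,
            ">s1\nACDEFGHIKL\n",
            "substrate_id\tprotease_id\tp1_positions\nmissing\tP\t4\n",
        )
        with pytest.raises(DatasetLoadError, match="missing"):
            read_substrates(fasta, table)

    def test_write_then_read_preserves_counts(self, tmp_path, tiny_dataset):
        fasta, table = tmp_path / "d.fasta", tmp_path / "d.tsv"
        write_substrates(tiny_dataset, fasta, table)
        # independent line-count check of the written fixture
        n_fasta_records = sum(1 for line in fasta.read_text().splitlines() if line.startswith(">"))
        n_sites = sum(
            len(line.split("\t")[2].split(","))
            for line in table.read_text().splitlines()[1:]
        )
        assert n_fasta_records == tiny_dataset.n_substrates == 3
        assert n_sites == tiny_dataset.n_sites == 4
        again = read_substrates(fasta, table)
        assert again.substrate_ids == tiny_dataset.substrate_ids
        assert again.n_sites == tiny_dataset.n_sites


class TestWindows:
    def test_window_index_arithmetic(self):
        # P1 = 7 in AAADEVDGAAA; P4-P2' covers 1-based 4..9
        rec = SubstrateRecord("s", "P", "AAADEVDGAAA", (7,))
        w = make_window(rec, 7, (4, 2), "cleaved")
        assert w.residues == "DEVDGA"
        assert w.residues[4 - 1] == "D"  # P1 at offset a-1

    @pytest.mark.parametrize(
        "p1,expected",
        [(1, "--ACD"), (2, "-ACDE"), (9, "HIKL-")],
    )
    def test_terminal_padding(self, p1, expected):
        rec = SubstrateRecord("s", "P", "ACDEFGHIKL", ())
        w = make_window(rec, p1, (3, 2), "non-cleaved")
        assert w.residues == expected

    @settings(derandomize=True, max_examples=50)
    @given(
        p1=st.integers(min_value=5, max_value=15),
        a=st.integers(min_value=1, max_value=4),
        b=st.integers(min_value=1, max_value=4),
    )
    def test_unpadded_windows_equal_sequence_slice(self, p1, a, b):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        rec = SubstrateRecord("s", "P", seq, ())
        w = make_window(rec, p1, (a, b), "non-cleaved")
        if GAP not in w.residues:
            assert w.residues == seq[p1 - a : p1 + b]

    def test_negative_ratio_and_exclusion(self):
        rec = SubstrateRecord("s", "P", "AAADEVDGAAA", (7,))
        ds = ProteaseDataset("P", [rec])
        windows = extract_windows(ds, (4, 2), negative_ratio=3.0, seed=0)
        positives = [w for w in windows if w.is_positive]
        negatives = [w for w in windows if not w.is_positive]
        assert len(positives) == 1 and len(negatives) == 3
        assert all(w.p1_index != 7 for w in negatives)

    def test_extraction_is_seed_deterministic(self, tiny_dataset):
        def digest(ws):
            return [(w.substrate_id, w.p1_index, w.residues, w.label) for w in ws]

        w1 = extract_windows(tiny_dataset, (4, 2), 3.0, seed=11)
        w2 = extract_windows(tiny_dataset, (4, 2), 3.0, seed=11)
        w3 = extract_windows(tiny_dataset, (4, 2), 3.0, seed=12)
        assert digest(w1) == digest(w2)
        assert digest(w1) != digest(w3)

    def test_positive_count_equals_annotated_sites(self, tiny_dataset):
        windows = extract_windows(tiny_dataset, (4, 2), 3.0, seed=0)
        n_pos = sum(w.is_positive for w in windows)
        n_neg = len(windows) - n_pos
        assert n_pos == tiny_dataset.n_sites
        assert n_neg == math.floor(3.0 * n_pos)

    def test_insufficient_negatives_warns_and_returns_all(self, caplog):
        rec = SubstrateRecord("s", "P", "AAAD", (3,))  # only 2 negative candidates
        ds = ProteaseDataset("P", [rec])
        with caplog.at_level(logging.WARNING, logger="cleavesite.substrates"):
            windows = extract_windows(ds, (2, 1), negative_ratio=3.0, seed=0)
        assert sum(not w.is_positive for w in windows) == 2
        assert any("negative candidates" in r.message for r in caplog.records)


class TestRedundancyReduction:
    def test_identical_sequences_collapse(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        ds = ProteaseDataset("P", [
            SubstrateRecord("a", "P", seq, ()),
            SubstrateRecord("b", "P", seq, ()),
        ])
        assert reduce_redundancy(ds, 0.7).n_substrates == 1

    def test_dissimilar_sequences_survive(self):
        ds = ProteaseDataset("P", [
            SubstrateRecord("a", "P", "AAAAAAAAAA", ()),
            SubstrateRecord("b", "P", "WWWWWWWWWW", ()),
        ])
        assert reduce_redundancy(ds, 0.7).n_substrates == 2

    def test_duplicated_set_collapses_to_unique(self):
        rng = np.random.default_rng(3)
        uniques = [
            "".join(rng.choice(list(AA_ALPHABET), size=30)) for _ in range(5)
        ]
        subs = [SubstrateRecord(f"u{i}", "P", s, ()) for i, s in enumerate(uniques)]
        subs += [SubstrateRecord(f"d{i}", "P", s, ()) for i, s in enumerate(uniques)]
        reduced = reduce_redundancy(ProteaseDataset("P", subs), 0.7)
        assert reduced.n_substrates == 5
        assert sorted(set(s.sequence for s in reduced.substrates)) == sorted(uniques)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        subs = [
            SubstrateRecord(f"s{i}", "P", "".join(rng.choice(list(AA_ALPHABET), size=25)), ())
            for i in range(6)
        ]
        once = reduce_redundancy(ProteaseDataset("P", subs), 0.7)
        twice = reduce_redundancy(once, 0.7)
        assert once.substrate_ids == twice.substrate_ids


class TestSpecificityProfile:
    def test_degenerate_p1_column(self):
        ds = ProteaseDataset("P", [SubstrateRecord("s", "P", "AAADAAAA", (4,))])
        prof = specificity_profile(ds, (2, 2))
        assert prof.loc["P1", "D"] == 1.0

    def test_two_residue_split(self):
        ds = ProteaseDataset("P", [
            SubstrateRecord("s1", "P", "AAADAAAA", (4,)),
            SubstrateRecord("s2", "P", "AAAEAAAA", (4,)),
        ])
        prof = specificity_profile(ds, (2, 2))
        assert prof.loc["P1", "D"] == pytest.approx(0.5)
        assert prof.loc["P1", "E"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, tiny_dataset):
        prof = specificity_profile(tiny_dataset, (6, 6))
        sums = prof.sum(axis=1).to_numpy()
        observed = sums > 0
        assert np.allclose(sums[observed], 1.0, atol=1e-12)

    def test_empty_dataset_rejected(self):
        ds = ProteaseDataset("P", [SubstrateRecord("s", "P", "ACDEF", ())])
        with pytest.raises(ValueError):
            specificity_profile(ds, (2, 2))

    def test_caspase_generator_p1_asp_near_fixation(self, caspase_data):
        dataset, _, _ = caspase_data
        prof = specificity_profile(dataset, (6, 6))
        assert prof.loc["P1", "D"] >= 0.997

    def test_subsite_labels(self):
        assert subsite_labels((4, 2)) == ["P4", "P3", "P2", "P1", "P1'", "P2'"]
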
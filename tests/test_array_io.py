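"""Array table I/O, replicate averaging, saturation correction, QC stats."""

import math

import numpy as np
import pytest

from epibind.array_io import (
    ArrayDataset,
    BindingTable,
    FormatError,
    average_replicates,
    correct_saturation,
    exclude_cognates,
    filter_by_length,
    kmer_coverage,
    read_array_table,
    replicate_correlation,
    write_array_table,
)
from epibind.synthetic import LibrarySpec, generate_library, simulate_binding

CONCS = (0.125, 0.5, 2.0, 8.0)


def make_dataset(counts_per_seq):
    seqs = list(counts_per_seq)
    counts = np.array([counts_per_seq[s] for s in seqs])
    return ArrayDataset(sequences=seqs, concentrations=CONCS, counts=counts)


def make_table(rows):
    """rows: {sequence: 4 log10 values}"""
    return BindingTable(
        sequences=list(rows),
        concentrations=CONCS,
        values=np.array(list(rows.values()), dtype=float),
    )


class TestIO:
    def test_round_trip(self, tmp_path, tiny_landscape):
        lib = generate_library(LibrarySpec(n_peptides=50, seed=4))
        ds = simulate_binding(tiny_landscape, lib)
        path = tmp_path / "arr.tsv"
        write_array_table(ds, path, comment="seed=4")
        back = read_array_table(path)
        assert back.sequences == ds.sequences
        assert (back.counts == ds.counts).all()
        assert back.concentrations == ds.concentrations

    def test_three_row_fixture(self, tmp_path):
        ds = make_dataset(
            {
                "ADEFG": np.full((4, 4), 850),
                "PLEEV": np.full((4, 4), 1000),
                "HKLNP": np.full((4, 4), 900),
            }
        )
        path = tmp_path / "t.tsv"
        write_array_table(ds, path)
        back = read_array_table(path)
        assert len(back.sequences) == 3
        assert back.counts.shape == (3, 4, 4)

    def test_cap_violation_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "sequence\t" + "\t".join(
            f"c{c:g}_r{r+1}" for c in CONCS for r in range(2)
        )
        row = "ADEFG\t" + "\t".join(["70000"] * 8)
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(FormatError, match="exceeds cap"):
            read_array_table(path)

    def test_bad_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "sequence\tc8_r1"
        path.write_text(header + "\nADEFG\t100\nADEFG\t3.5\n")
        with pytest.raises(FormatError, match="line 3"):
            read_array_table(path)

    def test_missing_sequence_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pep\tc8_r1\nADEFG\t3\n")
        with pytest.raises(FormatError, match="sequence"):
            read_array_table(path)


class TestAveraging:
    def test_mean_of_logs(self):
        ds = make_dataset({"ADEFG": np.tile([[100, 1000, 100, 1000]], (4, 1))})
        bt = average_replicates(ds)
        assert bt.values[0, 0] == pytest.approx(2.5)

    def test_identical_replicates_of_background(self):
        ds = make_dataset({"ADEFG": np.full((4, 4), 850)})
        bt = average_replicates(ds)
        assert bt.values[0, 0] == pytest.approx(math.log10(850), abs=1e-9)
        assert bt.values[0, 0] == pytest.approx(2.9294, abs=1e-4)

    def test_noise_free_equals_log_expectation(self, tiny_landscape):
        from epibind.synthetic import expected_counts

        lib = generate_library(LibrarySpec(n_peptides=100, seed=6))
        ds = simulate_binding(tiny_landscape, lib)
        bt = average_replicates(ds)
        mu = np.clip(np.rint(expected_counts(tiny_landscape, lib)), 1, 65_536)
        assert bt.values == pytest.approx(np.log10(mu), abs=1e-12)

    def test_duplicate_sequences_collapsed_by_log_average(self):
        ds = ArrayDataset(
            sequences=["ADEFG", "ADEFG"],
            concentrations=CONCS,
            counts=np.stack([np.full((4, 4), 100), np.full((4, 4), 1000)]),
        )
        bt = average_replicates(ds)
        assert len(bt) == 1
        assert bt.values[0, 0] == pytest.approx(2.5)


LOG_CAP = math.log10(65_536)


class TestSaturationCorrection:
    def test_single_substitution(self):
        bt = make_table({"ADEFG": [3.0, 3.5, 4.0, LOG_CAP]})
        out = correct_saturation(bt)
        assert out.values[0, 3] == pytest.approx(4.0 + math.log10(4), abs=1e-9)
        assert out.values[0, 3] == pytest.approx(4.602, abs=5e-4)
        assert out.saturation_substituted[0, 3]
        assert not out.saturation_substituted[0, :3].any()

    def test_cascade_two_levels(self):
        bt = make_table({"ADEFG": [3.2, 3.7, LOG_CAP, LOG_CAP]})
        out = correct_saturation(bt)
        assert out.values[0, 2] == pytest.approx(3.7 + math.log10(4), abs=1e-9)
        assert out.values[0, 3] == pytest.approx(3.7 + 2 * math.log10(4), abs=1e-9)
        # hand-checked: 4.302 and 4.904 to printed precision
        assert out.values[0, 2] == pytest.approx(4.302, abs=5e-4)
        assert out.values[0, 3] == pytest.approx(4.904, abs=5e-4)

    def test_unsaturated_table_unchanged(self):
        bt = make_table({"ADEFG": [3.0, 3.3, 3.6, 4.0]})
        out = correct_saturation(bt)
        assert (out.values == bt.values).all()
        assert not out.saturation_substituted.any()

    def test_lowest_concentration_left_with_warning(self):
        bt = make_table({"ADEFG": [LOG_CAP, LOG_CAP, LOG_CAP, LOG_CAP]})
        with pytest.warns(UserWarning, match="lowest"):
            out = correct_saturation(bt)
        assert out.values[0, 0] == pytest.approx(LOG_CAP)
        assert not out.saturation_substituted[0, 0]

    def test_idempotent_on_corrected_tables(self):
        bt = make_table({"ADEFG": [3.0, 3.5, 4.0, LOG_CAP], "HKLNP": [2.9, 2.9, 2.9, 2.9]})
        once = correct_saturation(bt)
        twice = correct_saturation(once)
        assert twice.values == pytest.approx(once.values)


class TestFilters:
    def test_length_filter_boundaries(self):
        bt = make_table(
            {"ADEF": [3] * 4, "ADEFG": [3] * 4, "ADEFGHKLNPQ": [3] * 4, "ADEFGHKLNPQR": [3] * 4}
        )
        out = filter_by_length(bt)
        assert out.sequences == ["ADEFG", "ADEFGHKLNPQ"]

    def test_empty_result_warns(self):
        bt = make_table({"ADEF": [3] * 4})
        with pytest.warns(UserWarning):
            out = filter_by_length(bt)
        assert len(out) == 0

    def test_exclude_cognates_removes_all_copies(self):
        bt = make_table({"PLEEVLN": [4] * 4, "ADEFG": [3] * 4})
        out, removed = exclude_cognates(bt, ["PLEEVLN", "ABSENT"])
        assert removed == 1
        assert out.sequences == ["ADEFG"]
        out2, removed2 = exclude_cognates(bt, ["NOTHERE"])
        assert removed2 == 0 and out2.sequences == bt.sequences

    def test_filters_preserve_values(self):
        bt = make_table({"ADEFG": [3.1, 3.2, 3.3, 3.4], "HKLNP": [2.9, 2.8, 2.7, 2.6]})
        out = filter_by_length(bt)
        assert out.values == pytest.approx(bt.values)


class TestKmerCoverage:
    def test_enumeration(self):
        assert kmer_coverage(["ADEF", "DEFG"], 4) == pytest.approx(2 / 65_536)

    def test_full_single_letter_coverage(self):
        assert kmer_coverage(["ADEFGHKLNPQRSVWY"], 1) == 1.0

    def test_monotone_nonincreasing_in_k(self):
        lib = generate_library(LibrarySpec(n_peptides=500, seed=8))
        cov = [kmer_coverage(lib, k) for k in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(cov, cov[1:]))

    def test_oversized_k_warns_zero(self):
        with pytest.warns(UserWarning):
            assert kmer_coverage(["ADEFG"], 9) == 0.0


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        counts = np.tile(np.array([100, 500, 2000, 8000])[None, :, None], (5, 1, 4))
        counts[:, :, :] += np.arange(5)[:, None, None]  # row-to-row variation
        ds = ArrayDataset(sequences=[f"ADEFG"[:4] + aa for aa in "ADEFG"], concentrations=CONCS, counts=counts)
        corr, flagged = replicate_correlation(ds)
        assert corr == pytest.approx(np.ones((4, 4)))
        assert flagged == []

    def test_permuted_replicate_decorrelates(self, tiny_landscape):
        from dataclasses import replace

        ls = replace(tiny_landscape, noise_sigma=0.02)
        lib = generate_library(LibrarySpec(n_peptides=2000, seed=10))
        rng = np.random.default_rng(0)
        letters = np.array(list("ADEFGHKLNPQRSVWY"))
        spikes = [
            "".join(letters[rng.integers(0, 16, 2)]) + ls.motif for _ in range(50)
        ]
        seqs = lib + spikes
        ds = simulate_binding(ls, seqs)
        counts = ds.counts.copy()
        counts[:, :, 3] = counts[rng.permutation(len(seqs)), :, 3]
        scrambled = ArrayDataset(sequences=seqs, concentrations=CONCS, counts=counts)
        corr, flagged = replicate_correlation(scrambled)
        # intact replicates share the binder signal; the permuted one has
        # lost peptide identity and its correlation collapses
        good = corr[:3, :3][np.triu_indices(3, 1)]
        assert good.min() > 0.95
        assert corr[0, 3] < 0.5
        assert any(3 in pair[:2] for pair in flagged)

    def test_low_noise_passes_qc(self, tiny_landscape):
        from dataclasses import replace

        ls = replace(tiny_landscape, noise_sigma=0.01)
        lib = generate_library(LibrarySpec(n_peptides=1000, seed=12))
        ds = simulate_binding(ls, lib + [ls.motif] * 5)
        corr, flagged = replicate_correlation(ds)
        assert flagged == []
        assert corr == pytest.approx(corr.T)
        assert np.diag(corr) == pytest.approx(np.ones(4))
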
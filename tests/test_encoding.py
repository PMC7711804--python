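"""Encoding: E-descriptor lookup and the ACC transform against a literal oracle."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accvax.data import ProteinRecord
from accvax.encoding import (STANDARD_AMINO_ACIDS, ACCVector, DescriptorTable,
                             EncodedSequence, EncodingError,
                             SequenceLengthError, acc_transform,
                             build_feature_matrix, default_descriptor_table,
                             encode_sequence, feature_names, ordering_tag)

from conftest import random_protein


def acc_oracle(matrix: np.ndarray, lag_max: int) -> np.ndarray:
    """Literal double-loop evaluation of the lagged covariance sums.

    Independent of the vectorized implementation: iterates lag, descriptor
    pair and position explicitly.
    """
    n = matrix.shape[1]
    out = []
    for lag in range(1, lag_max + 1):
        for j in range(5):
            for k in range(5):
                total = 0.0
                for i in range(n - lag):
                    total += matrix[j, i] * matrix[k, i + lag]
                out.append(total / (n - lag))
    return np.array(out)


def feature_index(lag: int, j: int, k: int) -> int:
    """Position of the (lag, j, k) term in the canonical lag-major ordering."""
    return (lag - 1) * 25 + (j - 1) * 5 + (k - 1)


class TestDescriptorTable:
    def test_default_table_covers_standard_alphabet(self, table):
        assert set(table.values) == set(STANDARD_AMINO_ACIDS)
        matrix = table.as_matrix()
        assert matrix.shape == (20, 5)
        assert np.isfinite(matrix).all()

    def test_rejects_missing_or_extra_residues(self):
        values = dict(default_descriptor_table().values)
        del values["W"]
        with pytest.raises(ValueError, match="W"):
            DescriptorTable(values=values)
        values["W"] = (0.1, 0.2, 0.3)  # wrong arity
        with pytest.raises(ValueError, match="5 components"):
            DescriptorTable(values=values)

    def test_loads_from_six_column_text(self, table):
        text = "# residue E1 E2 E3 E4 E5\n" + "\n".join(
            aa + "\t" + "\t".join(str(v) for v in table.values[aa])
            for aa in STANDARD_AMINO_ACIDS)
        loaded = DescriptorTable.from_file(io.StringIO(text), name="roundtrip")
        assert loaded.values == table.values
        with pytest.raises(ValueError, match="6 columns"):
            DescriptorTable.from_file(io.StringIO("A 1 2 3 4"))


class TestEncodeSequence:
    def test_homopolymer_repeats_table_column(self, table):
        encoded = encode_sequence("AAA", table)
        assert encoded.matrix.shape == (5, 3)
        for col in range(3):
            assert tuple(encoded.matrix[:, col]) == table.values["A"]

    @pytest.mark.parametrize("length", [1, 9, 57])
    def test_shape_contract(self, table, rng, length):
        seq = random_protein(rng, length)
        encoded = encode_sequence(seq, table)
        assert encoded.matrix.shape == (5, length)
        assert encoded.n == length

    def test_case_and_whitespace_insensitive(self, table):
        reference = encode_sequence("ACDEF", table)
        relaxed = encode_sequence(" acd\nEF ", table)
        np.testing.assert_array_equal(reference.matrix, relaxed.matrix)

    def test_strict_policy_names_offending_position(self, table):
        with pytest.raises(EncodingError, match="position 2"):
            encode_sequence("AXA", table, policy="strict")

    def test_skip_unknown_deletes_nonstandard_residues(self, table):
        skipped = encode_sequence("AXA", table, policy="skip-unknown")
        np.testing.assert_array_equal(skipped.matrix, encode_sequence("AA", table).matrix)
        assert skipped.n == 2

    def test_empty_inputs_error(self, table):
        with pytest.raises(EncodingError):
            encode_sequence("   ", table)
        with pytest.raises(EncodingError):
            encode_sequence("XXX", table, policy="skip-unknown")


class TestACCTransform:
    def test_lag8_gives_200_features(self, table, rng):
        encoded = encode_sequence(random_protein(rng, 50), table)
        acc = acc_transform(encoded, lag_max=8)
        assert acc.values.shape == (200,)
        assert len(feature_names(8)) == 200

    @pytest.mark.parametrize("lag_max", [1, 3, 8, 12])
    def test_output_length_is_25_per_lag_independent_of_n(self, table, rng, lag_max):
        for length in (lag_max + 1, lag_max + 20, 150):
            encoded = encode_sequence(random_protein(rng, length), table)
            assert acc_transform(encoded, lag_max).values.shape == (25 * lag_max,)

    def test_short_sequence_raises_with_minimum_length(self, table):
        encoded = encode_sequence("ACDEFGHI", table)  # n = 8
        with pytest.raises(SequenceLengthError, match="minimum admissible length is 9"):
            acc_transform(encoded, lag_max=8)

    def test_homopolymer_closed_form(self, table):
        # every averaged term of a homopolymer equals the same product, so
        # A_jj(L) = E_j^2 and C_jk(L) = E_j * E_k exactly
        e = np.array(table.values["W"])
        acc = acc_transform(encode_sequence("W" * 20, table), lag_max=4)
        expected = np.tile(np.outer(e, e).ravel(), 4)
        np.testing.assert_allclose(acc.values, expected, atol=1e-14)

    def test_matches_double_loop_oracle_on_random_sequences(self, table, rng):
        for _ in range(30):
            length = int(rng.integers(9, 61))
            lag_max = int(rng.integers(1, min(9, length)))
            encoded = encode_sequence(random_protein(rng, length), table)
            acc = acc_transform(encoded, lag_max)
            np.testing.assert_allclose(
                acc.values, acc_oracle(encoded.matrix, lag_max), atol=1e-12, rtol=0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.text(alphabet=STANDARD_AMINO_ACIDS, min_size=9, max_size=80),
           st.integers(min_value=1, max_value=8))
    def test_reversal_fixes_auto_terms_and_swaps_cross_terms(self, seq, lag_max):
        table = default_descriptor_table()
        forward = acc_transform(encode_sequence(seq, table), lag_max).values
        backward = acc_transform(encode_sequence(seq[::-1], table), lag_max).values
        for lag in range(1, lag_max + 1):
            for j in range(1, 6):
                for k in range(1, 6):
                    expected = forward[feature_index(lag, k, j)]
                    assert backward[feature_index(lag, j, k)] == pytest.approx(
                        expected, abs=1e-12)

    def test_descriptor_scaling_scales_acc_quadratically(self, table, rng):
        seq = random_protein(rng, 40)
        scale = 3.5
        scaled_table = DescriptorTable(
            values={aa: tuple(scale * v for v in row) for aa, row in table.values.items()},
            name="scaled")
        base = acc_transform(encode_sequence(seq, table), 8).values
        scaled = acc_transform(encode_sequence(seq, scaled_table), 8).values
        np.testing.assert_allclose(scaled, scale**2 * base, rtol=1e-12)

    def test_descriptor_shift_changes_auto_terms(self, table, rng):
        # witnesses that the transform is a raw (uncentered) covariance
        seq = random_protein(rng, 40)
        shifted_table = DescriptorTable(
            values={aa: (row[0] + 1.0, *row[1:]) for aa, row in table.values.items()},
            name="shifted")
        base = acc_transform(encode_sequence(seq, table), 8).values
        shifted = acc_transform(encode_sequence(seq, shifted_table), 8).values
        a11_indices = [feature_index(lag, 1, 1) for lag in range(1, 9)]
        assert not np.allclose(base[a11_indices], shifted[a11_indices])


class TestBuildFeatureMatrix:
    def test_feature_matrix_shape_and_order(self, synthetic_records, table):
        dataset = build_feature_matrix(synthetic_records, table, lag_max=8)
        assert dataset.features.shape == (500, 200)
        assert dataset.ids == [rec.id for rec in synthetic_records]
        np.testing.assert_array_equal(
            dataset.labels, [rec.label for rec in synthetic_records])
        assert dataset.feature_ordering_tag == ordering_tag(table, 8)

    def test_subset_matrix_shape(self, synthetic_records, table):
        dataset = build_feature_matrix(synthetic_records[:134], table, lag_max=8)
        assert dataset.features.shape == (134, 200)

    def test_inadmissible_records_raise_aggregated_error(self, table):
        records = [
            ProteinRecord("ok", "ACDEFGHIKLMNP", label=1),
            ProteinRecord("too_short", "ACDEF", label=0),
            ProteinRecord("bad_residue", "ACDEFGHIKXLMNP", label=0),
        ]
        with pytest.raises(EncodingError) as excinfo:
            build_feature_matrix(records, table, lag_max=8, policy="strict")
        message = str(excinfo.value)
        assert "too_short" in message and "bad_residue" in message
        assert "ok" not in message.split(":")[0]

    def test_empty_record_list_is_an_error(self, table):
        with pytest.raises(ValueError, match="empty record list"):
            build_feature_matrix([], table, lag_max=8)

    def test_partial_labels_rejected(self, table):
        records = [ProteinRecord("a", "ACDEFGHIKL", label=1),
                   ProteinRecord("b", "ACDEFGHIKL"[::-1], label=None)]
        with pytest.raises(ValueError, match="partially labeled"):
            build_feature_matrix(records, table, lag_max=8)
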
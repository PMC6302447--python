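import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from srnakit import (
    DEFAULT_SPECS,
    FEATURE_GROUPS,
    DnaSequence,
    FeatureSpec,
    PropertyTable,
    default_property_table,
    encode,
    group_concat,
    group_dimension,
    mismatch_profile,
    pse_nc,
    revc_kmer_profile,
    spectrum_profile,
    standardize_property_table,
)
from srnakit.errors import (
    ConfigError,
    DegeneratePropertyError,
    LengthError,
    TableError,
)
from conftest import random_dna

EXPECTED_DIMENSIONS = {
    "F1": 4, "F2": 16, "F3": 64, "F4": 256, "F5": 1024,
    "F6": 64, "F7": 256, "F8": 1024,
    "F9": 2, "F10": 10, "F11": 32, "F12": 136, "F13": 512,
    "F14": 25, "F15": 65, "F16": 106, "F17": 76,
}
GROUP_DIMENSIONS = {"SP": 1364, "MP": 1344, "RCK": 692, "PNC": 272}


class TestSpectrum:
    def test_homopolymer(self):
        fv = spectrum_profile(DnaSequence("s", "AAAA"), 2)
        assert fv.values[fv.names.index("AA")] == 1.0
        assert fv.values.sum() == pytest.approx(1.0)

    def test_uniform_composition(self):
        fv = spectrum_profile(DnaSequence("s", "ACGT"), 1)
        np.testing.assert_allclose(fv.values, [0.25] * 4)

    def test_too_short_sequence(self):
        with pytest.raises(LengthError):
            spectrum_profile(DnaSequence("s", "AC"), 3)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_naive_enumeration(self, rng, k):
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(k + 1, 31)))
            got = spectrum_profile(seq, k).values
            np.testing.assert_allclose(
                got, oracles.naive_spectrum(seq.residues, k), atol=1e-12
            )

    def test_raw_counts_flag(self):
        fv = spectrum_profile(DnaSequence("s", "AAAA"), 2, normalize=False)
        assert fv.values[0] == 3.0


class TestMismatch:
    def test_single_window_hamming_ball(self):
        # one 3-mer window: exactly the 1 + 9 Hamming<=1 neighbors hit, each 1.0
        fv = mismatch_profile(DnaSequence("s", "ACG"), 3, 1)
        nonzero = fv.values[fv.values > 0]
        assert nonzero.size == 10
        np.testing.assert_allclose(nonzero, 1.0)

    @pytest.mark.parametrize("k,m", [(2, 1), (3, 1), (3, 2)])
    def test_matches_naive_enumeration(self, rng, k, m):
        for _ in range(10):
            seq = random_dna(rng, int(rng.integers(k + 1, 31)))
            got = mismatch_profile(seq, k, m).values
            np.testing.assert_allclose(
                got, oracles.naive_mismatch(seq.residues, k, m), atol=1e-12
            )

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_zero_mismatch_degenerates_to_spectrum(self, rng, k):
        for _ in range(10):
            seq = random_dna(rng, int(rng.integers(45, 121)))
            np.testing.assert_allclose(
                mismatch_profile(seq, k, 0).values,
                spectrum_profile(seq, k).values,
                atol=0,
            )

    def test_invalid_m(self):
        with pytest.raises(ConfigError):
            mismatch_profile(DnaSequence("s", "ACGTACGT"), 3, 3)


class TestRevcKmer:
    def test_k1_collapses_complements(self):
        fv = revc_kmer_profile(DnaSequence("s", "AATT"), 1)
        assert fv.names == ("A", "C")
        np.testing.assert_allclose(fv.values, [1.0, 0.0])

    def test_k2_canonical_classes(self):
        # windows AC, CG, GT: AC~GT share a class, CG is self-complementary
        fv = revc_kmer_profile(DnaSequence("s", "ACGT"), 2)
        assert fv.values[fv.names.index("AC")] == pytest.approx(2 / 3)
        assert fv.values[fv.names.index("CG")] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_naive_enumeration(self, rng, k):
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(k + 1, 31)))
            got = revc_kmer_profile(seq, k).values
            np.testing.assert_allclose(
                got, oracles.naive_revckmer(seq.residues, k), atol=1e-12
            )

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_reverse_complement_invariance(self, random_sequences, k):
        for seq in random_sequences:
            fwd = revc_kmer_profile(seq, k).values
            rev = revc_kmer_profile(seq.reverse_complement(), k).values
            np.testing.assert_array_equal(fwd, rev)


class TestPropertyTable:
    def test_default_tables_standardized(self):
        for alphabet in ("di", "tri"):
            t = default_property_table(alphabet)
            means = t.standardized.mean(axis=0)
            variances = t.standardized.var(axis=0, ddof=0)
            np.testing.assert_allclose(means, 0.0, atol=1e-9)
            np.testing.assert_allclose(variances, 1.0, atol=1e-9)

    def test_standardization_idempotent(self):
        t = default_property_table("di")
        again = standardize_property_table(t)
        np.testing.assert_allclose(
            again.standardized.to_numpy(), t.standardized.to_numpy(), atol=1e-9
        )

    def test_constant_column_rejected(self):
        oligos = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        df = pd.DataFrame({"P": [1.0] * 16}, index=oligos)
        with pytest.raises(DegeneratePropertyError):
            PropertyTable("di", df)

    def test_two_value_column_maps_to_plus_minus_one(self):
        oligos = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        df = pd.DataFrame({"P": [3.0] * 8 + [7.0] * 8}, index=oligos)
        t = PropertyTable("di", df)
        np.testing.assert_allclose(sorted(set(t.standardized["P"])), [-1.0, 1.0])

    def test_missing_oligo_rejected(self):
        df = pd.DataFrame({"P": [1.0, 2.0]}, index=["AA", "AC"])
        with pytest.raises(TableError):
            PropertyTable("di", df)


def _toy_table(order: int, n_props: int, seed: int = 5) -> PropertyTable:
    rng = np.random.default_rng(seed)
    oligos = ["".join(p) for p in itertools.product("ACGT", repeat=order)]
    df = pd.DataFrame(
        rng.normal(size=(len(oligos), n_props)),
        index=oligos,
        columns=[f"P{u}" for u in range(n_props)],
    )
    return PropertyTable("di" if order == 2 else "tri", df)


class TestPseNc:
    def test_homopolymer_pc_collapses_to_single_component(self):
        seq = DnaSequence("s", "A" * 50)
        fv = pse_nc(seq, FeatureSpec.psenc("PCPseDNC", 9))
        assert fv.values[fv.names.index("AA")] == pytest.approx(1.0)
        others = np.delete(fv.values, fv.names.index("AA"))
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    @pytest.mark.parametrize("variant", ["PCPseDNC", "SCPseDNC"])
    def test_matches_direct_summation_toy_table(self, variant):
        table = _toy_table(2, 2)
        seq = DnaSequence("s", "ACGTACGT")
        spec = FeatureSpec.psenc(variant, 2, w=0.05)
        got = pse_nc(seq, spec, props=table).values
        lookup = {o: table.standardized.loc[o].tolist() for o in table.standardized.index}
        expected = oracles.naive_psenc(seq.residues, variant, 2, 0.05, lookup)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @pytest.mark.parametrize("variant", ["PCPseTNC", "SCPseTNC"])
    def test_tri_variants_match_direct_summation(self, rng, variant):
        table = _toy_table(3, 3)
        seq = random_dna(rng, 25)
        spec = FeatureSpec.psenc(variant, 2, w=0.1)
        got = pse_nc(seq, spec, props=table).values
        lookup = {o: table.standardized.loc[o].tolist() for o in table.standardized.index}
        expected = oracles.naive_psenc(seq.residues, variant, 2, 0.1, lookup)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_pc_components_sum_to_one(self, random_sequences):
        for seq in random_sequences[:20]:
            for variant, lam in [("PCPseDNC", 9), ("PCPseTNC", 1)]:
                fv = pse_nc(seq, FeatureSpec.psenc(variant, lam))
                assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)
                assert (fv.values >= 0).all()

    def test_lambda_out_of_range_names_length(self):
        seq = DnaSequence("s", "ACGTACGTAC")  # L=10, di bound L-2=8
        with pytest.raises(ConfigError, match="10"):
            pse_nc(seq, FeatureSpec.psenc("PCPseDNC", 9))

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(TableError):
            pse_nc(
                DnaSequence("s", "ACGT" * 10),
                FeatureSpec.psenc("PCPseTNC", 1),
                props=_toy_table(2, 2),
            )


class TestDispatchAndGroups:
    def test_all_seventeen_dimensions(self, rng):
        seq = random_dna(rng, 100)
        for label, expected in EXPECTED_DIMENSIONS.items():
            fv = encode(seq, label)
            assert len(fv) == expected == DEFAULT_SPECS[label].dimension()

    def test_f6_equals_default_mismatch(self, rng):
        seq = random_dna(rng, 60)
        np.testing.assert_array_equal(
            encode(seq, "F6").values, mismatch_profile(seq, 3, 1).values
        )

    @pytest.mark.parametrize("group,dim", sorted(GROUP_DIMENSIONS.items()))
    def test_group_dimensions_and_order(self, rng, group, dim):
        seq = random_dna(rng, 80)
        fv = group_concat(seq, group)
        assert len(fv) == dim == group_dimension(group)
        # concatenation order: matches per-feature encoding in F-index order
        expected = np.concatenate(
            [encode(seq, f).values for f in FEATURE_GROUPS[group]]
        )
        np.testing.assert_array_equal(fv.values, expected)

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(ConfigError):
            group_concat(random_dna(rng, 50), "XX")

    def test_dimension_identities_closed_form(self):
        for k in range(1, 6):
            assert FeatureSpec.spectrum(k).dimension() == 4**k
            assert FeatureSpec.mismatch(k, 0).dimension() == 4**k
            expected_rck = (
                4**k // 2 if k % 2 else (4**k + 4 ** (k // 2)) // 2
            )
            assert FeatureSpec.revckmer(k).dimension() == expected_rck
        for lam in (1, 9, 15):
            assert FeatureSpec.psenc("PCPseDNC", lam).dimension() == 16 + lam
            assert FeatureSpec.psenc("PCPseTNC", lam).dimension() == 64 + lam
            assert FeatureSpec.psenc("SCPseDNC", lam).dimension() == 16 + 6 * lam
            assert FeatureSpec.psenc("SCPseTNC", lam).dimension() == 64 + 12 * lam

    def test_shortest_srna_length_accepted_by_all_defaults(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 45)
        for label in DEFAULT_SPECS:
            assert np.isfinite(encode(seq, label).values).all()

    def test_normalized_profiles_sum_to_one(self, random_sequences):
        for seq in random_sequences[:20]:
            for label in ("F1", "F3", "F5", "F9", "F12", "F13"):
                assert encode(seq, label).values.sum() == pytest.approx(1.0, abs=1e-12)
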
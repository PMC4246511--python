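"""Characterizer semantics: lookups, compositions, profiles, vector measures."""

import hashlib
import itertools
import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protfeat import (
    AA_ORDER,
    AnchoredMSA,
    AnnotationString,
    DomainError,
    ProteinRecord,
    UndefinedCorrelationError,
    aa_composition,
    atchley_factors,
    beta_contact_potential,
    calculate_cosine,
    calculate_entropy,
    calculate_r,
    column_profiles,
    hydrophobicity,
    interface_contact_potential,
    pssm_column_profiles,
    sa_composition,
    scaled_ordered_mean,
    ss_composition,
)
from protfeat.tables import TABLE_FILES, load_table

LOG2_20 = math.log2(20)

# Shipped table files are frozen: any edit to the digits must be deliberate
# (regenerate the checksum header) and will show up in review.
FROZEN_SHA256 = {
    "atchley": "314a452a7267633f7065c17ef3d3ca5cfa3621fa5c0205439a751ee2d14c6499",
    "hydrophobicity": "129fd3fc5292ce9d512075d181a71996de938766515fa82a674deae9fd87a904",
    "interface_contact": "486bdb4724f88c7052b020b543f1246cf60781dded08f98a104cfbe4ffa1278f",
    "beta_contact": "d3dcd92b3ba3ab24adc8203e793fab7b652d1b8444e1f9823efe745cd8bbad09",
}


class TestTables:
    @pytest.mark.parametrize("name", sorted(TABLE_FILES))
    def test_table_data_matches_frozen_checksum(self, name):
        text = resources.files("protfeat.data").joinpath(TABLE_FILES[name]).read_text()
        body = "\n".join(
            l for l in text.splitlines() if l.strip() and not l.startswith("#")
        ) + "\n"
        assert hashlib.sha256(body.encode()).hexdigest() == FROZEN_SHA256[name]

    def test_atchley_transcription_spot_checks(self):
        # first and last residues of the published factor-score table
        assert atchley_factors("A") == pytest.approx(
            [-0.591, -1.302, -0.733, 1.570, -0.146]
        )
        assert atchley_factors("Y") == pytest.approx(
            [0.260, 0.830, 3.097, -0.838, 1.512]
        )

    def test_hydrophobicity_scale_orientation(self):
        # Phe is the most hydrophobic side chain, Asp the most hydrophilic
        assert hydrophobicity("F") > hydrophobicity("D")
        assert hydrophobicity("G") == 0.0

    def test_pair_tables_labelled_synthetic(self):
        for name in ("interface_contact", "beta_contact"):
            assert "synthetic" in TABLE_FILES[name]


class TestResidueLookups:
    def test_atchley_unknown_residue_is_zero(self):
        assert atchley_factors("X").tolist() == [0.0] * 5

    def test_atchley_scaled_hits_exact_extremes(self):
        rows = np.array([atchley_factors(aa, scaled=True) for aa in AA_ORDER])
        assert np.all((rows >= 0) & (rows <= 1))
        # oracle: direct min-max over the embedded 20x5 table
        raw = np.array([atchley_factors(aa) for aa in AA_ORDER])
        expected = (raw - raw.min(axis=0)) / (raw.max(axis=0) - raw.min(axis=0))
        assert rows == pytest.approx(expected)
        assert np.all(rows.min(axis=0) == 0) and np.all(rows.max(axis=0) == 1)

    @pytest.mark.parametrize(
        "potential", [interface_contact_potential, beta_contact_potential]
    )
    def test_pair_potential_symmetry_all_210_pairs(self, potential):
        for a, b in itertools.combinations_with_replacement(AA_ORDER, 2):
            assert potential(a, b) == potential(b, a)

    @pytest.mark.parametrize(
        "potential, table",
        [
            (interface_contact_potential, "interface_contact"),
            (beta_contact_potential, "beta_contact"),
        ],
    )
    def test_pair_potential_scaling_and_x(self, potential, table):
        values = [
            potential(a, b)
            for a, b in itertools.combinations_with_replacement(AA_ORDER, 2)
        ]
        scaled = [
            potential(a, b, scaled=True)
            for a, b in itertools.combinations_with_replacement(AA_ORDER, 2)
        ]
        assert min(scaled) == 0.0 and max(scaled) == 1.0
        assert all(0 <= v <= 1 for v in scaled)
        assert potential("X", "A") == pytest.approx(np.mean(values))
        assert potential("X", "X") == pytest.approx(np.mean(values))

    def test_hydrophobicity_scaled_and_x(self):
        scaled = [hydrophobicity(aa, scaled=True) for aa in AA_ORDER]
        assert min(scaled) == 0.0 and max(scaled) == 1.0
        raw = [hydrophobicity(aa) for aa in AA_ORDER]
        assert hydrophobicity("X") == pytest.approx(np.mean(raw))


class TestCompositions:
    def test_aa_composition_direct_counts(self):
        comp = aa_composition("ACDC")
        by = dict(zip(AA_ORDER, comp.fractions))
        assert by["C"] == 0.5 and by["A"] == 0.25 and by["D"] == 0.25
        assert comp.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_residues_excluded_from_denominator(self):
        comp = aa_composition("AXA")
        assert comp.fractions[AA_ORDER.index("A")] == 1.0

    def test_ss_and_sa_composition(self):
        ss = ss_composition(AnnotationString("SS3", "HHEC"))
        assert ss.fractions.tolist() == [0.5, 0.25, 0.25]
        sa = sa_composition(AnnotationString("SA2", "bbee"))
        assert sa.fractions.tolist() == [0.5, 0.5]

    @pytest.mark.parametrize(
        "fn, arg",
        [
            (aa_composition, ""),
            (aa_composition, "XXX"),
            (ss_composition, AnnotationString("SS3", "")),
            (sa_composition, AnnotationString("SA2", "")),
        ],
    )
    def test_degenerate_inputs_rejected(self, fn, arg):
        with pytest.raises(DomainError):
            fn(arg)

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet=AA_ORDER, min_size=1, max_size=80))
    def test_composition_sums_to_one(self, seq):
        assert aa_composition(seq).fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestColumnProfiles:
    def test_single_row_msa_is_fully_conserved(self):
        msa = AnchoredMSA(query=ProteinRecord("q", "ACDE"), rows=("ACDE",))
        for profile in column_profiles(msa):
            assert profile.frequencies.max() == 1.0
            assert profile.information == pytest.approx(LOG2_20)

    def test_two_way_split_column(self):
        msa = AnchoredMSA(query=ProteinRecord("q", "A"), rows=("A", "C"))
        (profile,) = column_profiles(msa)
        assert profile.frequencies[AA_ORDER.index("A")] == 0.5
        assert profile.frequencies[AA_ORDER.index("C")] == 0.5
        assert profile.information == pytest.approx(LOG2_20 - 1.0)

    def test_uniform_column_information_approaches_zero(self):
        rng = np.random.default_rng(11)
        rows = tuple("".join(rng.choice(list(AA_ORDER), size=1)) for _ in range(500))
        msa = AnchoredMSA(query=ProteinRecord("q", rows[0]), rows=rows)
        (profile,) = column_profiles(msa)
        column = [r[0] for r in rows]
        freqs = np.array([column.count(aa) for aa in AA_ORDER]) / len(column)
        nz = freqs[freqs > 0]
        direct = LOG2_20 - float(-(nz * np.log2(nz)).sum())
        assert profile.information == pytest.approx(direct)
        assert profile.information < 1.0

    def test_gap_fraction_counts_gaps(self):
        msa = AnchoredMSA(query=ProteinRecord("q", "AC"), rows=("AC", "-C", "A-"))
        profiles = column_profiles(msa)
        assert profiles[0].gap_fraction == pytest.approx(1 / 3)
        assert profiles[1].gap_fraction == pytest.approx(1 / 3)

    def test_information_definitionally_consistent(self, bundle):
        for profile in column_profiles(bundle.msa):
            expected = LOG2_20 - calculate_entropy(profile.frequencies)
            assert profile.information == pytest.approx(max(0.0, expected), abs=1e-12)

    def test_pssm_profiles_from_percentages(self, bundle):
        profiles = pssm_column_profiles(bundle.pssm)
        assert len(profiles) == bundle.pssm.length
        for j, profile in enumerate(profiles):
            assert profile.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
            assert profile.gap_fraction == 0.0
            assert profile.information == bundle.pssm.information[j]

    def test_pssm_conserved_row(self, bundle):
        import protfeat

        pct = np.zeros((1, 20))
        pct[0, 0] = 100  # file order: column 0 is Ala
        pssm = protfeat.PSSMProfile(
            residues="A",
            log_odds=np.zeros((1, 20)),
            percentages=pct,
            information=np.array([LOG2_20]),
        )
        (profile,) = pssm_column_profiles(pssm)
        assert profile.frequencies[AA_ORDER.index("A")] == 1.0

    def test_pssm_all_zero_row_falls_back_to_uniform(self):
        import protfeat

        pssm = protfeat.PSSMProfile(
            residues="A",
            log_odds=np.zeros((1, 20)),
            percentages=np.zeros((1, 20)),
            information=np.array([0.0]),
        )
        with pytest.warns(UserWarning, match="all-zero"):
            (profile,) = pssm_column_profiles(pssm)
        assert profile.frequencies == pytest.approx(np.full(20, 0.05))


class TestVectorMeasures:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((1, 0, 0), 0.0),
            ((0.5, 0.25, 0.25), 1.5),
        ],
    )
    def test_entropy_closed_forms(self, p, expected):
        assert calculate_entropy(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4, 20])
    def test_entropy_of_uniform_is_log2_k(self, k):
        assert calculate_entropy(np.full(k, 1 / k)) == pytest.approx(
            math.log2(k), abs=1e-12
        )

    @pytest.mark.parametrize("bad", [(0.5, -0.1, 0.6), (0.2, 0.2)])
    def test_entropy_domain_errors(self, bad):
        with pytest.raises(DomainError):
            calculate_entropy(bad)

    def test_pearson_identity_and_anticorrelation(self):
        assert calculate_r((1, 2, 3), (1, 2, 3)) == pytest.approx(1.0)
        assert calculate_r((1, 2, 3), (3, 2, 1)) == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        x, y = np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert calculate_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_pearson_and_cosine_against_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            xm, ym = x - x.mean(), y - y.mean()
            r_oracle = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
            cos_oracle = (x * y).sum() / (
                math.sqrt((x**2).sum()) * math.sqrt((y**2).sum())
            )
            assert abs(calculate_r(x, y) - r_oracle) < 1e-12
            assert abs(calculate_cosine(x, y) - cos_oracle) < 1e-12

    def test_pearson_error_cases(self):
        with pytest.raises(DomainError):
            calculate_r((1, 2), (1, 2, 3))
        with pytest.raises(UndefinedCorrelationError):
            calculate_r((1, 1, 1), (1, 2, 3))

    def test_cosine_closed_forms(self):
        assert calculate_cosine((1, 0), (0, 1)) == pytest.approx(0.0, abs=1e-12)
        assert calculate_cosine((2, 2), (1, 1)) == pytest.approx(1.0)
        assert calculate_cosine((1, 1), (1, -1)) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DomainError):
            calculate_cosine((0, 0), (1, 1))


class TestOrderedMean:
    def test_order_one_is_arithmetic_mean(self):
        seq = "ACDEFY"
        values = [hydrophobicity(c, scaled=True) for c in seq]
        assert scaled_ordered_mean(seq, 1) == pytest.approx(np.mean(values))

    def test_constant_string_is_fixed_point(self):
        for n in (1, 2, 3, 4):
            assert scaled_ordered_mean("AAAA", n) == pytest.approx(
                hydrophobicity("A", scaled=True)
            )

    def test_monotone_in_order(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        means = [scaled_ordered_mean(seq, n) for n in (1, 2, 3, 4)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
        # brute-force cross-check of M_2
        v = np.array([hydrophobicity(c, scaled=True) for c in seq])
        assert means[1] == pytest.approx(math.sqrt((v**2).mean()))

    def test_annotation_strings_use_class_positions(self):
        assert scaled_ordered_mean("HHCC", 1) == pytest.approx(0.5)  # H=0, C=1
        assert scaled_ordered_mean("be", 1) == pytest.approx(0.5)

    def test_atchley_dimension_scale(self):
        v = [atchley_factors(c, scaled=True)[2] for c in "ACD"]
        assert scaled_ordered_mean("ACD", 1, scale="atchley3") == pytest.approx(
            np.mean(v)
        )

    @pytest.mark.parametrize("args", [("", 1), ("AC", 0)])
    def test_domain_errors(self, args):
        with pytest.raises(DomainError):
            scaled_ordered_mean(*args)

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet=AA_ORDER, min_size=1, max_size=30))
    def test_power_mean_inequality_property(self, seq):
        means = [scaled_ordered_mean(seq, n) for n in (1, 2, 3, 4)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
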
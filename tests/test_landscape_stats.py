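"""Distribution statistics: bands, class conditioning, rank-sum, profiles."""

import numpy as np
import pytest
from scipy import stats as sps

from satmut import (
    AnnotationSet,
    EffectModel,
    GeneratorConfig,
    ProteinSet,
    ResidueAnnotation,
    ValidationError,
    band_fractions,
    class_scores,
    codon_degeneracy_analysis,
    generate_proteome,
    generate_scan,
    pearson_r,
    positional_profile,
    ranksum_compare,
)
from satmut.alphabet import CODON_DEGENERACY, STANDARD_AAS
from satmut.landscape_stats import class_comparison_table
from satmut.saturation_scan import ScoredScan


def _uniform_scan(sequences, seed=0):
    """Scan over given sequences with uniform random scores."""
    proteome = ProteinSet.from_sequences(sequences)
    annotations = AnnotationSet([], proteome)
    return generate_scan(proteome, annotations, EffectModel.null(sigma=2.0), seed)


class TestBandFractions:
    def test_worked_example(self):
        summary = band_fractions([0.1, 0.5, 0.7, 0.95])
        assert summary.frac_below_t1 == 0.25
        assert summary.frac_above_t2 == 0.5
        assert summary.frac_above_t3 == 0.25
        assert sum(summary.partition) == pytest.approx(1.0)

    def test_all_zero_scores(self):
        summary = band_fractions(np.zeros(10))
        assert (summary.frac_below_t1, summary.frac_above_t2, summary.frac_above_t3) == (
            1.0,
            0.0,
            0.0,
        )

    def test_empty_and_unsorted_thresholds_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            band_fractions([])
        with pytest.raises(ValidationError, match="increasing"):
            band_fractions([0.5], thresholds=(0.6, 0.3, 0.9))

    def test_uniform_draws_within_binomial_3sigma(self):
        rng = np.random.default_rng(123)
        n = 100_000
        summary = band_fractions(rng.random(n))
        for frac, p in [
            (summary.frac_below_t1, 0.3),
            (summary.frac_above_t2, 0.4),
            (summary.frac_above_t3, 0.1),
        ]:
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_partition_always_sums_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            summary = band_fractions(rng.random(rng.integers(1, 50)))
            assert sum(summary.partition) == pytest.approx(1.0, abs=1e-12)


class TestClassScores:
    def test_single_interval_partition(self):
        proteome = ProteinSet.from_sequences([("P1", "ACDE")])
        annotations = AnnotationSet(
            [ResidueAnnotation("P1", 2, 3, "functional", "Active site")], proteome
        )
        scan = generate_scan(proteome, annotations, EffectModel.null(), seed=1)
        cls = class_scores(scan, annotations, "functional", "Active site")
        bg = class_scores(scan, annotations, "functional", "background")
        assert cls.size == 38 and bg.size == 38
        assert cls.size + bg.size == len(scan)

    def test_no_annotations_everything_background(self):
        proteome = ProteinSet.from_sequences([("P1", "ACDE")])
        annotations = AnnotationSet([], proteome)
        scan = generate_scan(proteome, annotations, EffectModel.null(), seed=1)
        assert class_scores(scan, annotations, "domain", "Domain").size == 0
        assert class_scores(scan, annotations, "domain", "background").size == len(scan)

    def test_unknown_class_rejected(self, small_study):
        with pytest.raises(ValidationError, match="unknown class"):
            class_scores(small_study.scan, small_study.annotations, "ptm", "Bogus")

    def test_matches_bruteforce_membership(self):
        """Random overlapping annotations vs a per-variant membership loop."""
        rng = np.random.default_rng(5)
        proteome = ProteinSet.from_sequences(
            [(f"P{i}", "".join(rng.choice(list(STANDARD_AAS), 25))) for i in range(3)]
        )
        records = []
        for _ in range(15):
            acc = f"P{rng.integers(3)}"
            start = int(rng.integers(1, 24))
            end = int(rng.integers(start, 26))
            label = ["Helix", "Beta strand", "Turn"][rng.integers(3)]
            records.append(
                ResidueAnnotation(acc, start, end, "secondary_structure", label)
            )
        annotations = AnnotationSet(records, proteome)
        scan = generate_scan(proteome, annotations, EffectModel.null(), seed=2)

        for label in ("Helix", "Turn", "background", None):
            got = np.sort(
                class_scores(scan, annotations, "secondary_structure", label)
            )
            want = []
            for row in scan.variants.itertuples(index=False):
                covering = {
                    lab
                    for rec in records
                    if rec.accession == row.accession
                    and rec.start <= row.position <= rec.end
                    for lab in [rec.class_label]
                }
                member = (
                    not covering
                    if label == "background"
                    else (bool(covering) if label is None else label in covering)
                )
                if member:
                    want.append(row.score)
            assert np.array_equal(got, np.sort(want))


class TestRanksum:
    def test_all_tied_gives_zero_statistic_p_one(self):
        result = ranksum_compare([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert result.statistic == 0.0
        assert result.p == 1.0
        assert result.direction == 0

    def test_hand_enumerated_exact_example(self):
        # ranks of a = {1,2}: W=3 is 1 of C(4,2)=6 assignments; doubled = 1/3
        result = ranksum_compare([1, 2], [3, 4])
        assert result.method == "exact"
        assert result.p == pytest.approx(1 / 3)

    def test_planted_shift_large_n(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 2000)
        b = rng.normal(0.0, 1.0, 2000)
        result = ranksum_compare(a, b)
        assert result.p < 1e-10
        assert result.direction == 1 and result.statistic > 0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(40), rng.random(25)
        fwd = ranksum_compare(a, b)
        rev = ranksum_compare(b, a)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)
        assert fwd.statistic == pytest.approx(-rev.statistic, rel=1e-12)

    def test_matches_scipy_on_large_tiefree_samples(self):
        """Independent cross-check against scipy's rank-sums implementation."""
        rng = np.random.default_rng(9)
        a = rng.normal(0.2, 1, 300)
        b = rng.normal(0.0, 1, 220)
        ours = ranksum_compare(a, b)
        ref_stat, ref_p = sps.ranksums(a, b)
        assert ours.statistic == pytest.approx(ref_stat, rel=1e-9)
        assert ours.p == pytest.approx(ref_p, rel=1e-9)

    def test_exact_matches_scipy_exact_mwu(self):
        """Small tie-free samples: exact permutation p vs scipy's exact MWU."""
        rng = np.random.default_rng(21)
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                a, b = rng.random(n_a), rng.random(n_b)
                ours = ranksum_compare(a, b)
                ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
                assert ours.p == pytest.approx(ref.pvalue, rel=1e-9), (n_a, n_b)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ranksum_compare([], [1.0])

    def test_underflow_flagged_not_zeroed_silently(self):
        a = np.concatenate([np.full(60000, 0.9), [0.89]])
        b = np.concatenate([np.full(60000, 0.1), [0.11]])
        result = ranksum_compare(a, b)
        assert result.p_underflow
        assert result.p_label == "< 1e-300"


class TestPearson:
    def test_identity_and_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 5)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = [1, 2, 3, 5]
        y = [2, 1, 4, 5]
        # covariance/(sigma_x*sigma_y) evaluated by hand: 8 / sqrt(8.75 * 10)
        r, p = pearson_r(x, y)
        assert r == pytest.approx(8 / np.sqrt(87.5))
        assert 0 < p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPositionalProfile:
    def test_constant_scores_constant_bins(self):
        proteome = ProteinSet.from_sequences([("P1", "ACDEFGHIKL")])
        annotations = AnnotationSet([], proteome)
        scan = generate_scan(proteome, annotations, EffectModel(beta_class={}, sigma=0.0), 0)
        profile = positional_profile(scan, n_bins=5)
        expected = scan.scores[0]
        filled = profile.counts > 0
        assert np.allclose(profile.means[filled], expected)
        assert profile.counts.sum() == len(scan)

    def test_bins_match_bruteforce(self):
        scan = _uniform_scan([("P1", "A" * 11), ("P2", "C" * 101)], seed=4)
        n_bins = 10
        profile = positional_profile(scan, n_bins=n_bins)
        counts = np.zeros(n_bins, int)
        sums = np.zeros(n_bins)
        for row in scan.variants.itertuples(index=False):
            length = 11 if row.accession == "P1" else 101
            rel = (row.position - 1) / (length - 1)
            idx = min(int(np.floor(rel * n_bins)), n_bins - 1)
            counts[idx] += 1
            sums[idx] += row.score
        assert np.array_equal(profile.counts, counts)
        np.testing.assert_allclose(
            profile.means[counts > 0], sums[counts > 0] / counts[counts > 0]
        )

    def test_protein_order_invariance(self):
        fwd = _uniform_scan([("P1", "A" * 11), ("P2", "C" * 31)], seed=4)
        # same per-protein streams, opposite proteome order
        proteome = ProteinSet.from_sequences([("P2", "C" * 31), ("P1", "A" * 11)])
        rev = ScoredScan(
            proteome,
            fwd.variants.sort_values("accession", ascending=False, kind="mergesort")
            .reset_index(drop=True),
        )
        prof_fwd = positional_profile(fwd, 8)
        prof_rev = positional_profile(rev, 8)
        assert np.array_equal(prof_fwd.counts, prof_rev.counts)
        np.testing.assert_allclose(
            np.nan_to_num(prof_fwd.means), np.nan_to_num(prof_rev.means)
        )

    def test_length_one_proteins_excluded(self):
        scan = _uniform_scan([("P1", "M"), ("P2", "ACD")], seed=1)
        profile = positional_profile(scan, n_bins=4)
        assert profile.counts.sum() == 57  # P1's 19 variants excluded


class TestCodonDegeneracy:
    def test_codon_counts_total_61_sense_codons(self):
        assert sum(CODON_DEGENERACY.values()) == 61

    def test_constant_scores_degenerate(self):
        proteome = ProteinSet.from_sequences([("P1", STANDARD_AAS)])
        annotations = AnnotationSet([], proteome)
        scan = generate_scan(proteome, annotations, EffectModel(beta_class={}, sigma=0.0), 0)
        with pytest.raises(ValidationError, match="constant"):
            codon_degeneracy_analysis(scan)

    def test_planted_degeneracy_trend_recovered(self):
        # plant per-mutant effects decreasing in codon count -> negative r
        gamma = np.zeros((20, 20))
        for j, aa in enumerate(STANDARD_AAS):
            gamma[:, j] = -0.35 * CODON_DEGENERACY[aa]
        proteome = ProteinSet.from_sequences(
            [("P1", STANDARD_AAS * 5), ("P2", STANDARD_AAS[::-1] * 5)]
        )
        annotations = AnnotationSet([], proteome)
        scan = generate_scan(
            proteome, annotations, EffectModel(beta_class={}, gamma=gamma, sigma=0.3), 0
        )
        result = codon_degeneracy_analysis(scan)
        assert result.r < -0.5
        assert sum(result.codon_count.values()) == 61

    def test_missing_target_amino_acid_listed(self):
        # all-A protein: variants never mutate *into* A
        proteome = ProteinSet.from_sequences([("P1", "AAAA")])
        annotations = AnnotationSet([], proteome)
        scan = generate_scan(proteome, annotations, EffectModel.null(), 0)
        with pytest.raises(ValidationError, match="into A"):
            codon_degeneracy_analysis(scan)


class TestComparisonTable:
    def test_covers_annotated_classes_with_bh_option(self, small_study):
        table = class_comparison_table(small_study.scan, small_study.annotations, bh=True)
        assert {"category", "class", "p", "p_bh", "direction"} <= set(table.columns)
        seen = {
            (rec.category, rec.class_label) for rec in small_study.annotations.records
        }
        assert seen == set(map(tuple, table[["category", "class"]].itertuples(index=False)))
        assert (table["p_bh"] >= table["p"] - 1e-15).all()
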
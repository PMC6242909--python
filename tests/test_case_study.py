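"""Per-protein landscapes and blind-test procedures."""

import numpy as np
import pandas as pd
import pytest

from satmut import (
    AnnotationSet,
    EffectModel,
    GeneratorConfig,
    LabelledVariantSet,
    LandscapeMatrix,
    ProteinSet,
    ScoredScan,
    ValidationError,
    cross_predictor_agreement,
    discrimination_test,
    generate_blind_set,
    generate_scan,
    min_score_check,
    protein_landscape,
    read_labelled_variants,
    simulate_study,
)
from satmut.alphabet import AA_INDEX, STANDARD_AAS

COLS = ["accession", "position", "wt", "mut", "score"]


def _constant_scan(sequences, value):
    proteome = ProteinSet.from_sequences(sequences)
    rows = []
    for protein in proteome:
        for pos, wt in enumerate(protein.sequence, start=1):
            if wt not in AA_INDEX:
                continue
            for mut in STANDARD_AAS:
                if mut != wt:
                    rows.append((protein.accession, pos, wt, mut, value))
    return ScoredScan(proteome, pd.DataFrame(rows, columns=COLS))


class TestLandscape:
    def test_constant_two_residue_protein(self):
        scan = _constant_scan([("P1", "AC")], 0.7)
        matrix = protein_landscape(scan, "P1")
        assert matrix.scores.shape == (2, 20)
        assert np.nansum(matrix.scores) == pytest.approx(38 * 0.7)
        # exactly one wild-type (NaN) cell per standard row
        assert np.isnan(matrix.scores[0, AA_INDEX["A"]])
        assert np.isnan(matrix.scores[1, AA_INDEX["C"]])
        assert np.isnan(matrix.scores).sum() == 2

    def test_tsv_roundtrip(self, tmp_path):
        study = simulate_study(
            GeneratorConfig(n_proteins=1, length_range=(25, 25), category_plans={}, seed=2)
        )
        matrix = protein_landscape(study.scan, study.proteome.accessions[0])
        path = tmp_path / "landscape.tsv"
        matrix.to_tsv(path)
        assert LandscapeMatrix.from_tsv(path) == matrix

    def test_cells_match_scan_point_lookups(self, small_study):
        accession = small_study.proteome.accessions[0]
        matrix = protein_landscape(small_study.scan, accession)
        sub = small_study.scan.variants
        sub = sub[sub["accession"] == accession]
        rng = np.random.default_rng(0)
        probes = sub.sample(n=100, random_state=7)
        for row in probes.itertuples(index=False):
            assert matrix.scores[row.position - 1, AA_INDEX[row.mut]] == row.score

    def test_lossless_rebuild_of_scan_subset(self):
        scan = _constant_scan([("P1", "ACD")], 0.25)
        matrix = protein_landscape(scan, "P1")
        rebuilt = matrix.to_scan_frame().sort_values(COLS[:4]).reset_index(drop=True)
        original = scan.variants.sort_values(COLS[:4]).reset_index(drop=True)
        pd.testing.assert_frame_equal(rebuilt, original)

    def test_incomplete_scan_lists_missing_cells(self):
        scan = _constant_scan([("P1", "AC")], 0.5)
        truncated = ScoredScan(scan.proteome, scan.variants.iloc[:-2], complete=False)
        with pytest.raises(ValidationError, match=r"2 missing cells.*\(2, "):
            protein_landscape(truncated, "P1")

    def test_nonstandard_rows_have_no_marker_or_scores(self):
        scan = _constant_scan([("P1", "AXC")], 0.5)
        matrix = protein_landscape(scan, "P1")
        assert np.isnan(matrix.scores[1]).all()


def _labelled(rows, labels=("change", "no_change")):
    frame = pd.DataFrame(rows, columns=COLS[:4] + ["label", "score"])
    return LabelledVariantSet(frame, labels=labels)


class TestMinScoreCheck:
    def test_above_threshold(self):
        variants = _labelled(
            [("P1", 1, "A", "V", "change", 0.6), ("P1", 2, "C", "W", "change", 0.8)]
        )
        check = min_score_check(variants, threshold=0.59)
        assert (check.min_score, check.all_above) == (0.6, True)

    def test_boundary_is_strict_by_default(self):
        variants = _labelled(
            [("P1", 1, "A", "V", "change", 0.59), ("P1", 2, "C", "W", "change", 0.8)]
        )
        strict = min_score_check(variants, threshold=0.59)
        assert (strict.min_score, strict.all_above) == (0.59, False)
        inclusive = min_score_check(variants, threshold=0.59, strict=False)
        assert inclusive.all_above

    def test_label_filter_and_empty_rejection(self):
        variants = _labelled([("P1", 1, "A", "V", "no_change", 0.2)])
        with pytest.raises(ValidationError, match="empty"):
            min_score_check(variants, label="change")

    def test_high_planted_effect_clears_conventional_threshold(self):
        """Deleterious-labelled synthetic variants exceed 0.5 in ≥95% of seeds."""
        from satmut import CategoryPlan

        model = EffectModel(
            beta0=-0.8,
            beta_class={"Active site": 4.0},
            sigma=0.3,
        )
        plans = {"functional": CategoryPlan(0.08, (1, 3), labels=("Active site",))}
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            study = simulate_study(
                GeneratorConfig(
                    n_proteins=4, length_range=(120, 150),
                    category_plans=plans, seed=seed,
                ),
                model,
            )
            blind = generate_blind_set(
                study.scan,
                study.annotations,
                category="functional",
                class_label="Active site",
                n_positive=25,
                n_negative=25,
                seed=seed,
            )
            check = min_score_check(blind, label="change", threshold=0.5)
            hits += check.all_above
        assert hits >= 0.95 * n_seeds


class TestDiscrimination:
    def test_identical_distributions_p_one(self):
        rows = [("P1", i + 1, "A", "V", lab, s)
                for i, (lab, s) in enumerate(
                    [("change", 0.2), ("change", 0.5), ("no_change", 0.2), ("no_change", 0.5)]
                )]
        result = discrimination_test(_labelled(rows))
        assert result.comparison.p == 1.0

    def test_perfect_separation_small_p(self):
        rows = [("P1", i + 1, "A", "V", "change", 0.6 + i * 0.01) for i in range(20)]
        rows += [("P1", 100 + i, "A", "V", "no_change", 0.1 + i * 0.01) for i in range(20)]
        result = discrimination_test(_labelled(rows))
        assert result.comparison.p < 1e-6
        assert result.comparison.direction == 1

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        rows = [
            ("P1", i + 1, "A", "V", "change" if i % 2 else "no_change", rng.random())
            for i in range(30)
        ]
        fwd = discrimination_test(_labelled(rows))
        swapped = [
            (acc, pos, wt, mut, "no_change" if lab == "change" else "change", s)
            for acc, pos, wt, mut, lab, s in rows
        ]
        rev = discrimination_test(_labelled(swapped))
        assert fwd.comparison.p == pytest.approx(rev.comparison.p)
        assert fwd.comparison.statistic == pytest.approx(-rev.comparison.statistic)

    def test_single_label_rejected(self):
        variants = _labelled([("P1", 1, "A", "V", "change", 0.4)])
        with pytest.raises(ValidationError, match="both labels"):
            discrimination_test(variants)

    def test_planted_two_class_direction(self):
        """Positives from an enriched class score higher in ≥99% of replicates."""
        from satmut import CategoryPlan

        plans = {"functional": CategoryPlan(0.08, (1, 3), labels=("Active site",))}
        ok = 0
        n_seeds = 25
        for seed in range(n_seeds):
            study = simulate_study(
                GeneratorConfig(
                    n_proteins=4, length_range=(150, 150),
                    category_plans=plans, seed=seed,
                )
            )
            blind = generate_blind_set(
                study.scan,
                study.annotations,
                category="functional",
                class_label="Active site",
                n_positive=80,
                n_negative=80,
                seed=seed,
            )
            ok += discrimination_test(blind).comparison.direction == 1
        assert ok == n_seeds


class TestCrossPredictor:
    def test_self_agreement(self, small_study):
        result = cross_predictor_agreement(small_study.scan, small_study.scan)
        assert result.r == pytest.approx(1.0)
        assert result.n_matched == len(small_study.scan)

    def test_anticorrelated_transform(self, small_study):
        flipped_frame = small_study.scan.variants.copy()
        flipped_frame["score"] = 1.0 - flipped_frame["score"]
        flipped = ScoredScan(small_study.proteome, flipped_frame)
        assert cross_predictor_agreement(small_study.scan, flipped).r == pytest.approx(-1.0)

    def test_noise_attenuation_matches_monte_carlo(self, small_study):
        """r under additive noise tracks sd_s/sqrt(sd_s² + σ²)."""
        scores = small_study.scan.scores
        sigma = 0.05
        expected = scores.std() / np.sqrt(scores.var() + sigma**2)
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(20):
            noisy_frame = small_study.scan.variants.copy()
            noisy_frame["score"] = np.clip(
                scores + rng.normal(0, sigma, scores.size), 0, 1
            )
            noisy = ScoredScan(small_study.proteome, noisy_frame)
            rs.append(cross_predictor_agreement(small_study.scan, noisy).r)
        rs = np.array(rs)
        assert abs(rs.mean() - expected) < 3 * rs.std() + 0.005

    def test_too_few_matches_rejected(self):
        a = _constant_scan([("P1", "AC")], 0.5)
        b = _constant_scan([("P2", "AC")], 0.5)
        with pytest.raises(ValidationError, match="matched"):
            cross_predictor_agreement(a, b)


class TestLabelledVariantIO:
    def test_read_joins_scores_and_roundtrips(self, tmp_path, small_study):
        blind = generate_blind_set(
            small_study.scan,
            small_study.annotations,
            category="domain",
            class_label="Domain",
            n_positive=10,
            n_negative=10,
            seed=1,
        )
        path = tmp_path / "labels.tsv"
        blind.write(path)
        again = read_labelled_variants(path, small_study.scan)
        pd.testing.assert_frame_equal(
            again.frame[COLS[:4] + ["label", "score"]],
            blind.frame[COLS[:4] + ["label", "score"]],
        )

    def test_unscored_variant_rejected(self, tmp_path):
        scan = _constant_scan([("P1", "AC")], 0.5)
        path = tmp_path / "labels.tsv"
        path.write_text(
            "accession\tposition\twt\tmut\tlabel\nP9\t1\tA\tV\tchange\n"
        )
        with pytest.raises(ValidationError, match="no score"):
            read_labelled_variants(path, scan)

    def test_duplicate_keys_and_bad_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            _labelled([("P1", 1, "A", "V", "change", 0.4)] * 2)
        with pytest.raises(ValidationError, match="vocabulary"):
            _labelled([("P1", 1, "A", "V", "maybe", 0.4)])
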
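"""PWM handling, exact p-values, scanning, shuffles, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from atacrna import motif as mo
from atacrna.synthetic import random_pwm, sample_pwm_instance

from conftest import random_sequences


def one_hot_pwm(consensus: str, pwm_id="oh") -> mo.PWM:
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0
    return mo.PWM(pwm_id, mat)


class TestPWM:
    def test_information_content_closed_forms(self):
        uniform = mo.PWM("u", np.full((8, 4), 0.25))
        assert uniform.information_content == pytest.approx(0.0)
        assert one_hot_pwm("ACGTACGT").information_content == \
            pytest.approx(16.0)

    def test_columns_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mo.PWM("bad", np.full((4, 4), 0.3))

    def test_jaspar_roundtrip(self, tmp_path):
        pwm = random_pwm(9, np.random.default_rng(0), "MA0001", "SOX9")
        path = tmp_path / "m.jaspar"
        mo.write_jaspar([pwm], path, counts_scale=10_000)
        back = mo.read_jaspar(path)
        assert len(back) == 1 and back[0].width == 9
        assert np.allclose(back[0].matrix, pwm.matrix, atol=1e-3)


class TestEstimateBackground:
    def test_palindromic_sequence_is_uniform(self):
        bg = mo.estimate_background(["ACGT"])
        assert np.allclose(bg.frequencies, 0.25)

    def test_hand_counted_pseudocount_example(self):
        bg = mo.estimate_background(["AAAA"])
        # strand sum: A=4 + revcomp T=4; +1 pseudocount each, total 12
        assert np.allclose(bg.frequencies,
                           [5 / 12, 1 / 12, 1 / 12, 5 / 12])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mo.estimate_background(["NNN"])

    def test_order1_conditionals_normalized(self):
        bg = mo.estimate_background(random_sequences(
            np.random.default_rng(0), 5, 200), order=1)
        assert np.allclose(bg.conditional.sum(axis=1), 1.0)


class TestExactPValues:
    def test_dp_equals_enumeration(self, uniform_bg):
        rng = np.random.default_rng(5)
        for w in (3, 4, 5, 6):
            pwm = mo.PWM(f"p{w}", rng.dirichlet([0.5] * 4, size=w))
            offset, probs = mo.score_distribution(pwm, uniform_bg)
            tails = mo.tail_probabilities(offset, probs)
            lom = pwm.int_log_odds(uniform_bg.frequencies)
            enum: dict[int, float] = {}
            for word in itertools.product(range(4), repeat=w):
                s = int(sum(lom[j, b] for j, b in enumerate(word)))
                enum[s] = enum.get(s, 0.0) + 0.25 ** w
            for s in enum:
                brute = sum(p for t, p in enum.items() if t >= s)
                assert abs(tails[s - offset] - brute) <= 1e-9

    def test_width1_one_hot_threshold_boundaries(self, uniform_bg):
        pwm = one_hot_pwm("A")
        max_score = int(pwm.int_log_odds(uniform_bg.frequencies).max())
        # P(consensus) = 0.25: passes at p=0.3, unattainable at p=0.2
        assert mo.pwm_pvalue_threshold_score(pwm, uniform_bg, 0.3) \
            <= max_score
        assert mo.pwm_pvalue_threshold_score(pwm, uniform_bg, 0.2) \
            > max_score

    def test_threshold_one_returns_minimal_score(self, uniform_bg):
        pwm = random_pwm(4, np.random.default_rng(1))
        offset, _ = mo.score_distribution(pwm, uniform_bg)
        thr = mo.pwm_pvalue_threshold_score(pwm, uniform_bg, 1.0)
        assert thr == offset

    def test_invalid_threshold_rejected(self, uniform_bg):
        pwm = random_pwm(4, np.random.default_rng(2))
        with pytest.raises(ValueError):
            mo.pwm_pvalue_threshold_score(pwm, uniform_bg, 1.5)

    def test_printed_threshold_formula(self):
        assert mo.threshold_from_alpha(0.1, 250, 2) == pytest.approx(2e-4)


class TestScanning:
    def test_planted_consensus_found(self, uniform_bg):
        pwm = random_pwm(8, np.random.default_rng(3))
        seq = "ACGTACGTACGT" + pwm.consensus() + "TTGACGTACA"
        hits = mo.MotifScanner(pwm, uniform_bg).scan(seq)
        assert 12 in hits["position"].tolist()

    def test_strand_symmetry(self, uniform_bg):
        rng = np.random.default_rng(4)
        pwm = random_pwm(7, rng)
        scanner = mo.MotifScanner(pwm, uniform_bg)
        for seq in random_sequences(rng, 20, 120):
            seq = seq[:40] + pwm.consensus() + seq[40:]
            rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert scanner.count_hits([seq])[0] == \
                scanner.count_hits([rc])[0]

    def test_sequence_shorter_than_pwm(self, uniform_bg):
        pwm = random_pwm(10, np.random.default_rng(5))
        assert mo.MotifScanner(pwm, uniform_bg).count_hits(["ACG"])[0] == 0

    def test_null_hit_rate_matches_threshold(self, uniform_bg):
        """On i.i.d. background the per-window hit rate is at most the
        threshold p, and close to it within a Poisson band."""
        rng = np.random.default_rng(53)
        pwm = random_pwm(8, rng)
        scanner = mo.MotifScanner(pwm, uniform_bg, p_threshold=2e-4)
        offset, probs = mo.score_distribution(pwm, uniform_bg)
        exact_p = float(mo.tail_probabilities(offset, probs)[
            scanner.threshold_score - offset])
        seqs = random_sequences(rng, 500, 1000)
        total = scanner.count_hits(seqs).sum()
        n_windows = 500 * (1000 - 8 + 1) * 2
        expected = n_windows * exact_p
        assert exact_p <= 2e-4
        assert abs(total - expected) <= 3 * np.sqrt(expected)


class TestShuffleRegions:
    def _regions(self, n=20, length=100):
        starts = np.arange(n) * 1000
        return pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": starts + length})

    def test_universe_mode_size_and_membership(self):
        regions = self._regions(10)
        universe = self._regions(50)
        rng = np.random.default_rng(0)
        sets = mo.shuffle_regions(regions, "peak_universe", 5, rng,
                                  universe=universe)
        keys = set(zip(universe["chrom"], universe["start"]))
        for s in sets:
            assert len(s) == 10
            assert set(zip(s["chrom"], s["start"])) <= keys

    def test_universe_smaller_than_target_rejected(self):
        with pytest.raises(ValueError):
            mo.shuffle_regions(self._regions(30), "peak_universe", 2,
                               np.random.default_rng(0),
                               universe=self._regions(10))

    def test_genome_mode_respects_exclusion(self):
        rng = np.random.default_rng(59)
        regions = self._regions(10, length=50)
        excl = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                             "end": [40_000]})
        sets = mo.shuffle_regions(regions, "genome", 3, rng,
                                  chrom_sizes={"chr1": 100_000},
                                  exclusion=excl)
        for s in sets:
            assert (s["start"] >= 40_000).all()

    def test_genome_mode_dense_exclusion_fails(self):
        excl = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                             "end": [99_990]})
        with pytest.raises(RuntimeError):
            mo.shuffle_regions(self._regions(5, 50), "genome", 1,
                               np.random.default_rng(1),
                               chrom_sizes={"chr1": 100_000},
                               exclusion=excl, max_tries=50)

    def test_genome_mode_placement_proportional_to_length(self):
        rng = np.random.default_rng(59)
        sizes = {"chr1": 300_000, "chr2": 100_000}
        regions = self._regions(4, 100)
        sets = mo.shuffle_regions(regions, "genome", 500, rng,
                                  chrom_sizes=sizes)
        counts = pd.concat(sets)["chrom"].value_counts()
        n = counts.sum()
        p = 0.75
        sd = np.sqrt(n * p * (1 - p))
        assert abs(counts["chr1"] - n * p) <= 3 * sd


class TestEnrichment:
    def test_planted_motif_strongly_enriched(self, uniform_bg):
        rng = np.random.default_rng(67)
        pwm = random_pwm(10, rng)
        univ = random_sequences(rng, 400, 250)
        targets = []
        for i in range(100):
            s = random_sequences(rng, 1, 250)[0]
            if i < 50:
                pos = int(rng.integers(0, 240))
                s = s[:pos] + sample_pwm_instance(pwm, rng) + s[pos + 10:]
            targets.append(s)
        shuffles = [[univ[j] for j in rng.choice(400, 100, replace=False)]
                    for _ in range(40)]
        res = mo.enrichment_test(targets, shuffles, pwm, uniform_bg)
        assert res["p_enrich"] < 1e-4

    def test_depletion_mirror(self, uniform_bg):
        rng = np.random.default_rng(68)
        pwm = random_pwm(10, rng)
        univ = []
        for i in range(400):
            s = random_sequences(rng, 1, 250)[0]
            pos = int(rng.integers(0, 240))
            univ.append(s[:pos] + sample_pwm_instance(pwm, rng)
                        + s[pos + 10:])
        targets = random_sequences(rng, 100, 250)
        shuffles = [[univ[j] for j in rng.choice(400, 100, replace=False)]
                    for _ in range(40)]
        res = mo.enrichment_test(targets, shuffles, pwm, uniform_bg)
        assert res["p_deplete"] < 1e-4 and res["p_enrich"] > 0.999

    def test_tail_probabilities_sum_to_one(self, uniform_bg):
        res = mo.standardized_enrichment(5.0, np.array([1.0, 2, 3, 4, 5]))
        assert res["p_enrich"] + res["p_deplete"] == pytest.approx(1.0)

    def test_zero_variance_background_flagged(self):
        res = mo.standardized_enrichment(3.0, np.full(50, 2.0))
        assert res["degenerate"] and res["p_enrich"] == 1.0

    def test_too_few_shuffles_rejected(self, uniform_bg):
        pwm = random_pwm(5, np.random.default_rng(0))
        with pytest.raises(ValueError):
            mo.enrichment_test(["ACGT"], [["ACGT"]] * 5, pwm, uniform_bg)


class TestSelectDeTfs:
    def _library(self):
        uniform = mo.PWM("u8", np.full((8, 4), 0.25), name="SOX9")
        sharp = one_hot_pwm("ACGTACGT")
        sharp.name = "SOX9"
        other = one_hot_pwm("TTTTAAAA", pwm_id="oh2")
        other.name = "RUNX2"
        return [uniform, sharp, other]

    def test_highest_ic_matrix_retained(self):
        chosen = mo.select_de_tfs(["Sox9"], self._library())
        assert list(chosen) == ["SOX9"]
        assert chosen["SOX9"].information_content == pytest.approx(16.0)

    def test_no_overlap_gives_empty_set(self):
        assert mo.select_de_tfs(["GATA4"], self._library()) == {}

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            mo.select_de_tfs(["SOX9"], [])


class TestIcDiagnostic:
    def test_requires_three_tfs(self, uniform_bg):
        pwms = {f"t{i}": random_pwm(6, np.random.default_rng(i))
                for i in range(2)}
        with pytest.raises(ValueError):
            mo.ic_hit_fraction_diagnostic(pwms, ["ACGTACGT"], uniform_bg)

    def test_negative_ic_hit_correlation_on_designed_set(self, uniform_bg):
        # one-hot PWMs of growing width: IC = 2w grows while the
        # achievable per-window hit probability (4^-w) falls, so the
        # hit fraction strictly decreases in IC
        rng = np.random.default_rng(6)
        pwms = {}
        for w in (5, 6, 7, 8):
            cons = "".join(rng.choice(list("ACGT"), w))
            pwms[f"w{w}"] = one_hot_pwm(cons, pwm_id=f"w{w}")
        seqs = random_sequences(rng, 300, 400)
        res = mo.ic_hit_fraction_diagnostic(pwms, seqs, uniform_bg,
                                            p_threshold=1e-3)
        # the discrete score distribution makes the achieved per-window
        # p sawtooth below the threshold, so only the trend is asserted
        assert res["pearson_r"] < 0

    def test_duplicate_pwms_flagged_undefined(self, uniform_bg):
        pwm = random_pwm(6, np.random.default_rng(7))
        pwms = {f"t{i}": pwm for i in range(3)}
        res = mo.ic_hit_fraction_diagnostic(pwms, ["ACGTACGTAC"], uniform_bg)
        assert np.isnan(res["pearson_r"])


def brute_force_hypergeom(N, K, n, k):
    """P(X >= k) by direct combinatorial enumeration."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
    return total / comb(N, n, exact=True)


class TestChipOverlap:
    def _frames(self, n, overlap_with_chip):
        regions = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 100})
        chip = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(overlap_with_chip) * 1000 + 50,
            "end": np.arange(overlap_with_chip) * 1000 + 80})
        return regions, chip

    def test_closed_form_example(self):
        universe, chip = self._frames(10, 5)
        target = universe.iloc[:4].reset_index(drop=True)
        res = mo.chip_overlap_test(target, chip, universe)
        assert (res["N"], res["K"], res["n"], res["k"]) == (10, 5, 4, 4)
        assert res["p"] == pytest.approx(5 / 210)

    def test_saturated_and_empty_overlap(self):
        universe, chip = self._frames(6, 6)
        res = mo.chip_overlap_test(universe, chip, universe)
        assert res["p"] == pytest.approx(1.0)
        no_chip = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [1]})
        res0 = mo.chip_overlap_test(universe.iloc[:3], no_chip, universe)
        assert res0["k"] == 0 and res0["p"] == 1.0

    def test_target_outside_universe_rejected(self):
        universe, chip = self._frames(5, 2)
        stranger = pd.DataFrame({"chrom": ["chr2"], "start": [0],
                                 "end": [10]})
        with pytest.raises(ValueError):
            mo.chip_overlap_test(stranger, chip, universe)

    def test_exhaustive_small_instances(self):
        for N in (4, 8, 12):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    universe, chip = self._frames(N, K)
                    target = universe.iloc[:n].reset_index(drop=True)
                    res = mo.chip_overlap_test(target, chip, universe)
                    assert res["p"] == pytest.approx(
                        brute_force_hypergeom(N, K, n, res["k"]), abs=1e-12)
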
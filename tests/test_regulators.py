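"""PWM scanning, target sets, activity tests, GSEA and over-representation
against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from exondys.regulators import (
    EnrichmentResult,
    Pwm,
    RegulatorError,
    TargetSet,
    build_target_sets,
    gsea_enrichment,
    interaction_test,
    overrepresentation_test,
    reverse_complement,
    scan_pwm,
    target_set_activity,
)


def _consensus_pwm(consensus, tf_id="TF"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((4, len(consensus)))
    for i, b in enumerate(consensus):
        mat[idx[b], i] = 1.0
    return Pwm(tf_id, mat, pseudocount=0.01)


class TestScanPwm:
    def test_exact_consensus_similarity_one(self, rng):
        consensus = "TGACCTTTGACCTTT"
        pwm = _consensus_pwm(consensus)
        seq = "".join(rng.choice(list("CG"), size=40)) + consensus + "".join(
            rng.choice(list("CG"), size=40)
        )
        hits = scan_pwm(seq, pwm, min_similarity=0.99)
        fw = [h for h in hits if h[1] == "+"]
        assert len(fw) == 1
        assert fw[0][0] == 40
        assert fw[0][2] == pytest.approx(1.0)

    def test_no_window_above_threshold_empty(self):
        pwm = _consensus_pwm("AAAAAAAA")
        assert scan_pwm("CCCCCCCCCCCCCCCC", pwm, 0.95) == []

    def test_matches_naive_oracle_on_10kb(self, rng):
        """Hit set at threshold 0.95 equals a per-window brute-force scan."""
        pwm = Pwm("TF", rng.dirichlet([0.3] * 4, size=10).T, pseudocount=0.01)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        hits = scan_pwm(seq, pwm, min_similarity=0.95)

        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        lo = pwm.matrix.min(axis=0).sum()
        hi = pwm.matrix.max(axis=0).sum()

        def naive(s):
            out = []
            for off in range(len(s) - pwm.length + 1):
                score = sum(pwm.matrix[idx[s[off + i]], i] for i in range(pwm.length))
                sim = (score - lo) / (hi - lo)
                if sim >= 0.95:
                    out.append((off, sim))
            return out

        expected = [(o, "+", s) for o, s in naive(seq)]
        expected += [
            (len(seq) - pwm.length - o, "-", s) for o, s in naive(reverse_complement(seq))
        ]
        expected.sort(key=lambda h: (h[0], h[1]))
        assert [(o, st) for o, st, _ in hits] == [(o, st) for o, st, _ in expected]
        np.testing.assert_allclose([h[2] for h in hits], [h[2] for h in expected], rtol=1e-9)

    def test_strand_symmetric(self, rng):
        pwm = Pwm("TF", rng.dirichlet([0.5] * 4, size=8).T)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd = scan_pwm(seq, pwm, 0.8)
        rev = scan_pwm(reverse_complement(seq), pwm, 0.8)
        # offsets mirror, similarities identical
        mirrored = sorted(
            (len(seq) - pwm.length - o, {"+": "-", "-": "+"}[st], sim) for o, st, sim in rev
        )
        assert [(o, sim) for o, _, sim in sorted(fwd)] == pytest.approx(
            [(o, sim) for o, _, sim in mirrored]
        )

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(RegulatorError):
            scan_pwm("ACG", _consensus_pwm("AAAAAAAA"), 0.9)


class TestTargetSets:
    def test_planted_sites_recovered_exactly(self, small_dataset):
        """Promoter target sets equal exactly the genes the generator
        planted sites into."""
        ds = small_dataset
        truth = ds.gene_truth.set_index("gene_id")
        promoters = {g: ds.sequences[f"{g}_promoter"] for g in truth.index}
        sets = build_target_sets(promoters, ds.pwm_library, "promoter_1kb")
        for tf in ds.pwm_library:
            planted = {
                g for g in truth.index
                if f"{tf}:promoter" in str(truth.loc[g, "tf_memberships"]).split(";")
            }
            assert sets[tf].gene_ids == frozenset(planted)

    def test_intron_and_promoter_scopes_differ(self, small_dataset):
        ds = small_dataset
        truth = ds.gene_truth.set_index("gene_id")
        tf = next(
            (t for t in ds.pwm_library
             if any(f"{t}:intron" in str(m).split(";") for m in truth["tf_memberships"])),
            None,
        )
        if tf is None:
            pytest.skip("no intron-scope memberships in this scenario")
        introns = {g: ds.sequences[f"{g}_intron"] for g in truth.index}
        promoters = {g: ds.sequences[f"{g}_promoter"] for g in truth.index}
        s_int = build_target_sets(introns, {tf: ds.pwm_library[tf]}, "intron")
        s_pro = build_target_sets(promoters, {tf: ds.pwm_library[tf]}, "promoter_1kb")
        assert s_int[tf].gene_ids != s_pro[tf].gene_ids

    def test_empty_library_empty_output(self):
        assert build_target_sets({"g": "ACGT" * 50}, {}, "promoter_1kb") == {}


class TestTargetSetActivity:
    def test_planted_shift_detected(self, rng):
        changes = {f"g{i}": float(rng.normal(0, 10)) for i in range(2000)}
        targets = [f"g{i}" for i in range(200)]
        for t in targets:
            changes[t] += 10.0
        mt, mn, p = target_set_activity(changes, targets)
        assert p < 0.01
        assert (mt - mn) == pytest.approx(10.0, abs=2.0)

    def test_null_calibration(self, rng):
        """1,000 random 'TF' target sets on null changes: rejection at
        0.05 stays within the binomial band around the nominal level."""
        changes = {f"g{i}": float(rng.normal(0, 10)) for i in range(2000)}
        genes = np.array(list(changes))
        rejections = 0
        for _ in range(1000):
            targets = rng.choice(genes, size=100, replace=False)
            _, _, p = target_set_activity(changes, targets)
            rejections += p < 0.05
        assert 30 <= rejections <= 70

    def test_identical_changes_zero_difference(self):
        changes = {f"g{i}": 5.0 for i in range(10)}
        mt, mn, p = target_set_activity(changes, ["g0", "g1"])
        assert mt - mn == 0.0

    def test_invariant_to_unmeasured_genes(self, rng):
        changes = {f"g{i}": float(rng.normal()) for i in range(50)}
        targets = [f"g{i}" for i in range(10)] + ["missing1", "missing2"]
        assert target_set_activity(changes, targets) == target_set_activity(
            changes, targets[:10]
        )


class TestInteraction:
    def test_planted_interaction_detected(self, rng):
        genes = [f"g{i}" for i in range(600)]
        set_a = TargetSet("A", "promoter_1kb", frozenset(genes[:300]))
        set_b = TargetSet("B", "promoter_1kb", frozenset(genes[150:450]))
        changes = {g: float(rng.normal(0, 5)) for g in genes}
        for g in genes[150:300]:  # both sites
            changes[g] -= 10.0
        out = interaction_test(set_a, set_b, changes)
        assert out["p_both_vs_a"] < 0.05
        assert out["p_both_vs_b"] < 0.05
        assert out["mean_both"] < out["mean_a_only"]

    def test_empty_both_set_rejected(self):
        set_a = TargetSet("A", "promoter_1kb", frozenset(["g1"]))
        set_b = TargetSet("B", "promoter_1kb", frozenset(["g2"]))
        with pytest.raises(RegulatorError):
            interaction_test(set_a, set_b, {"g1": 1.0, "g2": 2.0})


class TestGsea:
    def test_top_ranked_members_give_es_one(self):
        stats_ = {f"g{i}": 10.0 - i for i in range(10)}
        res = gsea_enrichment(stats_, {"g0", "g1", "g2"}, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_single_member_ranked_first_es_one(self):
        stats_ = {f"g{i}": 10.0 - i for i in range(20)}
        res = gsea_enrichment(stats_, {"g0"}, n_perm=50, seed=0, min_set_size=1)
        assert res.es == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        """10-gene list, 3-member set: ES equals a hand-rolled running sum
        and p equals exhaustive enumeration over C(10,3)=120 sets."""
        values = np.sort(rng.normal(size=10))[::-1]
        genes = [f"g{i}" for i in range(10)]
        stats_ = dict(zip(genes, values))
        members = {"g1", "g4", "g7"}
        res = gsea_enrichment(stats_, members, weight=1.0, seed=0)

        def brute_es(member_idx):
            hits = np.zeros(10, dtype=bool)
            hits[list(member_idx)] = True
            norm = np.abs(values[hits]).sum()
            running, best = 0.0, 0.0
            for i in range(10):
                running += abs(values[i]) / norm if hits[i] else -1.0 / 7
                if abs(running) > abs(best):
                    best = running
            return best

        es_oracle = brute_es([1, 4, 7])
        assert res.es == pytest.approx(es_oracle, abs=1e-9)
        perm = [brute_es(c) for c in itertools.combinations(range(10), 3)]
        assert len(perm) == 120
        p_oracle = np.mean([abs(e) >= abs(es_oracle) - 1e-12 for e in perm])
        assert res.p == pytest.approx(p_oracle, abs=1e-9)

    def test_running_sum_terminates_at_zero(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            stats_ = {f"g{i}": float(rng.normal()) for i in range(n)}
            members = set(rng.choice(n, size=5, replace=False))
            res = gsea_enrichment(stats_, {f"g{i}" for i in members}, n_perm=10, seed=0)
            assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-9)

    def test_small_set_rejected(self):
        stats_ = {f"g{i}": float(i) for i in range(10)}
        with pytest.raises(RegulatorError):
            gsea_enrichment(stats_, {"g0", "g1"}, seed=0)


class TestOverrepresentation:
    def test_no_overlap_p_near_one(self):
        background = {f"g{i}" for i in range(100)}
        overlap, p = overrepresentation_test(
            {f"g{i}" for i in range(50)}, {"g90", "g91"}, background
        )
        assert overlap == 0
        # exact hypergeometric tail at 0 is 1
        assert p == pytest.approx(1.0)

    def test_matches_factorial_oracle(self):
        """subset == category: p equals the closed-form hypergeometric
        mass computed from factorials."""
        background = {f"g{i}" for i in range(100)}
        category = {f"g{i}" for i in range(10)}
        overlap, p = overrepresentation_test(category, category, background)
        assert overlap == 10

        def comb(n, k):
            return math.factorial(n) // (math.factorial(k) * math.factorial(n - k))

        # P(X >= 10) drawing 10 from 100 with 10 marked = only X=10 term
        p_oracle = comb(10, 10) * comb(90, 0) / comb(100, 10)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_category_equals_background_p_one(self):
        background = {f"g{i}" for i in range(20)}
        _, p = overrepresentation_test({"g1", "g2"}, background, background)
        assert p == pytest.approx(1.0)

    def test_subset_outside_background_rejected(self):
        with pytest.raises(RegulatorError):
            overrepresentation_test({"x"}, {"g1"}, {"g1", "g2"})
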
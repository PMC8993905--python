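"""Alignment filtering/reweighting and contact-prediction evaluation."""

import numpy as np
import pytest

from masdyn.coevolution_eval import (ContactReference, RankedPairs,
                                     evaluate_predictions, filter_coverage,
                                     mi_apc_scores, read_alignment, reweight)
from masdyn.synthetic_data import make_msa


class TestFilterCoverage:
    def test_boundary_is_inclusive(self):
        s_keep = "-" * 25 + "A" * 75
        s_drop = "-" * 26 + "A" * 74
        kept = filter_coverage([s_keep, s_drop])
        assert kept == [s_keep]

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        seqs = []
        for _ in range(50):
            n_gaps = rng.integers(0, 40)
            chars = ["A"] * (40 - n_gaps) + ["-"] * n_gaps
            rng.shuffle(chars)
            seqs.append("".join(chars))
        kept = filter_coverage(seqs, 0.25)
        expected = [s for s in seqs if s.count("-") / len(s) <= 0.25]
        assert kept == expected

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="removed every"):
            filter_coverage(["-" * 10])


class TestReweight:
    def test_identical_sequences_share_unit_weight(self):
        w = reweight(["ACDEF"] * 10)
        assert np.allclose(w.weights, 0.1)
        assert w.b_eff == pytest.approx(1.0)

    def test_diverse_sequences_keep_full_weight(self):
        seqs = ["ACDEFGHIKL", "LMNPQRSTVW", "YACDGHWLMN"]
        w = reweight(seqs)
        assert np.allclose(w.weights, 1.0)
        assert w.b_eff == pytest.approx(3.0)

    def test_duplication_invariance_of_beff(self):
        msa = make_msa(60, 25, covarying_pairs=(), seed=2)["sequences"]
        w1 = reweight(msa)
        w2 = reweight(msa + msa)  # every sequence duplicated
        assert w2.b_eff == pytest.approx(w1.b_eff, rel=1e-9)

    def test_gap_handling_option(self):
        # 9 of 10 matching columns; the tenth gapped in one sequence
        a = "AAAAAAAAA-"
        b = "AAAAAAAAAC"
        # gap as 21st symbol: identity 9/10 = 0.9 > 0.85 -> clustered
        w_gap = reweight([a, b], 0.85)
        assert w_gap.b_eff == pytest.approx(1.0)
        w_nogap = reweight([a, b], 0.95, include_gaps=False)
        # ignoring the gapped column, identity = 9/9 = 1 > 0.95 -> clustered
        assert w_nogap.b_eff == pytest.approx(1.0)


class TestEvaluatePredictions:
    @staticmethod
    def toy_reference(n=20, seed=0):
        rng = np.random.default_rng(seed)
        dist = {}
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                dist[(i, j)] = float(rng.uniform(3.0, 15.0))
        return ContactReference(dist, set(range(1, n + 1)))

    def test_oracle_ranking_gives_perfect_ppv(self):
        ref = self.toy_reference()
        pairs = RankedPairs([(i, j, -d) for (i, j), d in
                             ref.distances.items()])
        contacts = [(i, j) for (i, j), d in ref.distances.items()
                    if d < 8.0 and j - i > 4]
        ppv, ppv_def, _ = evaluate_predictions(pairs, ref, len(contacts))
        assert ppv == 1.0
        assert ppv_def == 1.0

    def test_brute_force_recount(self):
        ref = self.toy_reference(seed=3)
        rng = np.random.default_rng(4)
        pairs = RankedPairs([(i, j, float(rng.normal()))
                             for (i, j) in ref.distances])
        top_k = 25
        ppv, _, labels = evaluate_predictions(pairs, ref, top_k,
                                              min_separation=4, cutoff=8.0)
        # independent recount
        eligible = sorted(((i, j, s) for i, j, s in pairs.pairs
                           if j - i > 4), key=lambda p: -p[2])[:top_k]
        expected = sum(ref.distances[(i, j)] < 8.0
                       for i, j, _ in eligible) / top_k
        assert ppv == pytest.approx(expected, abs=1e-12)
        assert len(labels) == top_k

    def test_topk_exceeding_pairs_warns(self):
        ref = self.toy_reference(n=8)
        pairs = RankedPairs([(1, 7, 1.0), (2, 8, 0.5)])
        with pytest.warns(UserWarning, match="eligible pairs"):
            ppv, _, labels = evaluate_predictions(pairs, ref, 50)
        assert len(labels) == 2

    def test_contact_sets_nested_in_cutoff(self):
        ref = self.toy_reference(seed=9)
        pairs = RankedPairs([(i, j, 1.0 / (i + j))
                             for (i, j) in ref.distances])
        tp = {}
        for cutoff in (5.0, 7.0, 8.0):
            _, _, labels = evaluate_predictions(pairs, ref, 40,
                                                cutoff=cutoff)
            tp[cutoff] = set(map(tuple, labels[labels["contact"]]
                                 [["i", "j"]].to_numpy()))
        assert tp[5.0] <= tp[7.0] <= tp[8.0]

    def test_random_scores_recover_contact_density(self):
        # mean PPV of random rankings estimates the contact density among
        # eligible pairs, within binomial error
        ref = self.toy_reference(n=30, seed=11)
        eligible = [(i, j) for (i, j) in ref.distances if j - i > 4]
        density = np.mean([ref.distances[p] < 8.0 for p in eligible])
        top_k = 50
        n_seeds = 100
        ppvs = []
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            pairs = RankedPairs([(i, j, float(rng.normal()))
                                 for (i, j) in ref.distances])
            ppvs.append(evaluate_predictions(pairs, ref, top_k)[0])
        se = np.sqrt(density * (1 - density) / (n_seeds * top_k))
        assert np.mean(ppvs) == pytest.approx(density, abs=5 * se)


class TestMiApc:
    def test_covarying_pair_ranks_first(self):
        msa = make_msa(300, 30, covarying_pairs=((4, 17),),
                       coupling_strength=0.95, seed=7)
        w = reweight(msa["sequences"])
        ranked = mi_apc_scores(w)
        assert ranked.pairs[0][:2] == (4, 17)

    def test_no_signal_in_independent_columns(self):
        top_pairs = set()
        for seed in (1, 2, 3):
            msa = make_msa(150, 20, covarying_pairs=(), seed=seed)
            ranked = mi_apc_scores(reweight(msa["sequences"]))
            top_pairs.add(ranked.pairs[0][:2])
            scores = np.array([s for _, _, s in ranked.pairs])
            assert abs(np.median(scores)) < 0.05
        assert len(top_pairs) > 1  # top pair not reproducible across seeds

    def test_duplicated_rows_leave_ranking_unchanged(self):
        msa = make_msa(120, 15, covarying_pairs=((2, 9),),
                       coupling_strength=0.9, seed=5)["sequences"]
        r1 = mi_apc_scores(reweight(msa))
        r2 = mi_apc_scores(reweight(msa + msa))
        assert [p[:2] for p in r1.pairs] == [p[:2] for p in r2.pairs]

    def test_single_column_rejected(self):
        w = reweight(["A", "C", "A"])
        with pytest.raises(ValueError):
            mi_apc_scores(w)


class TestIo:
    def test_fasta_roundtrip_and_ranked_tsv(self, tmp_path):
        msa = make_msa(20, 12, covarying_pairs=(), seed=0)["sequences"]
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">s{k}\n{s}\n" for k, s in enumerate(msa)))
        back = read_alignment(fasta)
        assert back == msa
        rp = RankedPairs([(1, 6, 0.5), (2, 9, 1.5)])
        tsv = tmp_path / "scores.tsv"
        rp.to_tsv(tsv)
        back_rp = RankedPairs.from_tsv(tsv)
        assert back_rp.pairs[0][:2] == (2, 9)
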
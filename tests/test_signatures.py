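"""96-channel classification, profile building, NMF extraction, matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from comutsig.cohort_io import MutationRecord, MutationTable
from comutsig.signatures import (
    CHANNELS_96,
    ClassificationError,
    MutationalProfile,
    NMFResult,
    SignatureCatalog,
    _mu_fit,
    build_profile_matrix,
    classify_96,
    cosine,
    load_catalog,
    match_signatures,
    nmf_extract,
    normalize_signatures,
    poisson_log_likelihood,
    revcomp,
    select_rank,
)
from comutsig.simulate import simulate_profiles, synthetic_catalog


class TestClassify96:
    @pytest.mark.parametrize(
        "ref, alt, context, channel",
        [
            ("C", "T", "ACA", "A[C>T]A"),
            ("G", "A", "TGT", "A[C>T]A"),  # purine strand, revcomp first
            ("A", "G", "AAA", "T[T>C]T"),
        ],
    )
    def test_pyrimidine_convention(self, ref, alt, context, channel):
        assert classify_96(ref, alt, context) == channel

    def test_channel_order_is_substitution_major(self):
        assert CHANNELS_96[0] == "A[C>A]A"
        assert CHANNELS_96[16] == "A[C>G]A"
        assert CHANNELS_96[-1] == "T[T>G]T"

    @pytest.mark.parametrize(
        "ref, alt, context",
        [("C", "C", "ACA"), ("C", "T", "AGA"), ("C", "T", "ANA"),
         ("CC", "T", "ACA")],
    )
    def test_invalid_inputs_rejected(self, ref, alt, context):
        with pytest.raises(ClassificationError):
            classify_96(ref, alt, context)


class TestBuildProfile:
    def test_single_snv_lands_on_one_channel(self):
        t = MutationTable([MutationRecord("s1", "G", "c", 5, "C", "T", "SNV",
                                          context="ACA")])
        prof = build_profile_matrix(t)
        frame = prof.to_frame()
        assert frame.loc["A[C>T]A", "s1"] == 1
        assert frame["s1"].sum() == 1

    def test_context_lookup_from_fasta(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\nAACAG\n")
        t = MutationTable([MutationRecord("s1", "G", "chr1", 3, "C", "G",
                                          "SNV")])
        prof = build_profile_matrix(t, reference=fa)
        assert prof.to_frame().loc["A[C>G]A", "s1"] == 1

    def test_fasta_ref_mismatch_skipped_or_strict(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\nAATAG\n")
        t = MutationTable([MutationRecord("s1", "G", "chr1", 3, "C", "G",
                                          "SNV")])
        prof = build_profile_matrix(t, reference=fa)
        assert prof.n_skipped == 1 and prof.counts.sum() == 0
        with pytest.raises(ClassificationError):
            build_profile_matrix(t, reference=fa, strict=True)

    def test_indels_excluded_and_conservation(self, small_cohort):
        prof = build_profile_matrix(small_cohort.mutations)
        n_snv = sum(1 for r in small_cohort.mutations
                    if r.variant_class == "SNV")
        assert prof.counts.sum() + prof.n_skipped == n_snv

    def test_strand_invariance(self, small_cohort):
        flipped = MutationTable([
            MutationRecord(r.sample_id, r.gene, r.chrom, r.pos,
                           revcomp(r.ref), revcomp(r.alt), r.variant_class,
                           context=revcomp(r.context))
            if r.variant_class == "SNV" else r
            for r in small_cohort.mutations
        ])
        a = build_profile_matrix(small_cohort.mutations)
        b = build_profile_matrix(flipped, samples=a.samples)
        assert np.array_equal(a.counts, b.counts)


class TestCosine:
    def test_reference_values(self):
        v = np.zeros(96)
        v[0] = 1
        u = np.zeros(96)
        u[:2] = 1
        assert cosine(v, v) == pytest.approx(1.0)
        w = np.zeros(96)
        w[50] = 1
        assert cosine(v, w) == 0.0
        assert cosine(u, v) == pytest.approx(1 / np.sqrt(2), abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(96), np.ones(96))


def rank1_profile(seed=0, n=10, total=2000):
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(96) * 0.2)
    h = rng.uniform(0.5, 1.5, n)
    counts = rng.poisson(np.outer(w, h) * total)
    return MutationalProfile([f"s{i}" for i in range(n)], counts), w


class TestNMF:
    def test_rank1_recovers_generating_signature(self):
        prof, w = rank1_profile()
        res = nmf_extract(prof, 1, seed=0, restarts=3, max_iter=500)
        assert cosine(res.signatures[:, 0], w) > 0.99
        assert res.signatures[:, 0].sum() == pytest.approx(1.0)

    def test_two_disjoint_signatures_recovered(self):
        cat = synthetic_catalog(2, mode="disjoint")
        rng = np.random.default_rng(1)
        expo = rng.dirichlet([1, 1], size=25).T
        prof = simulate_profiles(cat.matrix, expo, 500, seed=1)
        res = match_signatures(
            nmf_extract(prof, 2, seed=0, restarts=5, max_iter=500), cat)
        assert all(m.cosine > 0.95 and m.matched for m in res.matches)

    def test_objective_nondecreasing_over_iterations(self):
        prof, _ = rank1_profile(seed=3)
        trace: list = []
        _mu_fit(np.asarray(prof.counts, float), 2,
                np.random.default_rng(0), max_iter=200, tol=0.0, mode="ml",
                gamma_shape=1.0, gamma_rate=0.0, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-6 * np.abs(np.asarray(trace[:-1])))

    def test_normalization_leaves_product_unchanged(self, rng):
        W = rng.uniform(0.1, 2.0, (96, 3))
        H = rng.uniform(0.1, 2.0, (3, 10))
        Wn, Hn = normalize_signatures(W, H)
        assert np.allclose(Wn @ Hn, W @ H, atol=1e-10)
        assert np.allclose(Wn.sum(axis=0), 1.0)

    def test_reconstruction_preserves_column_sums(self):
        prof, _ = rank1_profile(seed=5)
        res = nmf_extract(prof, 2, seed=0, restarts=2, max_iter=300)
        recon = res.signatures @ res.exposures
        assert np.allclose(recon.sum(axis=0), prof.counts.sum(axis=0),
                           rtol=1e-6)

    def test_map_mode_runs_and_stays_positive(self):
        prof, _ = rank1_profile(seed=6)
        res = nmf_extract(prof, 2, seed=0, restarts=2, max_iter=300,
                          mode="map")
        assert np.all(res.signatures >= 0) and np.all(res.exposures >= 0)

    def test_deterministic_for_fixed_seed(self):
        prof, _ = rank1_profile(seed=7)
        a = nmf_extract(prof, 2, seed=11, restarts=3, max_iter=200)
        b = nmf_extract(prof, 2, seed=11, restarts=3, max_iter=200)
        assert np.array_equal(a.signatures, b.signatures)
        assert a.log_likelihood == b.log_likelihood

    def test_zero_column_dropped(self):
        counts = np.zeros((96, 3), dtype=int)
        counts[0, 0] = 5
        counts[1, 2] = 5
        prof = MutationalProfile(["a", "b", "c"], counts)
        res = nmf_extract(prof, 1, seed=0, restarts=1, max_iter=50)
        assert res.samples == ["a", "c"]

    def test_k_out_of_range(self):
        prof, _ = rank1_profile()
        with pytest.raises(ValueError):
            nmf_extract(prof, 50, seed=0, restarts=1)

    def test_agrees_with_sklearn_kl_nmf(self):
        # independent cross-check: sklearn's KL multiplicative solver should
        # find the same two disjoint signatures
        from sklearn.decomposition import NMF

        cat = synthetic_catalog(2, mode="disjoint")
        rng = np.random.default_rng(2)
        expo = rng.dirichlet([1, 1], size=25).T
        prof = simulate_profiles(cat.matrix, expo, 500, seed=2)
        ours = nmf_extract(prof, 2, seed=0, restarts=5, max_iter=500)
        sk = NMF(n_components=2, beta_loss="kullback-leibler", solver="mu",
                 init="random", random_state=0, max_iter=1000)
        W_sk = sk.fit_transform(np.asarray(prof.counts, float))
        best = [max(cosine(W_sk[:, j], ours.signatures[:, i])
                    for i in range(2)) for j in range(2)]
        assert min(best) > 0.95


class TestSelectRank:
    def test_rank1_profile_selects_one(self):
        prof, _ = rank1_profile(seed=9, n=15, total=3000)
        k, diag = select_rank(prof, range(1, 4), seed=0, restarts=3,
                              max_iter=300)
        assert k == 1
        assert len(diag) == 3 and np.isfinite(diag["log_likelihood"]).all()

    def test_unpenalized_likelihood_monotone_in_k(self):
        prof, _ = rank1_profile(seed=10)
        _, diag = select_rank(prof, range(1, 4), seed=0, restarts=3,
                              max_iter=300, penalty="none")
        ll = diag["log_likelihood"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-3 * np.abs(ll[:-1]))


class TestMatchSignatures:
    def result_with(self, W):
        k = W.shape[1]
        return NMFResult(rank=k, signatures=W, exposures=np.ones((k, 2)),
                         samples=["a", "b"], log_likelihood=0.0, seed=0,
                         restarts=1)

    def test_identical_column_matched_at_one(self):
        cat = synthetic_catalog(3, mode="random", seed=4)
        res = self.result_with(cat.matrix[:, [1]])
        res = match_signatures(res, cat)
        assert res.matches[0].best_match == "SYN2"
        assert res.matches[0].cosine == pytest.approx(1.0)
        assert res.labels == ["SYN2"]

    def test_orthogonal_column_keeps_de_novo_label(self):
        cat = synthetic_catalog(2, mode="disjoint")
        W = np.zeros((96, 1))
        W[0, 0] = 1.0
        # orthogonal to SYN2 (T>* block); SYN1 overlaps partially
        res = match_signatures(self.result_with(W), cat, threshold=0.999)
        assert not res.matches[0].matched
        assert res.labels == ["SBSA"]
        assert res.matches[0].cosine > 0  # sub-threshold value still reported

    def test_one_to_one_contention_resolution(self):
        cat = synthetic_catalog(2, mode="disjoint")
        w1 = cat.matrix[:, 0]
        w2 = 0.9 * cat.matrix[:, 0] + 0.1 * cat.matrix[:, 1]
        W = np.column_stack([w2, w1])  # both closest to SYN1; w1 is closer
        res = match_signatures(self.result_with(W), cat, threshold=0.0)
        assert res.matches[1].best_match == "SYN1"  # higher cosine claims it
        assert res.matches[0].best_match == "SYN2"

    def test_greedy_against_exhaustive_assignment(self, rng):
        # greedy matching is the contract: it must yield a valid one-to-one
        # assignment never exceeding the exhaustively optimal total, and in
        # the 2x2 case where the optimum keeps greedy's top pair the two
        # must coincide exactly
        for _ in range(30):
            k = int(rng.integers(2, 5))
            W = rng.dirichlet(np.ones(96) * 0.3, size=k).T
            cat = SignatureCatalog(
                [f"SYN{i+1}" for i in range(k)],
                rng.dirichlet(np.ones(96) * 0.3, size=k).T,
            )
            C = np.array([[cosine(W[:, i], cat.matrix[:, j]) for j in range(k)]
                          for i in range(k)])
            best_perm = max(itertools.permutations(range(k)),
                            key=lambda p: sum(C[i, p[i]] for i in range(k)))
            best_total = sum(C[i, best_perm[i]] for i in range(k))
            greedy = match_signatures(self.result_with(W), cat, threshold=0.0)
            names = [m.best_match for m in greedy.matches]
            assert len(set(names)) == k  # one-to-one
            greedy_total = sum(m.cosine for m in greedy.matches)
            assert greedy_total <= best_total + 1e-12
            top = np.unravel_index(np.argmax(C), C.shape)
            if k == 2 and best_perm[top[0]] == top[1]:
                assert names == [cat.names[best_perm[i]] for i in range(k)]

    def test_channel_order_mismatch_rejected(self):
        cat = synthetic_catalog(2, mode="disjoint")
        cat.channels = tuple(reversed(CHANNELS_96))
        with pytest.raises(ValueError, match="channel order"):
            match_signatures(self.result_with(cat.matrix), cat)


class TestCatalogIO:
    def test_round_trip_cosmic_layout(self, tmp_path):
        cat = synthetic_catalog(3, mode="random", seed=8)
        p = tmp_path / "catalog.tsv"
        frame = cat.to_frame()
        frame.index.name = "Type"
        frame.to_csv(p, sep="\t")
        again = load_catalog(p)
        assert again.names == cat.names
        assert np.allclose(again.matrix, cat.matrix)

    def test_shuffled_rows_are_reordered_on_load(self, tmp_path):
        cat = synthetic_catalog(2, mode="random", seed=9)
        frame = cat.to_frame().sample(frac=1.0, random_state=0)
        frame.index.name = "Type"
        p = tmp_path / "catalog.tsv"
        frame.to_csv(p, sep="\t")
        again = load_catalog(p)
        assert np.allclose(again.matrix, cat.matrix)
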
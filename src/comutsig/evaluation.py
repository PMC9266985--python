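"""Validation studies with independent oracles and known ground truth.

Each study here checks one pillar of the pipeline against something it
cannot share code with: exhaustive hypergeometric enumeration for the
Fisher exact test, a hand-written step-up procedure for the
Benjamini-Hochberg adjustment, and simulated cohorts with planted
clusters, planted clinical odds ratios, or known signature mixtures for
the statistical recovery claims. The same functions back the test suite
and the reproduction script, with problem sizes chosen so the whole set
runs in minutes on one CPU.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import adjusted_rand_score

from comutsig import clinical as clin_mod
from comutsig import cohort_io, comut
from comutsig import signatures as sig_mod
from comutsig import simulate as sim_mod


# ---------------------------------------------------------------- oracles

def exhaustive_fisher_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed one (relative tolerance
    1e-7 for ties). Independent of scipy's implementation.
    """
    N = n11 + n10 + n01 + n00
    K = n11 + n10  # row-1 margin
    n = n11 + n01  # column-1 margin
    lo, hi = max(0, K + n - N), min(K, n)

    def point(k: int) -> float:
        return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)

    p_obs = point(n11)
    return sum(point(k) for k in range(lo, hi + 1)
               if point(k) <= p_obs * (1 + 1e-7))


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment written from the definition.

    Sort, divide by rank/m, take running minima from the largest rank
    down, clip at 1, and map back to input order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] / (np.arange(1, m + 1) / m)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out


# ----------------------------------------------------------- oracle sweeps

def fisher_oracle_sweep(max_margin: int = 12) -> dict:
    """Max |p difference| between fisher_pair and enumeration, all small tables."""
    worst = 0.0
    n_tables = 0
    for n11, n10, n01, n00 in product(range(max_margin + 1), repeat=4):
        if n11 + n10 + n01 + n00 == 0:
            continue
        if (n11 + n10 > max_margin or n01 + n00 > max_margin
                or n11 + n01 > max_margin or n10 + n00 > max_margin):
            continue
        p = comut.fisher_pair(n11, n10, n01, n00).p
        worst = max(worst, abs(p - exhaustive_fisher_p(n11, n10, n01, n00)))
        n_tables += 1
    return {"max_abs_diff": worst, "n_tables": n_tables}


def bh_oracle_sweep(n_vectors: int = 100, max_len: int = 1000,
                    seed: int = 0) -> dict:
    """Max |difference| between adjust_bh and the step-up oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, max_len + 1))
        p = rng.random(n)
        if rng.random() < 0.3:  # exercise ties
            p = np.round(p, 2)
        worst = max(worst, float(np.max(np.abs(
            clin_mod.adjust_bh(p) - bh_step_up(p)
        ))))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


# ------------------------------------------------------ calibration studies

def null_calibration(n_reps: int = 200, n_genes: int = 10,
                     n_samples: int = 168, prevalence: float = 0.3,
                     seed: int = 0) -> dict:
    """Type-I behavior with no planted structure.

    Genes are mutated independently at the same rate in every sample
    (q_in = q_out), so every pairwise co-mutation test and every
    subtype-clinical association is null. Reports the fraction of raw
    pairwise p-values below 0.05 with its 99% binomial reference band
    around 0.05, and the empirical false discovery rate of
    BH-significant calls in subtype-clinical scans (arbitrary null gene
    clusters of 3).
    """
    genes = sim_mod.PANEL_POOL[:n_genes]
    n_pairs = n_genes * (n_genes - 1) // 2
    null_assignment = {g: i // 3 + 1 for i, g in enumerate(genes[:9])}
    reject = 0
    fdr_per_rep = []
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    for rep_seed in seeds:
        cfg = sim_mod.SimConfig(
            genes=tuple(genes), clusters=(), clinical_effects=(),
            background_rate=prevalence, seed=int(rep_seed),
        )
        cohort = sim_mod.simulate_cohort(cfg)
        samples = [r.sample_id for r in cohort.clinical]
        m = cohort_io.build_mutation_matrix(cohort.mutations, samples,
                                            min_mutated_samples=1)
        if len(m.genes) >= 2:
            s = comut.score_matrix(m)
            iu = np.triu_indices(len(m.genes), k=1)
            # reconstruct raw p from |score|: p < 0.05 iff |score| > -log10(.05)
            reject += int(np.sum(np.abs(s.scores[iu]) > -math.log10(0.05)))
        tmb = cohort_io.compute_tmb(cohort.mutations, panel_mb=cfg.panel_mb,
                                    samples=samples)
        clin = cohort_io.binarize_clinical(cohort.clinical,
                                           tmb_class=tmb["tmb_class"])
        assignment = {g: c for g, c in null_assignment.items() if g in m.genes}
        clusters = comut.GeneClusterSet(
            k=len(set(assignment.values())), assignment=assignment,
            linkage=None,
        )
        subtypes = comut.assign_subtypes(m, clusters)
        scan = clin_mod.subtype_clinical_scan(subtypes, clin)
        n_sig = int(scan["significant"].sum())
        fdr_per_rep.append(1.0 if n_sig > 0 else 0.0)  # every discovery is false
    n_tests = n_reps * n_pairs
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_tests)
    return {
        "rejection_rate": reject / n_tests,
        "n_tests": n_tests,
        "band_low": 0.05 - half_width,
        "band_high": 0.05 + half_width,
        "empirical_fdr": float(np.mean(fdr_per_rep)),
    }


def cluster_recovery(n_seeds: int = 20, n_samples: int = 200,
                     seed: int = 0) -> dict:
    """Mean adjusted Rand index of k=3 Ward cuts vs planted gene clusters."""
    clusters = sim_mod.default_clusters()
    genes = tuple(g for c in clusters for g in c.genes)
    aris = []
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for rep_seed in seeds:
        cfg = sim_mod.SimConfig(n_samples=n_samples, genes=genes,
                                clusters=clusters, seed=int(rep_seed))
        cohort = sim_mod.simulate_cohort(cfg)
        samples = [r.sample_id for r in cohort.clinical]
        m = cohort_io.build_mutation_matrix(cohort.mutations, samples,
                                            min_mutated_samples=1)
        s = comut.score_matrix(m)
        cut = comut.cluster_genes(s, k=3)
        planted = [cohort.truth.gene_clusters[g] for g in m.genes]
        found = [cut.assignment[g] for g in m.genes]
        aris.append(adjusted_rand_score(planted, found))
    return {"mean_ari": float(np.mean(aris)), "n_seeds": n_seeds,
            "min_ari": float(np.min(aris))}


def family_history_power(n_seeds: int = 50, seed: int = 0) -> dict:
    """How often the planted family-history effect tops its cluster's scan.

    Default cohort (n=168, OR=3 on cluster 2): for each seed, subtype the
    patients by the planted gene clusters and check that family history is
    the highest-scoring clinical variable for cluster 2.
    """
    top = 0
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for rep_seed in seeds:
        cfg = sim_mod.SimConfig(seed=int(rep_seed))
        cohort = sim_mod.simulate_cohort(cfg)
        samples = [r.sample_id for r in cohort.clinical]
        m = cohort_io.build_mutation_matrix(cohort.mutations, samples,
                                            min_mutated_samples=1)
        assignment = {g: c for g, c in cohort.truth.gene_clusters.items()
                      if g in m.genes}
        clusters = comut.GeneClusterSet(
            k=len(set(assignment.values())), assignment=assignment,
            linkage=None,
        )
        subtypes = comut.assign_subtypes(m, clusters)
        tmb = cohort_io.compute_tmb(cohort.mutations, panel_mb=cfg.panel_mb,
                                    samples=samples)
        clin = cohort_io.binarize_clinical(cohort.clinical,
                                           tmb_class=tmb["tmb_class"])
        scan = clin_mod.subtype_clinical_scan(subtypes, clin)
        c2 = scan[scan["feature"] == "cluster_2"]
        best = c2.loc[c2["score"].idxmax(), "variable"]
        top += int(best == "family_history")
    return {"top_rate": top / n_seeds, "n_seeds": n_seeds}


def signature_recovery(n_seeds: int = 20, n_samples: int = 25,
                       mutations_per_sample: int = 500, seed: int = 0,
                       restarts: int = 5, max_iter: int = 500) -> dict:
    """Recovery of two disjoint-support signatures from multinomial draws.

    For each seed: draw 96-channel profiles from a two-signature mixture,
    select the rank by BIC over 1..4, extract at k=2, and match against
    the generating catalog at the 0.85 cosine threshold.
    """
    catalog = sim_mod.synthetic_catalog(2, mode="disjoint")
    min_cosines = []
    rank_correct = 0
    renamed_both = 0
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for rep_seed in seeds:
        rep_seed = int(rep_seed)
        rng = np.random.default_rng(rep_seed)
        exposures = rng.dirichlet([1.0, 1.0], size=n_samples).T
        profile = sim_mod.simulate_profiles(catalog.matrix, exposures,
                                            mutations_per_sample,
                                            seed=rep_seed)
        best_k, _ = sig_mod.select_rank(profile, k_range=range(1, 5),
                                        seed=rep_seed, restarts=restarts,
                                        max_iter=max_iter)
        rank_correct += int(best_k == 2)
        result = sig_mod.nmf_extract(profile, 2, seed=rep_seed,
                                     restarts=restarts, max_iter=max_iter)
        result = sig_mod.match_signatures(result, catalog, threshold=0.85)
        min_cosines.append(min(m.cosine for m in result.matches))
        renamed_both += int(all(m.matched for m in result.matches))
    return {
        "mean_min_cosine": float(np.mean(min_cosines)),
        "worst_cosine": float(np.min(min_cosines)),
        "rank_correct_rate": rank_correct / n_seeds,
        "renamed_both_rate": renamed_both / n_seeds,
        "n_seeds": n_seeds,
    }


def channel_map_census() -> dict:
    """Classify all 192 valid SNV configurations onto the 96 channels.

    Every (ref != alt, 5' flank, 3' flank) combination with the context
    middle fixed to ref must land on a channel, each channel exactly twice
    (once per strand).
    """
    counts: dict[str, int] = {}
    n_configs = 0
    for ref in "ACGT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    ch = sig_mod.classify_96(ref, alt, five + ref + three)
                    counts[ch] = counts.get(ch, 0) + 1
                    n_configs += 1
    return {
        "n_configs": n_configs,
        "n_channels": len(counts),
        "per_channel_min": min(counts.values()),
        "per_channel_max": max(counts.values()),
    }
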
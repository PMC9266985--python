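"""96-trinucleotide mutational profiles and NMF signature extraction.

Single-base substitutions are classified into the 96 standard channels
``X[R>A]Y`` (pyrimidine reference convention: purine-reference calls are
reverse-complemented first), counted per sample, and the resulting
96 x samples matrix is factorized as counts ~ Poisson(W H) by multiplicative
KL-divergence updates. Rank is selected by BIC-penalized log-likelihood,
and extracted signatures are renamed by greedy one-to-one cosine matching
against a reference catalog (match iff cosine > 0.85).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from comutsig.cohort_io import MutationRecord, MutationTable

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 channels, substitution-major, 16 flank contexts lexicographic within
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

_EPS = 1e-12


class ClassificationError(ValueError):
    """A record cannot be placed on the 96-channel grid."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_96(ref: str, alt: str, context: str) -> str:
    """Channel label for one SNV given its reference trinucleotide context.

    ``context`` is the reference 3-mer centered on the mutated base. Calls
    with a purine reference (A/G) are reverse-complemented onto the
    pyrimidine strand first.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ClassificationError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or any(b not in "ACGT" for b in context):
        raise ClassificationError(f"invalid context {context!r}")
    if context[1] != ref:
        raise ClassificationError(
            f"context {context!r} middle base does not match ref {ref!r}"
        )
    if ref in "AG":
        context = revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def classify_record(record: MutationRecord, context: str | None = None) -> str:
    """Classify a mutation record (SNVs only)."""
    if record.variant_class != "SNV":
        raise ClassificationError(
            f"cannot classify {record.variant_class} record on SNV channels"
        )
    ctx = context if context is not None else record.context
    if ctx is None:
        raise ClassificationError("record has no trinucleotide context")
    return classify_96(record.ref, record.alt, ctx)


@dataclass
class MutationalProfile:
    """96 x samples SNV count matrix in fixed channel order."""

    samples: list[str]
    counts: np.ndarray  # shape (96, n_samples), non-negative
    n_skipped: int = 0
    channels: tuple[str, ...] = CHANNELS_96

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.samples)):
            raise ValueError("profile shape must be (96, n_samples)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.channels),
                            columns=self.samples)

    def subset(self, samples: Sequence[str]) -> "MutationalProfile":
        idx = [self.samples.index(s) for s in samples]
        return MutationalProfile(list(samples), self.counts[:, idx])


@dataclass
class SignatureCatalog:
    """Reference signatures: 96 x K column-stochastic matrix."""

    names: list[str]
    matrix: np.ndarray
    channels: tuple[str, ...] = CHANNELS_96

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("catalog shape must be (96, n_signatures)")
        if np.any(self.matrix < 0):
            raise ValueError("catalog entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValueError("catalog columns must sum to 1 (tolerance 1e-6)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.channels),
                            columns=self.names)


@dataclass(frozen=True)
class SignatureMatch:
    label: str  # de-novo label (SBSA, SBSB, ...) in extraction order
    best_match: str  # best catalog signature by cosine
    cosine: float
    matched: bool  # cosine > threshold

    @property
    def name(self) -> str:
        """Display name: catalog name when matched, else the de-novo label."""
        return self.best_match if self.matched else self.label


@dataclass
class NMFResult:
    """Extracted signatures W (96 x k, columns sum 1) and exposures H (k x n)."""

    rank: int
    signatures: np.ndarray
    exposures: np.ndarray
    samples: list[str]
    log_likelihood: float
    seed: int
    restarts: int
    mode: str = "ml"
    matches: list[SignatureMatch] | None = None
    channels: tuple[str, ...] = CHANNELS_96

    @property
    def labels(self) -> list[str]:
        if self.matches is not None:
            return [m.name for m in self.matches]
        return [f"SBS{string.ascii_uppercase[i]}" for i in range(self.rank)]

    def signatures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signatures, index=list(self.channels),
                            columns=self.labels)

    def exposures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exposures, index=self.labels,
                            columns=self.samples)


def build_profile_matrix(
    muts: MutationTable,
    reference: str | Path | None = None,
    samples: Sequence[str] | None = None,
    strict: bool = False,
) -> MutationalProfile:
    """Aggregate per-sample 96-channel SNV counts.

    Contexts come from the record's ``context`` column or, failing that,
    from a FASTA ``reference`` (1-based positions; the context is bases
    pos-1..pos+1). SNVs that cannot be classified — contig edge, N in the
    context, or a reference base disagreeing with the recorded ref — are
    skipped and counted in ``n_skipped`` (strict mode raises on
    ref/reference mismatches). Non-SNV records are ignored.
    """
    fasta = None
    if reference is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(reference))

    if samples is None:
        samples = muts.samples
    samples = list(samples)
    col = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((96, len(samples)), dtype=np.int64)
    n_skipped = 0
    for r in muts:
        if r.variant_class != "SNV" or r.sample_id not in col:
            continue
        ctx = r.context
        if ctx is None:
            if fasta is None:
                n_skipped += 1
                continue
            try:
                seq = fasta[r.chrom][r.pos - 2 : r.pos + 1].seq.upper()
            except (KeyError, IndexError):
                n_skipped += 1
                continue
            if len(seq) != 3:  # contig edge
                n_skipped += 1
                continue
            if seq[1] != r.ref:
                msg = (f"reference base {seq[1]!r} != record ref {r.ref!r} at "
                       f"{r.chrom}:{r.pos}")
                if strict:
                    raise ClassificationError(msg)
                logger.warning(msg)
                n_skipped += 1
                continue
            ctx = seq
        try:
            channel = classify_96(r.ref, r.alt, ctx)
        except ClassificationError:
            n_skipped += 1
            continue
        counts[_CHANNEL_INDEX[channel], col[r.sample_id]] += 1
    if n_skipped:
        logger.info("skipped %d unclassifiable SNV(s)", n_skipped)
    return MutationalProfile(samples, counts, n_skipped=n_skipped)


def load_catalog(path: str | Path) -> SignatureCatalog:
    """Load a tab-delimited reference catalog (96 rows, "Type" label column)."""
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    df = df.set_index(label_col)
    missing = [c for c in CHANNELS_96 if c not in df.index]
    if missing:
        raise ValueError(f"catalog missing channel(s): {missing[:5]} ...")
    df = df.loc[list(CHANNELS_96)]
    return SignatureCatalog(names=list(df.columns), matrix=df.to_numpy())


def cosine(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity of two non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


def poisson_log_likelihood(X: np.ndarray, mean: np.ndarray) -> float:
    """log P(X | counts ~ Poisson(mean)), elementwise independent."""
    mean = np.maximum(mean, _EPS)
    return float(np.sum(X * np.log(mean) - mean - gammaln(X + 1)))


def normalize_signatures(
    W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scale W columns to sum 1, absorbing the scale into H.

    Leaves the product ``W @ H`` unchanged (the scale indeterminacy of any
    NMF factorization).
    """
    col = W.sum(axis=0)
    return W / col[None, :], H * col[:, None]


def _mu_fit(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    mode: str,
    gamma_shape: float,
    gamma_rate: float,
    trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One run of multiplicative KL updates from a random initialization."""
    m, n = X.shape
    scale = X.mean() / k
    W = rng.uniform(0.5, 1.5, size=(m, k)) * np.sqrt(scale)
    H = rng.uniform(0.5, 1.5, size=(k, n)) * np.sqrt(scale)
    a, b = gamma_shape, gamma_rate
    prev = -np.inf
    for it in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        R = X / WH
        if mode == "map":
            W = (W * (R @ H.T) + (a - 1.0)) / (H.sum(axis=1)[None, :] + b)
        else:
            W = W * (R @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        W = np.maximum(W, _EPS)
        WH = np.maximum(W @ H, _EPS)
        R = X / WH
        if mode == "map":
            H = (H * (W.T @ R) + (a - 1.0)) / (W.sum(axis=0)[:, None] + b)
        else:
            H = H * (W.T @ R) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        H = np.maximum(H, _EPS)
        if trace is not None:
            trace.append(poisson_log_likelihood(X, W @ H))
        if it % 10 == 9 or it == max_iter - 1:
            ll = poisson_log_likelihood(X, W @ H)
            if abs(ll - prev) < tol * (abs(prev) + 1.0):
                break
            prev = ll
    # rescale exposures so fitted column sums match the data exactly
    WH = np.maximum(W @ H, _EPS)
    H = H * (X.sum(axis=0) / WH.sum(axis=0))[None, :]
    ll = poisson_log_likelihood(X, W @ H)
    return W, H, ll


def nmf_extract(
    profile: MutationalProfile,
    k: int,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-8,
    mode: str = "ml",
    gamma_shape: float = 1.001,
    gamma_rate: float = 1e-3,
    normalize_input: bool = False,
) -> NMFResult:
    """Factorize the profile into ``k`` signatures by Poisson-KL NMF.

    Runs ``restarts`` seeded random initializations of the multiplicative
    KL-divergence update and keeps the run with the highest Poisson
    log-likelihood. ``mode="map"`` adds independent Gamma(shape, rate)
    priors on every W and H entry and maximizes the posterior instead
    (weakly informative defaults keep entries strictly positive).
    Signature columns are normalized to sum 1 with the scale absorbed into
    the exposures, leaving the reconstruction unchanged. All-zero sample
    columns are dropped with a warning.
    """
    X = np.asarray(profile.counts, dtype=float)
    samples = list(profile.samples)
    if normalize_input:
        X = X / np.maximum(X.sum(axis=0), 1.0)[None, :]
    zero = X.sum(axis=0) == 0
    if zero.any():
        logger.warning("dropping %d all-zero sample column(s)", int(zero.sum()))
        X = X[:, ~zero]
        samples = [s for s, z in zip(samples, zero) if not z]
    if not 1 <= k <= min(96, X.shape[1]):
        raise ValueError(f"rank k={k} out of range 1..{min(96, X.shape[1])}")
    if mode not in ("ml", "map"):
        raise ValueError(f"unknown mode {mode!r}")

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in np.random.SeedSequence(seed).spawn(restarts):
        rng = np.random.default_rng(child)
        W, H, ll = _mu_fit(X, k, rng, max_iter, tol, mode, gamma_shape,
                           gamma_rate)
        if best is None or ll > best[2]:
            best = (W, H, ll)
    W, H, ll = best
    W, H = normalize_signatures(W, H)
    return NMFResult(rank=k, signatures=W, exposures=H, samples=samples,
                     log_likelihood=ll, seed=seed, restarts=restarts, mode=mode)


def select_rank(
    profile: MutationalProfile,
    k_range: Sequence[int] = range(1, 6),
    seed: int = 0,
    restarts: int = 10,
    penalty: str = "bic",
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of signatures by penalized log-likelihood.

    For each candidate rank the best log-likelihood over restarts is
    recorded; the selected rank maximizes ``LL - 0.5 * k * (96 + n) *
    log(total mutations)`` (BIC). ``penalty="none"`` maximizes the raw
    likelihood, which is non-decreasing in the rank, so it effectively
    returns the largest candidate; exposed for transparency. Ties break
    toward the smaller rank. Returns (k, diagnostics table).
    """
    if penalty not in ("bic", "none"):
        raise ValueError(f"unknown penalty {penalty!r}")
    total = float(profile.counts.sum())
    n = len(profile.samples)
    rows = []
    for k in k_range:
        res = nmf_extract(profile, k, seed=seed, restarts=restarts, **fit_kwargs)
        ll = res.log_likelihood
        n_params = k * (96 + n)
        bic = ll - 0.5 * n_params * np.log(max(total, 2.0))
        rows.append({"k": k, "log_likelihood": ll, "n_params": n_params,
                     "bic": bic})
    diag = pd.DataFrame(rows)
    crit = "bic" if penalty == "bic" else "log_likelihood"
    best_k = int(diag.loc[diag[crit].idxmax(), "k"])
    return best_k, diag


def match_signatures(
    result: NMFResult,
    catalog: SignatureCatalog,
    threshold: float = 0.85,
) -> NMFResult:
    """Rename extracted signatures by greedy one-to-one cosine matching.

    Pairs are claimed in descending cosine order, each extracted signature
    and each catalog signature at most once; an extracted signature takes
    its assigned catalog name iff the cosine exceeds ``threshold``,
    otherwise it keeps its de-novo label. Sub-threshold cosines are still
    reported (the best remaining catalog neighbor).
    """
    if tuple(catalog.channels) != tuple(result.channels):
        raise ValueError("catalog channel order does not match profile channels")
    k, K = result.rank, len(catalog.names)
    C = np.zeros((k, K))
    for i in range(k):
        for j in range(K):
            C[i, j] = cosine(result.signatures[:, i], catalog.matrix[:, j])
    assigned: dict[int, tuple[str, float]] = {}
    used_cols: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-C, axis=None), C.shape))[0]
    for i, j in order:
        if int(i) in assigned or int(j) in used_cols:
            continue
        assigned[int(i)] = (catalog.names[int(j)], float(C[i, j]))
        used_cols.add(int(j))
        if len(assigned) == min(k, K):
            break
    matches = []
    for i in range(k):
        label = f"SBS{string.ascii_uppercase[i]}"
        if i in assigned:
            name, cos = assigned[i]
        else:  # more extracted signatures than catalog entries
            name, cos = "", 0.0
        matches.append(SignatureMatch(label=label, best_match=name, cosine=cos,
                                      matched=cos > threshold))
    return replace(result, matches=matches)
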
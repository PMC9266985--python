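"""Association scans between mutations/subtypes and clinical variables.

Every association is a two-sided Fisher exact test on the 2x2 table of a
binary feature against a binary outcome over pairwise-complete samples,
reported as a signed ``-log10(p)`` score (positive when the feature is
enriched in the outcome, OR > 1). P-values are Benjamini-Hochberg adjusted
within each scan family; adjusted p < 0.05 is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from comutsig.cohort_io import BinaryClinicalMatrix, MutationMatrix, MutationTable
from comutsig.comut import DEFAULT_P_FLOOR, fisher_pair, pair_table

#: DNA mismatch-repair gene set used for the MMR mutation-burden comparison
MMR_GENES = frozenset(
    {"MSH2", "MSH3", "MSH6", "MLH1", "MLH3", "PMS2", "PMS1", "EXO1",
     "POLD3", "PCNA", "RPA1", "HMGB1", "RFC1", "LIG1"}
)

#: plot reference line for p = 0.05 on the score scale
SCORE_THRESHOLD_LINE = -math.log10(0.05)


@dataclass
class AssociationResult:
    feature: str
    variable: str
    n_used: int
    p: float
    odds_ratio: float
    score: float
    p_adjusted: float = math.nan
    significant: bool = False
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "feature": self.feature, "variable": self.variable,
            "n": self.n_used, "odds_ratio": self.odds_ratio, "p": self.p,
            "p_adjusted": self.p_adjusted, "score": self.score,
            "significant": self.significant, "degenerate": self.degenerate,
        }


def associate(
    feature: Sequence[float],
    outcome: Sequence[float],
    feature_name: str = "feature",
    variable_name: str = "variable",
    p_floor: float = DEFAULT_P_FLOOR,
) -> AssociationResult:
    """Fisher exact association of two binary vectors with NA exclusion.

    Samples NA (NaN) in either vector are dropped before forming the 2x2
    table. A degenerate table (any zero margin) is reported with p = 1 and
    score 0 rather than raising, so scans over many variables never abort.
    """
    f = np.asarray(feature, dtype=float)
    o = np.asarray(outcome, dtype=float)
    if f.shape != o.shape:
        raise ValueError("feature and outcome lengths differ")
    ok = ~(np.isnan(f) | np.isnan(o))
    if not ok.any():
        raise ValueError("no samples with both feature and outcome observed")
    f, o = f[ok].astype(bool), o[ok].astype(bool)
    n11, n10, n01, n00 = pair_table(f, o)
    degenerate = (n11 + n10 == 0 or n01 + n00 == 0 or n11 + n01 == 0
                  or n10 + n00 == 0)
    if degenerate:
        return AssociationResult(feature_name, variable_name, int(ok.sum()),
                                 p=1.0, odds_ratio=math.nan, score=0.0,
                                 degenerate=True)
    t = fisher_pair(n11, n10, n01, n00, feature_name, variable_name)
    p = max(t.p, p_floor)
    if t.direction == "neutral":
        score = 0.0
    else:
        score = -math.log10(p)
        if t.direction == "exclusive":
            score = -score
    return AssociationResult(feature_name, variable_name, int(ok.sum()),
                             p=t.p, odds_ratio=t.odds_ratio, score=score)


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _associate_or_degenerate(
    feature, outcome, feature_name: str, variable_name: str
) -> AssociationResult:
    """Scan-safe associate: an all-NA pairing yields a degenerate result."""
    try:
        return associate(feature, outcome, feature_name, variable_name)
    except ValueError:
        return AssociationResult(feature_name, variable_name, 0, p=1.0,
                                 odds_ratio=math.nan, score=0.0,
                                 degenerate=True)


def _finalize(results: list[AssociationResult], alpha: float) -> pd.DataFrame:
    """Apply BH within one scan family and tabulate."""
    if results:
        adj = adjust_bh([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
            r.significant = bool(a < alpha)
    return pd.DataFrame([r.as_dict() for r in results])


def subtype_clinical_scan(
    subtypes: pd.DataFrame,
    clin: BinaryClinicalMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate every subtype with every binarized clinical variable.

    ``subtypes`` is the boolean cluster x sample frame from
    :func:`comutsig.comut.assign_subtypes`. Tests run on the intersection
    of samples; BH is applied across the whole scan as one family.
    """
    shared = [s for s in subtypes.columns if s in set(clin.samples)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between subtypes and clinical")
    clin_df = clin.to_frame()[shared]
    results = []
    for label in subtypes.index:
        feature = subtypes.loc[label, shared].to_numpy(dtype=float)
        for var in clin.variables:
            results.append(
                _associate_or_degenerate(feature, clin_df.loc[var].to_numpy(),
                                         f"cluster_{label}", var)
            )
    return _finalize(results, alpha)


def gene_clinical_scan(
    m: MutationMatrix,
    clin: BinaryClinicalMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate each gene's mutation indicator with each clinical variable."""
    shared = [s for s in m.samples if s in set(clin.samples)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between matrix and clinical")
    cols = [m.samples.index(s) for s in shared]
    clin_df = clin.to_frame()[shared]
    results = []
    for i, gene in enumerate(m.genes):
        feature = m.values[i, cols].astype(float)
        for var in clin.variables:
            results.append(
                _associate_or_degenerate(feature, clin_df.loc[var].to_numpy(),
                                         gene, var)
            )
    return _finalize(results, alpha)


def family_history_scan(
    clin: BinaryClinicalMatrix,
    alpha: float = 0.05,
    extra_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Associate family history with the other clinical variables.

    ``extra_features`` may add boolean feature rows (e.g. subtype flags)
    sharing the clinical sample order; all tests form one BH family.
    """
    fh = clin.row("family_history")
    results = []
    for var in clin.variables:
        if var == "family_history":
            continue
        results.append(
            _associate_or_degenerate(clin.row(var), fh, var, "family_history")
        )
    if extra_features is not None:
        for name, row in extra_features.iterrows():
            results.append(
                associate(row[clin.samples].to_numpy(dtype=float), fh,
                          feature_name=str(name), variable_name="family_history")
            )
    return _finalize(results, alpha)


def geneset_burden_test(
    m: MutationMatrix,
    gene_set: Iterable[str],
    group: Sequence[float],
    set_name: str = "gene_set",
    group_name: str = "group",
) -> AssociationResult:
    """Association of "mutated in any gene of the set" with a sample group.

    Missing set members (absent from the matrix) are dropped and reported;
    an empty intersection raises with the list of missing genes.
    """
    gene_set = set(gene_set)
    present = sorted(gene_set & set(m.genes))
    if not present:
        raise ValueError(
            "no gene-set member present in matrix; missing: "
            + ", ".join(sorted(gene_set))
        )
    missing = sorted(gene_set - set(m.genes))
    idx = [m.genes.index(g) for g in present]
    indicator = m.values[idx].any(axis=0).astype(float)
    res = associate(indicator, group, feature_name=set_name,
                    variable_name=group_name)
    res.feature = set_name + (f" (missing: {','.join(missing)})" if missing else "")
    return res


def domain_localization(
    muts: MutationTable,
    gene: str,
    domain: tuple[int, int],
    coordinate_kind: str = "genomic",
) -> tuple[int, int, list[int]]:
    """Count a gene's short-variant mutations inside vs outside an interval.

    The interval is closed on both ends. ``coordinate_kind`` documents
    whether the supplied interval is in protein or genomic coordinates and
    must match the coordinate system of the mutation positions; no
    conversion is performed. Returns (inside, outside, sorted positions)
    for lollipop-style display.
    """
    start, end = domain
    if start > end:
        raise ValueError(f"domain start {start} > end {end}")
    if coordinate_kind not in ("protein", "genomic"):
        raise ValueError(f"unknown coordinate kind {coordinate_kind!r}")
    positions = sorted(
        r.pos for r in muts if r.gene == gene and r.is_short_variant
    )
    if not positions:
        import logging

        logging.getLogger(__name__).warning(
            "no short-variant mutations found for gene %s", gene
        )
    inside = sum(1 for p in positions if start <= p <= end)
    return inside, len(positions) - inside, positions
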
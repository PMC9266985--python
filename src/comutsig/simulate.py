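"""Synthetic panel-sequencing cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
~168-patient cohort sequenced on a pan-cancer gene panel, with planted
co-mutated gene clusters (carrier status ~ Bernoulli(pi); cluster genes
mutated with probability q_in in carriers, q_out otherwise), planted
clinical associations at a configured odds ratio (e.g. family history of
cancer enriched in carriers of one cluster), and SNV trinucleotide
channels drawn from per-sample mixtures of known 96-channel signatures.
Every run is reproducible from its seed and returns full ground-truth
labels, so recovery of clusters, associations, and signatures can be
measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from comutsig.cohort_io import (
    ClinicalRecord,
    MutationRecord,
    MutationTable,
    Relative,
    write_clinical,
    write_mutations,
)
from comutsig.signatures import (
    CHANNELS_96,
    MutationalProfile,
    SignatureCatalog,
    revcomp,
)

# well-known colorectal/pan-cancer panel symbols head the pool; the rest are
# generated filler so any pool size up to 624 is available
_REAL_SYMBOLS = (
    "TP53 APC KRAS SMAD4 PIK3CA FBXW7 BRAF NRAS ARID1A RNF43 ACVR2A EPHA7 "
    "LRP1 SETBP1 SOX9 TCF7L2 AMER1 ATM BRCA2 POLE MSH2 MSH3 MSH6 MLH1 MLH3 "
    "PMS2 PMS1 EXO1 POLD3 PCNA RPA1 HMGB1 RFC1 LIG1 PTEN CTNNB1 GNAS ERBB2 "
    "KMT2D KMT2C ARID2 CREBBP EP300 NF1 RB1 CDKN2A MYC CCND1 FGFR1 EGFR"
).split()
PANEL_POOL: tuple[str, ...] = tuple(
    _REAL_SYMBOLS + [f"PANG{i:03d}" for i in range(1, 625 - len(_REAL_SYMBOLS) + 1)]
)

_LEFT_SITES = ("descending colon", "sigmoid colon", "rectum")
_RIGHT_SITES = ("cecum", "ascending colon", "transverse colon")
_RELATIVE_SITES = ("colorectal", "stomach", "lung", "liver", "breast", "bladder")
_RELATIVE_SITE_P = (0.28, 0.22, 0.22, 0.14, 0.09, 0.05)

_GENE_SPACING = 10  # bp between planted mutation slots on a gene contig


def _parse_channel(channel: str) -> tuple[str, str, str]:
    """(ref, alt, context) on the pyrimidine strand for a channel label."""
    five, rest = channel[0], channel[2:5]
    ref, alt = rest.split(">")
    three = channel[-1]
    return ref, alt, five + ref + three


@dataclass(frozen=True)
class ClusterSpec:
    """One planted co-mutation cluster."""

    genes: tuple[str, ...]
    carrier_fraction: float = 0.3
    q_in: float = 0.8
    q_out: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.q_out < self.q_in <= 1:
            raise ValueError(
                f"need 0 <= q_out < q_in <= 1, got q_in={self.q_in}, "
                f"q_out={self.q_out}"
            )
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ClinicalEffect:
    """A clinical variable enriched in carriers of one cluster at a given OR."""

    cluster: int  # 1-based cluster index
    variable: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.odds_ratio) or self.odds_ratio <= 0:
            raise ValueError(
                f"odds ratio must be a positive finite number (feasible range "
                f"(0, inf)), got {self.odds_ratio}"
            )


def default_clusters() -> tuple[ClusterSpec, ...]:
    """Three planted clusters of four genes; cluster 2 is the LAS-like one."""
    return (
        ClusterSpec(genes=("ARID1A", "RNF43", "EPHA7", "TCF7L2")),
        ClusterSpec(genes=("LRP1", "ACVR2A", "SETBP1", "SOX9")),
        ClusterSpec(genes=("ATM", "BRCA2", "POLE", "AMER1")),
    )


def default_signatures() -> np.ndarray:
    """Two deterministic disjoint-support signatures (C>* vs T>* channels)."""
    sigs = np.zeros((96, 2))
    sigs[:48, 0] = 1 / 48  # C>A, C>G, C>T contexts
    sigs[48:, 1] = 1 / 48  # T>A, T>C, T>G contexts
    return sigs


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the cohort the analysis is designed for: 168 patients,
    100 genes of a 624-symbol pan-cancer pool, three planted clusters of
    four genes (carrier fraction 0.3, q_in 0.8, q_out 0.05), family
    history enriched at OR 3 in cluster-2 carriers, two subtype-specific
    signatures, a 1.5 Mb panel, and Table-1-like clinical marginals with
    realistic missingness (grade 22%, sidedness 11%, family history 12%).
    """

    n_samples: int = 168
    genes: tuple[str, ...] = tuple(PANEL_POOL[:100])
    clusters: tuple[ClusterSpec, ...] = field(default_factory=default_clusters)
    clinical_effects: tuple[ClinicalEffect, ...] = (
        ClinicalEffect(cluster=2, variable="family_history", odds_ratio=3.0),
    )
    background_rate: float = 0.05
    indel_fraction: float = 0.15
    signatures: np.ndarray = field(default_factory=default_signatures)
    carrier_mixing: tuple[float, ...] = (0.8, 0.2)
    base_mixing: tuple[float, ...] = (0.2, 0.8)
    mixing_cluster: int = 2  # carriers of this cluster get carrier_mixing
    mutations_per_sample: int | None = None  # mean total SNVs; None = natural
    panel_mb: float = 1.5
    family_history_base_rate: float = 0.28
    missing_rates: dict = field(
        default_factory=lambda: {"grade": 0.22, "site": 0.113,
                                 "family_history": 0.12, "msi": 0.012}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.shape[0] != 96:
            raise ValueError("signatures must have 96 rows")
        for w in (self.carrier_mixing, self.base_mixing):
            if len(w) != self.signatures.shape[1]:
                raise ValueError("mixing weights must match signature count")
            if abs(sum(w) - 1) > 1e-9 or any(x < 0 for x in w):
                raise ValueError("mixing weights must be non-negative, sum 1")
        gene_set = set(self.genes)
        for c in self.clusters:
            missing = set(c.genes) - gene_set
            if missing:
                raise ValueError(
                    "cluster gene(s) not in gene list: " + ", ".join(sorted(missing))
                )
        for e in self.clinical_effects:
            if not 1 <= e.cluster <= len(self.clusters):
                raise ValueError(f"effect references unknown cluster {e.cluster}")


@dataclass
class GroundTruth:
    """What was planted: labels against which recovery is measured."""

    carriers: pd.DataFrame  # cluster label x sample, bool
    gene_clusters: dict[str, int]  # planted gene -> cluster label
    exposures: pd.DataFrame  # signature x sample mixing weights
    planted_effects: tuple[ClinicalEffect, ...]
    clinical_truth: pd.DataFrame  # variable x sample pre-missingness values


@dataclass
class SimulatedCohort:
    mutations: MutationTable
    clinical: list[ClinicalRecord]
    truth: GroundTruth
    reference: dict[str, str]  # contig -> sequence consistent with records
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit mutation TSV, clinical TSV, FASTA, and a config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": outdir / "mutations.tsv",
            "clinical": outdir / "clinical.tsv",
            "reference": outdir / "reference.fa",
            "truth": outdir / "truth.json",
        }
        write_mutations(self.mutations, paths["mutations"])
        write_clinical(self.clinical, paths["clinical"])
        with open(paths["reference"], "w") as fh:
            for contig in sorted(self.reference):
                fh.write(f">{contig}\n{self.reference[contig]}\n")
        truth = {
            "seed": self.config.seed,
            "carriers": {
                str(c): [s for s in self.truth.carriers.columns
                         if self.truth.carriers.loc[c, s]]
                for c in self.truth.carriers.index
            },
            "gene_clusters": self.truth.gene_clusters,
            "planted_effects": [
                {"cluster": e.cluster, "variable": e.variable,
                 "odds_ratio": e.odds_ratio}
                for e in self.truth.planted_effects
            ],
        }
        paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
        return paths


def _effect_probability(base: float, odds_ratio: float) -> float:
    """Carrier probability with the given odds ratio against base odds."""
    o = base / (1 - base) * odds_ratio
    return o / (1 + o)


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> SimulatedCohort:
    """Draw one cohort from the generative model; reproducible from seed."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    samples = [f"P{i + 1:04d}" for i in range(cfg.n_samples)]
    n = cfg.n_samples

    gene_clusters: dict[str, int] = {}
    for ci, c in enumerate(cfg.clusters, start=1):
        for g in c.genes:
            gene_clusters[g] = ci

    carriers = pd.DataFrame(
        False, index=range(1, len(cfg.clusters) + 1), columns=samples
    )
    for ci, c in enumerate(cfg.clusters, start=1):
        carriers.loc[ci] = rng.random(n) < c.carrier_fraction

    # mutation indicators gene x sample
    mutated = np.zeros((len(cfg.genes), n), dtype=bool)
    for gi, g in enumerate(cfg.genes):
        ci = gene_clusters.get(g)
        if ci is None:
            p = np.full(n, cfg.background_rate)
        else:
            c = cfg.clusters[ci - 1]
            p = np.where(carriers.loc[ci].to_numpy(), c.q_in, c.q_out)
        mutated[gi] = rng.random(n) < p

    # signature mixing per sample
    r = cfg.signatures.shape[1]
    mix = np.tile(np.asarray(cfg.base_mixing, dtype=float)[:, None], (1, n))
    if cfg.mixing_cluster in carriers.index:
        mix_carriers = carriers.loc[cfg.mixing_cluster].to_numpy()
        mix[:, mix_carriers] = np.asarray(cfg.carrier_mixing,
                                          dtype=float)[:, None]
    channel_p = cfg.signatures @ mix  # 96 x n

    # emit records; each gene gets its own contig with evenly spaced slots
    slot = {g: 0 for g in cfg.genes}
    ref_bases: dict[str, dict[int, str]] = {}
    records: list[MutationRecord] = []
    sample_index = {s: j for j, s in enumerate(samples)}

    def place(gene: str, sample: str) -> None:
        i = slot[gene]
        slot[gene] += 1
        pos = 5 + i * _GENE_SPACING
        if rng.random() < cfg.indel_fraction:
            base = rng.choice(list("ACGT"))
            records.append(MutationRecord(sample, gene, gene, pos, base, "-",
                                          "DEL"))
            ref_bases.setdefault(gene, {})[pos] = base
            return
        ch = CHANNELS_96[rng.choice(96, p=channel_p[:, sample_index[sample]])]
        ref, alt, ctx = _parse_channel(ch)
        if rng.random() < 0.5:  # emit on the purine strand
            ref, alt, ctx = (revcomp(ref), revcomp(alt), revcomp(ctx))
        records.append(MutationRecord(sample, gene, gene, pos, ref, alt, "SNV",
                                      context=ctx))
        bases = ref_bases.setdefault(gene, {})
        bases[pos - 1], bases[pos], bases[pos + 1] = ctx[0], ctx[1], ctx[2]

    for gi, g in enumerate(cfg.genes):
        for sj in np.flatnonzero(mutated[gi]):
            place(g, samples[sj])

    if cfg.mutations_per_sample is not None:
        # top up each sample's SNV load on its already-mutated genes so the
        # binary matrix is unchanged
        per_sample = {s: 0 for s in samples}
        for rec in records:
            per_sample[rec.sample_id] += 1
        for sj, s in enumerate(samples):
            extra = cfg.mutations_per_sample - per_sample[s]
            own = [cfg.genes[gi] for gi in np.flatnonzero(mutated[:, sj])]
            if extra <= 0 or not own:
                continue
            for g in rng.choice(own, size=extra):
                place(str(g), s)

    # materialize contig sequences: random fill, planted bases overwritten
    reference: dict[str, str] = {}
    for g in cfg.genes:
        length = 5 + max(slot[g], 1) * _GENE_SPACING + 5
        seq = rng.choice(list("ACGT"), size=length)
        for pos, base in ref_bases.get(g, {}).items():
            seq[pos - 1] = base  # 1-based record positions
        reference[g] = "".join(seq)

    clinical, clinical_truth = _simulate_clinical(cfg, samples, carriers, rng)

    truth = GroundTruth(
        carriers=carriers,
        gene_clusters=gene_clusters,
        exposures=pd.DataFrame(mix, index=[f"SYN{i + 1}" for i in range(r)],
                               columns=samples),
        planted_effects=tuple(cfg.clinical_effects),
        clinical_truth=clinical_truth,
    )
    return SimulatedCohort(MutationTable(records), clinical, truth, reference,
                           cfg)


def _simulate_clinical(
    cfg: SimConfig,
    samples: list[str],
    carriers: pd.DataFrame,
    rng: np.random.Generator,
):
    """Clinical table with Table-1-like marginals and planted effects."""
    n = len(samples)
    effects = {(e.variable): e for e in cfg.clinical_effects}

    def effect_p(variable: str, base: float) -> np.ndarray:
        p = np.full(n, base)
        e = effects.get(variable)
        if e is not None:
            is_carrier = carriers.loc[e.cluster].to_numpy()
            p[is_carrier] = _effect_probability(base, e.odds_ratio)
        return p

    age = np.clip(np.round(rng.normal(59, 13, size=n)), 17, 85).astype(int)
    male = rng.random(n) < 0.571
    stage_iv = rng.random(n) < 0.417
    grade_high = rng.random(n) < effect_p("grade_high", 0.28)
    right = rng.random(n) < effect_p("sidedness_right", 0.23)
    msi_h = rng.random(n) < effect_p("msi_high", 0.066)
    fh = rng.random(n) < effect_p("family_history",
                                  cfg.family_history_base_rate)

    miss = {k: rng.random(n) < v for k, v in cfg.missing_rates.items()}

    records = []
    for j, s in enumerate(samples):
        site = None
        if not miss.get("site", np.zeros(n, bool))[j]:
            pool = _RIGHT_SITES if right[j] else _LEFT_SITES
            site = str(rng.choice(pool))
        relatives: list[Relative] | None
        if miss.get("family_history", np.zeros(n, bool))[j]:
            relatives = None
        elif fh[j]:
            relatives = [
                Relative(
                    relation=str(rng.choice(["parent", "sibling", "child"])),
                    cancer_site=str(rng.choice(_RELATIVE_SITES,
                                               p=_RELATIVE_SITE_P)),
                    age_at_diagnosis=int(rng.integers(65, 76)),
                )
                for _ in range(int(rng.integers(1, 3)))
            ]
        else:
            relatives = []
        records.append(
            ClinicalRecord(
                sample_id=s,
                age=int(age[j]),
                gender="male" if male[j] else "female",
                stage="IV" if stage_iv[j] else "III",
                grade=None if miss.get("grade", np.zeros(n, bool))[j]
                else ("high" if grade_high[j] else "low"),
                site=site,
                msi=None if miss.get("msi", np.zeros(n, bool))[j]
                else ("MSI-H" if msi_h[j] else "MSS"),
                family_history_relatives=relatives,
            )
        )
    clinical_truth = pd.DataFrame(
        {
            "age_old": (age >= 60).astype(float),
            "gender_male": male.astype(float),
            "stage_IV": stage_iv.astype(float),
            "grade_high": grade_high.astype(float),
            "sidedness_right": right.astype(float),
            "msi_high": msi_h.astype(float),
            "family_history": fh.astype(float),
        },
        index=samples,
    ).T
    return records, clinical_truth


def simulate_profiles(
    signatures: np.ndarray,
    exposures: np.ndarray,
    total_mutations: int | Sequence[int],
    seed: int = 0,
    sample_prefix: str = "S",
) -> MutationalProfile:
    """Multinomial 96-channel counts from a signature mixture per sample."""
    signatures = np.asarray(signatures, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if signatures.shape[0] != 96:
        raise ValueError("signatures must have 96 rows")
    if np.any(np.abs(signatures.sum(axis=0) - 1) > 1e-9):
        raise ValueError("signature columns must sum to 1")
    if np.any(exposures < 0):
        raise ValueError("exposures must be non-negative")
    n = exposures.shape[1]
    totals = np.broadcast_to(np.asarray(total_mutations, dtype=int), (n,))
    col_sums = exposures.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("zero exposure column")
    probs = signatures @ (exposures / col_sums[None, :])
    rng = np.random.default_rng(seed)
    counts = np.zeros((96, n), dtype=np.int64)
    for j in range(n):
        if totals[j] > 0:
            counts[:, j] = rng.multinomial(totals[j], probs[:, j])
    samples = [f"{sample_prefix}{j + 1:03d}" for j in range(n)]
    return MutationalProfile(samples, counts)


def toy_reference(
    n_contigs: int = 1, length: int = 50, seed: int = 0
) -> tuple[str, list[tuple[str, int, str, str]]]:
    """Random FASTA text plus context-valid (contig, pos, ref, context) triples.

    Positions 2..length-1 (1-based) have both flanks defined; contig-edge
    positions are excluded.
    """
    if length < 3:
        raise ValueError("contig length must be >= 3")
    rng = np.random.default_rng(seed)
    lines = []
    triples = []
    for c in range(n_contigs):
        name = f"ctg{c + 1}"
        seq = "".join(rng.choice(list("ACGT"), size=length))
        lines.append(f">{name}\n{seq}\n")
        for pos in range(2, length):  # 1-based, flanks well-defined
            triples.append((name, pos, seq[pos - 1], seq[pos - 2 : pos + 1]))
    return "".join(lines), triples


def synthetic_catalog(
    n_signatures: int = 2,
    seed: int = 0,
    mode: str = "disjoint",
    concentration: float = 0.1,
) -> SignatureCatalog:
    """A synthetic reference catalog in the standard 96-channel layout.

    ``mode="disjoint"`` splits the channels into equal contiguous blocks
    (one uniform signature per block, deterministic); ``mode="random"``
    draws sparse Dirichlet signatures. Signatures are named SYN1, SYN2, ...
    to mark them as synthetic stand-ins for a published catalog.
    """
    if mode == "disjoint":
        if not 1 <= n_signatures <= 96:
            raise ValueError("need 1..96 disjoint signatures")
        matrix = np.zeros((96, n_signatures))
        bounds = np.linspace(0, 96, n_signatures + 1).astype(int)
        for i in range(n_signatures):
            lo, hi = bounds[i], bounds[i + 1]
            matrix[lo:hi, i] = 1.0 / (hi - lo)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        matrix = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    names = [f"SYN{i + 1}" for i in range(n_signatures)]
    return SignatureCatalog(names=names, matrix=matrix)
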
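"""Cohort input/output: mutation and clinical tables, matrices, TMB.

Reads MAF-like tab-delimited somatic mutation tables and a clinical table,
builds the binary gene-by-patient mutation indicator matrix that every
downstream test operates on, computes tumor mutational burden (TMB,
mutations per megabase of panel territory), and binarizes clinical
variables (age, sidedness, family history, MSI, ...) into a {0, 1, NA}
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_CLASSES = frozenset({"SNV", "INS", "DEL", "CNV", "FUSION"})
#: variant classes that count toward TMB (mutations / Mb convention)
SHORT_VARIANT_CLASSES = frozenset({"SNV", "INS", "DEL"})
FIRST_DEGREE_RELATIONS = frozenset({"parent", "sibling", "child"})
#: controlled vocabulary for family-history relations
KNOWN_RELATIONS = frozenset(
    {"parent", "mother", "father", "sibling", "brother", "sister", "child",
     "son", "daughter", "grandparent", "aunt", "uncle", "cousin"}
)
_FIRST_DEGREE_ALIASES = frozenset(
    {"parent", "mother", "father", "sibling", "brother", "sister", "child",
     "son", "daughter"}
)

_BASES = frozenset("ACGT")

#: anatomical site -> tumor sidedness ("right" / "left"); extensible via config
DEFAULT_SITE_MAP: dict[str, str] = {
    "cecum": "right",
    "ascending colon": "right",
    "transverse colon": "right",
    "descending colon": "left",
    "sigmoid colon": "left",
    "rectum": "left",
}

#: binary clinical variables, in output row order
CLINICAL_VARIABLES = (
    "age_old",
    "gender_male",
    "stage_IV",
    "grade_high",
    "sidedness_right",
    "tmb_high",
    "msi_high",
    "family_history",
)

# column aliases: MAF-standard name -> native name
MAF_ALIASES = {
    "Tumor_Sample_Barcode": "sample",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Type": "variant_class",
    "Context": "context",
}
NATIVE_COLUMNS = ("sample", "gene", "chrom", "pos", "ref", "alt", "variant_class")
# MAF Variant_Type vocabulary -> internal class names
_MAF_CLASS_MAP = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL",
                  "CNV": "CNV", "FUSION": "FUSION"}


class FormatError(ValueError):
    """Raised when an input file is structurally unreadable."""


class ValidationError(ValueError):
    """Raised in strict mode when record-level validation fails."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call in one sample.

    ``pos`` is 1-based. ``context`` is the reference trinucleotide centered
    on ``pos`` (SNVs only); its middle base must equal ``ref``.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    context: str | None = None

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty if valid)."""
        problems = []
        if self.variant_class not in VARIANT_CLASSES:
            problems.append(f"unknown variant class {self.variant_class!r}")
        if self.pos < 1:
            problems.append(f"position {self.pos} < 1")
        if self.variant_class == "SNV":
            if len(self.ref) != 1 or self.ref not in _BASES:
                problems.append(f"SNV ref {self.ref!r} is not a single ACGT base")
            if len(self.alt) != 1 or self.alt not in _BASES:
                problems.append(f"SNV alt {self.alt!r} is not a single ACGT base")
            if not problems and self.ref == self.alt:
                problems.append("SNV ref equals alt")
            if self.context is not None:
                if len(self.context) != 3 or any(b not in _BASES for b in self.context):
                    problems.append(f"context {self.context!r} is not an ACGT 3-mer")
                elif self.context[1] != self.ref:
                    problems.append(
                        f"context {self.context!r} middle base != ref {self.ref!r}"
                    )
        return problems

    @property
    def is_short_variant(self) -> bool:
        return self.variant_class in SHORT_VARIANT_CLASSES

    def _key(self) -> tuple:
        return (self.sample_id, self.gene, self.chrom, self.pos, self.ref,
                self.alt, self.variant_class)


@dataclass
class MutationTable:
    """A validated collection of :class:`MutationRecord`."""

    records: list[MutationRecord]
    n_deduplicated: int = 0
    invalid: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.records})

    def subset(self, sample_ids: Iterable[str]) -> "MutationTable":
        keep = set(sample_ids)
        return MutationTable([r for r in self.records if r.sample_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": r.sample_id, "gene": r.gene, "chrom": r.chrom,
                    "pos": r.pos, "ref": r.ref, "alt": r.alt,
                    "variant_class": r.variant_class,
                    "context": r.context if r.context is not None else "",
                }
                for r in self.records
            ],
            columns=list(NATIVE_COLUMNS) + ["context"],
        )


@dataclass(frozen=True)
class Relative:
    relation: str
    cancer_site: str
    age_at_diagnosis: int | None


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates.

    ``family_history_relatives`` is ``None`` when the field is missing and a
    (possibly empty) list when it was observed; an empty list means "no
    relative with cancer".
    """

    sample_id: str
    age: int | None = None
    gender: str | None = None  # "female" / "male"
    stage: str | None = None  # "III" / "IV"
    grade: str | None = None  # "low" / "high"
    site: str | None = None
    msi: str | None = None  # "MSS" / "MSI-H"
    family_history_relatives: list[Relative] | None = None


@dataclass
class MutationMatrix:
    """Binary gene x sample indicator matrix.

    ``values[i, j] = 1`` iff gene ``genes[i]`` carries at least one
    qualifying mutation in sample ``samples[j]``. Gene rows are ordered
    lexicographically; multiple mutations in a gene/sample collapse to 1.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # int8, shape (len(genes), len(samples))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class BinaryClinicalMatrix:
    """Binarized clinical variables x samples, values in {0, 1, NaN}."""

    variables: list[str]
    samples: list[str]
    values: np.ndarray  # float, NaN = missing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variables, columns=self.samples)

    def row(self, variable: str) -> np.ndarray:
        return self.values[self.variables.index(variable)]


def _resolve_columns(header: Sequence[str]) -> dict[str, str]:
    """Map file columns to native names, accepting MAF or native headers."""
    cols = {}
    for c in header:
        if c in MAF_ALIASES:
            cols[MAF_ALIASES[c]] = c
        elif c in NATIVE_COLUMNS or c == "context":
            cols[c] = c
    missing = [c for c in NATIVE_COLUMNS if c not in cols]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return cols


def read_mutations(path: str | Path, strict: bool = False) -> MutationTable:
    """Read a tab-delimited mutation table (native or MAF column names).

    Rows failing record-level validation are collected with their 1-based
    line numbers in ``MutationTable.invalid`` (fatal in ``strict`` mode).
    Exact duplicates on (sample, gene, chrom, pos, ref, alt, class) are
    removed; the number dropped is logged and stored in ``n_deduplicated``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)

    records: list[MutationRecord] = []
    invalid: list[tuple[int, str]] = []
    seen: set[tuple] = set()
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            pos = int(row[cols["pos"]])
        except ValueError:
            invalid.append((i, f"non-integer position {row[cols['pos']]!r}"))
            continue
        vclass = row[cols["variant_class"]].upper()
        vclass = _MAF_CLASS_MAP.get(vclass, vclass)
        ctx = row.get(cols.get("context", ""), "") if "context" in cols else ""
        rec = MutationRecord(
            sample_id=row[cols["sample"]],
            gene=row[cols["gene"]],
            chrom=row[cols["chrom"]],
            pos=pos,
            ref=row[cols["ref"]].upper(),
            alt=row[cols["alt"]].upper(),
            variant_class=vclass,
            context=ctx.upper() or None,
        )
        problems = rec.validate()
        if problems:
            invalid.append((i, "; ".join(problems)))
            continue
        key = rec._key()
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(rec)

    if invalid:
        msg = f"{len(invalid)} invalid row(s) in {path.name}: " + "; ".join(
            f"line {ln}: {why}" for ln, why in invalid[:10]
        )
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
    if n_dup:
        logger.info("deduplicated %d identical row(s) in %s", n_dup, path.name)
    return MutationTable(records, n_deduplicated=n_dup, invalid=invalid)


def write_mutations(table: MutationTable, path: str | Path) -> None:
    """Write a mutation table in the native tab-delimited dialect."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def _parse_relatives(text: str) -> list[Relative] | None:
    """Parse ``relation:site:age`` triples separated by ``;``.

    Empty string means "no relatives with cancer"; a lone ``.`` means the
    field is missing.
    """
    text = text.strip()
    if text == ".":
        return None
    if not text:
        return []
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        bits = part.split(":")
        if len(bits) != 3:
            raise FormatError(f"malformed relative entry {part!r}")
        relation = bits[0].strip().lower()
        if relation not in KNOWN_RELATIONS:
            raise FormatError(f"unknown relation {relation!r} in {part!r}")
        age = int(bits[2]) if bits[2].strip() not in ("", ".") else None
        out.append(Relative(relation, bits[1].strip().lower(), age))
    return out


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the tab-delimited clinical table.

    Expected columns: sample, age, gender, stage, grade, site, msi,
    family_history. A lone ``.`` marks a missing value in any field.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample", "age", "gender", "stage", "grade", "site", "msi",
                "family_history"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing clinical column(s): {', '.join(missing)}")

    def opt(v: str) -> str | None:
        v = v.strip()
        return None if v in ("", ".") else v

    records = []
    for row in df.itertuples(index=False):
        age = opt(row.age)
        records.append(
            ClinicalRecord(
                sample_id=row.sample,
                age=int(age) if age is not None else None,
                gender=(opt(row.gender) or "").lower() or None,
                stage=opt(row.stage),
                grade=(opt(row.grade) or "").lower() or None,
                site=(opt(row.site) or "").lower() or None,
                msi=opt(row.msi),
                family_history_relatives=_parse_relatives(row.family_history),
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.family_history_relatives is None:
            fh = "."
        else:
            fh = ";".join(
                f"{rel.relation}:{rel.cancer_site}:"
                f"{rel.age_at_diagnosis if rel.age_at_diagnosis is not None else '.'}"
                for rel in r.family_history_relatives
            )
        rows.append(
            {
                "sample": r.sample_id,
                "age": r.age if r.age is not None else ".",
                "gender": r.gender or ".",
                "stage": r.stage or ".",
                "grade": r.grade or ".",
                "site": r.site or ".",
                "msi": r.msi or ".",
                "family_history": fh,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_mutation_matrix(
    muts: MutationTable,
    samples: Sequence[str],
    min_mutated_samples: int = 2,
    classes: Iterable[str] | None = None,
) -> MutationMatrix:
    """Build the binary gene x sample indicator matrix.

    All variant classes set the indicator by default (``classes`` restricts,
    e.g. to :data:`SHORT_VARIANT_CLASSES`). Genes mutated in fewer than
    ``min_mutated_samples`` samples are dropped; ``min_mutated_samples=1``
    keeps every mutated gene. Samples with no mutations are kept as
    all-zero columns.
    """
    samples = list(samples)
    sample_index = {s: j for j, s in enumerate(samples)}
    if len(sample_index) != len(samples):
        raise ValueError("duplicate sample ids")
    allowed = VARIANT_CLASSES if classes is None else frozenset(classes)

    unknown = {r.sample_id for r in muts if r.sample_id not in sample_index}
    if unknown:
        raise ValueError(
            "mutation sample id(s) not in sample list: " + ", ".join(sorted(unknown))
        )

    genes = sorted({r.gene for r in muts if r.variant_class in allowed})
    gene_index = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for r in muts:
        if r.variant_class in allowed:
            values[gene_index[r.gene], sample_index[r.sample_id]] = 1

    keep = values.sum(axis=1) >= min_mutated_samples
    return MutationMatrix(
        genes=[g for g, k in zip(genes, keep) if k],
        samples=samples,
        values=values[keep],
    )


def compute_tmb(
    muts: MutationTable,
    panel_mb: float,
    cutoff: float = 10.0,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample tumor mutational burden.

    TMB = short-nucleotide mutations (SNV/INS/DEL; CNV and fusion excluded)
    divided by the panel footprint in megabases. Class "high" iff
    ``tmb >= cutoff`` (the boundary sample counts as high).

    Returns a DataFrame indexed by sample with columns ``tmb`` and
    ``tmb_class``.
    """
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be positive, got {panel_mb}")
    counts: dict[str, int] = {}
    if samples is not None:
        counts = {s: 0 for s in samples}
    for r in muts:
        if samples is None:
            counts.setdefault(r.sample_id, 0)
        if r.is_short_variant and r.sample_id in counts:
            counts[r.sample_id] += 1
    tmb = pd.Series({s: c / panel_mb for s, c in counts.items()}, name="tmb",
                    dtype=float)
    out = tmb.to_frame()
    out["tmb_class"] = np.where(out["tmb"] >= cutoff, "high", "low")
    out.index.name = "sample"
    return out


def binarize_clinical(
    records: Sequence[ClinicalRecord],
    tmb_class: pd.Series | dict | None = None,
    site_map: dict[str, str] | None = None,
) -> BinaryClinicalMatrix:
    """Binarize clinical covariates into a {0, 1, NA} matrix.

    Conventions: ``age_old`` = 1 iff age >= 60; ``sidedness_right`` from the
    site map (cecum / ascending / transverse colon are right-sided;
    descending / sigmoid colon and rectum left-sided; anything else NA with
    a warning); ``family_history`` = 1 iff at least one first-degree
    relative (parent, sibling, or child) has cancer; ``msi_high`` = 1 iff
    MSI-H; ``tmb_high`` from the supplied per-sample TMB class. Missing
    source fields yield NA.
    """
    if not records:
        raise ValueError("no clinical records")
    site_map = DEFAULT_SITE_MAP if site_map is None else site_map
    if tmb_class is not None and not isinstance(tmb_class, dict):
        tmb_class = dict(tmb_class)

    samples = [r.sample_id for r in records]
    values = np.full((len(CLINICAL_VARIABLES), len(records)), np.nan)
    vi = {v: i for i, v in enumerate(CLINICAL_VARIABLES)}
    unknown_sites: set[str] = set()

    for j, r in enumerate(records):
        if r.age is not None:
            values[vi["age_old"], j] = 1.0 if r.age >= 60 else 0.0
        if r.gender is not None:
            values[vi["gender_male"], j] = 1.0 if r.gender == "male" else 0.0
        if r.stage is not None:
            values[vi["stage_IV"], j] = 1.0 if r.stage == "IV" else 0.0
        if r.grade is not None:
            values[vi["grade_high"], j] = 1.0 if r.grade == "high" else 0.0
        if r.site is not None:
            side = site_map.get(r.site)
            if side is None:
                unknown_sites.add(r.site)
            else:
                values[vi["sidedness_right"], j] = 1.0 if side == "right" else 0.0
        if r.msi is not None:
            values[vi["msi_high"], j] = 1.0 if r.msi == "MSI-H" else 0.0
        if tmb_class is not None and r.sample_id in tmb_class:
            values[vi["tmb_high"], j] = 1.0 if tmb_class[r.sample_id] == "high" else 0.0
        if r.family_history_relatives is not None:
            has_fd = any(
                rel.relation in _FIRST_DEGREE_ALIASES
                for rel in r.family_history_relatives
            )
            values[vi["family_history"], j] = 1.0 if has_fd else 0.0

    if unknown_sites:
        logger.warning(
            "unmapped anatomical site(s), set to NA: %s",
            ", ".join(sorted(unknown_sites)),
        )
    return BinaryClinicalMatrix(list(CLINICAL_VARIABLES), samples, values)
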
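"""End-to-end orchestration: mutation matrix -> co-mutation scores ->
gene clusters -> subtypes -> clinical associations -> signatures per subtype.

All stage outputs are written as tab-delimited files under one output
directory together with a manifest (file, stage, sha256) and a human
summary; a rerun with the same configuration and seed reproduces identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from comutsig import clinical as clin_mod
from comutsig import cohort_io, comut, signatures as sig_mod

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage runs)."""


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    mutations: Path
    clinical: Path
    outdir: Path
    reference: Path | None = None
    catalog: Path | None = None
    min_mutated_samples: int = 2
    panel_mb: float = 1.5
    tmb_cutoff: float = 10.0
    k_clusters: int = 8
    k_min: int = 1
    k_max: int = 5
    cosine_threshold: float = 0.85
    alpha: float = 0.05
    seed: int = 0
    restarts: int = 10
    nmf_mode: str = "ml"
    gene_whitelist: tuple[str, ...] | None = None
    run_signatures: bool = True
    signature_cluster: int | None = None  # extract per this subtype vs rest

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw = {**raw.get("paths", {}), **raw.get("parameters", {}),
               **{k: v for k, v in raw.items()
                  if k not in ("paths", "parameters")}}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError("unknown config key(s): " + ", ".join(sorted(unknown)))
        for key in ("mutations", "clinical", "outdir", "reference", "catalog"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if raw.get("gene_whitelist") is not None:
            raw["gene_whitelist"] = tuple(raw["gene_whitelist"])
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("mutations", "clinical"):
            p = getattr(self, key)
            if p is None or not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        for key in ("reference", "catalog"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        if self.panel_mb <= 0:
            raise ConfigError("panel_mb must be positive")
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_mutated_samples < 1:
            raise ConfigError("min_mutated_samples must be >= 1")


@dataclass
class RunReport:
    outdir: Path
    manifest: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest.append({"file": path.name, "stage": stage,
                              "sha256": digest})

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2) + "\n"
        )
        (self.outdir / "report.json").write_text(
            json.dumps(self.summary, indent=2, default=str) + "\n"
        )


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run every enabled stage; outputs and manifest land under cfg.outdir."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir)
    t0 = time.time()

    stage = "io"
    try:
        muts = cohort_io.read_mutations(cfg.mutations)
        clin_records = cohort_io.read_clinical(cfg.clinical)
        samples = [r.sample_id for r in clin_records]

        tmb = cohort_io.compute_tmb(muts, panel_mb=cfg.panel_mb,
                                    cutoff=cfg.tmb_cutoff, samples=samples)
        tmb_path = outdir / "tmb.tsv"
        tmb.to_csv(tmb_path, sep="\t")
        report.add(stage, tmb_path)

        clin = cohort_io.binarize_clinical(clin_records,
                                           tmb_class=tmb["tmb_class"])

        stage = "matrix"
        matrix = cohort_io.build_mutation_matrix(
            muts.subset(samples), samples,
            min_mutated_samples=cfg.min_mutated_samples,
        )
        if cfg.gene_whitelist:
            keep = [g for g in matrix.genes if g in set(cfg.gene_whitelist)]
            idx = [matrix.genes.index(g) for g in keep]
            matrix = cohort_io.MutationMatrix(keep, matrix.samples,
                                              matrix.values[idx])
        mat_path = outdir / "mutation_matrix.tsv"
        matrix.to_frame().to_csv(mat_path, sep="\t")
        report.add(stage, mat_path)

        stage = "comut"
        scores = comut.score_matrix(matrix)
        score_path = outdir / "comutation_scores.tsv"
        scores.to_frame().to_csv(score_path, sep="\t")
        report.add(stage, score_path)

        stage = "cluster"
        k = min(cfg.k_clusters, len(matrix.genes))
        clusters = comut.cluster_genes(scores, k)
        cl_path = outdir / "gene_clusters.tsv"
        pd.DataFrame(
            sorted(clusters.assignment.items()), columns=["gene", "cluster"]
        ).to_csv(cl_path, sep="\t", index=False)
        report.add(stage, cl_path)
        link_path = outdir / "linkage.tsv"
        pd.DataFrame(
            clusters.linkage, columns=["left", "right", "height", "size"]
        ).to_csv(link_path, sep="\t", index=False)
        report.add(stage, link_path)

        stage = "subtype"
        subtypes = comut.assign_subtypes(matrix, clusters)
        sub_path = outdir / "subtypes.tsv"
        subtypes.astype(int).to_csv(sub_path, sep="\t")
        report.add(stage, sub_path)

        stage = "assoc"
        scan = clin_mod.subtype_clinical_scan(subtypes, clin, alpha=cfg.alpha)
        scan_path = outdir / "subtype_clinical_associations.tsv"
        scan.to_csv(scan_path, sep="\t", index=False)
        report.add(stage, scan_path)
        gene_scan = clin_mod.gene_clinical_scan(matrix, clin, alpha=cfg.alpha)
        gs_path = outdir / "gene_clinical_associations.tsv"
        gene_scan.to_csv(gs_path, sep="\t", index=False)
        report.add(stage, gs_path)

        signature_summary = {}
        if cfg.run_signatures:
            stage = "signatures"
            profile = sig_mod.build_profile_matrix(
                muts.subset(samples), reference=cfg.reference, samples=samples
            )
            prof_path = outdir / "profile_96.tsv"
            profile.to_frame().to_csv(prof_path, sep="\t")
            report.add(stage, prof_path)

            groups = {"all": samples}
            if cfg.signature_cluster is not None and \
                    cfg.signature_cluster in subtypes.index:
                flags = subtypes.loc[cfg.signature_cluster]
                groups = {
                    "subtype": [s for s in samples if flags[s]],
                    "rest": [s for s in samples if not flags[s]],
                }
            catalog = (sig_mod.load_catalog(cfg.catalog)
                       if cfg.catalog is not None else None)
            for name, members in groups.items():
                sub_profile = profile.subset(members)
                if sub_profile.counts.sum() == 0 or len(members) < 2:
                    logger.warning("skipping signature group %s (no data)", name)
                    continue
                k_hi = min(cfg.k_max, len(members))
                best_k, diag = sig_mod.select_rank(
                    sub_profile, k_range=range(cfg.k_min, k_hi + 1),
                    seed=cfg.seed, restarts=cfg.restarts, mode=cfg.nmf_mode,
                )
                result = sig_mod.nmf_extract(
                    sub_profile, best_k, seed=cfg.seed, restarts=cfg.restarts,
                    mode=cfg.nmf_mode,
                )
                if catalog is not None:
                    result = sig_mod.match_signatures(
                        result, catalog, threshold=cfg.cosine_threshold
                    )
                sig_path = outdir / f"signatures_{name}.tsv"
                result.signatures_frame().to_csv(sig_path, sep="\t")
                report.add(stage, sig_path)
                exp_path = outdir / f"exposures_{name}.tsv"
                result.exposures_frame().to_csv(exp_path, sep="\t")
                report.add(stage, exp_path)
                diag_path = outdir / f"rank_selection_{name}.tsv"
                diag.to_csv(diag_path, sep="\t", index=False)
                report.add(stage, diag_path)
                if result.matches is not None:
                    match_path = outdir / f"signature_matches_{name}.tsv"
                    pd.DataFrame(
                        [
                            {"signature": m.label, "best_match": m.best_match,
                             "cosine": m.cosine, "matched": m.matched}
                            for m in result.matches
                        ]
                    ).to_csv(match_path, sep="\t", index=False)
                    report.add(stage, match_path)
                signature_summary[name] = {
                    "k": best_k,
                    "log_likelihood": result.log_likelihood,
                    "matches": [
                        {"label": m.label, "best_match": m.best_match,
                         "cosine": round(m.cosine, 4), "matched": m.matched}
                        for m in (result.matches or [])
                    ],
                }
    except ConfigError:
        raise
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        report.summary = {"failed_stage": stage, "error": str(exc)}
        report.write()
        raise

    top = scan.sort_values("p").head(10)
    report.summary = {
        "n_samples": len(samples),
        "n_genes": len(matrix.genes),
        "k_clusters": clusters.k,
        "cluster_sizes": {
            int(c): len(clusters.genes_in(c))
            for c in sorted(set(clusters.assignment.values()))
        },
        "top_subtype_clinical_associations": top.round(
            {"odds_ratio": 3, "score": 3}
        ).to_dict(orient="records"),
        "signatures": signature_summary,
        "elapsed_seconds": round(time.time() - t0, 2),
        "seed": cfg.seed,
    }
    report.write()
    return report
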
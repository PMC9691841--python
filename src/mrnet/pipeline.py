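"""Orchestration of the full master-regulator study flow from one config.

Each cohort is analyzed independently end-to-end (network deconvolution,
then activity inference when it has controls); cohorts are merged only at
the consensus step. Clinical-only cohorts (no control samples, like a
grades+survival validation set) skip activity inference and contribute the
pathology/survival associations. A JSON manifest with the config echo,
derived stage seeds and sha256 checksums of every output is written last —
and also on failure, with the failure state recorded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .activity import intersect_mrs, permutation_pvalues, select_mrs
from .clinical import activity_cell_correlation, cox_fit, pearson_assoc, per_sample_activity, ssgsea_scores
from .enrichment import ora_test
from .network import apply_dpi, build_edge_list, edges_to_regulons

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    name: str
    expression: str
    labels: str | None = None
    clinical: str | None = None


@dataclass
class RunConfig:
    cohorts: list[CohortConfig]
    regulators: str
    outdir: str
    seed: int = 0
    p_threshold: float = 1e-8
    p_corrected: bool = False
    dpi_tolerance: float = 0.1
    min_regulon: int = 25
    n_perm_mi: int = 1000
    n_perm: int = 1000
    alpha: float = 0.05
    min_targets: int = 10
    cell_gmt: str | None = None
    pathway_gmt: str | None = None
    ssgsea_alpha: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["cohorts"] = [CohortConfig(**c) for c in raw["cohorts"]]
        return cls(**raw)

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        with_labels = [c for c in self.cohorts if c.labels]
        if len(with_labels) == 1:
            raise ValueError("consensus needs >= 2 case/control cohorts; got 1")
        for c in self.cohorts:
            for p in (c.expression, c.labels, c.clinical):
                if p and not Path(p).exists():
                    raise FileNotFoundError(p)
        for p in (self.regulators, self.cell_gmt, self.pathway_gmt):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the config enables; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {**{k: v for k, v in vars(config).items() if k != "cohorts"},
                   "cohorts": [vars(c) for c in config.cohorts]},
        "stages": {},
        "decisions": {
            "signature_statistic": "Welch t mapped to z",
            "mi_estimator": "copula-rank Gaussian kernel, Silverman bandwidth",
            "dpi_semantics": "single pass on original MI, multiplicative slack, ties keep",
            "null_pooling": "per-TF standardized permutation NES pooled across TFs",
            "multiple_testing": "Benjamini-Hochberg across TFs / gene sets",
        },
        "status": "running",
    }
    outputs: dict[str, Path] = {}

    def stage(name: str):
        t0 = _time.perf_counter()
        logger.info("stage %s started", name)
        manifest["stages"][name] = {"status": "running"}

        def done(ok: bool = True):
            manifest["stages"][name]["status"] = "ok" if ok else "failed"
            logger.info("stage %s finished in %.1fs", name, _time.perf_counter() - t0)
        return done

    try:
        regulators = mio.read_regulators(config.regulators)
        activity_tables: dict[str, pd.DataFrame] = {}
        regulon_sets: dict[str, dict] = {}
        cohort_data: dict[str, dict] = {}

        for cohort in config.cohorts:
            expr = mio.read_expression(cohort.expression)
            labels = mio.read_labels(cohort.labels) if cohort.labels else None
            if labels is not None:
                missing = labels.index.difference(expr.columns)
                if len(missing):
                    raise ValueError(f"label sample absent from expression: {missing[0]}")
            clinical = mio.read_clinical(cohort.clinical, expr) if cohort.clinical else None
            cohort_data[cohort.name] = {"expr": expr, "labels": labels, "clinical": clinical}

            done = stage(f"network:{cohort.name}")
            edges = build_edge_list(
                expr, regulators, p_threshold=config.p_threshold,
                n_perm=config.n_perm_mi, p_corrected=config.p_corrected,
                seed=stage_seed(config.seed, f"mi:{cohort.name}"))
            edges = apply_dpi(edges, tolerance=config.dpi_tolerance)
            path = outdir / f"network_{cohort.name}.tsv"
            mio.write_edges(edges, path)
            outputs[f"network_{cohort.name}"] = path
            regulons = edges_to_regulons(edges, expr, min_size=config.min_regulon)
            path = outdir / f"regulons_{cohort.name}.tsv"
            mio.write_regulons(regulons, path)
            outputs[f"regulons_{cohort.name}"] = path
            regulon_sets[cohort.name] = regulons
            done()

            if labels is None or (labels == "control").sum() < 2:
                logger.info("cohort %s has no controls: clinical-only role", cohort.name)
                continue
            done = stage(f"activity:{cohort.name}")
            table = permutation_pvalues(
                expr, labels, regulons, n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"viper:{cohort.name}"),
                min_targets=config.min_targets)
            path = outdir / f"activity_{cohort.name}.tsv"
            mio.write_activity(table, path)
            outputs[f"activity_{cohort.name}"] = path
            mrs = select_mrs(table, alpha=config.alpha)
            path = outdir / f"mrs_{cohort.name}.tsv"
            mio.write_activity(mrs, path)
            outputs[f"mrs_{cohort.name}"] = path
            activity_tables[cohort.name] = table
            done()

        consensus = None
        if len(activity_tables) >= 2:
            done = stage("consensus")
            consensus = intersect_mrs(list(activity_tables.values()), alpha=config.alpha)
            path = outdir / "consensus_mrs.tsv"
            consensus.to_csv(path, sep="\t", index=False, float_format=mio.FLOAT_FMT)
            outputs["consensus_mrs"] = path
            done()

        consensus_tfs = list(consensus["tf"]) if consensus is not None else []

        for cohort in config.cohorts:
            data = cohort_data[cohort.name]
            if data["clinical"] is None or not consensus_tfs:
                continue
            done = stage(f"clinical:{cohort.name}")
            expr, clinical = data["expr"], data["clinical"]
            rows = []
            for tf in consensus_tfs:
                if tf not in expr.index:
                    continue
                x = expr.loc[tf, clinical.index]
                for grade in ("inflammation", "fibrosis"):
                    res = pearson_assoc(x, clinical[grade])
                    rows.append({"tf": tf, "variable": grade,
                                 "r": res.r, "p": res.p, "n": res.n})
            path = outdir / f"pathology_{cohort.name}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=mio.FLOAT_FMT)
            outputs[f"pathology_{cohort.name}"] = path
            rows = []
            for tf in consensus_tfs:
                if tf not in expr.index:
                    continue
                fit = cox_fit(clinical["time"], clinical["event"],
                              expr.loc[tf, clinical.index])
                rows.append({"tf": tf, "beta": fit.beta, "hr": fit.hr,
                             "p": fit.p, "converged": fit.converged})
            path = outdir / f"survival_{cohort.name}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=mio.FLOAT_FMT)
            outputs[f"survival_{cohort.name}"] = path
            done()

        if config.cell_gmt:
            sets = mio.read_gmt(config.cell_gmt)
            for name, table in activity_tables.items():
                done = stage(f"infiltration:{name}")
                expr = cohort_data[name]["expr"]
                scores = ssgsea_scores(expr, sets, alpha_weight=config.ssgsea_alpha)
                path = outdir / f"ssgsea_{name}.tsv"
                scores.to_csv(path, sep="\t", index_label="sample", float_format=mio.FLOAT_FMT)
                outputs[f"ssgsea_{name}"] = path
                mr_regulons = {tf: reg for tf, reg in regulon_sets[name].items()
                               if tf in consensus_tfs} or regulon_sets[name]
                act = per_sample_activity(expr, mr_regulons, min_targets=config.min_targets)
                corr = activity_cell_correlation(act, scores)
                path = outdir / f"infiltration_{name}.tsv"
                corr.to_csv(path, sep="\t", index=False, float_format=mio.FLOAT_FMT)
                outputs[f"infiltration_{name}"] = path
                done()

        if config.pathway_gmt and consensus is not None and len(consensus):
            done = stage("enrichment")
            sets = mio.read_gmt(config.pathway_gmt)
            for direction in ("activated", "repressed"):
                tfs = consensus.loc[consensus["direction"] == direction, "tf"]
                targets: set = set()
                for name, regulons in regulon_sets.items():
                    for tf in tfs:
                        if tf in regulons:
                            targets |= set(regulons[tf].targets)
                if not targets:
                    continue
                universe = set()
                for data in cohort_data.values():
                    universe |= set(data["expr"].index)
                res = ora_test(targets, sets, universe)
                path = outdir / f"ora_{direction}_targets.tsv"
                res.to_csv(path, sep="\t", index=False, float_format=mio.FLOAT_FMT)
                outputs[f"ora_{direction}_targets"] = path
            done()

        manifest["status"] = "ok"
    except Exception as exc:  # manifest survives partial failure
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["checksums"] = {k: _sha256(p) for k, p in sorted(outputs.items())}
        manifest["stage_seeds"] = {s: stage_seed(config.seed, s)
                                   for s in sorted({f"mi:{c.name}" for c in config.cohorts}
                                                   | {f"viper:{c.name}" for c in config.cohorts})}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
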
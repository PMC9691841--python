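"""Plain-text readers and writers for every pipeline artifact.

All formats are TSV/GMT/JSON so diffs stay reviewable: expression (genes x
samples), two-column sample labels, clinical tables, regulator lists, GMT
gene sets, edge lists, regulons, activity tables and ground-truth networks.
Readers enforce the consistency rules the pipeline depends on (duplicate
gene rows collapsed by mean with a warning; clinical samples must exist in
the expression matrix).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Regulon
from .synthetic import SyntheticCohort, TrueNetwork

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    if expr.isna().any().any():
        bad = expr.index[expr.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing values in expression matrix (e.g. {bad})")
    if expr.index.duplicated().any():
        n_dup = int(expr.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", n_dup)
        expr = expr.groupby(level=0, sort=False).mean()
    return expr


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError("labels file must have exactly two columns: sample, condition")
    lab = df.iloc[:, 0].astype(str)
    bad = sorted(set(lab) - {"case", "control"})
    if bad:
        raise ValueError(f"unknown condition labels: {bad}")
    return lab.rename("condition")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("condition").to_csv(path, sep="\t", index_label="sample")


def read_clinical(path, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    need = {"inflammation", "fibrosis", "time", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(need)}")
    if expression is not None:
        missing = df.index.difference(expression.columns)
        if len(missing):
            raise ValueError(f"clinical sample absent from expression: {missing[0]}")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample", float_format=FLOAT_FMT)


def read_regulators(path) -> list[str]:
    with open(path) as fh:
        tfs = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return list(dict.fromkeys(tfs))


def write_regulators(tfs, path) -> None:
    Path(path).write_text("".join(f"{tf}\n" for tf in tfs))


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT rows need name, description, >=1 gene")
            sets[fields[0]] = list(dict.fromkeys(g for g in fields[2:] if g))
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description or name, *genes]) + "\n")


def read_edges(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    if list(edges.columns) != ["tf", "target", "mi", "p"]:
        raise ValueError("edge list must have columns tf, target, mi, p")
    return edges


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_regulons(path) -> dict[str, Regulon]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["tf", "target", "mode", "likelihood"]:
        raise ValueError("regulon table must have columns tf, target, mode, likelihood")
    out = {}
    for tf, grp in df.groupby("tf", sort=True):
        out[tf] = Regulon(tf, list(grp["target"]), grp["mode"].to_numpy(),
                          grp["likelihood"].to_numpy())
    return out


def write_regulons(regulons: dict[str, Regulon], path) -> None:
    rows = [{"tf": tf, "target": t, "mode": m, "likelihood": w}
            for tf, reg in regulons.items()
            for t, m, w in zip(reg.targets, reg.modes, reg.likelihoods)]
    pd.DataFrame(rows, columns=["tf", "target", "mode", "likelihood"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_regulons_json(regulons: dict[str, Regulon], path) -> None:
    payload = {tf: [[t, float(m), float(w)] for t, m, w in
                    zip(reg.targets, reg.modes, reg.likelihoods)]
               for tf, reg in regulons.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_activity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_activity(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_truth(truth: TrueNetwork, path) -> None:
    payload = {
        "regulators": truth.regulators,
        "genes": truth.genes,
        "planted_activated": sorted(truth.planted_activated),
        "planted_repressed": sorted(truth.planted_repressed),
        "regulons": {tf: [[t, m, s] for t, m, s in reg]
                     for tf, reg in truth.regulons.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> TrueNetwork:
    payload = json.loads(Path(path).read_text())
    return TrueNetwork(
        regulators=payload["regulators"],
        regulons={tf: [(t, int(m), float(s)) for t, m, s in reg]
                  for tf, reg in payload["regulons"].items()},
        planted_activated=set(payload["planted_activated"]),
        planted_repressed=set(payload["planted_repressed"]),
        genes=payload["genes"],
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write every artifact of a synthetic cohort; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "clinical": outdir / "clinical.tsv",
        "cell_signatures": outdir / "cell_signatures.gmt",
        "regulators": outdir / "regulators.txt",
        "truth": outdir / "truth.json",
        "abundances": outdir / "true_abundances.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_labels(cohort.labels, paths["labels"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gmt(cohort.cell_signatures, paths["cell_signatures"])
    write_regulators(cohort.truth.regulators, paths["regulators"])
    write_truth(cohort.truth, paths["truth"])
    cohort.true_abundances.to_csv(paths["abundances"], sep="\t",
                                  index_label="sample", float_format=FLOAT_FMT)
    return paths
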
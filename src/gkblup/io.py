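"""Readers and writers for the delimited-text interchange formats.

Markers: CSV/TSV, first column line ID, remaining columns numeric marker
codes, header row of marker names. Phenotypes: long-format CSV with columns
line, env, value. Kernels: square CSV with line IDs as both header and first
column. Reports: two CSVs (metrics, relative efficiencies) plus a JSON
manifest recording every seed and setting of the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import KernelMatrix, MarkerMatrix
from .metrics import EvaluationReport

__all__ = [
    "load_markers",
    "write_markers",
    "load_phenotypes",
    "write_phenotypes",
    "load_kernel",
    "write_kernel",
    "write_report",
    "write_manifest",
]

log = logging.getLogger("gkblup")


def load_markers(path) -> MarkerMatrix:
    """Read a marker matrix, column-mean imputing missing genotypes.

    The number of imputed cells is logged; a marker with no observed
    genotypes at all is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    try:
        G = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric marker codes in {path.name}: {exc}") from exc
    n_missing = int(np.isnan(G).sum())
    if n_missing:
        col_means = np.nanmean(G, axis=0)
        if np.isnan(col_means).any():
            bad = df.columns[np.isnan(col_means)][0]
            raise ValueError(
                f"marker {bad!r} has no observed genotypes; cannot impute"
            )
        idx = np.where(np.isnan(G))
        G[idx] = col_means[idx[1]]
        log.info("imputed %d missing genotype calls by column mean", n_missing)
    return MarkerMatrix(line_ids=df.index.astype(str).tolist(), G=G)


def write_markers(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(
        markers.G,
        index=pd.Index(markers.line_ids, name="line"),
        columns=[f"M{k + 1}" for k in range(markers.n_markers)],
    )
    df.to_csv(path)


def load_phenotypes(path, allow_missing: bool = False) -> pd.DataFrame:
    """Read long-format phenotype records with columns line, env, value.

    Duplicate (line, env) keys are rejected. NA trait values are allowed
    only with ``allow_missing=True`` (prediction-only records).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"line": str, "env": str})
    required = {"line", "env", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path.name} is missing required column(s) {sorted(missing)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        row = int(np.where(bad)[0][0])
        raise ValueError(
            f"non-numeric trait value {df['value'].iloc[row]!r} in column "
            f"'value', row {row + 2} of {path.name}"
        )
    df["value"] = values
    dup = df.duplicated(subset=["line", "env"])
    if dup.any():
        l, e = df.loc[dup, ["line", "env"]].iloc[0]
        raise ValueError(f"duplicate (line, env) record: ({l!r}, {e!r})")
    if df["value"].isna().any() and not allow_missing:
        raise ValueError(
            "phenotype file contains NA trait values; pass allow_missing=True "
            "for prediction-only records"
        )
    return df[["line", "env", "value"]]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[["line", "env", "value"]].to_csv(path, index=False)


def write_kernel(kernel: KernelMatrix, path) -> None:
    ids = pd.Index(kernel.line_ids, name="line")
    pd.DataFrame(kernel.K, index=ids, columns=ids).to_csv(path)


def load_kernel(path, rho: float | None = None) -> KernelMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("kernel CSV row and column line IDs disagree")
    return KernelMatrix(K=df.to_numpy(dtype=float),
                        line_ids=df.index.astype(str).tolist(), rho=rho)


def write_report(report: EvaluationReport, out_dir) -> dict:
    """Write metrics.csv and relative_efficiencies.csv; return written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out_dir / "metrics.csv",
        "relative_efficiencies": out_dir / "relative_efficiencies.csv",
    }
    report.metrics.to_csv(paths["metrics"], index=False)
    report.relative_efficiencies.to_csv(paths["relative_efficiencies"], index=False)
    return {k: str(v) for k, v in paths.items()}


def write_manifest(manifest: dict, path) -> None:
    """JSON manifest of seeds and settings sufficient to reproduce a run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(manifest, indent=2, default=_default, sort_keys=True))
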
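"""Delimited-text readers/writers for matrices, cohorts, atlases, and results.

Everything on disk is tab-separated text: connectivity matrices as node x
node tables with a node-id header row, one file per subject
(``<subject_id>.tsv``); the subjects table with columns ``subject_id``,
``score`` and optional ``age``, ``sex``, ``mean_fd``, ``label``; the atlas
as ``node_id, region, network, x, y, z``. Nested results go to JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    ConnectivityMatrix,
    CPMResult,
    Edge,
    EdgeSelection,
    InvalidParameterError,
    NodeAtlas,
    PermutationResult,
    TimeSeries,
)

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8


# ---------------------------------------------------------------------------
# Matrices and cohorts


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    node_ids = [str(i + 1) for i in range(m.n_nodes)]
    pd.DataFrame(m.z, columns=node_ids).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_matrix(path: str | Path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read one node x node matrix; symmetrize tiny float asymmetry.

    Asymmetry within 1e-8 is averaged away (and logged); anything larger is
    an error naming the file.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    z = df.to_numpy(dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise InvalidParameterError(f"{path}: matrix is {z.shape}, expected square")
    if not np.all(np.isfinite(z)):
        raise InvalidParameterError(f"{path}: matrix contains non-finite values")
    asym = np.max(np.abs(z - z.T)) if z.size else 0.0
    if asym > SYMMETRY_TOL:
        raise InvalidParameterError(f"{path}: asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}")
    if asym > 0:
        logger.info("%s: symmetrized asymmetry %g by averaging", path, asym)
        z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=subject_id or path.stem, z=z)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """One matrix file per subject plus a ``subjects.tsv`` table."""
    out_dir = Path(out_dir)
    matdir = out_dir / "matrices"
    matdir.mkdir(parents=True, exist_ok=True)
    for m in cohort.subjects:
        write_matrix(m, matdir / f"{m.subject_id}.tsv")
    table = pd.DataFrame({"subject_id": cohort.subject_ids(), "score": cohort.scores})
    if cohort.covariates is not None:
        for col in ("age", "sex", "mean_fd"):
            if col in cohort.covariates.columns:
                table[col] = cohort.covariates[col].to_numpy()
    if cohort.labels is not None:
        table["label"] = cohort.labels
    table.to_csv(out_dir / "subjects.tsv", sep="\t", index=False, float_format="%.17g")
    return out_dir


def read_cohort(cohort_dir: str | Path, scores_path: str | Path | None = None) -> Cohort:
    """Load matrices + subjects table, aligned by subject id.

    Every subject in the table must have a matrix file and vice versa;
    mismatches raise an error listing the offending ids.
    """
    cohort_dir = Path(cohort_dir)
    matdir = cohort_dir / "matrices" if (cohort_dir / "matrices").is_dir() else cohort_dir
    if scores_path is None:
        scores_path = cohort_dir / "subjects.tsv"
    scores_path = Path(scores_path)
    if not scores_path.exists():
        raise InvalidParameterError(f"subjects table not found: {scores_path}")
    table = pd.read_csv(scores_path, sep="\t", dtype={"subject_id": str},
                        float_precision="round_trip")
    if "subject_id" not in table.columns or "score" not in table.columns:
        raise InvalidParameterError(f"{scores_path}: needs subject_id and score columns")
    if table["score"].isna().any():
        bad = table.loc[table["score"].isna(), "subject_id"].tolist()
        raise InvalidParameterError(f"{scores_path}: NaN score for subject(s) {bad}")

    files = {p.stem: p for p in sorted(matdir.glob("*.tsv")) if p.name != "subjects.tsv"}
    wanted = table["subject_id"].tolist()
    missing = [s for s in wanted if s not in files]
    if missing:
        raise InvalidParameterError(f"no matrix file for subject(s) {missing} in {matdir}")
    extra = [s for s in files if s not in set(wanted)]
    if extra:
        raise InvalidParameterError(
            f"matrix files without a subjects-table row: {extra} (table {scores_path})"
        )

    subjects = [read_matrix(files[s], subject_id=s) for s in wanted]
    cov_cols = [c for c in ("age", "sex", "mean_fd") if c in table.columns]
    covariates = table[cov_cols].reset_index(drop=True) if cov_cols else None
    labels = table["label"].to_numpy(dtype=int) if "label" in table.columns else None
    return Cohort(
        subjects=subjects,
        scores=table["score"].to_numpy(dtype=float),
        covariates=covariates,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Time series


def write_timeseries(ts: TimeSeries, ts_dir: str | Path, fd_dir: str | Path | None = None) -> None:
    ts_dir = Path(ts_dir)
    ts_dir.mkdir(parents=True, exist_ok=True)
    cols = [str(i + 1) for i in range(ts.n_nodes)]
    pd.DataFrame(ts.data, columns=cols).to_csv(
        ts_dir / f"{ts.subject_id}.tsv", sep="\t", index=False, float_format="%.17g"
    )
    if fd_dir is not None and ts.fd is not None:
        fd_dir = Path(fd_dir)
        fd_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"fd": ts.fd}).to_csv(fd_dir / f"{ts.subject_id}.tsv", sep="\t", index=False)


def read_timeseries(
    path: str | Path, tr: float, fd_path: str | Path | None = None
) -> TimeSeries:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(dtype=float)
    fd = None
    if fd_path is not None:
        fd = pd.read_csv(fd_path, sep="\t")["fd"].to_numpy(dtype=float)
    return TimeSeries(subject_id=path.stem, data=data, tr=tr, fd=fd)


# ---------------------------------------------------------------------------
# Atlas


def write_atlas(atlas: NodeAtlas, path: str | Path) -> Path:
    path = Path(path)
    atlas.table.to_csv(path, sep="\t", index=False)
    return path


def read_atlas(path: str | Path) -> NodeAtlas:
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"atlas table not found: {path}")
    return NodeAtlas(table=pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Edge sets and results


def write_edge_table(
    selection_or_edges, path: str | Path, tail: str | None = None
) -> Path:
    """Edge sets as TSV: node_i, node_j (0-based), rho, p, tail."""
    path = Path(path)
    rows = []
    if isinstance(selection_or_edges, EdgeSelection):
        sel = selection_or_edges
        iu, ju = np.triu_indices(sel.n_nodes, k=1)
        index_of = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
        for name, edges in (("positive", sel.positive_edges), ("negative", sel.negative_edges)):
            for i, j in sorted(edges):
                k = index_of[(i, j)]
                rows.append((i, j, sel.rho[k], sel.p[k], name))
    else:
        for i, j in sorted(selection_or_edges):
            rows.append((i, j, np.nan, np.nan, tail or ""))
    pd.DataFrame(rows, columns=["node_i", "node_j", "rho", "p", "tail"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_edge_table(path: str | Path) -> dict[str, set[Edge]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[Edge]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["tail"]), set()).add((int(row["node_i"]), int(row["node_j"])))
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(list(e) for e in obj)
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for provenance stamping."""
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results_json(results: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
    return path


def cpm_result_summary(res: CPMResult, perm: PermutationResult | None = None) -> dict:
    out = {
        "tail": res.tail,
        "rho_pred_obs": res.rho_pred_obs,
        "predicted": res.predicted,
        "observed": res.observed,
        "n_contributing_edges": len(res.contributing_edges),
        "contributing_edges": res.contributing_edges,
        "edges_per_fold": [len(e) for e in res.per_fold_edges],
    }
    if perm is not None:
        out["p_perm"] = perm.p_perm
        out["n_perm"] = perm.n_perm
    return out
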
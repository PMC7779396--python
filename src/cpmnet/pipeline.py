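"""End-to-end orchestration: (connect) -> predict -> permute -> anatomy.

``run_pipeline`` ties the stages together, stamps every output with the
seed and a config hash, and fails with a stage-labeled message if any stage
errors. Runs are idempotent for a fixed seed and config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .anatomy import node_degree, region_edge_counts, top_nodes
from .core import covariate_screen, kfold_cv, loocv, permutation_test
from .io import (
    config_hash,
    cpm_result_summary,
    read_atlas,
    read_cohort,
    read_timeseries,
    write_edge_table,
    write_matrix,
    write_results_json,
)
from .preprocess import connectivity, scrub
from .types import CPMError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; validated before any computation."""

    cohort_dir: Optional[str] = None
    timeseries_dir: Optional[str] = None
    fd_dir: Optional[str] = None
    scores_path: Optional[str] = None
    atlas_path: Optional[str] = None
    out_dir: str = "cpm_out"
    threshold: float = 0.05
    cv: str = "loo"  # "loo" or "kfold:<k>"
    n_perm: int = 1000
    seed: int = 0
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    scrub_fd: float = 0.5
    top_k: int = 10
    threads: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise InvalidParameterError(f"threshold must be in (0,1), got {self.threshold}")
        if self.cohort_dir is None and self.timeseries_dir is None:
            raise InvalidParameterError("need either cohort_dir or timeseries_dir")
        if self.cv != "loo" and not self.cv.startswith("kfold:"):
            raise InvalidParameterError(f"cv must be 'loo' or 'kfold:<k>', got {self.cv!r}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CPMError as exc:
                raise CPMError(f"[stage: {name}] {exc}") from exc
        return wrapper
    return deco


@_stage("connect")
def _connect_stage(config: RunConfig, out_dir: Path):
    """Time series -> scrubbed, Fisher-z connectivity matrices on disk."""
    ts_dir = Path(config.timeseries_dir)
    matdir = out_dir / "matrices"
    matdir.mkdir(parents=True, exist_ok=True)
    for path in sorted(ts_dir.glob("*.tsv")):
        fd_path = None
        if config.fd_dir is not None:
            cand = Path(config.fd_dir) / path.name
            fd_path = cand if cand.exists() else None
        ts = read_timeseries(path, tr=config.tr, fd_path=fd_path)
        if ts.fd is not None:
            ts = scrub(ts, config.scrub_fd)
        write_matrix(connectivity(ts), matdir / path.name)
    return matdir


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a JSON summary plus edge tables.

    Returns the summary dict that was written to ``<out_dir>/results.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    chash = config_hash(cfg_dict)

    if config.timeseries_dir is not None:
        matdir = _connect_stage(config, out_dir)
        cohort_dir = out_dir
        scores_path = config.scores_path
    else:
        cohort_dir = config.cohort_dir
        scores_path = config.scores_path

    try:
        cohort = read_cohort(cohort_dir, scores_path)
    except CPMError as exc:
        raise CPMError(f"[stage: load] {exc}") from exc

    logger.info("cohort: %d subjects, %d nodes", cohort.n_subjects, cohort.n_nodes)

    try:
        if config.cv == "loo":
            pos, neg = loocv(cohort, config.threshold, threads=config.threads)
        else:
            k = int(config.cv.split(":", 1)[1])
            pos, neg = kfold_cv(cohort, config.threshold, k=k, seed=config.seed)
    except CPMError as exc:
        raise CPMError(f"[stage: predict] {exc}") from exc

    perm_pos = perm_neg = None
    if config.n_perm > 0 and config.cv == "loo":
        try:
            perm_pos, perm_neg = permutation_test(
                cohort, config.threshold, n_perm=config.n_perm,
                seed=config.seed, threads=config.threads,
            )
        except CPMError as exc:
            raise CPMError(f"[stage: permute] {exc}") from exc

    summary: dict = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
        "n_nodes": cohort.n_nodes,
        "positive": cpm_result_summary(pos, perm_pos),
        "negative": cpm_result_summary(neg, perm_neg),
    }
    if cohort.covariates is not None:
        summary["covariate_screen"] = covariate_screen(cohort)

    write_edge_table(pos.contributing_edges, out_dir / "contributing_positive.tsv", tail="positive")
    write_edge_table(neg.contributing_edges, out_dir / "contributing_negative.tsv", tail="negative")

    if config.atlas_path is not None:
        try:
            atlas = read_atlas(config.atlas_path)
            anat: dict = {}
            for tail, res in (("positive", pos), ("negative", neg)):
                deg = node_degree(res.contributing_edges, cohort.n_nodes)
                anat[tail] = {
                    "region_counts": region_edge_counts(res.contributing_edges, atlas, "region").to_frame().to_dict(),
                    "network_counts": region_edge_counts(res.contributing_edges, atlas, "network").to_frame().to_dict(),
                    "top_nodes": top_nodes(deg, min(config.top_k, cohort.n_nodes), atlas).to_dict("records"),
                }
                region_edge_counts(res.contributing_edges, atlas, "region").to_frame().to_csv(
                    out_dir / f"region_counts_{tail}.tsv", sep="\t"
                )
            summary["anatomy"] = anat
        except CPMError as exc:
            raise CPMError(f"[stage: anatomy] {exc}") from exc

    write_results_json(summary, out_dir / "results.json")
    return summary
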
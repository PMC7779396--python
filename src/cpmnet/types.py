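"""Core domain containers shared across the pipeline.

Edge indexing convention used throughout the package: edges are unordered
node pairs addressed as 0-based upper-triangle index pairs ``(i, j)`` with
``i < j``, enumerated row-major (the order of ``numpy.triu_indices(n, 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

Edge = tuple[int, int]


class CPMError(Exception):
    """Base class for package errors."""


class InvalidParameterError(CPMError, ValueError):
    """A configuration or argument violates its contract."""


class DegenerateInputError(CPMError, ValueError):
    """Input is structurally valid but leaves the operation undefined."""


def upper_triangle_edges(n_nodes: int) -> list[Edge]:
    """All candidate edges for an ``n_nodes`` graph, row-major upper triangle."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def n_candidate_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class TimeSeries:
    """One subject's node time courses plus a head-motion trace.

    Parameters
    ----------
    subject_id:
        Identifier used to align with behavior tables.
    data:
        Array of shape ``(n_timepoints, n_nodes)``.
    tr:
        Repetition time in seconds per volume.
    fd:
        Framewise displacement per volume in mm; first volume 0 by
        convention.
    rotation_max, translation_max:
        Peak head rotation (degrees) and translation (mm) over the run,
        used by the subject-level motion exclusion rule.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    fd: Optional[np.ndarray] = None
    rotation_max: float = 0.0
    translation_max: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("time series data must be 2-D (time x node)")
        if self.tr <= 0:
            raise InvalidParameterError(f"tr must be positive, got {self.tr}")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (self.data.shape[0],):
                raise InvalidParameterError(
                    "fd length must equal the number of volumes "
                    f"({self.fd.shape[0]} vs {self.data.shape[0]})"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node matrix of Fisher-z edge weights, zero diagonal."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise InvalidParameterError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise InvalidParameterError("connectivity matrix contains non-finite entries")
        if not np.allclose(self.z, self.z.T):
            raise InvalidParameterError("connectivity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle weights in the package's canonical edge order."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.z[iu, ju]


@dataclass
class Cohort:
    """Aligned connectivity matrices, behavior scores, and optional covariates.

    ``covariates``, when present, is a DataFrame indexed like ``scores`` with
    any of the columns ``age`` (years), ``sex`` (category), ``mean_fd`` (mm).
    ``labels`` is an optional binary diagnosis vector (1 = case).
    """

    subjects: list[ConnectivityMatrix]
    scores: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.subjects) != self.scores.shape[0]:
            raise InvalidParameterError("scores and subjects must be aligned")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidParameterError("scores must be finite")
        n_nodes = {m.n_nodes for m in self.subjects}
        if len(n_nodes) > 1:
            raise InvalidParameterError(f"subjects disagree on node count: {sorted(n_nodes)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.scores.shape:
                raise InvalidParameterError("labels must align with scores")
        if self.covariates is not None and len(self.covariates) != len(self.subjects):
            raise InvalidParameterError("covariates must align with subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].n_nodes if self.subjects else 0

    def edge_matrix(self) -> np.ndarray:
        """Stack upper-triangle edge weights into (n_subjects, n_edges)."""
        return np.stack([m.edge_vector() for m in self.subjects])

    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.subjects]


@dataclass
class EdgeSelection:
    """Edges whose weights correlate with the score in a training set.

    ``positive_edges`` / ``negative_edges`` partition the selected edges by
    the sign of the Spearman coefficient; the two sets are disjoint by
    construction because an edge has a single rho.
    """

    positive_edges: set[Edge]
    negative_edges: set[Edge]
    rho: np.ndarray
    p: np.ndarray
    threshold: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.positive_edges & self.negative_edges:
            raise InvalidParameterError("positive and negative edge sets overlap")


@dataclass
class CPMModel:
    """Linear model mapping summed network strength to the behavior score."""

    tail: str  # "positive" or "negative"
    edges: set[Edge]
    slope: float
    intercept: float


@dataclass
class CPMResult:
    """Cross-validated predictions for one tail of the model."""

    tail: str
    predicted: np.ndarray
    observed: np.ndarray
    rho_pred_obs: float
    per_fold_edges: list[set[Edge]]
    contributing_edges: set[Edge]
    p_perm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.predicted.shape != self.observed.shape:
            raise InvalidParameterError("predicted/observed length mismatch")


@dataclass
class PermutationResult:
    """Null distribution and one-sided p-value for one tail."""

    tail: str
    null_rhos: np.ndarray
    observed_rho: float
    p_perm: float
    n_perm: int


@dataclass
class NodeAtlas:
    """Node-level anatomical lookup table.

    ``table`` has one row per node in node order with columns ``node_id``
    (1-based, as written to disk), ``region`` (macroscale anatomical label),
    ``network`` (canonical functional network label) and optional ``x, y, z``
    MNI coordinates and ``hemisphere``. Edge indices used elsewhere in the
    package are 0-based positions into this table.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"node_id", "region", "network"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidParameterError(f"atlas table missing columns: {sorted(missing)}")
        if self.table["region"].isna().any() or self.table["network"].isna().any():
            raise InvalidParameterError("every node needs exactly one region and network label")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()


@dataclass
class RegionEdgeCounts:
    """Symmetric label x label matrix of edge counts; diagonal = within-label."""

    labels: list[str]
    counts: np.ndarray

    def total(self) -> int:
        iu = np.triu_indices(len(self.labels))
        return int(self.counts[iu].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class ClassificationReport:
    """Cross-validated binary classification summary."""

    balanced_accuracy: float
    sensitivity: float
    specificity: float
    weight_map: np.ndarray
    top_regions: list[str] = field(default_factory=list)
    p_perm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("balanced_accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} out of [0,1]: {v}")
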
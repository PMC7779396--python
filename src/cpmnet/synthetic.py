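"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a resting-state functional-connectivity study: a
continuous symptom score per subject, one symmetric Fisher-z connectivity
matrix per subject, and a planted subset of edges whose weights correlate
with the score. Defaults follow the study this package models: a 268-node
parcellation and a clinician-rated severity score with mean 40.1, SD 22.3,
observed range 3-95.

Planted effects are injected directly on the Fisher-z edge weights: a
planted edge is a linear mix of the standardized score and independent
noise, weighted so the population Pearson correlation between edge weight
and score equals ``effect_size`` exactly (sign flipped for negative edges).
Null edges are score-independent Gaussian weights around a plausible
resting-state baseline. A parallel time-series generator exercises the
time-course -> connectome path via a shared-latent-signal construction.

All randomness flows from a single integer seed through a splittable
``numpy.random.SeedSequence``, so per-subject draws do not depend on
evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    Cohort,
    ConnectivityMatrix,
    Edge,
    InvalidParameterError,
    NodeAtlas,
    TimeSeries,
)

logger = logging.getLogger(__name__)

# Default score distribution: clinician-administered severity scale,
# mean +/- SD (range) = 40.1 +/- 22.3 (3-95) in the modeled cohort.
DEFAULT_SCORE_MEAN = 40.1
DEFAULT_SCORE_SD = 22.3
DEFAULT_SCORE_MIN = 3.0
DEFAULT_SCORE_MAX = 95.0

# Null edge weights ~ Normal(0.3, 0.15) in Fisher-z units: plausible
# resting-state functional connectivity magnitudes.
DEFAULT_EDGE_BASELINE = 0.3
DEFAULT_EDGE_NOISE_SD = 0.15


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``effect_size`` is the target population correlation (in [0, 1)) between
    each planted edge's weight and the behavior score. ``noise_sd`` scales
    edge-weight dispersion in Fisher-z units. ``label_score_cutoff``, when
    set, derives a binary diagnosis label as ``score >= cutoff``.
    """

    n_subjects: int = 122
    n_nodes: int = 268
    n_timepoints: int = 190
    score_mean: float = DEFAULT_SCORE_MEAN
    score_sd: float = DEFAULT_SCORE_SD
    score_min: float = DEFAULT_SCORE_MIN
    score_max: float = DEFAULT_SCORE_MAX
    score_skew: float = 0.0
    planted_positive_edges: list[Edge] = field(default_factory=list)
    planted_negative_edges: list[Edge] = field(default_factory=list)
    effect_size: float = 0.0
    edge_baseline: float = DEFAULT_EDGE_BASELINE
    noise_sd: float = DEFAULT_EDGE_NOISE_SD
    fd_spike_fraction: float = 0.0
    label_score_cutoff: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise InvalidParameterError("n_nodes must be >= 3")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be positive")
        if not 0.0 <= self.effect_size < 1.0:
            raise InvalidParameterError("effect_size must be in [0, 1)")
        if self.score_min >= self.score_max:
            raise InvalidParameterError("score_min must be below score_max")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be positive")
        pos = {self._norm_edge(e) for e in self.planted_positive_edges}
        neg = {self._norm_edge(e) for e in self.planted_negative_edges}
        if pos & neg:
            raise InvalidParameterError("planted positive/negative edge lists overlap")
        for i, j in pos | neg:
            if not (0 <= i < j < self.n_nodes):
                raise InvalidParameterError(f"planted edge ({i},{j}) out of range for n_nodes={self.n_nodes}")
        self.planted_positive_edges = sorted(pos)
        self.planted_negative_edges = sorted(neg)

    @staticmethod
    def _norm_edge(e: Sequence[int]) -> Edge:
        i, j = int(e[0]), int(e[1])
        if i == j:
            raise InvalidParameterError("planted edge cannot be a self-loop")
        return (i, j) if i < j else (j, i)


def _calibrate_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Location/scale of the parent normal whose [lo, hi]-truncation has the
    requested mean and SD.

    Truncation both shifts the mean toward the interval's center of mass and
    shrinks the SD, so the stated cohort moments are only reproduced if the
    parent parameters are solved for. When the interval covers the parent by
    many SDs the correction is negligible and skipped.
    """
    if lo <= mean - 8 * sd and hi >= mean + 8 * sd:
        return mean, sd
    from scipy.optimize import fsolve

    def residuals(params):
        mu, log_s = params
        s = float(np.exp(log_s))
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    (mu, log_s), info, ok, _ = fsolve(residuals, [mean, np.log(sd)], full_output=True)
    if ok != 1:
        raise InvalidParameterError(
            f"cannot realize mean={mean}, sd={sd} on [{lo}, {hi}] with a truncated normal"
        )
    return float(mu), float(np.exp(log_s))


def simulate_behavior(
    n: int,
    mean: float = DEFAULT_SCORE_MEAN,
    sd: float = DEFAULT_SCORE_SD,
    lo: float = DEFAULT_SCORE_MIN,
    hi: float = DEFAULT_SCORE_MAX,
    seed: int | np.random.SeedSequence = 0,
    skew: float = 0.0,
) -> np.ndarray:
    """Draw behavior scores from a (possibly skewed) normal truncated to [lo, hi].

    Truncation is enforced by rejection sampling, so the support is exact.
    For the symmetric case the parent normal's location/scale are solved so
    that the *truncated* law has the requested mean and SD. ``skew`` is the
    shape parameter of a skew-normal (0 = symmetric); with nonzero skew the
    moment targets refer to the untruncated law. Reproducible for a fixed
    seed.
    """
    if n <= 0:
        raise InvalidParameterError("n must be positive")
    if sd <= 0:
        raise InvalidParameterError("sd must be positive")
    if lo >= hi:
        raise InvalidParameterError("lo must be below hi")
    rng = np.random.default_rng(seed)

    if skew == 0.0:
        loc, scale = _calibrate_truncnorm(mean, sd, lo, hi)

        def draw(k: int) -> np.ndarray:
            return rng.normal(loc, scale, size=k)
    else:
        # skew-normal reparameterized to hit the requested mean/SD
        delta = skew / np.sqrt(1.0 + skew**2)
        omega = sd / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
        xi = mean - omega * delta * np.sqrt(2.0 / np.pi)

        def draw(k: int) -> np.ndarray:
            return stats.skewnorm.rvs(skew, loc=xi, scale=omega, size=k, random_state=rng)

    out = np.empty(0)
    while out.size < n:
        cand = draw(max(n, 2 * (n - out.size)))
        out = np.concatenate([out, cand[(cand >= lo) & (cand <= hi)]])
    return out[:n]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a cohort of Fisher-z connectivity matrices plus scores.

    Each planted positive edge has weight
    ``baseline + noise_sd * (e * s + sqrt(1 - e^2) * eps)`` where ``s`` is the
    standardized score, ``eps`` standard normal, and ``e = effect_size``;
    the population edge-score correlation is therefore exactly ``e``
    (``-e`` for negative edges). All other edges are score-independent
    noise. Matrices are symmetric with zero diagonal.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects + 1)
    scores = simulate_behavior(
        cfg.n_subjects, cfg.score_mean, cfg.score_sd, cfg.score_min, cfg.score_max,
        seed=children[0], skew=cfg.score_skew,
    )
    s_std = _standardize(scores)

    iu, ju = np.triu_indices(cfg.n_nodes, k=1)
    edge_pos = {e: k for k, e in enumerate(zip(iu.tolist(), ju.tolist()))}
    planted = [(edge_pos[e], +1.0) for e in cfg.planted_positive_edges]
    planted += [(edge_pos[e], -1.0) for e in cfg.planted_negative_edges]

    e = cfg.effect_size
    resid = np.sqrt(1.0 - e**2)
    n_edges = iu.size
    subjects = []
    for idx in range(cfg.n_subjects):
        rng = np.random.default_rng(children[idx + 1])
        w = cfg.edge_baseline + cfg.noise_sd * rng.standard_normal(n_edges)
        for k, sign in planted:
            eps = rng.standard_normal()
            w[k] = cfg.edge_baseline + cfg.noise_sd * (sign * e * s_std[idx] + resid * eps)
        z = np.zeros((cfg.n_nodes, cfg.n_nodes))
        z[iu, ju] = w
        z += z.T
        subjects.append(ConnectivityMatrix(subject_id=f"sub-{idx + 1:04d}", z=z))

    labels = None
    if cfg.label_score_cutoff is not None:
        labels = (scores >= cfg.label_score_cutoff).astype(int)
    return Cohort(subjects=subjects, scores=scores, labels=labels)


def simulate_timeseries_cohort(
    config: SimulationConfig,
) -> tuple[list[TimeSeries], np.ndarray]:
    """Simulate node time courses whose planted-pair coupling tracks the score.

    For each planted pair the two node signals share a latent source with a
    score-scaled mixing weight: the subject-level target correlation is
    ``r0 + gain * effect_size * s`` (clipped to +/-0.95) around the baseline
    ``r0 = tanh(edge_baseline)``, so after ``connectivity()`` the edge's
    Fisher-z weight correlates with the score across subjects. A synthetic
    framewise-displacement trace carries ``fd_spike_fraction`` of volumes
    above the 0.5 mm scrubbing threshold.
    """
    cfg = config
    if cfg.n_timepoints < 20:
        raise InvalidParameterError("n_timepoints must be >= 20")
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects + 1)
    scores = simulate_behavior(
        cfg.n_subjects, cfg.score_mean, cfg.score_sd, cfg.score_min, cfg.score_max,
        seed=children[0], skew=cfg.score_skew,
    )
    s_std = _standardize(scores)

    r0 = float(np.tanh(cfg.edge_baseline))
    gain = 0.25  # score units of r per SD of score at effect_size = 1
    planted = [(e, +1.0) for e in cfg.planted_positive_edges]
    planted += [(e, -1.0) for e in cfg.planted_negative_edges]

    out = []
    for idx in range(cfg.n_subjects):
        rng = np.random.default_rng(children[idx + 1])
        data = rng.standard_normal((cfg.n_timepoints, cfg.n_nodes))
        for (i, j), sign in planted:
            target_r = np.clip(r0 + sign * gain * cfg.effect_size * s_std[idx], -0.95, 0.95)
            xi = _standardize(data[:, i])
            data[:, j] = target_r * xi + np.sqrt(1.0 - target_r**2) * rng.standard_normal(cfg.n_timepoints)
        fd = np.abs(rng.normal(0.08, 0.04, size=cfg.n_timepoints))
        if cfg.fd_spike_fraction > 0:
            n_spikes = int(round(cfg.fd_spike_fraction * cfg.n_timepoints))
            spike_at = rng.choice(np.arange(1, cfg.n_timepoints), size=n_spikes, replace=False)
            fd[spike_at] = rng.uniform(0.6, 1.2, size=n_spikes)
        fd[0] = 0.0
        out.append(
            TimeSeries(
                subject_id=f"sub-{idx + 1:04d}",
                data=data,
                tr=2.0,
                fd=fd,
                rotation_max=float(rng.uniform(0.0, 1.0)),
                translation_max=float(rng.uniform(0.0, 1.0)),
            )
        )
    return out, scores


# Macroscale-region node counts for the 268-node parcellation.
DEFAULT_REGION_COUNTS: dict[str, int] = {
    "prefrontal": 46,
    "cerebellum": 41,
    "temporal": 39,
    "limbic": 36,
    "parietal": 27,
    "occipital": 25,
    "motor": 21,
    "subcortical": 17,
    "brainstem": 9,
    "insula": 7,
}

# Eight canonical functional networks; counts here are a synthetic even
# split (the true node->network map is not published as text).
DEFAULT_NETWORK_NAMES = [
    "medial frontal",
    "frontoparietal",
    "default mode",
    "subcortical-cerebellum",
    "motor",
    "visual I",
    "visual II",
    "visual association",
]


def default_network_counts(n_nodes: int = 268) -> dict[str, int]:
    """Near-even synthetic split of ``n_nodes`` across the 8 canonical networks."""
    base, extra = divmod(n_nodes, len(DEFAULT_NETWORK_NAMES))
    return {
        name: base + (1 if k < extra else 0)
        for k, name in enumerate(DEFAULT_NETWORK_NAMES)
    }


def make_atlas(
    region_counts: dict[str, int] | None = None,
    network_counts: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> NodeAtlas:
    """Build a synthetic block-assignment atlas from label->count maps.

    Nodes 1..N are assigned deterministically in blocks: the first
    ``region_counts[first_label]`` nodes get the first region label, and so
    on; network labels are blocked independently the same way. This is a
    synthetic stand-in for a real parcellation's lookup table (the shipped
    defaults reproduce the 10 macroscale-region node counts of the 268-node
    atlas; the true node-level assignment is not public as text).
    Coordinates, if generated, are placeholder draws, not MNI anatomy.
    """
    if region_counts is None:
        region_counts = DEFAULT_REGION_COUNTS
    n_total = sum(region_counts.values())
    if network_counts is None:
        network_counts = default_network_counts(n_total)
    if sum(network_counts.values()) != n_total:
        raise InvalidParameterError(
            f"region counts sum to {n_total} but network counts sum to {sum(network_counts.values())}"
        )
    regions = np.repeat(list(region_counts.keys()), list(region_counts.values()))
    networks = np.repeat(list(network_counts.keys()), list(network_counts.values()))
    if rng is None:
        coords = np.zeros((n_total, 3))
    else:
        coords = rng.uniform(-70, 70, size=(n_total, 3))
    table = pd.DataFrame(
        {
            "node_id": np.arange(1, n_total + 1),
            "region": regions,
            "network": networks,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    return NodeAtlas(table=table)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd
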
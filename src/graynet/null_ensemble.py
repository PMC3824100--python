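"""Degree-matched random-graph null ensembles.

Each replicate is a double-edge-swap randomization of the observed graph
(same node count, same degree sequence, same edge count), on which a
metric curve — module count or gray-node proportion over a threshold
sweep — is evaluated.  The ensemble summary carries the per-threshold
Monte-Carlo mean and 1-sigma band used for observed-vs-null comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError
from .graph_core import Graph
from .gray_nodes import gray_proportion_curve
from .spectral_modularity import OptimizerSettings, module_count_curve

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsembleSummary",
    "rewire_degree_preserving",
    "configuration_model_null",
    "ensemble_curves",
    "compare_to_null",
    "METRICS",
]


@dataclass(frozen=True)
class NullEnsembleSummary:
    metric_name: str
    thresholds: tuple
    mean: np.ndarray
    sd: np.ndarray
    reps: int
    seed: int
    skewness: np.ndarray | None = None

    def __post_init__(self):
        if self.reps < 1:
            raise InputError("reps must be >= 1")
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (len(self.thresholds),) or sd.shape != mean.shape:
            raise InputError("summary arrays must align with thresholds")
        if np.any(sd < 0):
            raise InputError("sd must be non-negative")


def rewire_degree_preserving(g: Graph, swaps_per_edge: int = 10, seed: int = 0) -> Graph:
    """Randomize ``g`` by double edge swaps, preserving every degree.

    A swap picks two disjoint edges (u,v), (x,y) and rewires them to
    (u,x), (v,y); swaps that would create a self-loop or duplicate edge
    are rejected and resampled.  Attempts (not successes) are counted,
    capped at ``100 * m``, so saturated graphs such as K4 come back
    unchanged.  Graphs with fewer than 2 edges are returned as-is with a
    warning.
    """
    if g.m < 2:
        logger.warning("graph has %d edge(s); returning it unchanged", g.m)
        return g
    rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed))))
    A = np.array(g.A, dtype=np.int8)
    edges = np.array(g.edges(), dtype=np.int64)
    m = len(edges)
    target = swaps_per_edge * m
    max_attempts = 100 * m
    done = attempts = 0
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed rewire: (u,v),(x,y) -> (u,x),(v,y)
        if u == x or u == y or v == x or v == y:
            continue
        if A[u, x] or A[v, y]:
            continue
        A[u, v] = A[v, u] = 0
        A[x, y] = A[y, x] = 0
        A[u, x] = A[x, u] = 1
        A[v, y] = A[y, v] = 1
        edges[e1] = (u, x) if u < x else (x, u)
        edges[e2] = (v, y) if v < y else (y, v)
        done += 1
    if done < target:
        logger.warning(
            "rewiring stopped after %d/%d swaps (%d attempts)", done, target, attempts
        )
    return Graph(g.node_labels, A)


def configuration_model_null(g: Graph, seed: int = 0, max_tries: int = 1000) -> Graph:
    """Stub-matching alternative null: resample until the pairing is simple."""
    rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed))))
    stubs = np.repeat(np.arange(g.n), g.k)
    for _ in range(max_tries):
        perm = rng.permutation(stubs)
        u, v = perm[0::2], perm[1::2]
        if np.any(u == v):
            continue
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        pairs = lo * g.n + hi
        if len(np.unique(pairs)) != len(pairs):
            continue
        A = np.zeros((g.n, g.n), dtype=np.int8)
        A[lo, hi] = A[hi, lo] = 1
        return Graph(g.node_labels, A)
    logger.warning("configuration model failed to produce a simple graph; rewiring instead")
    return rewire_degree_preserving(g, seed=seed)


def _module_count_metric(g, thresholds, opt, seed):
    return [float(c) for c in module_count_curve(g, thresholds, opt=opt, seed=seed)]


def _gray_proportion_metric(g, thresholds, opt, seed):
    return [p for p, _ in gray_proportion_curve(g, thresholds, opt=opt, seed=seed)]


METRICS = {
    "module_count": _module_count_metric,
    "gray_proportion": _gray_proportion_metric,
}


def _child_seed(master: int, rep: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=(abs(int(master)), rep, stream))
    return int(ss.generate_state(1)[0])


def ensemble_curves(
    g: Graph,
    metric: str,
    thresholds,
    reps: int = 1000,
    seed: int = 0,
    opt: OptimizerSettings = OptimizerSettings(),
    swaps_per_edge: int = 10,
    null_model: str = "rewire",
) -> NullEnsembleSummary:
    """Per-threshold mean/sd of ``metric`` over degree-matched replicates.

    Child seeds are derived from ``(seed, replicate index)``, so the whole
    ensemble is reproducible and replicates are independent.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if null_model not in ("rewire", "configuration"):
        raise InputError("null_model must be 'rewire' or 'configuration'")
    fn = METRICS[metric]
    thresholds = tuple(float(t) for t in thresholds)
    curves = np.empty((reps, len(thresholds)))
    for rep in range(reps):
        if null_model == "rewire":
            null_g = rewire_degree_preserving(g, swaps_per_edge, seed=_child_seed(seed, rep, 1))
        else:
            null_g = configuration_model_null(g, seed=_child_seed(seed, rep, 1))
        curves[rep] = fn(null_g, thresholds, opt, _child_seed(seed, rep, 2))
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0)  # population sd: a single replicate has sd 0
    if reps >= 3:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-constant replicates
            skew = stats.skew(curves, axis=0)
    else:
        skew = None
    return NullEnsembleSummary(metric, thresholds, mean, sd, reps, seed, skew)


def compare_to_null(observed_curve, summary: NullEnsembleSummary):
    """Per-threshold z-scores of an observed curve against the null band.

    Where sd = 0 the z-score is undefined; the flag records whether the
    observed value at least matches the degenerate null exactly.
    """
    observed = np.asarray(observed_curve, dtype=float)
    if observed.shape != (len(summary.thresholds),):
        raise InputError("observed curve is not aligned with the null thresholds")
    records = []
    for i, tau in enumerate(summary.thresholds):
        sd = summary.sd[i]
        mean = summary.mean[i]
        if sd > 0:
            z = (observed[i] - mean) / sd
            flag = "inside_1sd" if abs(z) <= 1 else "outside_1sd"
        else:
            z = np.nan
            flag = "equal_degenerate" if observed[i] == mean else "diff_degenerate"
        records.append(
            {
                "threshold": tau,
                "observed": observed[i],
                "null_mean": mean,
                "null_sd": sd,
                "z": z,
                "flag": flag,
            }
        )
    return records
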
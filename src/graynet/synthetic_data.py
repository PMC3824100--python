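"""Seeded generators: toy graphs with known structure, synthetic cohorts.

Stands in for the (undeposited) study data: a two-group cohort of
thickness tables with block-structured interregional covariance, additive
age and global-scale effects, and a tunable group difference in
covariance strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .covariance_network import ThicknessTable
from .graph_core import Graph, from_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "planted_module_graph",
    "shared_node_modules",
    "random_graph",
    "random_connected_graph",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic two-group thickness cohort.

    Block covariance is induced by one latent factor per block (loading
    sqrt(rho_in - rho_out)) plus a global factor (loading sqrt(rho_out)),
    which guarantees a valid covariance without building a matrix.  Group
    B's block loadings are multiplied by ``group_covariance_scale``.
    """

    n_subjects: int = 21
    regions: tuple = ()
    blocks: tuple = ()  # tuple of tuples of region indices
    rho_in: float = 0.8
    rho_out: float = 0.1
    age_slope: float = 0.0  # mm per year, same for every region unless per-region below
    age_slopes: tuple | None = None  # optional per-region slopes
    group_covariance_scale: float = 1.0
    group_mean_shift: float = 0.0  # optional mm offset for group B
    noise_sd: float = 0.1
    baseline_mean: float = 2.5  # mm, typical cortical thickness
    age_range: tuple = (35.0, 64.0)
    seed: int = 0

    def __post_init__(self):
        if not self.regions:
            object.__setattr__(self, "regions", tuple(f"region_{i:02d}" for i in range(68)))
        object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))
        object.__setattr__(self, "blocks", tuple(tuple(int(i) for i in b) for b in self.blocks))
        if not (self.rho_out < self.rho_in <= 1):
            raise InputError("need rho_out < rho_in <= 1")
        if self.rho_out < 0:
            raise InputError("rho_out must be >= 0")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be > 0")
        if self.n_subjects < 3:
            raise InputError("need at least 3 subjects per group")
        seen: set = set()
        for b in self.blocks:
            if seen & set(b):
                raise InputError("blocks must be disjoint")
            seen |= set(b)
        if seen and max(seen) >= len(self.regions):
            raise InputError("block indices out of range")


def planted_module_graph(sizes, p_in: float, p_out: float, seed: int = 0):
    """Stochastic block graph with known ground-truth modules.

    Returns ``(Graph, modules)`` where ``modules`` are the planted
    node-index sets.  Deterministic given ``seed``.
    """
    if not 0 <= p_out <= p_in <= 1:
        raise InputError("need 0 <= p_out <= p_in <= 1")
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise InputError("block sizes must be >= 1")
    n = sum(sizes)
    block = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed))))
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(block[iu] == block[ju], p_in, p_out)
    hit = rng.random(len(prob)) < prob
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[hit], ju[hit]] = 1
    A += A.T
    bounds = np.cumsum([0] + sizes)
    modules = [set(range(bounds[i], bounds[i + 1])) for i in range(len(sizes))]
    return from_adjacency(A), modules


def shared_node_modules(k_modules: int, module_size: int, n_shared: int, bridge: bool = False):
    """Chain of complete modules, adjacent ones sharing ``n_shared`` nodes.

    With ``n_shared = 0`` and ``bridge=True``, consecutive modules are
    instead joined by a single edge (the resource-hungrier alternative to
    node sharing).  Returns ``(Graph, modules)``.
    """
    if k_modules < 1:
        raise InputError("need at least one module")
    if not 0 <= n_shared < module_size:
        raise InputError("need 0 <= n_shared < module_size")
    if bridge and n_shared:
        raise InputError("bridge edges only apply to non-sharing chains")
    step = module_size - n_shared
    n = module_size + (k_modules - 1) * step
    A = np.zeros((n, n), dtype=np.int8)
    modules = []
    for mod in range(k_modules):
        lo = mod * step
        members = list(range(lo, lo + module_size))
        modules.append(set(members))
        for a in members:
            for b in members:
                if a != b:
                    A[a, b] = 1
    if bridge:
        for mod in range(k_modules - 1):
            a = mod * step + module_size - 1
            b = (mod + 1) * step
            A[a, b] = A[b, a] = 1
    return from_adjacency(A), modules


def random_graph(n: int, p: float, seed: int = 0) -> Graph:
    """Erdos-Renyi G(n, p), deterministic given seed."""
    g, _ = planted_module_graph([n], p, p, seed=seed)
    return g


def random_connected_graph(n: int, p: float, seed: int = 0, max_tries: int = 1000) -> Graph:
    """Erdos-Renyi graph resampled until connected, then patched if needed.

    After ``max_tries`` rejections the components are chained together
    with single edges (keeps determinism for sparse settings).
    """
    from .graph_core import connected_components

    for t in range(max_tries):
        g = random_graph(n, p, seed=abs(int(seed)) * 1_000_003 + t)
        comps = connected_components(g)
        if len(comps) == 1:
            return g
    A = np.array(g.A)
    comps = connected_components(g)
    for a, b in zip(comps, comps[1:]):
        i, j = min(a), min(b)
        A[i, j] = A[j, i] = 1
    return Graph(g.node_labels, A)


def _simulate_group(spec: CohortSpec, rng, block_scale: float, mean_shift: float):
    n_sub, n_reg = spec.n_subjects, len(spec.regions)
    ages = rng.uniform(*spec.age_range, size=n_sub)
    global_f = rng.standard_normal(n_sub)
    block_f = rng.standard_normal((n_sub, len(spec.blocks)))
    noise = rng.standard_normal((n_sub, n_reg))
    z = np.sqrt(spec.rho_out) * global_f[:, None] + np.sqrt(1.0 - spec.rho_in) * noise
    in_block = np.zeros(n_reg, dtype=bool)
    for b, members in enumerate(spec.blocks):
        idx = list(members)
        in_block[idx] = True
        z[:, idx] += block_scale * np.sqrt(spec.rho_in - spec.rho_out) * block_f[:, [b]]
    # top up non-block regions with independent noise so every region has
    # unit latent variance and cross-correlation exactly rho_out
    free = np.flatnonzero(~in_block)
    if free.size:
        z[:, free] += np.sqrt(spec.rho_in - spec.rho_out) * rng.standard_normal(
            (n_sub, free.size)
        )
    slopes = (
        np.asarray(spec.age_slopes, dtype=float)
        if spec.age_slopes is not None
        else np.full(n_reg, spec.age_slope)
    )
    values = spec.baseline_mean + mean_shift + slopes[None, :] * ages[:, None] + spec.noise_sd * z
    return values, ages


def generate_cohort(spec: CohortSpec):
    """Two seeded :class:`ThicknessTable` groups plus the ground truth.

    thickness = baseline + slope*age + noise_sd * (latent factors + noise);
    group B's block loadings are scaled by ``group_covariance_scale`` and
    its means shifted by ``group_mean_shift``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(abs(int(spec.seed))))
    values_a, ages_a = _simulate_group(spec, rng, 1.0, 0.0)
    values_b, ages_b = _simulate_group(
        spec, rng, spec.group_covariance_scale, spec.group_mean_shift
    )
    def table(tag, values, ages):
        subjects = tuple(f"{tag}{i:03d}" for i in range(spec.n_subjects))
        return ThicknessTable(subjects, spec.regions, values, pd.DataFrame({"age": ages}))
    truth = {
        "blocks": [sorted(b) for b in spec.blocks],
        "rho_in": spec.rho_in,
        "rho_out": spec.rho_out,
        "group_covariance_scale": spec.group_covariance_scale,
        "seed": spec.seed,
    }
    return table("A", values_a, ages_a), table("B", values_b, ages_b), truth
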
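"""From thickness tables to binary covariance networks.

Pipeline: residualize each region on nuisance covariates, correlate
regions across subjects, discard non-positive correlations, FDR-threshold
the remainder and binarize.  Also provides the correlation-threshold
sweep (edge count / density / sparsity / isolated-group count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .graph_core import Graph, connected_components, from_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "ThicknessTable",
    "CorrelationMatrix",
    "MEAN_THICKNESS_COVARIATE",
    "residualize",
    "pearson_matrix",
    "fdr_binarize",
    "threshold_sweep",
]

#: covariate name derived on demand: each subject's unweighted mean across regions
MEAN_THICKNESS_COVARIATE = "mean_overall_thickness"


@dataclass(frozen=True)
class ThicknessTable:
    """Subjects x regions morphometry with per-subject covariates."""

    subjects: tuple
    regions: tuple
    values: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        subjects = tuple(str(s) for s in self.subjects)
        regions = tuple(str(r) for r in self.regions)
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "regions", regions)
        if len(set(regions)) != len(regions):
            raise InputError("region labels must be unique")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(subjects), len(regions)):
            raise InputError(
                f"values shape {values.shape} does not match "
                f"{len(subjects)} subjects x {len(regions)} regions"
            )
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            cells = ", ".join(f"({subjects[i]}, {regions[j]})" for i, j in bad[:10])
            raise InputError(f"missing/non-finite values at: {cells}")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        cov = self.covariates
        if cov is not None:
            cov = pd.DataFrame(cov)
            if len(cov) != len(subjects):
                raise InputError("covariate table length does not match subject count")
            if not np.isfinite(cov.to_numpy(dtype=float)).all():
                raise InputError("covariates contain missing/non-finite values")
            object.__setattr__(self, "covariates", cov.reset_index(drop=True))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def covariate_names(self):
        return [] if self.covariates is None else list(self.covariates.columns)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric region x region Pearson r with the sample size used."""

    regions: tuple
    R: np.ndarray
    n_subjects: int

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.regions),) * 2:
            raise InputError("correlation matrix shape does not match region labels")
        if not np.allclose(R, R.T, atol=1e-12):
            raise InputError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(R)) > 1 + 1e-9:
            raise InputError("correlation entries must lie in [-1, 1]")
        R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
        R.setflags(write=False)
        object.__setattr__(self, "R", R)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _covariate_matrix(t: ThicknessTable, covariate_names):
    cols = []
    for name in covariate_names:
        if name == MEAN_THICKNESS_COVARIATE and (
            t.covariates is None or name not in t.covariates.columns
        ):
            cols.append(t.values.mean(axis=1))
        elif t.covariates is not None and name in t.covariates.columns:
            cols.append(t.covariates[name].to_numpy(dtype=float))
        else:
            raise InputError(f"covariate {name!r} not present and not derivable")
    return np.column_stack(cols) if cols else np.empty((t.n_subjects, 0))


def residualize(t: ThicknessTable, covariate_names) -> ThicknessTable:
    """Replace each region's values by OLS residuals on the named covariates.

    The design always includes an intercept, so residuals sum to zero per
    region and are orthogonal to every covariate column.  The covariate
    ``"mean_overall_thickness"`` is derived from the raw table (each
    subject's mean across all regions) when not supplied explicitly.
    """
    covariate_names = list(covariate_names)
    C = _covariate_matrix(t, covariate_names)
    if t.n_subjects <= C.shape[1] + 1:
        raise InputError(
            f"need more than {C.shape[1] + 1} subjects to fit {C.shape[1]} covariates"
        )
    X = np.column_stack([np.ones(t.n_subjects), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for j, name in enumerate(covariate_names):
            others = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(name)
        raise InputError(f"rank-deficient covariate matrix; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, t.values, rcond=None)
    residuals = t.values - X @ beta
    return ThicknessTable(t.subjects, t.regions, residuals, t.covariates)


def pearson_matrix(t: ThicknessTable) -> CorrelationMatrix:
    """Pearson correlation of every region pair across subjects."""
    if t.n_subjects < 3:
        raise InputError("need at least 3 subjects to correlate")
    sd = t.values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [t.regions[i] for i in zero]
        raise InputError(f"zero-variance region(s): {names}")
    R = np.corrcoef(t.values, rowvar=False)
    return CorrelationMatrix(t.regions, R, t.n_subjects)


def correlation_pvalues(c: CorrelationMatrix) -> np.ndarray:
    """One-sided (upper-tail) p-values from the r-to-t transform.

    ``t = r sqrt(df / (1 - r^2))`` with ``df = n_subjects - 2``; |r| = 1
    maps to p = 0.  Returned as a full matrix aligned with ``c.R``.
    """
    df = c.n_subjects - 2
    r = c.R.copy()
    np.fill_diagonal(r, 0.0)
    r[np.abs(r) > 1.0 - 1e-14] = np.sign(r[np.abs(r) > 1.0 - 1e-14])  # snap float noise
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
    p = stats.t.sf(tstat, df)
    p[np.abs(r) >= 1.0] = np.where(r[np.abs(r) >= 1.0] > 0, 0.0, 1.0)
    return p


def fdr_binarize(c: CorrelationMatrix, q: float = 0.2, variant: str = "fdr_bh") -> Graph:
    """Binary graph of FDR-significant positive correlations.

    Negative and zero correlations are discarded first; the remaining
    upper-triangle entries get one-sided p-values and a Benjamini-Hochberg
    (or, optionally, Benjamini-Yekutieli) step-up correction at level
    ``q``.  Surviving pairs become edges.
    """
    if not 0 < q < 1:
        raise InputError("q must be in (0, 1)")
    if c.n_subjects < 4:
        raise InputError("need at least 4 subjects for the FDR step")
    if variant not in ("fdr_bh", "fdr_by"):
        raise InputError("fdr variant must be 'fdr_bh' or 'fdr_by'")
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    r = c.R[iu, ju]
    positive = r > 0
    A = np.zeros((n, n), dtype=np.int8)
    if positive.any():
        p = correlation_pvalues(c)[iu, ju][positive]
        reject, *_ = multipletests(p, alpha=q, method=variant)
        ei, ej = iu[positive][reject], ju[positive][reject]
        A[ei, ej] = A[ej, ei] = 1
        if reject.any():
            logger.info(
                "FDR q=%.3g: %d/%d positive pairs significant (max p kept %.3g)",
                q, int(reject.sum()), int(positive.sum()), float(p[reject].max()),
            )
    return from_adjacency(A, c.regions)


def threshold_sweep(c: CorrelationMatrix, thresholds):
    """Edge/density/component records for graphs with an edge iff r > threshold.

    Thresholds must be ascending fractions in (0, 1); negatives are
    automatically excluded by the strict '>' rule.  Both all-component and
    non-singleton component counts are reported because the isolated-group
    convention for singletons is ambiguous.
    """
    thresholds = [float(t) for t in thresholds]
    if thresholds != sorted(thresholds):
        raise InputError("thresholds must be sorted ascending")
    if any(not 0 < t < 1 for t in thresholds):
        raise InputError("thresholds must lie in (0, 1)")
    n = c.n_regions
    possible = n * (n - 1) // 2
    records = []
    for tau in thresholds:
        A = (c.R > tau).astype(np.int8)
        np.fill_diagonal(A, 0)
        g = from_adjacency(A, c.regions)
        comps = connected_components(g)
        records.append(
            {
                "threshold": tau,
                "edges": g.m,
                "density": g.m / possible,
                "sparsity": 1.0 - g.m / possible,
                "isolated_groups": len(comps),
                "components_all": len(comps),
                "components_nonsingleton": sum(1 for s in comps if len(s) > 1),
            }
        )
    return records
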
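"""Population-structure analysis: correlations, PCA, directions, alignment.

The decomposition at the heart of the package: a degenerate population's
conductance variability splits into (i) homogeneous scaling -- points
spread along the ray from the origin through the population's center of
mass, captured by the dominant principal component and by input-resistance
differences -- and (ii) degenerate conductance ratios along DIC
zero-sensitivity directions, captured by the secondary PCs.  Normalising
every neuron by its input resistance removes (i) and exposes (ii).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .populations import Population
from .simulate import input_conductance

__all__ = [
    "PCAResult",
    "DirectionVector",
    "pairwise_correlations",
    "correlation_graph",
    "pca",
    "homogeneous_scaling_direction",
    "alignment",
    "normalize_by_rin",
    "tls_regression",
]


@dataclass
class DirectionVector:
    """A unit direction in conductance space (or a 2D subspace of it)."""

    vector: np.ndarray
    description: str = ""
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        n = np.linalg.norm(self.vector)
        if n == 0 or not np.isfinite(n):
            raise ValueError("direction vector must be nonzero and finite")
        self.vector = self.vector / n


def pairwise_correlations(pop: Population) -> pd.DataFrame:
    """Pearson r between all conductance pairs (NaN where undefined).

    Zero-variance columns give undefined correlations; they are reported
    as NaN and excluded from correlation graphs, never imputed.
    """
    if len(pop) < 3:
        raise ValueError("need at least 3 members for correlations")
    X = pop.matrix
    names = pop.model.channel_names
    sd = X.std(axis=0)
    r = np.full((len(names), len(names)), np.nan)
    ok = sd > 0
    if np.any(ok):
        sub = np.corrcoef(X[:, ok], rowvar=False)
        r[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(r, index=names, columns=names)


def correlation_graph(pop: Population, threshold: float | None = None) -> nx.Graph:
    """Correlation graph: nodes = conductances, edges where |r| >= threshold.

    The default threshold is 1/N, the inverse of the number of
    conductances in the model.  Edge attributes: ``r``, ``sign`` (+1/-1)
    and ``weight`` = |r| (for line-thickness styling).
    """
    thr = 1.0 / pop.model.N if threshold is None else float(threshold)
    R = pairwise_correlations(pop)
    G = nx.Graph(threshold=thr, model=pop.model.name)
    G.add_nodes_from(R.columns)
    for i, a in enumerate(R.columns):
        for b in R.columns[i + 1 :]:
            r = R.loc[a, b]
            if np.isnan(r) or abs(r) < thr:
                continue
            G.add_edge(a, b, r=float(r), sign=1 if r >= 0 else -1, weight=abs(float(r)))
    return G


@dataclass
class PCAResult:
    """Variance fractions and orthonormal loadings of a population.

    ``loadings`` live in the (possibly standardised) variable space the
    PCA was run in; ``scale`` records the per-channel standard deviations
    used for standardisation (ones when unstandardised), so directions can
    be mapped back to conductance units via :meth:`component_raw`.
    """

    variance_fraction: np.ndarray  # non-increasing, sums to 1
    loadings: np.ndarray  # n_components x N, rows orthonormal
    mean: np.ndarray  # centering vector (zeros when uncentered)
    scale: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_names: list[str] = field(default_factory=list)

    def component(self, k: int) -> DirectionVector:
        return DirectionVector(self.loadings[k], description=f"PC{k + 1}",
                               channel_names=self.channel_names)

    def component_raw(self, k: int) -> DirectionVector:
        """PC direction mapped back to conductance units (mS/cm^2)."""
        v = self.loadings[k] * (self.scale if self.scale.size else 1.0)
        return DirectionVector(v, description=f"PC{k + 1} (raw units)",
                               channel_names=self.channel_names)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    # deterministic sign: the largest-|entry| component is positive
    out = loadings.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def pca(pop: Population, center: bool = True, standardize: bool = True) -> PCAResult:
    """PCA of the population's conductance matrix.

    Centered and standardised (correlation-matrix PCA) by default: the
    models span four decades of conductance magnitude between channels, so
    unstandardised covariance PCA degenerates to the single largest-range
    channel.  Both switches are exposed.  Requires more members than
    conductances.
    """
    X = pop.matrix
    n, N = X.shape
    if n <= N:
        raise ValueError(f"PCA needs n > N (got n={n}, N={N})")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance channel; cannot standardise")
    else:
        sd = np.ones(N)
    Xs = X / sd
    if center:
        sk = _SKPCA(n_components=N, svd_solver="full")
        sk.fit(Xs)
        return PCAResult(
            variance_fraction=sk.explained_variance_ratio_.copy(),
            loadings=_fix_signs(sk.components_),
            mean=sk.mean_.copy() * sd,
            scale=sd,
            channel_names=pop.model.channel_names,
        )
    # uncentered: SVD of the raw matrix (second-moment decomposition)
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    return PCAResult(
        variance_fraction=frac,
        loadings=_fix_signs(Vt),
        mean=np.zeros(N),
        scale=sd,
        channel_names=pop.model.channel_names,
    )


def homogeneous_scaling_direction(
    pop: Population, in_scale_of: PCAResult | None = None
) -> DirectionVector:
    """Unit vector from the conductance-space origin to the center of mass.

    Equals the total-least-squares regression direction without intercept
    for a population spread along a ray through the origin.  Pass a
    :class:`PCAResult` via ``in_scale_of`` to express the direction in
    that PCA's (standardised) variable space, so it can be compared with
    the PCA's loadings by a plain dot product.
    """
    mu = pop.matrix.mean(axis=0)
    if in_scale_of is not None and in_scale_of.scale.size:
        mu = mu / in_scale_of.scale
    if np.linalg.norm(mu) == 0:
        raise ValueError("population mean is zero; direction undefined")
    return DirectionVector(mu, description="homogeneous-scaling",
                           channel_names=pop.model.channel_names)


def alignment(u: DirectionVector | np.ndarray, v: DirectionVector | np.ndarray) -> float:
    """|u . v| for unit vectors: 1 = parallel, 0 = orthogonal.

    Sign-invariant because PC loadings have arbitrary sign.
    """
    a = u.vector if isinstance(u, DirectionVector) else np.asarray(u, float)
    b = v.vector if isinstance(v, DirectionVector) else np.asarray(v, float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    return float(abs(a @ b))


def normalize_by_rin(pop: Population, V_ref: float = -70.0) -> Population:
    """Multiply each member's conductances by its own input resistance.

    The result is dimensionless and free of homogeneous-scaling
    variability (a scaled neuron has proportionally lower R_in).  Members
    with non-positive input conductance at V_ref (unstable reference
    point) are excluded and recorded in provenance.
    """
    rows, kept, excluded = [], [], []
    for i, g in enumerate(pop):
        try:
            gin = input_conductance(pop.model, g, V_ref)
        except ValueError:
            excluded.append(i)
            continue
        rows.append(g.values / gin)
        kept.append(i)
    if not rows:
        raise ValueError("no member has a stable reference point at V_ref")
    return Population(
        pop.model,
        np.array(rows),
        provenance={
            **pop.provenance,
            "normalized_by_rin": True,
            "V_ref": V_ref,
            "source_indices": kept,
            "excluded_indices": excluded,
        },
    )


def tls_regression(
    pop: Population, pair: Sequence[str], through_origin: bool = False
) -> DirectionVector:
    """Total-least-squares direction of a conductance pair's scatter.

    The dominant right-singular direction of the (centered or raw) pair
    data: the line minimising orthogonal distances to the points.
    """
    X = pop.pair(pair)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 members")
    if not through_origin:
        X = X - X.mean(axis=0)
    if np.allclose(X, 0):
        raise ValueError("degenerate data: all points equal")
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    return DirectionVector(
        Vt[0],
        description=f"TLS[{pair[0]},{pair[1]}]"
        + (" through-origin" if through_origin else ""),
        channel_names=list(pair),
    )
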
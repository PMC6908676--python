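"""Similarity-sensitive diversity over the (a, delta, q) biodiversity space.

Diversity is computed in the Leinster-Cobbold framework: given relative
abundances p and a species similarity matrix Z (unit diagonal, entries in
[0, 1]), the order-q diversity is the effective number

    D_q(p, Z) = ( sum_i p_i (Zp)_i^(q-1) )^(1/(1-q)),   q not in {1, inf}

with the analytic limits D_1 = exp(-sum_i p_i ln (Zp)_i) and
D_inf = 1 / max_i (Zp)_i (maxima and sums over species with p_i > 0).
Z = identity recovers classical Hill numbers; q = 2 equals Rao* =
1/(1 - Q) with Q Rao's quadratic entropy under dissimilarity 1 - Z.

Similarity matrices are derived from trees: the delta-transformed
functional and phylogenetic cophenetic distances are each scaled to
maximum 1, blended as FPDist = (a FDist^2 + (1-a) PDist^2)^(1/2) with a
the trait weight, re-scaled, and converted by Z = 1 - scaled distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import DELTA_INF, pagel_delta_transform, tree_to_distance

__all__ = [
    "ParameterGrid",
    "combine_distances",
    "distance_to_similarity",
    "hill_diversity",
    "rao_star",
    "similarity_for",
    "diversity_grid",
]


@dataclass(frozen=True)
class ParameterGrid:
    """The (a, delta, q) coordinates at which diversity is evaluated.

    Defaults cover the full biodiversity space: six trait weights a, four
    similarity scales delta (including the taxonomic limit), six dominance
    weights q (including the Berger-Parker limit).
    """

    a_values: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    delta_values: tuple[float, ...] = (0.1, 1.0, 10.0, math.inf)
    q_values: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, math.inf)

    def __post_init__(self) -> None:
        if any(not (0.0 <= a <= 1.0) for a in self.a_values):
            raise ValueError("a values must lie in [0, 1]")
        if any(not (d > 0) for d in self.delta_values):
            raise ValueError("delta values must be > 0 (inf allowed)")
        if any(q < 0 for q in self.q_values):
            raise ValueError("q values must be >= 0 (inf allowed)")


def _check_labels(x: pd.DataFrame, y: pd.DataFrame) -> None:
    if list(x.index) != list(y.index) or list(x.columns) != list(y.columns):
        raise ValueError("distance matrices must share labels in the same order")


def combine_distances(pdist: pd.DataFrame, fdist: pd.DataFrame, a: float) -> pd.DataFrame:
    """Blend phylogenetic and functional distances with trait weight ``a``.

    FPDist = (a * FDist^2 + (1 - a) * PDist^2)^(1/2); a = 1 returns the
    functional distances, a = 0 the phylogenetic ones.  Both inputs are
    expected pre-scaled to maximum entry 1 so that ``a`` weighs comparable
    quantities.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"a must lie in [0, 1], got {a}")
    _check_labels(pdist, fdist)
    if a == 1.0:
        return fdist.copy()
    if a == 0.0:
        return pdist.copy()
    combined = np.sqrt(a * fdist.to_numpy() ** 2 + (1.0 - a) * pdist.to_numpy() ** 2)
    return pd.DataFrame(combined, index=pdist.index, columns=pdist.columns)


def distance_to_similarity(d: pd.DataFrame) -> pd.DataFrame:
    """Similarity Z = 1 - d / max(d), with an exactly-unit diagonal.

    A single-species matrix maps to the 1x1 identity.  A matrix whose
    off-diagonal entries are all equal (a rake tree) maps to the identity.
    """
    arr = d.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    if arr.shape[0] == 1:
        return pd.DataFrame([[1.0]], index=d.index, columns=d.columns)
    dmax = arr.max()
    z = 1.0 - arr / dmax if dmax > 0 else np.ones_like(arr)
    np.fill_diagonal(z, 1.0)
    return pd.DataFrame(z, index=d.index, columns=d.columns)


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    if abs(total - 1.0) > 1e-9:
        p = p / total
    return p


def hill_diversity(p: Sequence[float], z: np.ndarray | pd.DataFrame, q: float) -> float:
    """Order-q similarity-sensitive diversity (an effective species number).

    Species with p_i = 0 are excluded from the outer sum and from the max
    at q = inf; the similarity-weighted mean abundances (Zp)_i still sum
    over all species, where zero-abundance terms vanish anyway.
    """
    p = _validate_p(np.asarray(p, dtype=float))
    zarr = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    zp = zarr @ p
    support = p > 0
    ps, zps = p[support], zp[support]
    if math.isinf(q):
        return float(1.0 / zps.max())
    if q == 1.0:
        return float(np.exp(-np.sum(ps * np.log(zps))))
    return float(np.sum(ps * zps ** (q - 1.0)) ** (1.0 / (1.0 - q)))


def rao_star(p: Sequence[float], z: np.ndarray | pd.DataFrame) -> float:
    """Rao* = 1 / (1 - Q) with Q = sum_ij p_i p_j (1 - Z_ij).

    Algebraically identical to ``hill_diversity(p, z, q=2)``; kept as an
    independent route for cross-checking.
    """
    p = _validate_p(np.asarray(p, dtype=float))
    zarr = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    q_entropy = float(p @ (1.0 - zarr) @ p)
    return 1.0 / (1.0 - q_entropy)


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------

def similarity_for(
    ftree: dendropy.Tree,
    ptree: dendropy.Tree,
    a: float,
    delta: float,
) -> pd.DataFrame:
    """Species-pool similarity matrix at one (a, delta) coordinate.

    Both trees are delta-transformed, converted to cophenetic distances,
    each scaled to maximum 1, blended with trait weight ``a``, and
    converted to similarity.  Scaling happens at the pool level so
    diversity stays comparable across communities.
    """
    fdist = tree_to_distance(pagel_delta_transform(ftree, delta))
    pdist = tree_to_distance(pagel_delta_transform(ptree, delta))
    common = sorted(set(fdist.index) & set(pdist.index))
    fdist = fdist.loc[common, common]
    pdist = pdist.loc[common, common]
    for name, d in (("functional", fdist), ("phylogenetic", pdist)):
        m = d.to_numpy().max()
        if m > 0:
            d.iloc[:, :] = d.to_numpy() / m
    combined = combine_distances(pdist, fdist, a)
    return distance_to_similarity(combined)


def _diversity_columns(P: np.ndarray, Z: np.ndarray, q: float) -> np.ndarray:
    """Vectorized D_q over the columns of abundance matrix P (species x communities)."""
    ZP = Z @ P
    support = P > 0
    out = np.empty(P.shape[1])
    for j in range(P.shape[1]):
        s = support[:, j]
        ps, zps = P[s, j], ZP[s, j]
        if math.isinf(q):
            out[j] = 1.0 / zps.max()
        elif q == 1.0:
            out[j] = np.exp(-np.sum(ps * np.log(zps)))
        else:
            out[j] = np.sum(ps * zps ** (q - 1.0)) ** (1.0 / (1.0 - q))
    return out


def diversity_grid(
    communities: Sequence[pd.Series],
    ftree: dendropy.Tree,
    ptrees: Sequence[dendropy.Tree],
    grid: ParameterGrid = ParameterGrid(),
    community_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Evaluate diversity for every community at every (a, delta, q) point.

    ``communities`` holds per-community abundances indexed by species id
    (normalized internally).  Diversity is computed against each replicate
    phylogeny and averaged arithmetically over replicates; the returned
    tidy frame has columns (a, delta, q, community, D).
    """
    if community_ids is None:
        community_ids = list(range(len(communities)))
    if len(communities) == 0:
        return pd.DataFrame(columns=["a", "delta", "q", "community", "D"])

    rows = []
    for ptree in ptrees:
        for delta in grid.delta_values:
            cache: dict[float, pd.DataFrame] = {}
            for a in grid.a_values:
                zdf = similarity_for(ftree, ptree, a, delta)
                pool = list(zdf.index)
                pool_index = {sp: i for i, sp in enumerate(pool)}
                P = np.zeros((len(pool), len(communities)))
                for j, comm in enumerate(communities):
                    for sp, ab in comm.items():
                        if ab <= 0:
                            continue
                        if sp not in pool_index:
                            raise ValueError(f"species {sp!r} missing from the trees")
                        P[pool_index[sp], j] = ab
                P = P / P.sum(axis=0, keepdims=True)
                Z = zdf.to_numpy()
                for q in grid.q_values:
                    D = _diversity_columns(P, Z, q)
                    for cid, val in zip(community_ids, D):
                        rows.append((a, delta, q, cid, val))
    df = pd.DataFrame(rows, columns=["a", "delta", "q", "community", "D"])
    return (
        df.groupby(["a", "delta", "q", "community"], sort=False, as_index=False)["D"]
        .mean()
    )
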
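"""Census-based relatedness: generation-stratified migration matrices, their
composition, the coalescent census relatedness metric, and the
element-permutation Mantel test against genomic relatedness.

The model treats weighted census migration counts m_ij^(g) (region i -> j at
generation g, 30-year generations) as estimates of where the ancestors of
each region's residents lived.  Backward transition matrices P^(g) give the
probability that an ancestor of a resident of region j one generation later
was in region i; composing them over generations and weighting shared
ancestral regions by 1/N_k yields a symmetric relatedness metric comparable
to IBD-based relatedness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MigrationCounts",
    "TransitionMatrix",
    "CensusRelatedness",
    "MantelResult",
    "DEFAULT_GENERATION_MAP",
    "build_migration_counts",
    "transition_matrix",
    "compose_transitions",
    "census_relatedness",
    "mantel_element_test",
    "population_size_ratio",
]

#: Census years pooled into 30-year generations: 1900-1920 -> generation 3,
#: 1930-1950 -> 2, 1960-1980 -> 1 (generation time 30 years).
DEFAULT_GENERATION_MAP = {
    1900: 3, 1910: 3, 1920: 3,
    1930: 2, 1940: 2, 1950: 2,
    1960: 1, 1970: 1, 1980: 1,
}


@dataclass(frozen=True)
class MigrationCounts:
    """Weighted origin -> destination migration counts for one generation.

    ``m[i, j]`` is the weighted number of persons born in region i and
    residing in region j; ``m_out[j]`` counts inflow from outside the region
    set.  Optional ``populations`` holds region population sizes N_k.
    """

    generation: int
    regions: tuple
    m: np.ndarray
    m_out: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self):
        k = len(self.regions)
        if self.m.shape != (k, k):
            raise ValueError(f"migration matrix shape {self.m.shape} != ({k}, {k})")
        if self.m_out.shape != (k,):
            raise ValueError("external inflow vector length mismatch")
        if (self.m < 0).any() or (self.m_out < 0).any():
            raise ValueError("migration counts must be non-negative")
        if self.populations is not None and (self.populations <= 0).any():
            raise ValueError("region population sizes must be positive")


def build_migration_counts(
    records: pd.DataFrame,
    generation_map: dict | None = None,
    age_window=(20, 30),
    group=None,
    regions=None,
) -> dict:
    """Aggregate census microdata rows into per-generation migration counts.

    ``records`` needs columns ``year, age, group, region_birth,
    region_residence, weight``.  Rows outside the closed ``age_window`` or not
    matching ``group`` (when given) are ignored; rows with years absent from
    ``generation_map`` are skipped with a warning count.  Birthplaces outside
    the region list feed the external-inflow vector.

    Returns a dict ``generation -> MigrationCounts``.
    """
    if generation_map is None:
        generation_map = DEFAULT_GENERATION_MAP
    df = records.copy()
    lo, hi = age_window
    df = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if group is not None:
        df = df[df["group"] == group]

    mapped = df["year"].map(generation_map)
    n_skipped = int(mapped.isna().sum())
    if n_skipped:
        logger.warning(
            "%d census records with years outside the generation map skipped",
            n_skipped,
        )
    df = df[mapped.notna()]
    df = df.assign(generation=mapped[mapped.notna()].astype(int))

    if regions is None:
        regions = tuple(sorted(set(df["region_residence"])))
    else:
        regions = tuple(regions)
    r_index = {r: i for i, r in enumerate(regions)}
    generations = sorted(set(generation_map.values()))

    out = {}
    for g in generations:
        sub = df[df["generation"] == g]
        k = len(regions)
        m = np.zeros((k, k))
        m_out = np.zeros(k)
        for row in sub.itertuples(index=False):
            if row.region_residence not in r_index:
                continue
            j = r_index[row.region_residence]
            if row.region_birth in r_index:
                m[r_index[row.region_birth], j] += row.weight
            else:
                m_out[j] += row.weight
        counts = MigrationCounts(generation=g, regions=regions, m=m, m_out=m_out)
        object.__setattr__(counts, "n_skipped", n_skipped)
        out[g] = counts
    return out


@dataclass(frozen=True)
class TransitionMatrix:
    """Backward migration probabilities for one generation.

    ``P[i, j]`` is the probability that the ancestor of a region-j resident
    was in region i one generation earlier; columns index destination.
    Column sums fall short of 1 by the external-origin probability.
    """

    generation: int
    regions: tuple
    P: np.ndarray

    def __post_init__(self):
        if ((self.P < -1e-12) | (self.P > 1 + 1e-12)).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if (self.P.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("transition matrix column sums exceed 1")


def transition_matrix(counts: MigrationCounts) -> TransitionMatrix:
    """Column-normalise migration counts into backward ancestry probabilities:
    P_ij = m_ij / (sum_i' m_i'j + m_out_j)."""
    inbound = counts.m.sum(axis=0) + counts.m_out
    zero = inbound <= 0
    if zero.any():
        bad = [counts.regions[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"regions with zero total inbound migration: {bad}")
    P = counts.m / inbound[np.newaxis, :]
    return TransitionMatrix(generation=counts.generation, regions=counts.regions, P=P)


def compose_transitions(*matrices) -> np.ndarray:
    """Compose per-generation transition matrices, oldest first:
    P_bar = P^(3) P^(2) P^(1).

    ``P_bar[i, j]`` sums over all migration routes from region i to region j
    across the composed generations.  Passing a single matrix (birth-region
    analysis, P_bar = P^(3)) returns it unchanged.
    """
    arrs = []
    regions = None
    for M in matrices:
        if isinstance(M, TransitionMatrix):
            if regions is not None and M.regions != regions:
                raise ValueError("transition matrices use different region sets")
            regions = M.regions
            M = M.P
        M = np.asarray(M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"transition matrix is not square: shape {M.shape}")
        if arrs and M.shape != arrs[-1].shape:
            raise ValueError("transition matrix dimensions do not match")
        arrs.append(M)
    if not arrs:
        raise ValueError("no transition matrices given")
    out = arrs[0]
    for M in arrs[1:]:
        out = out @ M
    return out


@dataclass(frozen=True)
class CensusRelatedness:
    """Symmetric census relatedness metric I (units 1/persons)."""

    regions: tuple
    I: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.I, index=self.regions, columns=self.regions)


def census_relatedness(P_bar, populations, regions=None) -> CensusRelatedness:
    """Coalescent census relatedness: I_ij = sum_k P_bar_ki P_bar_kj / N_k.

    Two regions are related in proportion to the chance their residents'
    ancestors were in a common region k, discounted by that region's
    population size (common ancestry is ~1/N_k per generation).
    """
    P_bar = np.asarray(P_bar, dtype=float)
    N = np.asarray(populations, dtype=float)
    if (N <= 0).any():
        raise ValueError("population sizes must be positive")
    I = P_bar.T @ (P_bar / N[:, np.newaxis])
    I = 0.5 * (I + I.T)  # symmetrise away rounding
    if regions is None:
        regions = tuple(range(P_bar.shape[0]))
    return CensusRelatedness(regions=tuple(regions), I=I)


# ---------------------------------------------------------------------------
# Element-permutation Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    correlation: float
    pvalue: float
    n_permutations: int
    mode: str
    variant: str


def _pearson_many(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector a with each row of B."""
    a = a - a.mean()
    B = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((a @ a) * (B * B).sum(axis=1))
    return (B @ a) / denom


def mantel_element_test(
    A,
    B,
    mode: str = "exhaustive",
    n_perm: int = 100_000,
    seed=None,
    variant: str = "elements",
) -> MantelResult:
    """Permutation test of the Pearson correlation between two matrices.

    The default ``variant="elements"`` permutes the *elements* of ``B``
    (the census-derived matrix) and counts permutations whose correlation
    with ``A`` reaches the observed one; ties count as rejections, so
    p = #(r_perm >= r_obs) / n_total and the identity permutation guarantees
    p >= 1/n_total.  ``variant="rowcol"`` instead applies a common
    permutation to rows and columns of ``B`` (the classical Mantel
    convention) and correlates off-diagonal elements.

    ``mode="exhaustive"`` enumerates all permutations (allowed for at most 9
    permuted units); ``mode="random"`` draws ``n_perm`` permutations with the
    given seed.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"matrix shapes differ: {A.shape} vs {B.shape}")

    if variant == "elements":
        a = A.ravel()
        b = B.ravel()
        k = b.size

        def permute_rows(perms):
            return b[perms]

    elif variant == "rowcol":
        if A.shape[0] != A.shape[1]:
            raise ValueError("rowcol variant requires square matrices")
        n = A.shape[0]
        off = ~np.eye(n, dtype=bool)
        a = A[off]
        k = n

        def permute_rows(perms):
            return np.stack([B[np.ix_(p, p)][off] for p in perms])

        b = B[off]
    else:
        raise ValueError(f"unknown Mantel variant: {variant!r}")

    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance matrix: correlation undefined")

    r_obs = float(np.corrcoef(a, b)[0, 1])

    if mode == "exhaustive":
        if k > 9:
            raise ValueError(
                f"exhaustive mode limited to 9 permuted units, got {k}"
            )
        perms = np.array(list(itertools.permutations(range(k))))
    elif mode == "random":
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(k) for _ in range(int(n_perm))])
    else:
        raise ValueError(f"unknown Mantel mode: {mode!r}")

    if variant == "elements":
        rows = permute_rows(perms)
    else:
        rows = permute_rows(list(perms))
    r_perm = _pearson_many(a, rows)
    n_total = len(perms)
    n_reject = int(np.sum(r_perm >= r_obs - 1e-12))
    return MantelResult(
        correlation=r_obs,
        pvalue=n_reject / n_total,
        n_permutations=n_total,
        mode=mode,
        variant=variant,
    )


def population_size_ratio(share_a: float, share_b: float) -> float:
    """Ratio of two population shares (e.g. 2010 census self-identified
    shares, 72% "White alone" vs 13% "Black or African American alone",
    giving 5.5) — the census counterpart of the ratio of fitted population
    densities from the isolation-by-distance model."""
    if share_a <= 0 or share_b <= 0:
        raise ValueError("population shares must be positive")
    return share_a / share_b
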
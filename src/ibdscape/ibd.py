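"""Identity-by-descent segment handling: reading, hotspot filtering, and
pairwise / regional / distance-binned relatedness summaries.

Coordinates are genetic positions in centimorgans with 0-based half-open
intervals.  Two intervals overlap when their intersection is non-empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IBDSegment",
    "Cohort",
    "ForbiddenRegionSet",
    "RelatednessMatrices",
    "DecayCurve",
    "SUPPRESSED",
    "read_ibd_segments",
    "write_ibd_segments",
    "detect_forbidden_regions",
    "filter_by_forbidden",
    "build_relatedness_matrices",
    "regional_relatedness",
    "distance_decay_curve",
    "DEFAULT_LENGTH_WINDOWS",
]

_LEN_TOL = 1e-6

#: The three segment-length windows used throughout: [3, 10), [10, 18) and
#: [18, inf) cM.  The longest window is the one informative of the most
#: recent shared ancestry (expected common ancestor within ~8 generations).
DEFAULT_LENGTH_WINDOWS = ((3.0, 10.0), (10.0, 18.0), (18.0, np.inf))

#: Sentinel returned by :func:`regional_relatedness` when the number of
#: possible pairs is below the display threshold.
SUPPRESSED = "suppressed"


@dataclass(frozen=True, slots=True)
class IBDSegment:
    """One haplotype segment shared identical-by-descent between two people.

    ``start``/``end`` are genetic positions in cM, half-open; ``length`` must
    equal ``end - start`` within 1e-6 cM.
    """

    id_a: str
    id_b: str
    chrom: str
    start: float
    end: float
    length: float

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError(f"segment relates {self.id_a!r} to itself")
        if not self.end > self.start:
            raise ValueError(
                f"segment end {self.end} must exceed start {self.start}"
            )
        if abs((self.end - self.start) - self.length) > _LEN_TOL:
            raise ValueError(
                f"length {self.length} inconsistent with interval "
                f"[{self.start}, {self.end})"
            )


def _segments_to_frame(segments) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id_a": [s.id_a for s in segments],
            "id_b": [s.id_b for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "length": [s.length for s in segments],
        }
    )


def read_ibd_segments(path, dialect: str = "canonical", min_length: float = 3.0):
    """Read IBD segments from a TSV file.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"canonical", "germline-match"}
        ``canonical`` expects a header row with columns
        ``id_a  id_b  chrom  start_cM  end_cM  length_cM``.
        ``germline-match`` reads GERMLINE ``.match``-style whitespace-delimited
        rows, using the columns carrying the pair ids (2 and 4), chromosome
        (5), segment start (7), genetic length (11) and length unit (12,
        1-based).  The start column is interpreted as a genetic position in cM
        (i.e. runs where GERMLINE was given a map in cM units); the segment is
        reconstructed as ``[start, start + length)``.  Rows whose unit field
        is not ``cM`` are rejected.
    min_length : float
        Minimum segment length in cM; shorter segments are dropped
        (detection-threshold convention: segments of 3 cM or longer).

    Returns
    -------
    list of IBDSegment
    """
    if dialect == "canonical":
        rows = _read_canonical(path)
    elif dialect == "germline-match":
        rows = _read_germline_match(path)
    else:
        raise ValueError(f"unknown IBD file dialect: {dialect!r}")
    kept = [s for s in rows if s.length >= min_length]
    logger.info(
        "read %d segments from %s (%d below %.3g cM dropped)",
        len(rows), path, len(rows) - len(kept), min_length,
    )
    return kept


def _read_canonical(path):
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str, "chrom": str})
    if df.empty and df.columns.size == 0:
        return []
    required = ["id_a", "id_b", "chrom", "start_cM", "end_cM", "length_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"canonical IBD file missing columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                IBDSegment(
                    id_a=str(row.id_a), id_b=str(row.id_b), chrom=str(row.chrom),
                    start=float(row.start_cM), end=float(row.end_cM),
                    length=float(row.length_cM),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: one for the header row, one for 1-based numbering
            raise ValueError(f"malformed IBD record at line {i + 2}: {exc}") from exc
    return out


def _read_germline_match(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ValueError(
                    f"malformed GERMLINE match record at line {lineno}: "
                    f"expected >= 12 fields, got {len(fields)}"
                )
            unit = fields[11]
            if unit != "cM":
                raise ValueError(
                    f"malformed GERMLINE match record at line {lineno}: "
                    f"length unit {unit!r} is not cM"
                )
            try:
                start = float(fields[6])
                length = float(fields[10])
                out.append(
                    IBDSegment(
                        id_a=fields[1], id_b=fields[3], chrom=fields[4],
                        start=start, end=start + length, length=length,
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"malformed GERMLINE match record at line {lineno}: {exc}"
                ) from exc
    return out


def write_ibd_segments(segments, path):
    """Write segments in the canonical TSV dialect."""
    df = _segments_to_frame(segments)
    df.columns = ["id_a", "id_b", "chrom", "start_cM", "end_cM", "length_cM"]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Individual metadata: group labels, regions, coordinates, birth years,
    and the list of close-relative pairs to exclude from relatedness sums.

    ``table`` is indexed by individual id and may carry columns ``group``,
    ``region_residence``, ``region_birth``, ``x``, ``y`` (km-projected
    sampling coordinates) and ``birth_year``.  ``excluded_pairs`` holds
    unordered id pairs (kinship coefficient >= 0.1 convention).
    """

    table: pd.DataFrame
    excluded_pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique()
            raise ValueError(f"duplicate individual ids: {list(dupes)}")
        pairs = set()
        known = set(self.table.index)
        for pair in self.excluded_pairs:
            a, b = sorted(str(x) for x in pair)
            if a not in known or b not in known:
                raise ValueError(f"excluded pair ({a}, {b}) references unknown ids")
            pairs.add((a, b))
        self.excluded_pairs = frozenset(pairs)

    @classmethod
    def from_tsv(cls, path, exclusions_path=None) -> "Cohort":
        """Load cohort metadata (TSV with an ``id`` column) and, optionally,
        an exclusion-pair TSV with columns ``id_a`` and ``id_b``."""
        table = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
        pairs = frozenset()
        if exclusions_path is not None:
            ex = pd.read_csv(exclusions_path, sep="\t", dtype=str)
            pairs = frozenset(
                frozenset((a, b)) for a, b in zip(ex["id_a"], ex["id_b"])
            )
        return cls(table, pairs)

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def is_excluded(self, id_a, id_b) -> bool:
        a, b = sorted((str(id_a), str(id_b)))
        return (a, b) in self.excluded_pairs

    def members(self, region, group, by: str = "region_residence"):
        """Ids of individuals with the given region and group label."""
        t = self.table
        mask = (t[by] == region) & (t["group"] == group)
        return list(t.index[mask])

    def coordinates(self, ids=None) -> np.ndarray:
        """km-projected (x, y) coordinates; raises listing any missing ids."""
        t = self.table if ids is None else self.table.loc[list(ids)]
        if "x" not in t.columns or "y" not in t.columns:
            raise ValueError("cohort table has no coordinate columns 'x'/'y'")
        xy = t[["x", "y"]].astype(float)
        bad = list(t.index[xy.isna().any(axis=1)])
        if bad:
            raise ValueError(f"missing coordinates for individuals: {bad}")
        return xy.to_numpy()


# ---------------------------------------------------------------------------
# Forbidden-region (IBD hotspot) filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForbiddenRegionSet:
    """Per-chromosome half-open cM intervals of excess IBD coverage.

    Positions covered by more segments than ``threshold`` are marked
    forbidden; nearby regions closer than ``merge_gap`` cM are merged.
    """

    regions: dict  # chrom -> tuple of (start, end)
    threshold: float
    merge_gap: float

    def __post_init__(self):
        clean = {}
        for chrom, intervals in self.regions.items():
            ivs = sorted((float(a), float(b)) for a, b in intervals)
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 - b1 < self.merge_gap:
                    raise ValueError(
                        f"chromosome {chrom}: intervals [{a1},{b1}) and "
                        f"[{a2},{b2}) closer than merge gap {self.merge_gap}"
                    )
            if ivs:
                clean[str(chrom)] = tuple(ivs)
        object.__setattr__(self, "regions", clean)

    @property
    def n_regions(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def intervals(self, chrom):
        return self.regions.get(str(chrom), ())


def detect_forbidden_regions(
    segments,
    grid_step: float = 0.05,
    threshold=25000,
    merge_gap: float = 0.1,
    auto_factor: float = 25000.0 / 15000.0,
):
    """Locate genomic regions overlapped by an excess number of IBD segments.

    Coverage is counted on a regular cM grid of spacing ``grid_step`` (the
    computable surrogate for "each genomic position").  Grid points whose
    coverage count exceeds ``threshold`` are forbidden; runs of such points
    become intervals, and intervals separated by less than ``merge_gap`` cM
    are merged.

    ``threshold`` may be ``None``, in which case it is set automatically to
    ``ceil(auto_factor * genome-wide mean coverage)`` — the default factor
    reproduces the 25,000 threshold derived from a ~15,000 genome-wide mean.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not segments:
        return ForbiddenRegionSet({}, threshold=threshold or 0, merge_gap=merge_gap)

    by_chrom: dict[str, list] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)

    counts_per_chrom = {}
    all_counts = []
    for chrom, segs in by_chrom.items():
        starts = np.sort(np.array([s.start for s in segs]))
        ends = np.sort(np.array([s.end for s in segs]))
        lo = np.floor(starts[0] / grid_step) * grid_step
        hi = ends[-1]
        grid = np.arange(lo, hi + grid_step, grid_step)
        # coverage at x: #(start <= x) - #(end <= x)
        cov = np.searchsorted(starts, grid, side="right") - np.searchsorted(
            ends, grid, side="right"
        )
        counts_per_chrom[chrom] = (grid, cov)
        all_counts.append(cov)

    if threshold is None:
        mean_cov = float(np.mean(np.concatenate(all_counts)))
        threshold = int(np.ceil(auto_factor * mean_cov))
        logger.info(
            "auto hotspot threshold: %d (%.3g x genome-wide mean %.1f)",
            threshold, auto_factor, mean_cov,
        )

    regions = {}
    for chrom, (grid, cov) in counts_per_chrom.items():
        hot = cov > threshold
        if not hot.any():
            continue
        intervals = []
        edges = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            # grid points grid[i0:i1] are hot; they forbid [x, x + step)
            intervals.append((grid[i0], grid[i1 - 1] + grid_step))
        merged = [list(intervals[0])]
        for a, b in intervals[1:]:
            if a - merged[-1][1] < merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        regions[chrom] = [tuple(iv) for iv in merged]

    out = ForbiddenRegionSet(regions, threshold=threshold, merge_gap=merge_gap)
    logger.info("detected %d forbidden regions (threshold %s)", out.n_regions, threshold)
    return out


def filter_by_forbidden(segments, regions: ForbiddenRegionSet, min_flank: float = 3.0):
    """Drop segments overlapping forbidden regions unless they extend far
    enough outside them.

    A segment overlapping forbidden intervals is kept if its maximal
    contiguous extent outside the union of forbidden intervals is at least
    ``min_flank`` cM (either side — or any gap between regions — sufficing),
    on the view that a long stretch of non-forbidden support is evidence the
    segment is genuine.  Non-overlapping segments always pass.
    """
    kept = []
    n_removed = 0
    for s in segments:
        ivs = regions.intervals(s.chrom)
        pieces = _complement_within(s.start, s.end, ivs)
        if not ivs or sum(b - a for a, b in ivs_overlap(s, ivs)) == 0:
            kept.append(s)
            continue
        max_piece = max((b - a for a, b in pieces), default=0.0)
        if max_piece >= min_flank:
            kept.append(s)
        else:
            n_removed += 1
    logger.info(
        "hotspot filter kept %d of %d segments (%d removed)",
        len(kept), len(segments), n_removed,
    )
    return kept


def ivs_overlap(segment, intervals):
    """Intersections of a segment with a sorted list of half-open intervals."""
    out = []
    for a, b in intervals:
        lo, hi = max(segment.start, a), min(segment.end, b)
        if hi > lo:
            out.append((lo, hi))
    return out


def _complement_within(start, end, intervals):
    """Sub-intervals of [start, end) not covered by the given intervals."""
    pieces = []
    pos = start
    for a, b in intervals:
        if b <= start or a >= end:
            continue
        if a > pos:
            pieces.append((pos, min(a, end)))
        pos = max(pos, b)
        if pos >= end:
            break
    if pos < end:
        pieces.append((pos, end))
    return pieces


# ---------------------------------------------------------------------------
# Relatedness matrices and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelatednessMatrices:
    """Pairwise total shared IBD length (L, cM) and segment count (N).

    Symmetric with zero diagonal (self-IBD is zero by definition); entries of
    excluded close-relative pairs are zeroed.
    """

    ids: tuple
    L: np.ndarray
    N: np.ndarray
    window: tuple

    def index_of(self, individual) -> int:
        return self.ids.index(str(individual))

    def pair_length(self, id_a, id_b) -> float:
        return float(self.L[self.index_of(id_a), self.index_of(id_b)])


def build_relatedness_matrices(segments, cohort: Cohort, window=(18.0, np.inf)):
    """Aggregate segments with length in ``window`` (cM, half-open) into the
    pairwise L (total length) and N (count) matrices over the cohort."""
    ids = tuple(cohort.ids)
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    L = np.zeros((n, n))
    N = np.zeros((n, n), dtype=int)
    lmin, lmax = window
    for s in segments:
        if s.id_a not in idx or s.id_b not in idx:
            raise ValueError(
                f"segment references unknown individual(s): {s.id_a}, {s.id_b}"
            )
        if not (lmin <= s.length < lmax):
            continue
        a, b = idx[s.id_a], idx[s.id_b]
        L[a, b] += s.length
        L[b, a] += s.length
        N[a, b] += 1
        N[b, a] += 1
    for id_a, id_b in cohort.excluded_pairs:
        a, b = idx[id_a], idx[id_b]
        L[a, b] = L[b, a] = 0.0
        N[a, b] = N[b, a] = 0
    np.fill_diagonal(L, 0.0)
    np.fill_diagonal(N, 0)
    return RelatednessMatrices(ids=ids, L=L, N=N, window=(float(lmin), float(lmax)))


def regional_relatedness(
    matrices: RelatednessMatrices,
    cohort: Cohort,
    group1,
    group2,
    min_pairs: int = 0,
    by: str = "region_residence",
):
    """Average total shared IBD length between two (region, group) strata.

    Returns ``sum(L_ij) / N_pairs`` over relevant pairs, where
    ``N_pairs = n1 * n2`` for distinct strata and ``n1 * (n1 - 1) / 2`` when
    the two strata coincide.  When fewer than ``min_pairs`` pairs exist the
    sentinel :data:`SUPPRESSED` is returned (display convention: 10,000).
    """
    r1, s1 = group1
    r2, s2 = group2
    ids1 = cohort.members(r1, s1, by=by)
    ids2 = cohort.members(r2, s2, by=by)
    if not ids1 or not ids2:
        raise ValueError(f"empty stratum: {group1 if not ids1 else group2}")
    same = (r1, s1) == (r2, s2)
    n1, n2 = len(ids1), len(ids2)
    n_pairs = n1 * (n1 - 1) // 2 if same else n1 * n2
    if n_pairs < min_pairs:
        return SUPPRESSED
    i1 = [matrices.index_of(i) for i in ids1]
    i2 = [matrices.index_of(i) for i in ids2]
    sub = matrices.L[np.ix_(i1, i2)]
    total = float(sub.sum()) / 2.0 if same else float(sub.sum())
    return total / n_pairs


@dataclass(frozen=True)
class DecayCurve:
    """Distance-binned mean pairwise IBD totals.

    ``mean`` is NaN for bins with no pairs (flagged, never zero-filled);
    ``se`` is the standard error of the per-pair totals within the bin.
    """

    bin_edges: np.ndarray      # km, len nbins + 1
    midpoints: np.ndarray      # km
    mean: np.ndarray           # cM
    se: np.ndarray             # cM
    count: np.ndarray          # pairs per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_km": self.bin_edges[:-1],
                "bin_hi_km": self.bin_edges[1:],
                "midpoint_km": self.midpoints,
                "mean_cM": self.mean,
                "se_cM": self.se,
                "n_pairs": self.count,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DecayCurve":
        edges = np.concatenate([df["bin_lo_km"].to_numpy(), [df["bin_hi_km"].iloc[-1]]])
        return cls(
            bin_edges=edges,
            midpoints=df["midpoint_km"].to_numpy(float),
            mean=df["mean_cM"].to_numpy(float),
            se=df["se_cM"].to_numpy(float),
            count=df["n_pairs"].to_numpy(int),
        )

    def plot(self, ax=None, **kwargs):
        """Log-scale scatter of mean IBD vs distance with SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.count > 0
        ax.errorbar(
            self.midpoints[ok], self.mean[ok], yerr=self.se[ok],
            fmt=kwargs.pop("fmt", "o"), **kwargs,
        )
        ax.set_yscale("log")
        ax.set_xlabel("distance (km)")
        ax.set_ylabel("mean pairwise IBD (cM)")
        return ax


def default_distance_bins(max_distance_km: float) -> np.ndarray:
    """Bins {[0,1), [1,101), [101,201), ...} out to the maximum distance.
    The first bin holds same-location (same clinic) pairs."""
    upper = 101.0
    edges = [0.0, 1.0]
    while upper <= max_distance_km + 100.0:
        edges.append(upper)
        upper += 100.0
    if edges[-1] <= max_distance_km:
        edges.append(edges[-1] + 100.0)
    return np.array(edges)


def distance_decay_curve(matrices: RelatednessMatrices, cohort: Cohort, bin_edges=None):
    """Bin all cohort pairs by geographic distance and average pairwise IBD.

    Every non-excluded pair enters its distance bin, contributing its total
    shared length (zero for pairs sharing nothing); bin means are sums over
    pairs divided by pair counts.  The midpoint of [1, 101) km is 51 km.
    """
    ids = list(matrices.ids)
    xy = cohort.coordinates(ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    dist = np.hypot(xy[iu, 0] - xy[ju, 0], xy[iu, 1] - xy[ju, 1])
    lengths = matrices.L[iu, ju]

    if cohort.excluded_pairs:
        keep = np.array(
            [not cohort.is_excluded(ids[i], ids[j]) for i, j in zip(iu, ju)]
        )
        dist, lengths = dist[keep], lengths[keep]

    if bin_edges is None:
        bin_edges = default_distance_bins(dist.max() if dist.size else 0.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(dist, bin_edges) - 1
    nbins = len(bin_edges) - 1

    mean = np.full(nbins, np.nan)
    se = np.full(nbins, np.nan)
    count = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        vals = lengths[which == b]
        count[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            se[b] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    midpoints = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return DecayCurve(bin_edges=bin_edges, midpoints=midpoints, mean=mean, se=se, count=count)
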
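"""Synthetic-data generators mirroring the statistical structure each
pipeline stage assumes: pairwise IBD segments under the diffusion
isolation-by-distance model, ancestry tracts from forward Wright-Fisher
admixture, generation-stratified census migration tables, planted IBD
hotspots, and birth-year/admixture-time cohorts.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeMap, default_genome_map
from .ibd import Cohort, DecayCurve, IBDSegment
from .census import MigrationCounts
from .spatial import DiffusionParams
from .tracts import AncestryTract, PulseModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PairIbdSampler",
    "simulate_pair_ibd",
    "simulate_decay_curve",
    "simulate_cohort_ibd",
    "simulate_wf_admixture_tracts",
    "simulate_census_tables",
    "inject_hotspot",
    "simulate_birth_year_admixture",
]


@dataclass
class SimulationConfig:
    """Bundle of generator settings for a cohort-level IBD simulation.

    ``clinics`` is a list of dicts with keys ``name, x, y, n`` (km-projected
    coordinates and the number of sampled individuals); all individuals get
    the same ``group`` label.
    """

    seed: int
    clinics: list
    params: DiffusionParams
    window: tuple = (0.18, np.inf)
    genome: GenomeMap = field(default_factory=default_genome_map)
    group: str = "AFR"

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genome = (
            GenomeMap(raw["genome"]) if "genome" in raw else default_genome_map()
        )
        p = raw["params"]
        return cls(
            seed=int(raw["seed"]),
            clinics=list(raw["clinics"]),
            params=DiffusionParams(n=p["n"], D=p["D"], b=p.get("b", 0.0)),
            window=tuple(raw.get("window", (0.18, np.inf))),
            genome=genome,
            group=raw.get("group", "AFR"),
        )


# ---------------------------------------------------------------------------
# Pairwise IBD under the diffusion model
# ---------------------------------------------------------------------------

class PairIbdSampler:
    """Draw IBD segments for pairs a fixed distance R apart.

    Construction: under the diffusion-coalescent model the expected density
    of genome fraction in segments of length l (Morgans) is

        q(l) = R^2 / (32 pi n D^2) * K2(R sqrt(l / D))      (R > 0)
        q(l) = 1 / (16 pi n D l)                            (R = 0),

    so segments are generated as a Poisson process with per-chromosome count
    intensity 2 L_c * int q(l)/l dl over the window (capped at L_c) and
    lengths drawn proportional to q(l)/l.  The mean total length in the
    window then equals the analytic expectation exactly; higher moments are
    implementation-defined (Poisson counts, independent lengths).  A
    distance-independent background channel with mean total b is added the
    same way using the R = 0 length shape.
    """

    def __init__(
        self,
        params: DiffusionParams,
        R: float,
        genome: GenomeMap | None = None,
        window=(0.18, np.inf),
        n_grid: int = 512,
    ):
        from scipy import special

        if genome is None:
            genome = default_genome_map()
        self.params = params
        self.R = float(R)
        self.genome = genome
        l_min, l_max = float(window[0]), float(window[1])
        if not l_min > 0:
            raise ValueError("window lower bound must be positive")
        self.window = (l_min, l_max)
        Ls = genome.lengths_morgans
        h_global = min(l_max, Ls.max())
        if h_global <= l_min:
            raise ValueError("window lies above every chromosome length")

        # tabulated CDF of the count density g(l) = q(l)/l on [l_min, h_max]
        grid = np.geomspace(l_min, h_global, n_grid)
        n, D = params.n, params.D
        if self.R > 0:
            u = self.R * np.sqrt(grid / D)
            q = self.R ** 2 / (32.0 * np.pi * n * D ** 2) * special.kv(2, u)
        else:
            q = 1.0 / (16.0 * np.pi * n * D * grid)
        g = q / grid
        cum = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (g[1:] + g[:-1]))])
        self._grid = grid
        self._cum = cum
        self.chroms = list(genome.lengths)
        self._L_cM = np.array([genome.length_cM(c) for c in self.chroms])
        caps = np.minimum(h_global, np.minimum(l_max, Ls))
        self._cap_cum = np.interp(caps, grid, cum)
        self._lams = 2.0 * Ls * self._cap_cum          # counts per pair per chrom
        self._lams[np.minimum(l_max, Ls) <= l_min] = 0.0

        # background channel: R = 0 length shape, mean total b
        self._bg_lams = np.zeros_like(self._lams)
        if params.b > 0:
            g0 = 1.0 / (16.0 * np.pi * n * D * grid ** 2)
            cum0 = np.concatenate(
                [[0.0], np.cumsum(np.diff(grid) * 0.5 * (g0[1:] + g0[:-1]))]
            )
            self._cum_bg = cum0
            cap0 = np.interp(caps, grid, cum0)
            # mean length of a background segment on each chromosome
            mean_num = np.concatenate(
                [[0.0], np.cumsum(np.diff(grid) * 0.5 * (g0[1:] * grid[1:] + g0[:-1] * grid[:-1]))]
            )
            mean_len = np.where(cap0 > 0, np.interp(caps, grid, mean_num) / np.where(cap0 > 0, cap0, 1.0), 0.0)
            # distribute the b Morgans of expected background over chromosomes
            weights = Ls * (cap0 > 0)
            weights = weights / weights.sum()
            b_morgans = params.b / 100.0
            with np.errstate(invalid="ignore", divide="ignore"):
                self._bg_lams = np.where(
                    mean_len > 0, b_morgans * weights / mean_len, 0.0
                )
            self._bg_cap = cap0

    @property
    def expected_total_cM(self) -> float:
        """Analytic mean total segment length per pair (window + background)."""
        Ls = self.genome.lengths_morgans
        grid, g = self._grid, None
        # integrate q over [l_min, cap_c] per chromosome via the length-moment
        from scipy import special

        n, D = self.params.n, self.params.D
        if self.R > 0:
            u = self.R * np.sqrt(grid / D)
            q = self.R ** 2 / (32.0 * np.pi * n * D ** 2) * special.kv(2, u)
        else:
            q = 1.0 / (16.0 * np.pi * n * D * grid)
        cumq = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (q[1:] + q[:-1]))])
        caps = np.minimum(self.window[1], np.minimum(grid[-1], Ls))
        frac = np.interp(caps, grid, cumq)
        frac[np.minimum(self.window[1], Ls) <= self.window[0]] = 0.0
        return float(100.0 * np.sum(2.0 * Ls * frac) + self.params.b)

    def _draw_lengths(self, total_counts, cum, caps_cum, chrom_idx, rng):
        u = rng.uniform(0.0, caps_cum[chrom_idx])
        return np.interp(u, cum, self._grid)

    def sample_totals(self, n_pairs: int, rng) -> np.ndarray:
        """Total shared length (cM) per pair; the cheap bulk path used for
        decay curves."""
        totals = np.zeros(n_pairs)
        for k in range(len(self.chroms)):
            lam = self._lams[k] + self._bg_lams[k]
            if lam <= 0:
                continue
            counts = rng.poisson(self._lams[k], size=n_pairs)
            if counts.sum():
                reps = np.repeat(np.arange(n_pairs), counts)
                u = rng.uniform(0.0, self._cap_cum[k], size=counts.sum())
                lens = np.interp(u, self._cum, self._grid)
                np.add.at(totals, reps, 100.0 * lens)
            if self._bg_lams[k] > 0:
                counts = rng.poisson(self._bg_lams[k], size=n_pairs)
                if counts.sum():
                    reps = np.repeat(np.arange(n_pairs), counts)
                    u = rng.uniform(0.0, self._bg_cap[k], size=counts.sum())
                    lens = np.interp(u, self._cum_bg, self._grid)
                    np.add.at(totals, reps, 100.0 * lens)
        return totals

    def sample_pair(self, rng, id_a: str = "A", id_b: str = "B"):
        """Segments (cM coordinates) for one pair."""
        out = []
        for k, chrom in enumerate(self.chroms):
            L_cM = self._L_cM[k]
            for lam, cum, cap in (
                (self._lams[k], self._cum, self._cap_cum[k]),
                (self._bg_lams[k], getattr(self, "_cum_bg", None),
                 self._bg_cap[k] if self._bg_lams[k] > 0 else 0.0),
            ):
                if lam <= 0 or cum is None:
                    continue
                n_seg = rng.poisson(lam)
                for _ in range(n_seg):
                    u = rng.uniform(0.0, cap)
                    l_cM = 100.0 * float(np.interp(u, cum, self._grid))
                    l_cM = min(l_cM, L_cM)
                    start = rng.uniform(0.0, max(L_cM - l_cM, 1e-12))
                    out.append(
                        IBDSegment(
                            id_a=id_a, id_b=id_b, chrom=chrom,
                            start=start, end=start + l_cM, length=l_cM,
                        )
                    )
        return out


def simulate_pair_ibd(
    params: DiffusionParams,
    R: float,
    genome: GenomeMap | None = None,
    window=(0.18, np.inf),
    seed=None,
    id_a: str = "A",
    id_b: str = "B",
):
    """IBD segments for one pair a distance R apart; see
    :class:`PairIbdSampler` for the generative construction (the mean total
    window length matches the analytic expectation exactly)."""
    sampler = PairIbdSampler(params, R, genome=genome, window=window)
    rng = np.random.default_rng(seed)
    return sampler.sample_pair(rng, id_a=id_a, id_b=id_b)


def simulate_decay_curve(
    params: DiffusionParams,
    bin_edges,
    n_pairs_per_bin: int,
    genome: GenomeMap | None = None,
    window=(0.18, np.inf),
    seed=None,
) -> DecayCurve:
    """Distance-binned decay curve with ``n_pairs_per_bin`` simulated pairs
    placed at each bin midpoint."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    rng = np.random.default_rng(seed)
    mean = np.empty(len(mids))
    se = np.empty(len(mids))
    count = np.full(len(mids), n_pairs_per_bin)
    for i, R in enumerate(mids):
        sampler = PairIbdSampler(params, R, genome=genome, window=window)
        totals = sampler.sample_totals(n_pairs_per_bin, rng)
        mean[i] = totals.mean()
        se[i] = totals.std(ddof=1) / np.sqrt(n_pairs_per_bin)
    return DecayCurve(bin_edges=bin_edges, midpoints=mids, mean=mean, se=se, count=count)


def simulate_cohort_ibd(config: SimulationConfig):
    """Full input bundle for the IBD pipeline: a clinic-structured cohort,
    pairwise segments drawn under the diffusion model from clinic-to-clinic
    distances, and the ground-truth parameters.

    Returns ``(segments, cohort, truth)`` where ``truth`` records the
    generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for clinic in config.clinics:
        for i in range(int(clinic["n"])):
            rows.append(
                {
                    "id": f"{clinic['name']}_{i}",
                    "group": config.group,
                    "region_residence": clinic.get("region", clinic["name"]),
                    "region_birth": clinic.get("region", clinic["name"]),
                    "x": float(clinic["x"]),
                    "y": float(clinic["y"]),
                }
            )
    truth = {
        "n": config.params.n, "D": config.params.D, "b": config.params.b,
        "window": tuple(config.window), "seed": config.seed,
    }
    if not rows:
        empty = Cohort(pd.DataFrame(columns=["group", "x", "y"]).rename_axis("id"))
        return [], empty, truth
    table = pd.DataFrame(rows).set_index("id")
    cohort = Cohort(table)

    ids = list(table.index)
    xy = table[["x", "y"]].to_numpy(float)
    samplers: dict[float, PairIbdSampler] = {}
    segments = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            R = float(np.hypot(*(xy[i] - xy[j])))
            key = round(R, 6)
            if key not in samplers:
                samplers[key] = PairIbdSampler(
                    config.params, R, genome=config.genome, window=config.window
                )
            segments.extend(samplers[key].sample_pair(rng, ids[i], ids[j]))
    logger.info(
        "simulated %d segments for %d individuals at %d clinics",
        len(segments), n, len(config.clinics),
    )
    return segments, cohort, truth


# ---------------------------------------------------------------------------
# Forward Wright-Fisher admixture tracts
# ---------------------------------------------------------------------------

def _gamete(hap0, hap1, L_cM, rng):
    """One meiosis: crossovers as a Poisson process of rate 1 per Morgan,
    alternating between the two parental haplotypes."""
    n_x = rng.poisson(L_cM / 100.0)
    first = rng.integers(2)
    if n_x == 0:
        ends, labels = (hap0, hap1)[first]
        return ends.copy(), labels.copy()
    xs = np.sort(rng.uniform(0.0, L_cM, n_x))
    bounds = np.concatenate([[0.0], xs, [L_cM]])
    out_ends, out_labels = [], []
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        ends, labels = (hap0, hap1)[(first + k) % 2]
        i0 = int(np.searchsorted(ends, a, side="right"))
        i1 = int(np.searchsorted(ends, b, side="left"))
        for i in range(i0, i1 + 1):
            seg_end = min(float(ends[i]), b)
            if seg_end > a:
                if out_labels and out_labels[-1] == labels[i]:
                    out_ends[-1] = seg_end
                else:
                    out_ends.append(seg_end)
                    out_labels.append(labels[i])
                a = seg_end
    return np.array(out_ends), np.array(out_labels)


def simulate_wf_admixture_tracts(
    N: int,
    model: PulseModel,
    genome: GenomeMap | None = None,
    n_sample: int | None = None,
    seed=None,
):
    """Ancestry tracts from a forward Wright-Fisher admixture simulation.

    A population of ``N`` monoecious diploids reproduces by random mating
    (selfing excluded) with per-meiosis recombination as a Poisson process
    of rate 1 per Morgan per chromosome.  Migrants enter according to the
    model's discretized schedule (fraction replaced per generation, pure
    source ancestry); sampling happens at generation 0.  Output tracts tile
    each haplotype's chromosomes exactly.
    """
    if genome is None:
        genome = default_genome_map()
    if n_sample is None:
        n_sample = 2 * N
    if n_sample > 2 * N:
        raise ValueError(f"cannot sample {n_sample} haplotypes from {N} diploids")
    rng = np.random.default_rng(seed)
    sched = model.discretize()
    G = max(sched)
    chroms = list(genome.lengths)
    L_cMs = [genome.length_cM(c) for c in chroms]

    def pure_diploid(ancestry):
        return [
            [(np.array([L]), np.array([ancestry])) for L in L_cMs],
            [(np.array([L]), np.array([ancestry])) for L in L_cMs],
        ]

    def draw_ancestry(comp):
        pops = list(comp)
        probs = np.array([comp[p] for p in pops])
        return pops[rng.choice(len(pops), p=probs / probs.sum())]

    # founding generation: all migrants
    comp_G = sched[G]["composition"]
    pop = [pure_diploid(draw_ancestry(comp_G)) for _ in range(N)]

    for t in range(G - 1, -1, -1):
        mag = sched[t]["magnitude"] if t in sched and t >= 1 else 0.0
        comp = sched[t]["composition"] if t in sched and t >= 1 else None
        new_pop = []
        for _ in range(N):
            if mag > 0 and rng.random() < mag:
                new_pop.append(pure_diploid(draw_ancestry(comp)))
                continue
            pa, pb = rng.choice(N, size=2, replace=False)
            child = [[], []]
            for k, L in enumerate(L_cMs):
                child[0].append(_gamete(pop[pa][0][k], pop[pa][1][k], L, rng))
                child[1].append(_gamete(pop[pb][0][k], pop[pb][1][k], L, rng))
            new_pop.append(child)
        pop = new_pop

    tracts = []
    for h in range(n_sample):
        ind, hap = divmod(h, 2)
        for k, chrom in enumerate(chroms):
            ends, labels = pop[ind][hap][k]
            start = 0.0
            for e, lab in zip(ends, labels):
                tracts.append(
                    AncestryTract(
                        id=f"ind{ind}", haplotype=hap, chrom=chrom,
                        start=start, end=float(e), ancestry=str(lab),
                    )
                )
                start = float(e)
    return tracts


# ---------------------------------------------------------------------------
# Census tables
# ---------------------------------------------------------------------------

def simulate_census_tables(
    regions,
    generations=(1, 2, 3),
    route_intensities=None,
    external_rates=None,
    populations=None,
    stay_intensity: float = 1000.0,
    seed=None,
) -> dict:
    """Generation-stratified migration counts with Poisson-distributed
    weighted counts around the given route intensities.

    ``route_intensities`` maps (origin, destination) — or
    (origin, destination, generation) — to an expected weighted count;
    unlisted off-diagonal routes default to 0 and diagonal (stayer) routes
    to ``stay_intensity``.  Returns ``{generation: MigrationCounts}`` with
    ground truth retained in ``.truth`` attributes.
    """
    regions = tuple(regions)
    rng = np.random.default_rng(seed)
    route_intensities = dict(route_intensities or {})
    external_rates = dict(external_rates or {})
    if populations is None:
        populations = {r: 1e6 for r in regions}
    out = {}
    k = len(regions)
    for g in generations:
        lam = np.zeros((k, k))
        for i, ri in enumerate(regions):
            for j, rj in enumerate(regions):
                if (ri, rj, g) in route_intensities:
                    lam[i, j] = route_intensities[(ri, rj, g)]
                elif (ri, rj) in route_intensities:
                    lam[i, j] = route_intensities[(ri, rj)]
                elif i == j:
                    lam[i, j] = stay_intensity
        m = rng.poisson(lam).astype(float)
        m_out = np.array(
            [rng.poisson(external_rates.get(r, 0.0)) for r in regions], dtype=float
        )
        counts = MigrationCounts(
            generation=g, regions=regions, m=m, m_out=m_out,
            populations=np.array([populations[r] for r in regions], dtype=float),
        )
        object.__setattr__(counts, "truth", {"lam": lam, "external": m_out})
        out[g] = counts
    return out


# ---------------------------------------------------------------------------
# Hotspot injection
# ---------------------------------------------------------------------------

def inject_hotspot(segments, chrom, interval, extra_count: int, seed=None, ids=None):
    """Append ``extra_count`` spurious short segments covering ``interval``
    on ``chrom`` between random pairs (emulating a false-positive IBD
    hotspot).  The injected segments are the trailing ``extra_count``
    entries of the returned list; the input list is not modified.
    """
    a, b = float(interval[0]), float(interval[1])
    if not b > a:
        raise ValueError(f"invalid hotspot interval [{a}, {b})")
    if extra_count == 0:
        return list(segments)
    if ids is None:
        ids = sorted({s.id_a for s in segments} | {s.id_b for s in segments})
    if len(ids) < 2:
        raise ValueError("need at least two individual ids to inject segments")
    rng = np.random.default_rng(seed)
    out = list(segments)
    for _ in range(int(extra_count)):
        i, j = rng.choice(len(ids), size=2, replace=False)
        start = a - rng.uniform(0.05, 0.5)
        end = b + rng.uniform(0.05, 0.5)
        out.append(
            IBDSegment(
                id_a=str(ids[i]), id_b=str(ids[j]), chrom=str(chrom),
                start=start, end=end, length=end - start,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Birth-year / admixture-time cohorts
# ---------------------------------------------------------------------------

def simulate_birth_year_admixture(
    tau: float,
    onset_year: float,
    group_spec,
    noise: float = 0.0,
    seed=None,
):
    """(mean birth year, inferred admixture time g) pairs per birth-year
    group: g = 1 + (T_s - onset_year)/tau plus Gaussian noise of the given
    standard deviation (in generations)."""
    if not tau > 0:
        raise ValueError("generation time tau must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for spec in group_spec:
        year = float(spec["year"] if isinstance(spec, dict) else spec)
        g = 1.0 + (year - onset_year) / tau
        if noise > 0:
            g = g + rng.normal(0.0, noise)
        out.append((year, g))
    return out
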
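"""Ancestry tracts and the discrete-pulse admixture tract-length model.

Local-ancestry calls partition each haplotype into continuous tracts of
single continental ancestry; because recombination breaks ancestral
haplotypes apart, the tract-length distribution dates the admixture events.
This module provides:

* containers and I/O for ancestry tracts and tract-length histograms;
* global ancestry proportions from tract tilings;
* pulse-model descriptions (``pp``, ``pp_xp``, ``pxp_xpx_xpx``, ...) in the
  underscore nomenclature, where each event string has one letter per source
  population — ``p`` a pulse of migration, ``x`` no migration — and events
  are listed oldest first;
* the analytic expected tract-length histogram under a pulse model: a
  continuous-time Markov chain along the chromosome whose states are
  (migrant-arrival epoch, source population) pairs, with per-Morgan switch
  rate t - 1 out of an epoch-t state and phase-type sojourn laws censored at
  both chromosome ends.

Positions are cM in the containers; the Markov-model math is on the Morgan
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genome import GenomeMap, default_genome_map

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryTract",
    "TractHistogram",
    "PulseModel",
    "PulseEvent",
    "read_tracts",
    "write_tracts",
    "global_ancestry",
    "tract_length_histogram",
    "default_tract_bins",
    "expected_tract_histogram",
    "TractMarkovModel",
    "DEFAULT_EXCLUDE_BELOW_CM",
]

_TOL = 1e-6

#: Histogram exclusion cutoff: segments below 11.7 cM (the first two default
#: bins) are dropped from fitting because short-tract counts are most
#: affected by local-ancestry false positives.
DEFAULT_EXCLUDE_BELOW_CM = 11.7

#: Default bin width so that the exclusion cutoff lands exactly on the edge
#: of the second bin.
DEFAULT_BIN_WIDTH_CM = DEFAULT_EXCLUDE_BELOW_CM / 2.0


@dataclass(frozen=True, slots=True)
class AncestryTract:
    """One continuous local-ancestry tract on one haplotype (cM, half-open)."""

    id: str
    haplotype: int
    chrom: str
    start: float
    end: float
    ancestry: str

    def __post_init__(self):
        if self.haplotype not in (0, 1):
            raise ValueError(f"haplotype index must be 0 or 1, got {self.haplotype}")
        if not self.end > self.start:
            raise ValueError(f"tract end {self.end} must exceed start {self.start}")

    @property
    def length(self) -> float:
        return self.end - self.start


def read_tracts(path):
    """Read a BED-like tract TSV with columns
    ``id  haplotype  chrom  start_cM  end_cM  ancestry``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "ancestry": str})
    return [
        AncestryTract(
            id=str(r.id), haplotype=int(r.haplotype), chrom=str(r.chrom),
            start=float(r.start_cM), end=float(r.end_cM), ancestry=str(r.ancestry),
        )
        for r in df.itertuples(index=False)
    ]


def write_tracts(tracts, path):
    pd.DataFrame(
        {
            "id": [t.id for t in tracts],
            "haplotype": [t.haplotype for t in tracts],
            "chrom": [t.chrom for t in tracts],
            "start_cM": [t.start for t in tracts],
            "end_cM": [t.end for t in tracts],
            "ancestry": [t.ancestry for t in tracts],
        }
    ).to_csv(path, sep="\t", index=False)


def global_ancestry(tracts, bootstrap_reps: int = 0, seed=None):
    """Per-individual global ancestry proportions from tract tilings.

    Tracts of each (individual, haplotype, chromosome) must tile a contiguous
    interval starting at 0 without gaps or overlaps; proportions are total
    tract length per ancestry over total assigned length, so they sum to 1
    per individual.

    Returns a DataFrame indexed by individual with one column per ancestry;
    with ``bootstrap_reps > 0`` the returned frame carries a ``cohort_mean``
    attribute dict ``ancestry -> (mean, lo95, hi95)`` from a sample
    bootstrap over individuals.
    """
    if not tracts:
        raise ValueError("no tracts given")
    by_key: dict = {}
    for t in tracts:
        by_key.setdefault((t.id, t.haplotype, t.chrom), []).append(t)

    totals: dict = {}
    for (ind, hap, chrom), ts in by_key.items():
        ts = sorted(ts, key=lambda t: t.start)
        if abs(ts[0].start) > _TOL:
            raise ValueError(
                f"{ind} hap {hap} chr {chrom}: tiling does not start at 0"
            )
        for a, b in zip(ts, ts[1:]):
            if abs(b.start - a.end) > _TOL:
                kind = "gap" if b.start > a.end else "overlap"
                raise ValueError(
                    f"{ind} hap {hap} chr {chrom}: {kind} between "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        for t in ts:
            totals.setdefault(ind, {}).setdefault(t.ancestry, 0.0)
            totals[ind][t.ancestry] += t.length

    df = pd.DataFrame(totals).T.fillna(0.0).sort_index()
    df = df.div(df.sum(axis=1), axis=0)
    if bootstrap_reps:
        rng = np.random.default_rng(seed)
        vals = df.to_numpy()
        n = len(df)
        means = np.stack([
            vals[rng.integers(0, n, n)].mean(axis=0) for _ in range(bootstrap_reps)
        ])
        lo, hi = np.percentile(means, [2.5, 97.5], axis=0)
        df.attrs["cohort_mean"] = {
            anc: (float(vals[:, k].mean()), float(lo[k]), float(hi[k]))
            for k, anc in enumerate(df.columns)
        }
    return df


# ---------------------------------------------------------------------------
# Tract-length histograms
# ---------------------------------------------------------------------------

def default_tract_bins(genome: GenomeMap, width_cM: float = DEFAULT_BIN_WIDTH_CM):
    """Linear cM bins of the default width; the final edge clears the longest
    chromosome so whole-chromosome tracts land in the terminal bin."""
    max_cM = 100.0 * genome.lengths_morgans.max()
    n = int(np.ceil(max_cM / width_cM)) + 1
    return width_cM * np.arange(n + 1)


@dataclass
class TractHistogram:
    """Observed tract-length counts per ancestry in shared cM bins.

    ``excluded`` marks bins left out of likelihood fitting (by default the
    bins below the 11.7 cM cutoff, where local-ancestry false positives
    concentrate).
    """

    bin_edges: np.ndarray
    counts: dict            # ancestry -> integer counts, len nbins
    n_haplotypes: int
    excluded: np.ndarray | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        nbins = len(self.bin_edges) - 1
        for anc, c in self.counts.items():
            c = np.asarray(c)
            if len(c) != nbins:
                raise ValueError(f"{anc}: {len(c)} counts for {nbins} bins")
            if (c < 0).any():
                raise ValueError(f"{anc}: negative counts")
            self.counts[anc] = c.astype(int)
        if self.excluded is None:
            self.excluded = np.zeros(nbins, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def ancestries(self):
        return tuple(self.counts)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def exclude_below(self, cutoff_cM: float = DEFAULT_EXCLUDE_BELOW_CM):
        """Return a copy with bins entirely below ``cutoff_cM`` excluded."""
        mask = self.bin_edges[1:] <= cutoff_cM + _TOL
        return TractHistogram(
            bin_edges=self.bin_edges, counts=dict(self.counts),
            n_haplotypes=self.n_haplotypes, excluded=mask,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"bin_lo_cM": self.bin_edges[:-1], "bin_hi_cM": self.bin_edges[1:]}
        data.update({a: c for a, c in self.counts.items()})
        data["excluded"] = self.excluded
        return pd.DataFrame(data)


def tract_length_histogram(
    tracts, bin_edges=None, genome: GenomeMap | None = None, ancestries=None
) -> TractHistogram:
    """Bin tract lengths (cM) per ancestry.  ``n_haplotypes`` is the number
    of distinct (individual, haplotype) pairs seen."""
    if genome is None:
        genome = default_genome_map()
    if bin_edges is None:
        bin_edges = default_tract_bins(genome)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if ancestries is None:
        ancestries = tuple(sorted({t.ancestry for t in tracts}))
    counts = {a: np.zeros(len(bin_edges) - 1, dtype=int) for a in ancestries}
    for t in tracts:
        if t.ancestry not in counts:
            continue
        k = int(np.digitize(t.length, bin_edges)) - 1
        if 0 <= k < len(bin_edges) - 1:
            counts[t.ancestry][k] += 1
    n_hap = len({(t.id, t.haplotype) for t in tracts})
    return TractHistogram(bin_edges=bin_edges, counts=counts, n_haplotypes=n_hap)


# ---------------------------------------------------------------------------
# Pulse admixture models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseEvent:
    """One discrete migration event.

    ``time`` is in generations before sampling (continuous; fractional times
    spread migrants linearly over the two adjacent integer generations).
    ``magnitude`` is the fraction of the population replaced by migrants at
    the event, and ``composition`` the source-population mix of those
    migrants (sums to 1).
    """

    time: float
    magnitude: float
    composition: dict

    def __post_init__(self):
        if not self.time >= 1.0:
            raise ValueError(f"event time {self.time} must be >= 1 generation")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError(f"event magnitude {self.magnitude} outside [0, 1]")
        comp = {str(k): float(v) for k, v in self.composition.items() if v > 0}
        if comp and abs(sum(comp.values()) - 1.0) > 1e-9:
            raise ValueError("event composition must sum to 1")
        object.__setattr__(self, "composition", comp)


def _parse_family(family: str):
    """Parse the underscore nomenclature into per-event contribution masks.

    Each event string has one letter per population: ``p`` = pulse from that
    population, ``x`` = no migration.  Events are listed oldest first and the
    first event is the founding one.
    """
    events = family.split("_")
    if not events or not all(events):
        raise ValueError(f"cannot parse model family {family!r}")
    npop = len(events[0])
    masks = []
    for ev in events:
        if len(ev) != npop or any(ch not in "px" for ch in ev):
            raise ValueError(f"cannot parse model family {family!r}: event {ev!r}")
        mask = tuple(ch == "p" for ch in ev)
        if not any(mask):
            raise ValueError(f"event {ev!r} in {family!r} has no migration")
        masks.append(mask)
    return masks


def n_free_parameters(family: str) -> int:
    """Free parameters of a family with present-day totals held fixed: one
    time per event plus one relative-contribution parameter per population
    appearing in more than one event (pp has 1; pp_xp has 3; pxp_xpx has 2;
    ppp_xpx has 3; pxp_xpx_xpx and xpp_pxx_xpx have 4)."""
    masks = _parse_family(family)
    npop = len(masks[0])
    n_splits = sum(1 for p in range(npop) if sum(m[p] for m in masks) > 1)
    return len(masks) + n_splits


@dataclass(frozen=True)
class PulseModel:
    """A discrete-pulse admixture history: ordered events, oldest first.

    ``labels`` names the source populations in family-string letter order.
    The oldest event is the founding one (magnitude 1).  Present-day ancestry
    proportions are a derived quantity (:meth:`ancestry_proportions`).
    """

    labels: tuple
    events: tuple

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        events = tuple(self.events)
        if not events:
            raise ValueError("pulse model needs at least one event")
        times = [e.time for e in events]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"event times must strictly decrease toward the present: {times}"
            )
        if abs(events[0].magnitude - 1.0) > 1e-9:
            raise ValueError("the oldest (founding) event must have magnitude 1")
        for e in events:
            unknown = set(e.composition) - set(labels)
            if unknown:
                raise ValueError(f"event uses unknown populations {unknown}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "events", events)

    # -- construction ------------------------------------------------------
    @classmethod
    def single_pulse(cls, g: float, fractions, labels=None) -> "PulseModel":
        """Founding pulse at generation ``g`` with the given ancestry
        fractions (``g = 1``: the parents of the sample are the founders)."""
        if labels is None:
            labels = tuple(fractions)
        comp = {l: fractions[l] for l in labels}
        return cls(labels=tuple(labels),
                   events=(PulseEvent(time=g, magnitude=1.0, composition=comp),))

    @classmethod
    def from_family(
        cls, family: str, labels, times, totals, splits=()
    ) -> "PulseModel":
        """Build a model from a family string, event times (oldest first),
        present-day ancestry ``totals`` and relative-contribution ``splits``.

        For each population contributing to more than one event, one split
        parameter in [0, 1] gives the share of that population's total
        ancestry delivered by its *more recent* events, assigned from the
        most recent occurrence backwards (populations ordered as in the
        family string).  Magnitudes are solved so present-day proportions
        equal ``totals`` exactly; infeasible settings raise ValueError.
        """
        masks = _parse_family(family)
        labels = tuple(labels)
        npop = len(masks[0])
        if len(labels) != npop:
            raise ValueError(
                f"family {family!r} has {npop} populations, got labels {labels}"
            )
        times = [float(t) for t in times]
        if len(times) != len(masks):
            raise ValueError(
                f"family {family!r} has {len(masks)} events, got {len(times)} times"
            )
        totals = {str(k): float(v) for k, v in totals.items()}
        tot = np.array([totals.get(l, 0.0) for l in labels])
        if abs(tot.sum() - 1.0) > 1e-6:
            raise ValueError(f"ancestry totals must sum to 1, got {tot.sum()}")

        # assign each population's total across its contributing events
        splits = list(splits)
        amounts = np.zeros((len(masks), npop))
        for p in range(npop):
            evs = [e for e, m in enumerate(masks) if m[p]]
            if not evs:
                if tot[p] > 0:
                    raise ValueError(
                        f"population {labels[p]} has ancestry {tot[p]} but no event"
                    )
                continue
            if len(evs) == 1:
                amounts[evs[0], p] = tot[p]
            elif len(evs) == 2:
                if not splits:
                    raise ValueError(
                        f"family {family!r}: missing split parameter for "
                        f"population {labels[p]}"
                    )
                r = float(splits.pop(0))
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"split parameter {r} outside [0, 1]")
                amounts[evs[0], p] = (1.0 - r) * tot[p]
                amounts[evs[1], p] = r * tot[p]
            else:
                raise ValueError(
                    f"population {labels[p]} contributes to {len(evs)} events; "
                    "at most 2 supported"
                )
        if splits:
            raise ValueError(f"{len(splits)} unused split parameters")

        # solve magnitudes from the youngest event backwards:
        # contribution(e) = magnitude(e) * prod_{younger f}(1 - magnitude(f))
        n_ev = len(masks)
        mags = np.zeros(n_ev)
        discount = 1.0
        for e in range(n_ev - 1, 0, -1):
            s = amounts[e].sum()
            if discount <= 0 and s > 0:
                raise ValueError("later pulses already replace the population")
            m = s / discount if discount > 0 else 0.0
            if m > 1.0 + 1e-9:
                raise ValueError(
                    f"infeasible totals/splits: event {e} magnitude {m:.4g} > 1"
                )
            mags[e] = min(m, 1.0)
            discount *= 1.0 - mags[e]
        # founding event absorbs the remainder
        s0 = amounts[0].sum()
        if discount < 1e-12:
            raise ValueError("founding event has no remaining population share")
        if abs(s0 - discount) > 1e-6:
            raise ValueError(
                f"infeasible totals/splits: founding share {s0:.6g} != "
                f"remaining {discount:.6g}"
            )
        mags[0] = 1.0
        amounts[0] *= discount / s0 if s0 > 0 else 0.0

        events = []
        for e in range(n_ev):
            s = amounts[e].sum()
            if e > 0 and s <= 0:
                # zero-magnitude pulse: keep as an explicit no-op event
                comp = {labels[p]: 1.0 for p in range(npop) if masks[e][p]}
                first = next(iter(comp))
                comp = {first: 1.0}
                events.append(PulseEvent(time=times[e], magnitude=0.0, composition=comp))
                continue
            comp = {
                labels[p]: amounts[e, p] / s for p in range(npop) if amounts[e, p] > 0
            }
            events.append(
                PulseEvent(time=times[e], magnitude=float(mags[e]), composition=comp)
            )
        return cls(labels=labels, events=tuple(events))

    # -- derived quantities -------------------------------------------------
    def discretize(self) -> dict:
        """Integer-generation migration schedule ``{g: {pop: fraction}}``.

        A pulse at fractional time k + f sends shares (1 - f) and f of its
        migrant mass to generations k and k + 1.  The founding pulse becomes
        full replacement at generation k + 1 plus a magnitude-(1 - f) pulse
        at k, which delivers the same linear mass split while keeping the
        oldest generation fully migrant-derived.
        """
        schedule: dict[int, list] = {}

        def add(g, mag, comp):
            if mag <= 0:
                return
            schedule.setdefault(g, []).append((mag, comp))

        for i, ev in enumerate(self.events):
            k = int(np.floor(ev.time))
            f = ev.time - k
            if i == 0:  # founding
                if f < 1e-9:
                    add(k, 1.0, ev.composition)
                else:
                    add(k + 1, 1.0, ev.composition)
                    add(k, 1.0 - f, ev.composition)
            else:
                m = ev.magnitude
                if f < 1e-9:
                    add(k, m, ev.composition)
                else:
                    m_young = (1.0 - f) * m
                    m_old = f * m / (1.0 - m_young) if m_young < 1 else 0.0
                    add(k, m_young, ev.composition)
                    add(k + 1, m_old, ev.composition)

        # merge same-generation sub-pulses (applied youngest-layer first)
        out: dict[int, dict] = {}
        for g, pulses in schedule.items():
            mag_total = 0.0
            comp_total: dict[str, float] = {}
            for m, comp in pulses:
                add_m = m * (1.0 - mag_total)
                for pop, c in comp.items():
                    comp_total[pop] = comp_total.get(pop, 0.0) + add_m * c
                mag_total = mag_total + add_m
            out[g] = {pop: v / mag_total for pop, v in comp_total.items()}
            out[g]["__magnitude__"] = mag_total
        return {
            g: {
                "magnitude": v.pop("__magnitude__"),
                "composition": v,
            }
            for g, v in sorted(out.items(), reverse=True)
        }

    def ancestry_proportions(self) -> dict:
        """Present-day per-population ancestry fractions implied by the
        discretized schedule."""
        sched = self.discretize()
        out = {l: 0.0 for l in self.labels}
        gens = sorted(sched)  # youngest first
        discount = 1.0
        for g in gens:
            m = sched[g]["magnitude"]
            for pop, c in sched[g]["composition"].items():
                out[pop] += discount * m * c
            discount *= 1.0 - m
        return out


# ---------------------------------------------------------------------------
# The Markov tract-length engine
# ---------------------------------------------------------------------------

class TractMarkovModel:
    """Continuous-time Markov chain along the chromosome for a discrete-pulse
    admixture schedule.

    States are (arrival epoch t, source population); the ancestor of a locus
    arrived in the admixed population t generations ago.  Switches occur at
    rate t - 1 per Morgan (one unit per post-admixture meiosis in the
    lineage); a switch at pedigree depth k (uniform over 1..t-1) restarts the
    lineage at generation k + 1, whence it exits into epoch v >= k + 1 with
    probability m_v * prod_{k<u<v}(1 - m_u).  Tract lengths of an ancestry
    are phase-type sojourns in that ancestry's states, censored at both
    chromosome ends.
    """

    def __init__(self, model: PulseModel):
        self.model = model
        sched = model.discretize()
        self.epochs = sorted(sched)          # ascending generation
        self.mags = {g: sched[g]["magnitude"] for g in self.epochs}
        self.comps = {g: sched[g]["composition"] for g in self.epochs}
        if abs(self.mags[self.epochs[-1]] - 1.0) > 1e-9:
            raise ValueError("oldest discretized generation must be fully migrant")

        self.states = []                     # (epoch, pop)
        for g in self.epochs:
            for pop, c in self.comps[g].items():
                if c > 0:
                    self.states.append((g, pop))
        self.n_states = len(self.states)
        self._index = {s: i for i, s in enumerate(self.states)}

        # arrival (stationary) probabilities
        self.pi = np.zeros(self.n_states)
        discount = 1.0
        for g in self.epochs:
            m = self.mags[g]
            for pop, c in self.comps[g].items():
                if c > 0:
                    self.pi[self._index[(g, pop)]] = discount * m * c
            discount *= 1.0 - m

        # exit distribution for a lineage restarting at generation k + 1
        G = self.epochs[-1]
        exit_dist = {}                       # k -> state-vector
        for k in range(1, G):
            vec = np.zeros(self.n_states)
            disc = 1.0
            for g in self.epochs:
                if g < k + 1:
                    continue
                m = self.mags[g]
                for pop, c in self.comps[g].items():
                    if c > 0:
                        vec[self._index[(g, pop)]] = disc * m * c
                disc *= 1.0 - m
            exit_dist[k] = vec

        Q = np.zeros((self.n_states, self.n_states))
        for i, (t, _pop) in enumerate(self.states):
            for k in range(1, t):
                Q[i] += exit_dist[k]
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        self.Q = Q

    def ancestry_states(self, ancestry: str) -> np.ndarray:
        return np.array(
            [i for i, (_, pop) in enumerate(self.states) if pop == ancestry],
            dtype=int,
        )

    def _phase_type(self, ancestry):
        """Sub-generator and (unnormalised) entry vectors for one ancestry:
        interior-entry rate density beta and chromosome-start mass pi_A."""
        A = self.ancestry_states(ancestry)
        if A.size == 0:
            return None
        notA = np.setdiff1d(np.arange(self.n_states), A)
        U = self.Q[np.ix_(A, A)]
        beta = self.pi[notA] @ self.Q[np.ix_(notA, A)] if notA.size else np.zeros(A.size)
        return U, beta, self.pi[A]

    def _survivals(self, ancestry, x_morgans):
        """S_beta(x) (interior entries, per-Morgan rate units) and S_0(x)
        (chromosome-start mass) at the given lengths."""
        pt = self._phase_type(ancestry)
        if pt is None:
            z = np.zeros(len(x_morgans))
            return z, z
        U, beta, pi_A = pt
        ones = np.ones(U.shape[0])
        S_beta = np.empty(len(x_morgans))
        S_0 = np.empty(len(x_morgans))
        for j, x in enumerate(x_morgans):
            E = expm(U * x)
            S_beta[j] = beta @ E @ ones
            S_0[j] = pi_A @ E @ ones
        return S_beta, S_0

    def expected_bin_counts(self, ancestry, bin_edges_cM, genome: GenomeMap):
        """Expected number of tracts per length bin for one haploid genome."""
        edges = np.asarray(bin_edges_cM, dtype=float) / 100.0  # Morgans
        S_beta, S_0 = self._survivals(ancestry, edges)
        nbins = len(edges) - 1
        out = np.zeros(nbins)
        for L in genome.lengths_morgans:
            for b in range(nbins):
                b1, b2 = edges[b], edges[b + 1]
                if b1 >= L:
                    continue
                # tract starting at the chromosome start
                if b2 <= L:
                    out[b] += S_0[b] - S_0[b + 1]
                else:
                    out[b] += S_0[b]
                # tracts entered in the interior at rate density S_beta
                interior = max(0.0, L - b2) * (S_beta[b] - S_beta[b + 1])
                edge_zone = (min(b2, L) - min(b1, L)) * S_beta[b]
                out[b] += interior + edge_zone
        return out

    def expected_total_length(self, ancestry, genome: GenomeMap, n_quad: int = 64):
        """Expected total tract length (Morgans) per haploid genome, by
        integrating the censored sojourn survivals (self-consistency check
        against the exact value pi(A) * total genome length)."""
        nodes, weights = np.polynomial.legendre.leggauss(n_quad)
        total = 0.0
        for L in genome.lengths_morgans:
            x = 0.5 * L * (nodes + 1.0)
            w = 0.5 * L * weights
            S_beta, S_0 = self._survivals(ancestry, x)
            total += np.sum(w * S_0) + np.sum(w * (L - x) * S_beta)
        return total

    def stationary_residual(self) -> float:
        """max |pi Q| — zero when the arrival distribution is stationary."""
        return float(np.abs(self.pi @ self.Q).max())


def expected_tract_histogram(
    model: PulseModel,
    genome: GenomeMap | None = None,
    n_haplotypes: int = 1,
    bin_edges=None,
    ancestries=None,
) -> dict:
    """Expected per-bin tract counts under a pulse model.

    Returns ``{ancestry: expected counts}`` over the given cM bins for
    ``n_haplotypes`` haploid genomes.  Ancestries absent from the model (or
    with zero migrant fraction) get all-zero expectations.
    """
    if genome is None:
        genome = default_genome_map()
    if bin_edges is None:
        bin_edges = default_tract_bins(genome)
    engine = TractMarkovModel(model)
    if ancestries is None:
        ancestries = model.labels
    out = {}
    for anc in ancestries:
        counts = engine.expected_bin_counts(anc, bin_edges, genome)
        out[anc] = n_haplotypes * counts
    return out
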
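"""Fitting pulse-admixture histories to tract-length histograms, model
selection, calendar calibration, bootstrap uncertainty, the X-vs-autosome
sex-bias solver, and ancestry-difference bootstrap tests.

The tract fit maximises a per-bin Poisson likelihood of observed tract
counts against the analytic expectations of the Markov tract model, over
event times and relative pulse contributions, with the present-day ancestry
totals held fixed.  Bins below the short-tract exclusion cutoff are ignored
in the objective but predictions are still reported for them.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .genome import GenomeMap, default_genome_map
from .tracts import (
    PulseModel,
    TractHistogram,
    _parse_family,
    expected_tract_histogram,
    n_free_parameters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PulseTractModel",
    "PulseTractResults",
    "fit_pulse_model",
    "model_selection",
    "GenerationTimeFit",
    "generation_time_fit",
    "admixture_calendar_year",
    "bootstrap_ci",
    "SexBias",
    "sex_bias_solve",
    "ancestry_difference_test",
]


# ---------------------------------------------------------------------------
# Pulse-model fitting
# ---------------------------------------------------------------------------

@dataclass
class PulseTractResults:
    """Best-fit admixture history for one model family."""

    model: "PulseTractModel"
    family: str
    times: np.ndarray            # generations, oldest event first
    splits: np.ndarray
    pulse_model: PulseModel
    loglik: float
    k: int
    n_points: int
    expected: dict               # ancestry -> expected counts (all bins)
    converged: bool
    bootstrap: pd.DataFrame | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n_points) - 2.0 * self.loglik

    @property
    def params(self) -> dict:
        out = {f"t{i + 1}": t for i, t in enumerate(self.times)}
        out.update({f"split{i + 1}": s for i, s in enumerate(self.splits)})
        return out

    def admixture_years(self, mean_birth_year: float, tau: float) -> dict:
        """Calendar year of each event via T = T_s - (g - 1) tau."""
        return {
            f"t{i + 1}": admixture_calendar_year(mean_birth_year, g, tau)
            for i, g in enumerate(self.times)
        }

    def summary(self) -> str:
        lines = [
            f"Pulse admixture fit: family {self.family}",
            "=" * 40,
            f"  log-likelihood : {self.loglik:.3f}",
            f"  free params k  : {self.k}",
            f"  n data points  : {self.n_points}",
            f"  AIC            : {self.aic:.3f}",
            f"  BIC            : {self.bic:.3f}",
        ]
        for name, val in self.params.items():
            line = f"  {name:<14} : {val:.3f}"
            if self.bootstrap is not None and name in self.bootstrap.columns:
                lo, hi = np.percentile(self.bootstrap[name], [2.5, 97.5])
                line += f"  (95% CI [{lo:.2f}, {hi:.2f}])"
            lines.append(line)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed tract-length counts (dots) against model expectations
        (lines), log scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.model.hist
        mids = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        for anc in hist.ancestries:
            pts = ax.plot(mids, hist.counts[anc], "o", label=f"{anc} observed")
            if anc in self.expected:
                ax.plot(mids, self.expected[anc], "-",
                        color=pts[0].get_color(), label=f"{anc} model")
        ax.set_yscale("log")
        ax.set_xlabel("tract length (cM)")
        ax.set_ylabel("tract count")
        ax.legend()
        return ax


class PulseTractModel:
    """Poisson likelihood of a tract-length histogram under a pulse family.

    Parameters
    ----------
    hist : TractHistogram
        Observed counts; its ``excluded`` mask removes short-tract bins from
        the objective.
    family : str
        Model nomenclature string (``pp``, ``pp_xp``, ...).
    totals : dict
        Present-day ancestry proportions, held fixed during optimisation.
    genome : GenomeMap, optional
    """

    def __init__(self, hist: TractHistogram, family: str, totals: dict,
                 genome: GenomeMap | None = None, labels=None):
        self.hist = hist
        self.family = family
        self.masks = _parse_family(family)
        self.totals = {str(k): float(v) for k, v in totals.items()}
        self.genome = genome if genome is not None else default_genome_map()
        if labels is None:
            labels = tuple(self.totals)
        self.labels = tuple(labels)
        if len(self.labels) != len(self.masks[0]):
            raise ValueError(
                f"family {family!r} has {len(self.masks[0])} populations, "
                f"labels {self.labels}"
            )
        positive = [l for l in self.labels if self.totals.get(l, 0.0) > 0]
        if len(positive) < 2:
            raise ValueError(
                "non-identifiable: tract timing needs at least two ancestries "
                f"with positive totals, got {positive}"
            )
        self.n_events = len(self.masks)
        self.n_splits = n_free_parameters(family) - self.n_events
        self._fit_ancestries = [
            a for a in self.labels if a in hist.counts
        ]
        if not self._fit_ancestries:
            raise ValueError("histogram has no counts for any model ancestry")
        self._use = ~hist.excluded
        if not self._use.any():
            raise ValueError("all histogram bins are excluded from fitting")

    # -- likelihood --------------------------------------------------------
    def _build(self, times, splits) -> PulseModel:
        return PulseModel.from_family(
            self.family, self.labels, times, self.totals, splits
        )

    def loglike(self, times, splits=()) -> float:
        """Poisson log-likelihood over non-excluded bins (up to the
        data-dependent constant sum log(count!))."""
        try:
            pm = self._build(times, splits)
        except ValueError:
            return -np.inf
        expected = expected_tract_histogram(
            pm, self.genome, self.hist.n_haplotypes, self.hist.bin_edges,
            ancestries=self._fit_ancestries,
        )
        ll = 0.0
        for anc in self._fit_ancestries:
            lam = np.maximum(expected[anc][self._use], 1e-12)
            obs = self.hist.counts[anc][self._use]
            ll += float(np.sum(obs * np.log(lam) - lam))
        return ll

    def _theta_loglike(self, theta) -> float:
        times = np.asarray(theta[: self.n_events], dtype=float)
        splits = np.asarray(theta[self.n_events:], dtype=float)
        if np.any(np.diff(times) >= -1e-9) and self.n_events > 1:
            return -np.inf
        if np.any(times < 1.0) or np.any((splits < 0) | (splits > 1)):
            return -np.inf
        return self.loglike(times, splits)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        time_grid=None,
        split_grid=None,
        maxiter: int = 600,
    ) -> PulseTractResults:
        """Brute-force grid search over event times (and relative
        contributions) followed by Nelder-Mead local refinement from the
        best grid point.  Deterministic.
        """
        if time_grid is None:
            step = 0.25 if self.n_events == 1 else 1.0
            time_grid = np.arange(1.0, 20.0 + step / 2, step)
        if split_grid is None:
            split_grid = (
                np.arange(0.05, 0.96, 0.05) if self.n_events == 1
                else np.arange(0.1, 0.91, 0.1)
            )

        best = (-np.inf, None)
        time_combos = itertools.combinations(sorted(time_grid, reverse=True),
                                             self.n_events)
        split_combos = (
            [()] if self.n_splits == 0
            else list(itertools.product(split_grid, repeat=self.n_splits))
        )
        for times in time_combos:
            for splits in split_combos:
                ll = self._theta_loglike(np.r_[times, splits])
                if ll > best[0]:
                    best = (ll, np.r_[times, splits])
        if best[1] is None or not np.isfinite(best[0]):
            raise RuntimeError("grid search found no valid parameter point")

        res = optimize.minimize(
            lambda th: -self._theta_loglike(th), best[1], method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7},
        )
        theta = res.x if np.isfinite(res.fun) and -res.fun >= best[0] else best[1]
        ll = self._theta_loglike(theta)
        times = np.asarray(theta[: self.n_events], dtype=float)
        splits = np.asarray(theta[self.n_events:], dtype=float)
        pm = self._build(times, splits)
        expected = expected_tract_histogram(
            pm, self.genome, self.hist.n_haplotypes, self.hist.bin_edges,
            ancestries=self._fit_ancestries,
        )
        n_points = int(self._use.sum()) * len(self._fit_ancestries)
        logger.info(
            "pulse fit %s: loglik %.2f at times %s", self.family, ll,
            np.round(times, 3),
        )
        return PulseTractResults(
            model=self, family=self.family, times=times, splits=splits,
            pulse_model=pm, loglik=ll, k=n_free_parameters(self.family),
            n_points=n_points, expected=expected,
            converged=bool(res.success or -res.fun <= best[0]),
        )


def fit_pulse_model(
    hist: TractHistogram, family: str, totals: dict,
    genome: GenomeMap | None = None, **fit_kwargs
) -> PulseTractResults:
    """Functional wrapper around :class:`PulseTractModel`."""
    return PulseTractModel(hist, family, totals, genome=genome).fit(**fit_kwargs)


def model_selection(fits, n_points: int | None = None) -> pd.DataFrame:
    """Compare fitted families by AIC (2k - 2 loglik) and BIC
    (k ln n - 2 loglik).

    All fits must describe the same data; ``n_points`` overrides the number
    of data points (one per bin and per population) when given.
    """
    rows = []
    for fit in fits:
        n = n_points if n_points is not None else fit.n_points
        rows.append(
            {
                "family": fit.family,
                "k": fit.k,
                "loglik": fit.loglik,
                "aic": 2.0 * fit.k - 2.0 * fit.loglik,
                "bic": fit.k * math.log(n) - 2.0 * fit.loglik,
                "n_points": n,
            }
        )
    df = pd.DataFrame(rows).set_index("family")
    df["aic_preferred"] = df["aic"] == df["aic"].min()
    df["bic_preferred"] = df["bic"] == df["bic"].min()
    return df


# ---------------------------------------------------------------------------
# Generation-time calibration and calendar years
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationTimeFit:
    """Least-squares calibration of generation time from birth-year groups.

    Individuals born tau years earlier are one generation closer to the
    onset of admixture, so regressing inferred admixture time g on mean
    birth year gives slope -1/tau.
    """

    tau: float
    r_squared: float
    slope: float
    intercept: float
    n_groups: int
    degenerate: bool = False


def generation_time_fit(birth_year_groups) -> GenerationTimeFit:
    """Fit g ~ birth year by ordinary least squares; tau = 1/slope.

    With a fixed admixture-onset year, g = 1 + (T_s - T_onset)/tau, so the
    inferred admixture time grows by one generation per tau years of birth
    year (individuals born tau years earlier are one generation closer to
    the onset).  ``birth_year_groups`` is a sequence of (mean birth year,
    fitted g) pairs, one per birth-year group (at least 2; exactly 2 is
    flagged as a degenerate exact interpolation).  A non-positive slope
    contradicts the model and raises.
    """
    pts = np.asarray(list(birth_year_groups), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (birth year, g) groups")
    years, gs = pts[:, 0], pts[:, 1]
    model = sm.OLS(gs, sm.add_constant(years))
    res = model.fit()
    intercept, slope = res.params
    if slope <= 0:
        raise ValueError(
            f"non-positive slope {slope:.4g}: inferred admixture time does "
            "not grow with birth year, contradicting a fixed admixture onset"
        )
    r2 = float(res.rsquared) if pts.shape[0] > 2 else 1.0
    return GenerationTimeFit(
        tau=float(1.0 / slope), r_squared=r2, slope=float(slope),
        intercept=float(intercept), n_groups=pts.shape[0],
        degenerate=pts.shape[0] == 2,
    )


def admixture_calendar_year(mean_birth_year: float, g: float, tau: float) -> float:
    """Calendar year of birth of the first admixed generation:
    T = T_s - (g - 1) * tau.

    ``g = 1`` (parents are founders) gives the mean sampling birth year
    itself.  Returns the unrounded year; rounding to an integer year is a
    reporting choice.
    """
    if g < 1:
        raise ValueError(f"admixture time g = {g} must be >= 1 generation")
    return float(mean_birth_year - (g - 1.0) * tau)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    procedure,
    cohort,
    reps: int = 100,
    seed=None,
    alpha: float = 0.05,
):
    """Percentile bootstrap CIs by resampling individuals with replacement.

    ``procedure`` maps a resampled list of individuals (elements of
    ``cohort``) to a scalar or a dict of named parameters.  Failing
    replicates are dropped with a warning count.  Returns a dict
    ``name -> (lo, hi)`` (name ``"value"`` for scalar procedures) with the
    replicate table attached as ``.draws`` and failures as ``.n_failed``.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    draws = []
    n_failed = 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        sample = [cohort[i] for i in idx]
        try:
            out = procedure(sample)
        except Exception as exc:  # noqa: BLE001 - replicate failures reported
            n_failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        if not isinstance(out, dict):
            out = {"value": out}
        draws.append(out)
    if not draws:
        raise RuntimeError(f"all {reps} bootstrap replicates failed")
    if n_failed:
        logger.warning("%d of %d bootstrap replicates failed", n_failed, reps)
    table = pd.DataFrame(draws)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)

    class _CIDict(dict):
        pass

    out = _CIDict()
    for col in table.columns:
        lo, hi = np.percentile(table[col].astype(float), [lo_q, hi_q])
        out[col] = (float(lo), float(hi))
    out.draws = table
    out.n_failed = n_failed
    return out


# ---------------------------------------------------------------------------
# Sex-biased contributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexBias:
    """Per-ancestry male (m) and female (f) contributor fractions under a
    single-pulse model: autosomes carry (m + f)/2, the X carries
    (m + 2 f)/3 of each ancestry."""

    male: dict
    female: dict
    residual: float

    def __post_init__(self):
        for d in (self.male, self.female):
            for anc, v in d.items():
                if not -1e-9 <= v <= 1 + 1e-9:
                    raise ValueError(f"{anc}: fraction {v} outside [0, 1]")


def sex_bias_solve(autosomal: dict, x_chromosome: dict) -> SexBias:
    """Solve male/female contributor fractions from autosomal and
    X-chromosome ancestry proportions.

    For each ancestry the single-pulse model gives a = (m + f)/2 and
    x = (m + 2 f)/3; the system is solved jointly across ancestries by
    constrained least squares with m, f in [0, 1] per ancestry (and, when
    the supplied proportions form a full simplex, sum-to-one constraints on
    the male and female vectors).  With a single ancestry supplied and an
    interior optimum this reduces to the exact 2x2 solve m = 4a - 3x,
    f = 3x - 2a; a negative unconstrained solution is pinned to the bound.
    """
    ancestries = list(autosomal)
    if set(x_chromosome) != set(ancestries):
        raise ValueError("autosomal and X ancestry sets differ")
    a = np.array([autosomal[k] for k in ancestries], dtype=float)
    x = np.array([x_chromosome[k] for k in ancestries], dtype=float)
    if ((a < 0) | (a > 1) | (x < 0) | (x > 1)).any():
        raise ValueError("ancestry proportions must lie in [0, 1]")
    p = len(ancestries)
    full_simplex = abs(a.sum() - 1.0) < 1e-3 and abs(x.sum() - 1.0) < 1e-3

    def objective(theta):
        m, f = theta[:p], theta[p:]
        return np.sum((a - (m + f) / 2.0) ** 2) + np.sum(
            (x - (m + 2.0 * f) / 3.0) ** 2
        )

    theta0 = np.r_[a, a]
    constraints = []
    if full_simplex:
        constraints = [
            {"type": "eq", "fun": lambda th: th[:p].sum() - 1.0},
            {"type": "eq", "fun": lambda th: th[p:].sum() - 1.0},
        ]
    res = optimize.minimize(
        objective, theta0, method="SLSQP", bounds=[(0.0, 1.0)] * (2 * p),
        constraints=constraints, options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise ValueError(
            f"sex-bias solve failed ({res.message}); residual {res.fun:.3g} "
            f"for a={dict(zip(ancestries, a))}, x={dict(zip(ancestries, x))}"
        )
    m, f = res.x[:p], res.x[p:]
    return SexBias(
        male={k: float(np.clip(v, 0, 1)) for k, v in zip(ancestries, m)},
        female={k: float(np.clip(v, 0, 1)) for k, v in zip(ancestries, f)},
        residual=float(res.fun),
    )


# ---------------------------------------------------------------------------
# Ancestry-difference bootstrap test
# ---------------------------------------------------------------------------

def ancestry_difference_test(group_a, group_b, reps: int = 10_000, seed=None):
    """Two-sample bootstrap test of a difference in mean ancestry between
    disjoint sets of individuals.

    Both groups are resampled with replacement; the two-sided p-value is
    twice the fraction of resampled mean differences crossing zero, capped
    at 1.  Returns (p_value, observed difference).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    if a.size == 1 or b.size == 1:
        logger.warning("singleton group: bootstrap p-value will be very wide")
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    idx_a = rng.integers(0, a.size, size=(reps, a.size))
    idx_b = rng.integers(0, b.size, size=(reps, b.size))
    diffs = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    if obs > 0:
        frac = np.mean(diffs <= 0)
    elif obs < 0:
        frac = np.mean(diffs >= 0)
    else:
        frac = 0.5
    return min(1.0, 2.0 * float(frac)), float(obs)
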
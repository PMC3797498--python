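"""Individual-based null models for species turnover.

The null model assembles each plot by randomly sampling individuals from the
regional species pool (all individuals observed across plots), preserving the
relative abundance of each species in the pool and the total number of
individuals in each plot. Two randomization schemes are provided:

``without_replacement``
    A permutation of the pooled individuals among plots: every plot keeps its
    observed individual total and every species keeps its exact pool
    abundance (a random contingency table with fixed margins).

``with_replacement``
    Each plot draws its individual total from a multinomial with the pool's
    relative abundances, so species totals are preserved in expectation only.

The standardized turnover deviation for a plot pair is the standardized
effect size (observed Bray-Curtis minus the null mean, divided by the null
sample SD). Positive values mean more species turnover than random assembly
from the pool predicts; negative values mean less.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from ecoassembly.data import CommunityMatrix, ValidationError
from ecoassembly.distance import DistanceMatrix, bray_curtis, from_condensed

SCHEMES = ("without_replacement", "with_replacement")

#: null SDs below this are treated as degenerate and the pair is excluded
DEGENERATE_SD = 1e-12


@dataclass(frozen=True)
class NullModelResult:
    """Observed, null-mean, null-SD and per-pair deviation (SES) matrices."""

    observed: DistanceMatrix
    null_mean: np.ndarray
    null_sd: np.ndarray
    deviation: DistanceMatrix  # kind="deviation"; NaN for degenerate pairs
    per_iteration_mean: np.ndarray  # mean Bray-Curtis of each null iteration
    n_iterations: int
    seed: int
    scheme: str

    @property
    def valid_pairs(self) -> np.ndarray:
        """Condensed deviation values for pairs with a non-degenerate null SD."""
        vec = self.deviation.condensed
        return vec[np.isfinite(vec)]

    @property
    def n_degenerate(self) -> int:
        vec = self.deviation.condensed
        return int(np.sum(~np.isfinite(vec)))

    @property
    def mean_deviation(self) -> float:
        return float(self.valid_pairs.mean())

    @property
    def wholly_degenerate(self) -> bool:
        return self.valid_pairs.size == 0

    def summary(self) -> dict:
        return {
            "mean_deviation": None if self.wholly_degenerate else self.mean_deviation,
            "n_pairs": int(self.deviation.condensed.size),
            "n_degenerate_pairs": self.n_degenerate,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "scheme": self.scheme,
        }


@dataclass(frozen=True)
class DeviationTest:
    """One-sample Student's t-test of the mean turnover deviation against 0."""

    mean_deviation: float
    t_statistic: float
    df: int
    p_value: float


def _rng_for_iteration(seed: int, iteration: int) -> np.random.Generator:
    # each iteration's matrix is a pure function of (seed, i)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def randomize_community(
    comm: CommunityMatrix,
    scheme: str = "without_replacement",
    rng_seed: int | np.random.Generator = 0,
) -> CommunityMatrix:
    """Draw one randomized community under the species-pool null model."""
    counts = _randomize_counts(
        comm.counts.to_numpy(),
        scheme,
        rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed),
    )
    return CommunityMatrix(
        pd.DataFrame(counts, index=comm.counts.index, columns=comm.counts.columns)
    )


def _randomize_counts(counts: np.ndarray, scheme: str, rng: np.random.Generator) -> np.ndarray:
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown randomization scheme {scheme!r}")
    plot_totals = counts.sum(axis=1)
    species_totals = counts.sum(axis=0)
    total = int(species_totals.sum())
    if total == 0:
        raise ValidationError("empty community")
    if total < counts.shape[0]:
        raise ValidationError("fewer individuals than plots")
    n_plots, n_species = counts.shape
    if scheme == "without_replacement":
        pool = np.repeat(np.arange(n_species), species_totals)
        rng.shuffle(pool)
        out = np.empty((n_plots, n_species), dtype=np.int64)
        edges = np.concatenate([[0], np.cumsum(plot_totals)])
        for j in range(n_plots):
            out[j] = np.bincount(pool[edges[j] : edges[j + 1]], minlength=n_species)
        return out
    p = species_totals / total
    return rng.multinomial(plot_totals, p)


def _bray_curtis_condensed(counts: np.ndarray) -> np.ndarray:
    return pdist(counts.astype(float), metric="braycurtis")


def turnover_deviation(
    comm: CommunityMatrix,
    n_iter: int = 1000,
    scheme: str = "without_replacement",
    seed: int = 0,
) -> NullModelResult:
    """Per-pair standardized turnover deviation from ``n_iter`` null draws.

    For each plot pair the null mean and sample SD of Bray-Curtis
    dissimilarity are estimated over ``n_iter`` randomized communities, and
    the deviation is (observed - null mean) / null SD. Pairs whose null SD is
    numerically zero are set to NaN, counted, and excluded from downstream
    tests rather than producing infinities.
    """
    if n_iter < 2:
        raise ValidationError("n_iter must be >= 2")
    observed = bray_curtis(comm)
    counts = comm.counts.to_numpy()
    m = counts.shape[0] * (counts.shape[0] - 1) // 2
    null_bc = np.empty((n_iter, m))
    for i in range(n_iter):
        rng = _rng_for_iteration(seed, i)
        null_bc[i] = _bray_curtis_condensed(_randomize_counts(counts, scheme, rng))
    iter_means = null_bc.mean(axis=1)
    mean = null_bc.mean(axis=0)
    sd = null_bc.std(axis=0, ddof=1)
    obs = observed.condensed
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(sd > DEGENERATE_SD, (obs - mean) / sd, np.nan)
    ids = tuple(comm.plot_ids)
    return NullModelResult(
        observed=observed,
        null_mean=from_condensed(mean, ids, "euclidean").values,
        null_sd=from_condensed(sd, ids, "euclidean").values,
        deviation=from_condensed(dev, ids, "deviation"),
        per_iteration_mean=iter_means,
        n_iterations=n_iter,
        seed=seed,
        scheme=scheme,
    )


def test_mean_deviation(result: NullModelResult) -> DeviationTest:
    """Two-sided one-sample t-test of the condensed deviations against zero.

    The test treats plot pairs as independent observations, which overstates
    the effective sample size because pairs share plots; see the methods
    documentation for the calibration of this convention.
    """
    vals = result.valid_pairs
    if vals.size < 2:
        raise ValidationError("need at least 2 non-degenerate pairs for the t-test")
    if np.ptp(vals) == 0:
        raise ValidationError("deviation values have zero variance; t undefined")
    t = stats.ttest_1samp(vals, popmean=0.0)
    return DeviationTest(
        mean_deviation=float(vals.mean()),
        t_statistic=float(t.statistic),
        df=int(vals.size - 1),
        p_value=float(t.pvalue),
    )
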
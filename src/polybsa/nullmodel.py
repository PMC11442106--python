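"""Polysomic F1 segregation model and simulation-based null for the ΔSNP-index.

Model
-----
An autopolyploid with even ploidy 2m transmits m of its 2m homologs to each
gamete.  Under polysomic inheritance with random bivalent pairing (no double
reduction), the number of allele-bearing homologs in a gamete from a parent
carrying the allele on ``d`` homologs is hypergeometric: choose m homologs
out of 2m, d of which are marked.  For a hexaploid simplex parent
(2m = 6, d = 1) this reproduces the 1:1 presence/absence segregation of the
allele among progeny, hence the expected allele frequency of plexity/(2·2m)
= 1/12 ~ 0.083 in an unselected bulk.

The no-QTL null distribution of the observed ΔSNP-index at a site is
obtained by Monte Carlo: each bulk member's allele dose is drawn i.i.d. from
the progeny dose distribution, the bulk allele frequency is the dose sum
over ploidy x bulk size, and the observed bulk SNP-index is a binomial read
draw at the site's depth.  Confidence thresholds are empirical percentiles
of the simulated Δ = index(high bulk) − index(low bulk); per-variant P
values are two-sided empirical tail probabilities with the (r+1)/(N+1)
floor, so -log10 P is always finite.

An exact-enumeration oracle (:func:`exact_bulk_index_pmf`) is provided for
small bulk sizes and depths to validate the simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "SegregationModel",
    "NullDistribution",
    "PvalueResult",
    "NullModel",
    "gamete_dose_pmf",
    "progeny_dose_pmf",
    "simulate_null",
    "exact_bulk_index_pmf",
    "p_value",
]


def gamete_dose_pmf(ploidy: int, parent_dose: int) -> np.ndarray:
    """Distribution of allele dose in a gamete from a parent with ``parent_dose`` copies.

    Hypergeometric draw of ploidy/2 homologs from ploidy, ``parent_dose`` of
    which carry the allele.  Support is 0..parent_dose (doses above ploidy/2
    have zero mass and are trimmed at parent_dose for convenience).
    """
    if ploidy % 2:
        raise ValueError("ploidy must be even for bivalent polysomic segregation")
    if not 0 <= parent_dose <= ploidy:
        raise ValueError(f"parent_dose must be in [0, {ploidy}]")
    k = np.arange(parent_dose + 1)
    pmf = stats.hypergeom.pmf(k, ploidy, parent_dose, ploidy // 2)
    return pmf / pmf.sum()


def progeny_dose_pmf(ploidy: int, plexity: int) -> np.ndarray:
    """Allele-dose distribution of an F1 progeny from donor (plexity) x nulliplex.

    The nulliplex gamete contributes dose 0, so this equals
    :func:`gamete_dose_pmf`.  Expected progeny allele frequency is
    plexity / (2 * ploidy).
    """
    return gamete_dose_pmf(ploidy, plexity)


@dataclass(frozen=True)
class SegregationModel:
    """Polysomic donor x nulliplex segregation at one plexity."""

    ploidy: int = 6
    plexity: int = 1

    @cached_property
    def gamete_pmf(self) -> np.ndarray:
        return gamete_dose_pmf(self.ploidy, self.plexity)

    @cached_property
    def progeny_pmf(self) -> np.ndarray:
        return progeny_dose_pmf(self.ploidy, self.plexity)

    @property
    def doses(self) -> np.ndarray:
        return np.arange(self.plexity + 1)

    @property
    def expected_allele_frequency(self) -> float:
        """Mean allele frequency among unselected progeny: plexity/(2*ploidy)."""
        return float(self.progeny_pmf @ self.doses) / self.ploidy

    @property
    def donor_parent_index(self) -> float:
        """Expected alt-read fraction of the donor parent: plexity/ploidy."""
        return self.plexity / self.ploidy

    def enriched_bulk_index(self) -> float:
        """Expected bulk index when every member carries the allele.

        E[dose | dose > 0] / ploidy; the ceiling the enriched bulk's
        SNP-index approaches under a fully penetrant QTL (1/6 for simplex).
        """
        pmf = self.progeny_pmf
        carrier = pmf[1:] / pmf[1:].sum()
        return float(carrier @ self.doses[1:]) / self.ploidy


@dataclass
class NullDistribution:
    """Empirical no-QTL distribution of Δ at one (depth_low, depth_high) pair."""

    n_low: int
    n_high: int
    depth_low: int
    depth_high: int
    replicates: int
    delta_samples: np.ndarray
    thresholds: Mapping[float, tuple[float, float]]

    def __post_init__(self) -> None:
        lo95, hi95 = self.thresholds[0.95]
        lo99, hi99 = self.thresholds[0.99]
        assert lo99 <= lo95 <= hi95 <= hi99, "confidence intervals must nest"

    @cached_property
    def _sorted_abs(self) -> np.ndarray:
        return np.sort(np.abs(self.delta_samples))

    def p_value(self, delta_observed: float) -> "PvalueResult":
        n = self.replicates
        ge = n - np.searchsorted(self._sorted_abs, abs(delta_observed), side="left")
        p = (1 + ge) / (n + 1)
        lo95, hi95 = self.thresholds[0.95]
        lo99, hi99 = self.thresholds[0.99]
        sig95 = bool(delta_observed < lo95 or delta_observed > hi95)
        sig99 = bool(delta_observed < lo99 or delta_observed > hi99)
        return PvalueResult(p=float(p), sig95=sig95, sig99=sig99)

    def p_values(self, delta: np.ndarray):
        """Vectorised two-sided empirical P values and significance flags."""
        delta = np.asarray(delta, dtype=float)
        n = self.replicates
        ge = n - np.searchsorted(self._sorted_abs, np.abs(delta), side="left")
        p = (1 + ge) / (n + 1)
        lo95, hi95 = self.thresholds[0.95]
        lo99, hi99 = self.thresholds[0.99]
        sig95 = (delta < lo95) | (delta > hi95)
        sig99 = (delta < lo99) | (delta > hi99)
        return p, sig95, sig99


@dataclass(frozen=True)
class PvalueResult:
    p: float
    sig95: bool
    sig99: bool

    def __post_init__(self) -> None:
        if self.sig99 and not self.sig95:
            raise ValueError("sig99 implies sig95")


def _simulate_bulk_index(
    rng: np.random.Generator,
    n: int,
    depth: int,
    model: SegregationModel,
    replicates: int,
) -> np.ndarray:
    comp = rng.multinomial(n, model.progeny_pmf, size=replicates)
    freq = (comp @ model.doses) / (model.ploidy * n)
    return rng.binomial(depth, freq) / depth


def simulate_bulk_index(
    n: int,
    depth: int,
    model: SegregationModel,
    replicates: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Monte-Carlo sample of one bulk's observed SNP-index under no selection."""
    rng = np.random.default_rng(seed)
    return _simulate_bulk_index(rng, n, depth, model, replicates)


def simulate_null(
    n_low: int,
    n_high: int,
    depth_low: int,
    depth_high: int,
    model: SegregationModel,
    replicates: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Monte-Carlo null of Δ = idx(high) − idx(low) at the given depths.

    Per replicate each bulk member's dose is drawn i.i.d. from the progeny
    dose distribution and reads are a binomial draw at the bulk frequency.
    Thresholds are the empirical 2.5/97.5 (95%) and 0.5/99.5 (99%)
    percentiles.
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("bulk sizes must be >= 1")
    if depth_low < 1 or depth_high < 1:
        raise ValueError("depths must be >= 1")
    if replicates < 1000:
        warnings.warn(
            f"replicates={replicates} < 1000: confidence thresholds will be unstable",
            stacklevel=2,
        )
    if rng is None:
        if seed is not None and not isinstance(seed, (int, np.integer, np.random.SeedSequence)):
            raise TypeError(f"seed must be an int or SeedSequence, got {type(seed).__name__}")
        rng = np.random.default_rng(seed)
    idx_low = _simulate_bulk_index(rng, n_low, depth_low, model, replicates)
    idx_high = _simulate_bulk_index(rng, n_high, depth_high, model, replicates)
    delta = idx_high - idx_low
    q = np.quantile(delta, [0.005, 0.025, 0.975, 0.995])
    thresholds = {0.95: (float(q[1]), float(q[2])), 0.99: (float(q[0]), float(q[3]))}
    return NullDistribution(
        n_low=n_low, n_high=n_high, depth_low=depth_low, depth_high=depth_high,
        replicates=replicates, delta_samples=delta, thresholds=thresholds,
    )


def exact_bulk_index_pmf(
    n: int, depth: int, model: SegregationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the observed bulk SNP-index (enumeration oracle).

    Sums over the bulk dose-sum distribution (n-fold convolution of the
    progeny dose pmf) times binomial read outcomes at the bulk frequency.
    Returns (support = k/depth for k in 0..depth, probabilities).  Guarded so
    the enumeration stays below ~10^7 combinations.
    """
    if n < 1 or depth < 1:
        raise ValueError("n and depth must be >= 1")
    n_sums = n * model.plexity + 1
    if n_sums * (depth + 1) > 10_000_000:
        raise ValueError(
            "enumeration too large (> 1e7 combinations); use simulate_null instead"
        )
    dose_sum_pmf = np.array([1.0])
    for _ in range(n):
        dose_sum_pmf = np.convolve(dose_sum_pmf, model.progeny_pmf)
    sums = np.arange(dose_sum_pmf.size)
    freqs = sums / (model.ploidy * n)
    k = np.arange(depth + 1)
    # rows: dose sums, cols: read counts
    read_pmf = stats.binom.pmf(k[None, :], depth, freqs[:, None])
    probs = dose_sum_pmf @ read_pmf
    probs /= probs.sum()
    return k / depth, probs


def p_value(delta_observed: float, nulldist: NullDistribution) -> PvalueResult:
    """Two-sided empirical P value of an observed Δ against a simulated null."""
    return nulldist.p_value(delta_observed)


class NullModel:
    """Per-depth-pair null distributions with deterministic seeding and caching.

    The stream for pair (dl, dh) is derived from the global seed via
    ``SeedSequence(seed, spawn_key=(dl, dh))`` so results are independent of
    evaluation order.  :meth:`score` computes pair groups on the fly and
    retains only thresholds, keeping memory bounded on dense scans;
    :meth:`get` returns (and caches) the full distribution for one pair.
    """

    def __init__(
        self,
        model: SegregationModel,
        n_low: int,
        n_high: int,
        replicates: int = 10_000,
        seed: int = 0,
    ) -> None:
        self.model = model
        self.n_low = int(n_low)
        self.n_high = int(n_high)
        self.replicates = int(replicates)
        self.seed = int(seed)
        self._cache: dict[tuple[int, int], NullDistribution] = {}
        self._threshold_cache: dict[tuple[int, int], Mapping[float, tuple[float, float]]] = {}

    def _rng(self, depth_low: int, depth_high: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(depth_low, depth_high))
        return np.random.default_rng(ss)

    def _simulate(self, depth_low: int, depth_high: int) -> NullDistribution:
        return simulate_null(
            self.n_low, self.n_high, depth_low, depth_high, self.model,
            replicates=self.replicates, rng=self._rng(depth_low, depth_high),
        )

    def get(self, depth_low: int, depth_high: int) -> NullDistribution:
        key = (int(depth_low), int(depth_high))
        if key not in self._cache:
            self._cache[key] = self._simulate(*key)
            self._threshold_cache[key] = self._cache[key].thresholds
        return self._cache[key]

    def thresholds(self, depth_low: int, depth_high: int) -> Mapping[float, tuple[float, float]]:
        key = (int(depth_low), int(depth_high))
        if key not in self._threshold_cache:
            nd = self._simulate(*key)
            self._threshold_cache[key] = nd.thresholds
        return self._threshold_cache[key]

    def score(
        self,
        delta: np.ndarray,
        depth_low: np.ndarray,
        depth_high: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """P values and significance flags for arrays of variants.

        Variants are grouped by their exact (depth_low, depth_high) pair;
        one null simulation serves each group.
        """
        delta = np.asarray(delta, dtype=float)
        dl = np.asarray(depth_low, dtype=np.int64)
        dh = np.asarray(depth_high, dtype=np.int64)
        p = np.empty(delta.shape, dtype=float)
        sig95 = np.empty(delta.shape, dtype=bool)
        sig99 = np.empty(delta.shape, dtype=bool)
        pairs = np.stack([dl, dh], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        for i, (a, b) in enumerate(uniq):
            mask = inverse == i
            key = (int(a), int(b))
            nd = self._cache.get(key)
            if nd is None:
                nd = self._simulate(*key)
                self._threshold_cache[key] = nd.thresholds
            p[mask], sig95[mask], sig99[mask] = nd.p_values(delta[mask])
        return p, sig95, sig99
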
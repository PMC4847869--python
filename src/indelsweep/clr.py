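"""SweepFinder-style composite likelihood ratio scan.

The scan contrasts, at each point of a genomic grid, the composite
likelihood of the observed derived-allele counts under a background
site frequency spectrum (SFS, invariant classes included) against a
sweep-distorted spectrum. The distortion follows the hitchhiking-escape
model: at distance d from the swept site a lineage escapes the sweep
with probability p_e = 1 - exp(-alpha * d); the B escaping lineages
retain background variation while the n - B swept lineages collapse to
a single ancestor, whose allele is then expanded back to n - B copies.
The per-bp intensity alpha absorbs the regional recombination rate and
the strength of selection.

Significance thresholds come from neutral coalescent simulation: the
maximum scan statistic of each replicate forms the null distribution
and its 95th percentile the 5% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .coalescent import (
    DemographicModel,
    drop_mutations_fixed_s,
    drop_mutations_theta,
    simulate_genealogy,
)

_SMOOTH = 1.0  # pseudo-count added to empty SFS classes


@dataclass
class SiteFrequencySpectrum:
    """Distribution over derived-count classes 0..n (or minor classes).

    ``probs`` sums to one; unfolded spectra carry the invariant classes
    0 and n explicitly, folded spectra run over minor counts
    0..floor(n/2).
    """

    n: int
    probs: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (self.n // 2 + 1) if self.folded else (self.n + 1)
        if self.probs.shape != (expected,):
            raise ValueError(
                f"expected {expected} classes, got {self.probs.shape}"
            )
        if np.any(self.probs < 0):
            raise ValueError("negative class probability")
        total = self.probs.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(
        cls, counts: Sequence[float], folded: bool = False
    ) -> "SiteFrequencySpectrum":
        """Normalize class counts, smoothing empty classes by one pseudo-count."""
        counts = np.asarray(counts, dtype=float)
        if counts.sum() <= 0:
            raise ValueError("all-zero site counts")
        counts = np.where(counts == 0, _SMOOTH, counts)
        n = (counts.size - 1) if not folded else None
        if folded:
            raise NotImplementedError(
                "build unfolded and call .fold() for folded backgrounds"
            )
        return cls(n=n, probs=counts / counts.sum(), folded=False)

    def fold(self) -> "SiteFrequencySpectrum":
        """Collapse derived counts i and n-i onto minor counts."""
        if self.folded:
            return self
        half = self.n // 2 + 1
        probs = np.zeros(half)
        for i in range(self.n + 1):
            probs[min(i, self.n - i)] += self.probs[i]
        return SiteFrequencySpectrum(self.n, probs, folded=True)


def background_sfs(
    derived_counts: Sequence[int],
    n: int,
    weights: Sequence[float] | None = None,
) -> SiteFrequencySpectrum:
    """Empirical background SFS from per-site derived counts.

    Invariant sites enter as counts 0 and n; empty classes are smoothed
    with one pseudo-count before normalization.
    """
    counts = np.zeros(n + 1)
    derived_counts = np.asarray(derived_counts, dtype=int)
    if np.any((derived_counts < 0) | (derived_counts > n)):
        raise ValueError("derived counts outside 0..n")
    w = np.ones(len(derived_counts)) if weights is None else np.asarray(weights)
    np.add.at(counts, derived_counts, w)
    return SiteFrequencySpectrum.from_counts(counts)


def neutral_sfs(n: int, theta_per_site: float, L: int) -> SiteFrequencySpectrum:
    """Standard-neutral expectation: class i ~ theta/i, rest invariant."""
    counts = np.zeros(n + 1)
    for i in range(1, n):
        counts[i] = theta_per_site * L / i
    counts[0] = max(L - counts[1:].sum(), 0.0)
    return SiteFrequencySpectrum.from_counts(counts)


def _downsample_matrices(n: int) -> list[np.ndarray | None]:
    """D[m][j, i] = P(j derived in subsample of m | i derived in n)."""
    lc = gammaln(np.arange(n + 2))

    def logC(a, b):
        return lc[a + 1] - lc[b + 1] - lc[a - b + 1]

    mats: list[np.ndarray | None] = [None] * (n + 1)
    for m in range(1, n + 1):
        D = np.zeros((m + 1, n + 1))
        for i in range(n + 1):
            jmin = max(0, m - (n - i))
            jmax = min(i, m)
            for j in range(jmin, jmax + 1):
                D[j, i] = np.exp(
                    logC(i, j) + logC(n - i, m - j) - logC(n, m)
                )
        mats[m] = D
    return mats


class SweepSpectrumTransform:
    """Maps a background SFS to post-sweep spectra as a function of p_e."""

    def __init__(self, bg: SiteFrequencySpectrum):
        if bg.folded:
            raise ValueError("sweep transform requires an unfolded background")
        self.bg = bg
        self.n = bg.n
        self._down = _downsample_matrices(bg.n)
        # Q[m] = class distribution after downsampling bg to m samples
        self._q = [None] + [self._down[m] @ bg.probs for m in range(1, bg.n + 1)]

    def spectrum(self, p_e: float) -> np.ndarray:
        """Post-sweep class probabilities at escape probability *p_e*."""
        from scipy.stats import binom

        n = self.n
        out = np.zeros(n + 1)
        bprobs = binom.pmf(np.arange(n + 1), n, p_e)
        for B in range(n + 1):
            pb = bprobs[B]
            if pb == 0:
                continue
            if B == n:
                out += pb * self.bg.probs
                continue
            m = B + 1  # escapees plus the single swept ancestor
            q = self._q[m]
            j = np.arange(m + 1)
            # the collapsed lineage is one of the m; if it carries the
            # derived allele its count expands to n - B copies
            frac_derived = j / m
            contrib = np.zeros(n + 1)
            np.add.at(contrib, j + n - m, q * frac_derived)
            np.add.at(contrib, j, q * (1 - frac_derived))
            out += pb * contrib
        return out


def sweep_sfs(
    bg: SiteFrequencySpectrum, alpha: float, d: float
) -> SiteFrequencySpectrum:
    """Post-sweep SFS at per-bp intensity *alpha* and distance *d* bp."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p_e = 1.0 - np.exp(-alpha * max(d, 0.0))
    probs = SweepSpectrumTransform(bg).spectrum(p_e)
    return SiteFrequencySpectrum(bg.n, probs / probs.sum())


@dataclass
class CLRPoint:
    grid_pos: float
    lam: float
    alpha_hat: float
    significant: bool | None = None


@dataclass
class ThresholdCalibration:
    """Null distribution of per-replicate maximum scan statistics."""

    model_name: str
    reps: int
    max_lambdas: np.ndarray
    quantile: float = 0.95

    @property
    def threshold(self) -> float:
        return float(np.quantile(self.max_lambdas, self.quantile))


class ClrScanResults:
    """Fitted scan: one composite likelihood ratio per grid point."""

    def __init__(
        self,
        table: pd.DataFrame,
        model: "ClrSweepScan",
        threshold: float | None = None,
    ):
        self.table = table
        self.model = model
        self.threshold = threshold
        if threshold is not None:
            self.table = self.table.assign(
                significant=self.table["lambda"] > threshold
            )

    @property
    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lambda"].idxmax()]

    @property
    def peak_position(self) -> float:
        return float(self.peak["grid_pos"])

    @property
    def max_lambda(self) -> float:
        return float(self.peak["lambda"])

    @property
    def alpha_hat(self) -> float:
        """Sweep intensity at the scan maximum (per bp)."""
        return float(self.peak["alpha_hat"])

    def summary(self) -> str:
        lines = [
            "Composite likelihood ratio sweep scan",
            "=" * 48,
            f"grid points        {len(self.table)}",
            f"sites (weighted)   {self.model.total_weight:.0f}",
            f"sample size n      {self.model.bg.n}",
            f"peak position      {self.peak_position:.0f} bp",
            f"peak CLR (lambda)  {self.max_lambda:.3f}",
            f"alpha at peak      {self.alpha_hat:.3e} /bp",
        ]
        if self.threshold is not None:
            sig = bool(self.peak.get("significant", False))
            lines += [
                f"5% threshold       {self.threshold:.3f}",
                f"peak significant   {sig}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """CLR profile along the locus; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        ax.plot(self.table["grid_pos"], self.table["lambda"], "o-", ms=3)
        if self.threshold is not None:
            ax.axhline(self.threshold, color="k", lw=1, label="5% threshold")
            ax.legend(frameon=False)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("CLR statistic")
        return ax


class ClrSweepScan:
    """Composite likelihood ratio scan over a genomic interval.

    Parameters
    ----------
    positions
        Site positions in bp (SNPs and invariant sites alike).
    derived_counts
        Derived-allele count per site, 0..n (0 and n = invariant).
    bg
        Background SFS at the same sample size, unfolded with invariant
        classes (fold with ``folded=True`` when polarization is absent).
    grid_spacing
        Distance between scan grid points, bp.
    weights
        Optional per-site multiplicities (used to aggregate invariant
        sites onto a sparse lattice).
    alpha_range, n_alpha
        Log-spaced search grid for the sweep intensity (per bp),
        refined by golden-section around the grid optimum.
    n_pe_bins
        Escape-probability discretization: site likelihoods are looked
        up in a table of spectra precomputed on this many p_e values.
    """

    def __init__(
        self,
        positions: Sequence[float],
        derived_counts: Sequence[int],
        bg: SiteFrequencySpectrum,
        grid_spacing: float = 1000.0,
        weights: Sequence[float] | None = None,
        folded: bool = False,
        alpha_range: tuple[float, float] = (1e-6, 1e-1),
        n_alpha: int = 50,
        n_pe_bins: int = 128,
        span: tuple[float, float] | None = None,
    ):
        self.positions = np.asarray(positions, dtype=float)
        self.counts = np.asarray(derived_counts, dtype=int)
        if self.positions.size == 0:
            raise ValueError("empty site list")
        if self.positions.shape != self.counts.shape:
            raise ValueError("positions and counts differ in length")
        if np.any((self.counts < 0) | (self.counts > bg.n)):
            raise ValueError("derived counts outside 0..n")
        self.bg = bg
        self.folded = folded
        self.weights = (
            np.ones_like(self.positions)
            if weights is None
            else np.asarray(weights, dtype=float)
        )
        self.total_weight = float(self.weights.sum())
        self.grid_spacing = float(grid_spacing)
        self.alpha_range = alpha_range
        self.n_alpha = n_alpha
        lo, hi = span if span is not None else (
            self.positions.min(), self.positions.max()
        )
        self.grid = np.arange(lo, hi + 0.5 * grid_spacing, grid_spacing)

        # precompute spectra on a p_e lattice; likelihoods become lookups
        self._pe_grid = np.linspace(0.0, 1.0, n_pe_bins)
        transform = SweepSpectrumTransform(bg)
        spectra = np.stack([transform.spectrum(p) for p in self._pe_grid])
        spectra /= spectra.sum(axis=1, keepdims=True)
        bg_probs = bg.probs
        if folded:
            spectra = np.stack(
                [
                    SiteFrequencySpectrum(bg.n, s).fold().probs
                    for s in spectra
                ]
            )
            bg_probs = bg.fold().probs
            self.counts = np.minimum(self.counts, bg.n - self.counts)
        with np.errstate(divide="ignore"):
            self._log_spectra = np.log(spectra)
            self._log_bg = np.log(bg_probs)
        self._null_loglik = float(
            (self.weights * self._log_bg[self.counts]).sum()
        )

    def _loglik_many(self, grid_pos: float, alphas: np.ndarray) -> np.ndarray:
        """Composite log-likelihood for a vector of alpha values."""
        d = np.abs(self.positions - grid_pos)
        pe = 1.0 - np.exp(-np.outer(alphas, d))
        bins = np.rint(pe * (len(self._pe_grid) - 1)).astype(np.intp)
        return (self.weights * self._log_spectra[bins, self.counts]).sum(axis=1)

    def _loglik(self, grid_pos: float, alpha: float) -> float:
        return float(self._loglik_many(grid_pos, np.array([alpha]))[0])

    def _fit_point(self, grid_pos: float) -> tuple[float, float]:
        alphas = np.geomspace(*self.alpha_range, self.n_alpha)
        logliks = self._loglik_many(grid_pos, alphas)
        k = int(np.argmax(logliks))
        # golden-section refinement on log(alpha)
        lo = np.log(alphas[max(k - 1, 0)])
        hi = np.log(alphas[min(k + 1, len(alphas) - 1)])
        gr = (np.sqrt(5.0) - 1) / 2
        a, b = lo, hi
        c1 = b - gr * (b - a)
        c2 = a + gr * (b - a)
        f1 = self._loglik(grid_pos, np.exp(c1))
        f2 = self._loglik(grid_pos, np.exp(c2))
        for _ in range(12):
            if f1 < f2:
                a, c1, f1 = c1, c2, f2
                c2 = a + gr * (b - a)
                f2 = self._loglik(grid_pos, np.exp(c2))
            else:
                b, c2, f2 = c2, c1, f1
                c1 = b - gr * (b - a)
                f1 = self._loglik(grid_pos, np.exp(c1))
        best_ll = max(logliks[k], f1, f2)
        best_alpha = float(
            np.exp([np.log(alphas[k]), c1, c2][int(np.argmax([logliks[k], f1, f2]))])
        )
        lam = 2.0 * (best_ll - self._null_loglik)
        # the background is the alpha -> inf limit, so lambda >= 0 up to
        # discretization; clip the tiny negative residue
        return max(lam, 0.0), best_alpha

    def fit(self, threshold: float | None = None) -> ClrScanResults:
        rows = []
        for x in self.grid:
            lam, alpha_hat = self._fit_point(float(x))
            rows.append(
                {"grid_pos": float(x), "lambda": lam, "alpha_hat": alpha_hat}
            )
        return ClrScanResults(pd.DataFrame(rows), self, threshold=threshold)


def invariant_lattice(
    locus_length: float,
    n_invariant: float,
    n: int,
    spacing: float = 50.0,
    snp_positions: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Represent invariant sites as weighted lattice pseudo-sites.

    Spreads ``n_invariant`` ancestral-invariant sites (class 0) evenly
    over a lattice across the locus so scans stay cheap; returns
    (positions, counts, weights).
    """
    k = max(int(locus_length // spacing), 1)
    pos = (np.arange(k) + 0.5) * (locus_length / k)
    counts = np.zeros(k, dtype=int)
    weights = np.full(k, n_invariant / k)
    return pos, counts, weights


def calibrate_threshold(
    bg: SiteFrequencySpectrum,
    model: DemographicModel | None = None,
    locus_length: float = 6000.0,
    n: int | None = None,
    rho: float = 0.0,
    theta: float | None = None,
    fixed_s: int | None = None,
    reps: int = 10_000,
    seed: int | None = None,
    grid_spacing: float = 1000.0,
    quantile: float = 0.95,
    invariant_spacing: float = 50.0,
    **scan_kwargs,
) -> ThresholdCalibration:
    """Simulation-calibrated significance threshold for the scan.

    Per replicate a neutral locus is simulated under *model*, scanned
    against the SAME empirical background *bg* used for the data scan,
    and the maximum statistic recorded; the threshold is the
    ``quantile`` order statistic of those maxima.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if (theta is None) == (fixed_s is None):
        raise ValueError("specify exactly one of theta / fixed_s")
    n = n if n is not None else bg.n
    if n != bg.n:
        raise ValueError("sample size must match background SFS")
    model = model or DemographicModel.constant()
    rng = np.random.default_rng(seed)
    maxima = np.empty(reps)
    for r in range(reps):
        g = simulate_genealogy(n, model, rho=rho, rng=rng)
        if theta is not None:
            rep = drop_mutations_theta(g, theta, rng=rng)
        else:
            rep = drop_mutations_fixed_s(g, fixed_s, rng=rng)
        snp_pos = rep.positions * locus_length
        snp_counts = rep.haplotypes.sum(axis=0)
        n_inv = max(locus_length - rep.segsites, 0.0)
        inv_pos, inv_counts, inv_w = invariant_lattice(
            locus_length, n_inv, n, spacing=invariant_spacing
        )
        scan = ClrSweepScan(
            positions=np.concatenate([snp_pos, inv_pos]),
            derived_counts=np.concatenate([snp_counts, inv_counts]),
            bg=bg,
            grid_spacing=grid_spacing,
            weights=np.concatenate([np.ones_like(snp_pos), inv_w]),
            span=(0.0, locus_length),
            **scan_kwargs,
        )
        maxima[r] = scan.fit().table["lambda"].max()
    return ThresholdCalibration(
        model_name=model.name,
        reps=reps,
        max_lambdas=maxima,
        quantile=quantile,
    )
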
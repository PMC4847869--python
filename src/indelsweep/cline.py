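"""Latitudinal clines and linkage disequilibrium.

A latitudinal cline is fitted by ordinary least squares of per-
population allele frequency on latitude, each population one point;
significance of the slope is the usual t test with n - 2 degrees of
freedom and the correlation is reported as Pearson's r. Two-population
frequency differences use Fisher's exact test on allele counts.
Linkage disequilibrium between SNP pairs is Lewontin's
r^2 = D^2 / (p1 q1 p2 q2) on haploid haplotype counts, with an exact
test on the 2x2 haplotype table; singleton sites are excluded by
default, as is conventional for LD screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import HaplotypeAlignment
from .popstats import _column_matrix, _usable_columns


@dataclass
class ClineResults:
    """OLS fit of allele frequency on latitude."""

    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float
    n: int
    use_abs_latitude: bool
    weighted: bool

    def predict(self, latitude: np.ndarray) -> np.ndarray:
        lat = np.abs(latitude) if self.use_abs_latitude else np.asarray(latitude)
        return self.intercept + self.slope * lat

    def summary(self) -> str:
        lines = [
            "Latitudinal cline regression",
            "=" * 42,
            f"populations        {self.n}",
            f"latitude           {'absolute' if self.use_abs_latitude else 'signed'}",
            f"weighting          {'by allele count' if self.weighted else 'none'}",
            f"slope              {self.slope:.5f} per degree",
            f"  std err          {self.stderr:.5f}",
            f"intercept          {self.intercept:.4f}",
            f"Pearson r          {self.r:.4f}",
            f"two-sided p        {self.p_value:.2e}",
        ]
        return "\n".join(lines)


class ClineRegression:
    """Model: deletion frequency ~ latitude across populations.

    Parameters
    ----------
    latitudes, frequencies
        One value per population.
    weights
        Optional per-population weights (e.g. allele counts); default
        unweighted, matching the convention of treating each
        population as one point.
    use_abs_latitude
        Regress on \|latitude\| so that clines on both hemispheres
        align; default off.
    """

    def __init__(
        self,
        latitudes,
        frequencies,
        weights=None,
        use_abs_latitude: bool = False,
    ):
        lat = np.asarray(latitudes, dtype=float)
        freq = np.asarray(frequencies, dtype=float)
        if lat.size != freq.size:
            raise ValueError("latitudes and frequencies differ in length")
        if lat.size < 3:
            raise ValueError("need at least 3 populations")
        x = np.abs(lat) if use_abs_latitude else lat
        if np.ptp(x) == 0:
            raise ValueError("latitude is constant; cline undefined")
        self.x = x
        self.y = freq
        self.weights = None if weights is None else np.asarray(weights, float)
        self.use_abs_latitude = use_abs_latitude

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        latitude: str = "latitude",
        frequency: str = "frequency",
        weights: str | None = None,
        use_abs_latitude: bool = False,
    ) -> "ClineRegression":
        return cls(
            df[latitude].to_numpy(),
            df[frequency].to_numpy(),
            weights=None if weights is None else df[weights].to_numpy(),
            use_abs_latitude=use_abs_latitude,
        )

    def fit(self) -> ClineResults:
        if self.weights is None:
            res = stats.linregress(self.x, self.y)
            return ClineResults(
                slope=float(res.slope),
                intercept=float(res.intercept),
                r=float(res.rvalue),
                p_value=float(res.pvalue),
                stderr=float(res.stderr),
                n=self.x.size,
                use_abs_latitude=self.use_abs_latitude,
                weighted=False,
            )
        w = self.weights / self.weights.sum()
        xm = float(np.sum(w * self.x))
        ym = float(np.sum(w * self.y))
        sxx = float(np.sum(w * (self.x - xm) ** 2))
        sxy = float(np.sum(w * (self.x - xm) * (self.y - ym)))
        syy = float(np.sum(w * (self.y - ym) ** 2))
        slope = sxy / sxx
        intercept = ym - slope * xm
        r = sxy / np.sqrt(sxx * syy)
        n = self.x.size
        t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r**2, 1e-300))
        p = float(2 * stats.t.sf(abs(t), n - 2))
        resid = self.y - intercept - slope * self.x
        s2 = float(np.sum(w * resid**2)) * n / (n - 2)
        stderr = float(np.sqrt(s2 / (n * sxx)))
        return ClineResults(
            slope=slope,
            intercept=intercept,
            r=float(r),
            p_value=p,
            stderr=stderr,
            n=n,
            use_abs_latitude=self.use_abs_latitude,
            weighted=True,
        )


def cline_regression(
    df: pd.DataFrame, use_abs_latitude: bool = False, weighted: bool = False
) -> ClineResults:
    """Convenience wrapper: fit a cline from a table.

    Expects columns ``latitude`` and ``frequency`` (plus ``n_alleles``
    when *weighted*).
    """
    return ClineRegression.from_dataframe(
        df,
        weights="n_alleles" if weighted else None,
        use_abs_latitude=use_abs_latitude,
    ).fit()


def fisher_two_pops(del1: int, n1: int, del2: int, n2: int) -> float:
    """Two-sided Fisher exact p for a frequency difference.

    The 2x2 table is [[del1, n1-del1], [del2, n2-del2]]; the two-sided
    p sums hypergeometric outcome probabilities <= the observed one.
    """
    if min(del1, del2) < 0 or del1 > n1 or del2 > n2 or min(n1, n2) <= 0:
        raise ValueError("invalid allele counts")
    table = [[del1, n1 - del1], [del2, n2 - del2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class LDPair:
    pos1: int
    pos2: int
    r2: float
    fisher_p: float


def _biallelic_sites(
    aln: HaplotypeAlignment, exclude_singletons: bool
) -> tuple[np.ndarray, np.ndarray]:
    """0/1 matrix of biallelic SNP columns and their 1-based positions."""
    arr = _column_matrix(aln)
    mask = _usable_columns(aln)
    cols = []
    positions = []
    for col in np.flatnonzero(mask):
        states, counts = np.unique(arr[:, col], return_counts=True)
        if len(states) != 2:
            continue
        minor = counts.min()
        if exclude_singletons and minor <= 1:
            continue
        cols.append((arr[:, col] == states[1]).astype(np.int8))
        positions.append(col + 1)
    if not cols:
        return np.zeros((aln.n, 0), dtype=np.int8), np.array([], dtype=int)
    return np.column_stack(cols), np.asarray(positions)


def r_squared(h1: np.ndarray, h2: np.ndarray) -> float:
    """Lewontin's r^2 from two 0/1 haploid site vectors."""
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    p1 = h1.mean()
    p2 = h2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic site reached LD computation")
    d = np.mean(h1 * h2) - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


def ld_matrix(
    aln: HaplotypeAlignment,
    exclude_singletons: bool = True,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Pairwise r^2 and Fisher exact p over all retained SNP pairs.

    Returns a table (pos1, pos2, r2, fisher_p) with 1-based alignment
    columns; p-values are raw unless *bonferroni* multiplies them by
    the number of pairs (capped at 1).
    """
    sites, positions = _biallelic_sites(aln, exclude_singletons)
    rows = []
    npairs = sites.shape[1] * (sites.shape[1] - 1) // 2
    for i, j in combinations(range(sites.shape[1]), 2):
        h1, h2 = sites[:, i], sites[:, j]
        n11 = int(np.sum((h1 == 1) & (h2 == 1)))
        n10 = int(np.sum((h1 == 1) & (h2 == 0)))
        n01 = int(np.sum((h1 == 0) & (h2 == 1)))
        n00 = int(np.sum((h1 == 0) & (h2 == 0)))
        p = float(stats.fisher_exact([[n11, n10], [n01, n00]])[1])
        if bonferroni:
            p = min(p * npairs, 1.0)
        rows.append(
            LDPair(
                pos1=int(positions[i]),
                pos2=int(positions[j]),
                r2=r_squared(h1, h2),
                fisher_p=p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
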
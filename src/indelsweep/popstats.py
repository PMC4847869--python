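"""Classical diversity statistics on haplotype alignments.

Implements the segregating-site count S, Watterson's theta and mean
pairwise diversity pi (both reported per 100 sites), Tajima's D with its
significance assessed by conditional-on-S coalescent simulation, the
haplotype count, Hudson-Slatkin-Maddison F_st for haploid panels, and
sliding-window profiles of all of the above.

Gap handling follows site-wise deletion: any column containing a gap or
``N`` is dropped from nucleotide statistics, consistent with
:mod:`indelsweep.alignment`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import MISSING_STATES, HaplotypeAlignment


@dataclass(frozen=True)
class TajimaConstants:
    """Normalizing coefficients for Tajima's D at sample size n."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants require n >= 2")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class SummaryStats:
    """Whole-locus summary statistics for one population sample."""

    n: int
    S: int
    theta_w: float
    pi: float
    tajima_d: float | None
    n_hap: int
    L_eff: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "S": self.S,
            "theta_w": self.theta_w,
            "pi": self.pi,
            "tajima_d": self.tajima_d,
            "n_hap": self.n_hap,
            "L_eff": self.L_eff,
        }


@dataclass(frozen=True)
class FstResult:
    """Hudson-Slatkin-Maddison F_st = 1 - Hw/Hb for two populations."""

    hw: float
    hb: float
    fst: float | None


@dataclass(frozen=True)
class WindowSpec:
    width: int = 500
    step: int = 250

    def __post_init__(self) -> None:
        if self.width <= 0 or not (0 < self.step <= self.width):
            raise ValueError(f"invalid window spec {self}")


def _usable_columns(aln: HaplotypeAlignment) -> np.ndarray:
    """Boolean mask of columns free of gaps and Ns (site-wise deletion)."""
    arr = np.frombuffer(
        "".join(aln.seqs).encode(), dtype="S1"
    ).reshape(aln.n, aln.length)
    mask = np.ones(aln.length, dtype=bool)
    for ch in MISSING_STATES:
        mask &= ~(arr == ch.encode()).any(axis=0)
    return mask


def _column_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    return np.frombuffer("".join(aln.seqs).encode(), dtype="S1").reshape(
        aln.n, aln.length
    )


def segregating_sites(aln: HaplotypeAlignment) -> tuple[int, int]:
    """Count segregating sites among usable columns.

    Returns
    -------
    (S, L_eff)
        Number of columns with >= 2 states, and the number of usable
        (gap/N-free) columns the count was taken over.
    """
    if aln.n < 2:
        raise ValueError("segregating sites require at least 2 sequences")
    arr = _column_matrix(aln)
    mask = _usable_columns(aln)
    sub = arr[:, mask]
    seg = (sub != sub[0]).any(axis=0)
    return int(seg.sum()), int(mask.sum())


def watterson_theta(S: int, n: int, L_eff: int, per: int = 100) -> float:
    """Watterson's estimator S / (a1 * L_eff), scaled per *per* sites."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2")
    if L_eff <= 0:
        raise ValueError("L_eff must be positive")
    a1 = TajimaConstants.from_n(n).a1
    return per * S / (a1 * L_eff)


def pairwise_differences(aln: HaplotypeAlignment) -> tuple[float, int]:
    """Mean pairwise differences per locus and usable column count."""
    if aln.n < 2:
        raise ValueError("pi requires at least 2 sequences")
    arr = _column_matrix(aln)
    mask = _usable_columns(aln)
    sub = arr[:, mask]
    total = 0
    npairs = 0
    for i, j in combinations(range(aln.n), 2):
        total += int((sub[i] != sub[j]).sum())
        npairs += 1
    return total / npairs, int(mask.sum())


def pairwise_pi(aln: HaplotypeAlignment, per: int = 100) -> float:
    """Mean pairwise diversity per *per* sites over usable columns."""
    diffs, L_eff = pairwise_differences(aln)
    if L_eff == 0:
        raise ValueError("no usable columns for pi")
    return per * diffs / L_eff


def haplotype_count(aln: HaplotypeAlignment) -> int:
    """Distinct haplotypes over usable columns."""
    arr = _column_matrix(aln)
    mask = _usable_columns(aln)
    return len({row.tobytes() for row in arr[:, mask]})


def tajima_d(S: int, n: int, pi_locus: float) -> float | None:
    """Tajima's D from S, n and per-locus pi; None when S == 0.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).
    """
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    if S == 0:
        return None
    c = TajimaConstants.from_n(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi_locus - S / c.a1) / math.sqrt(var)


def tajima_d_pvalue(
    d_obs: float,
    n: int,
    S: int,
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided empirical p-value for Tajima's D.

    Simulates constant-size coalescent genealogies, places exactly *S*
    mutations on each, and reports the fraction of replicates whose |D|
    is at least |d_obs|.
    """
    from .coalescent import DemographicModel, drop_mutations_fixed_s, simulate_genealogy

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    model = DemographicModel.constant()
    hits = 0
    for _ in range(reps):
        g = simulate_genealogy(n, model, rho=0.0, rng=rng)
        rep = drop_mutations_fixed_s(g, S, rng=rng)
        pi_locus = _pi_from_matrix(rep.haplotypes)
        d_sim = tajima_d(rep.haplotypes.shape[1], n, pi_locus)
        if d_sim is not None and abs(d_sim) >= abs(d_obs):
            hits += 1
    return hits / reps


def _pi_from_matrix(hap: np.ndarray) -> float:
    """Mean pairwise differences per locus for a 0/1 haplotype matrix."""
    n, s = hap.shape
    if s == 0:
        return 0.0
    counts = hap.sum(axis=0)
    # per-site heterozygosity summed over sites: sum k(n-k)/C(n,2)
    return float((counts * (n - counts)).sum() / (n * (n - 1) / 2))


def summary_stats(aln: HaplotypeAlignment) -> SummaryStats:
    """All whole-locus summaries for one alignment."""
    S, L_eff = segregating_sites(aln)
    diffs, _ = pairwise_differences(aln)
    theta = watterson_theta(S, aln.n, L_eff) if L_eff else float("nan")
    pi = 100 * diffs / L_eff if L_eff else float("nan")
    return SummaryStats(
        n=aln.n,
        S=S,
        theta_w=theta,
        pi=pi,
        tajima_d=tajima_d(S, aln.n, diffs),
        n_hap=haplotype_count(aln),
        L_eff=L_eff,
    )


def hudson_fst(
    aln: HaplotypeAlignment, pop_a: str, pop_b: str
) -> FstResult:
    """F_st = 1 - Hw/Hb between two labeled populations.

    Hw averages the two within-population mean pairwise differences;
    Hb is the mean pairwise difference across population boundaries.
    Differences are per usable column, jointly masked.
    """
    ids_a = [i for i, p in zip(aln.ids, aln.pop) if p == pop_a]
    ids_b = [i for i, p in zip(aln.ids, aln.pop) if p == pop_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both populations need >= 2 sequences")
    sub = aln.subset(ids_a + ids_b)
    arr = _column_matrix(sub)
    mask = _usable_columns(sub)
    m = arr[:, mask]
    na = len(ids_a)

    def mean_pairwise(rows_i, rows_j=None) -> float:
        if rows_j is None:
            pairs = list(combinations(rows_i, 2))
        else:
            pairs = [(i, j) for i in rows_i for j in rows_j]
        return float(
            np.mean([(m[i] != m[j]).sum() for i, j in pairs])
        )

    hw_a = mean_pairwise(range(na))
    hw_b = mean_pairwise(range(na, sub.n))
    hb = mean_pairwise(range(na), range(na, sub.n))
    hw = 0.5 * (hw_a + hw_b)
    fst = None if hb == 0 else 1.0 - hw / hb
    return FstResult(hw=hw, hb=hb, fst=fst)


def sliding_windows(
    aln: HaplotypeAlignment,
    spec: WindowSpec = WindowSpec(),
    fst_pairs: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Per-window theta/pi/D (and optional pairwise F_st) profiles.

    Windows are ``[start, start + width)`` in alignment columns with
    starts ``1, 1+step, ...``; the last start is the largest one with a
    full-width window (a single truncated window is used when the
    alignment is shorter than the width). Statistics are normalized by
    each window's usable column count; windows with no usable columns
    get missing values.
    """
    width, step = spec.width, spec.step
    if aln.length < width:
        starts = [1]
    else:
        starts = list(range(1, aln.length - width + 2, step))
    rows = []
    for start in starts:
        end = min(start + width - 1, aln.length)
        win = aln.slice_columns(start, end)
        row: dict = {"start": start, "end": end}
        try:
            st = summary_stats(win)
            if st.L_eff == 0:
                raise ValueError
            row.update(
                n_sites_used=st.L_eff,
                theta_w=st.theta_w,
                pi=st.pi,
                tajima_d=st.tajima_d,
            )
        except ValueError:
            row.update(
                n_sites_used=0,
                theta_w=np.nan,
                pi=np.nan,
                tajima_d=np.nan,
            )
        for pa, pb in fst_pairs:
            try:
                res = hudson_fst(win, pa, pb)
                row[f"fst_{pa}_{pb}"] = (
                    np.nan if res.fst is None else res.fst
                )
            except ValueError:
                row[f"fst_{pa}_{pb}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
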
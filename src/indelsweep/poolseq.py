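"""Indel allele frequencies from pooled sequencing reads.

Reads from a pooled sample are aligned to two reference haplotypes of
the indel region — the ancestral sequence and the deletion-bearing
sequence — and only reads spanning the indel junction with sufficient
flank on both sides count as informative. The deletion frequency is
the proportion of informative reads matching the deletion allele, with
a binomial 95% confidence interval computed on the probit (inverse
normal) scale by the delta method, falling back to exact
Clopper-Pearson bounds when the count sits on a boundary (0 or n
successes, where the probit transform degenerates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import Align, SeqIO
from scipy.stats import beta, norm


@dataclass(frozen=True)
class IndelReferences:
    """The two reference haplotypes around an indel.

    ``anc`` contains the segment of length ``del_len`` starting at
    0-based position ``del_start``; ``deleted`` is ``anc`` with that
    segment removed, so its junction point is ``del_start``.
    """

    anc: str
    deleted: str
    del_start: int
    del_len: int

    def __post_init__(self) -> None:
        expected = self.anc[: self.del_start] + self.anc[self.del_start + self.del_len :]
        if expected != self.deleted:
            raise ValueError(
                "deleted reference is not anc with the segment removed"
            )

    @classmethod
    def from_ancestral(cls, anc: str, del_start: int, del_len: int) -> "IndelReferences":
        deleted = anc[:del_start] + anc[del_start + del_len :]
        return cls(anc=anc, deleted=deleted, del_start=del_start, del_len=del_len)


@dataclass
class PooledCounts:
    """Read tallies over the indel junction."""

    informative: int
    del_reads: int
    anc_reads: int
    dropped: int = 0

    def __post_init__(self) -> None:
        if min(self.informative, self.del_reads, self.anc_reads, self.dropped) < 0:
            raise ValueError("negative read counts")
        if self.del_reads + self.anc_reads + self.dropped != self.informative:
            raise ValueError("del + anc + dropped must equal informative")


@dataclass(frozen=True)
class FrequencyEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    n_eff: int
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1):
            raise ValueError("interval must bracket the estimate within [0,1]")


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% (by default) binomial CI for k successes in n trials.

    Interior counts use the probit delta method: z0 = Phi^-1(p_hat),
    se = sqrt(p q / n) / phi(z0), bounds Phi(z0 -+ z_crit * se).
    Boundary counts (k = 0 or k = n) use exact Clopper-Pearson bounds.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must lie in 0..n")
    alpha = 1.0 - level
    if k == 0:
        return 0.0, float(1.0 - (alpha / 2) ** (1.0 / n))
    if k == n:
        return float((alpha / 2) ** (1.0 / n)), 1.0
    p = k / n
    z0 = norm.ppf(p)
    se = np.sqrt(p * (1 - p) / n) / norm.pdf(z0)
    zc = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(z0 - zc * se)), float(norm.cdf(z0 + zc * se))


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI; independent reference for coverage checks."""
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def pool_frequency(c: PooledCounts, level: float = 0.95) -> FrequencyEstimate:
    """Deletion frequency among classified informative reads, with CI."""
    n = c.del_reads + c.anc_reads
    if n == 0:
        raise ValueError("no classified reads to estimate a frequency from")
    lo, hi = binomial_ci(c.del_reads, n, level=level)
    method = "boundary-exact" if c.del_reads in (0, n) else "probit"
    return FrequencyEstimate(
        p_hat=c.del_reads / n, ci_low=lo, ci_high=hi, n_eff=n, method=method
    )


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -3
    a.extend_gap_score = -1
    # free end gaps on the reference (the read is a local placement);
    # reference overhangs appear as end "deletions" relative to the read
    a.open_left_deletion_score = 0
    a.extend_left_deletion_score = 0
    a.open_right_deletion_score = 0
    a.extend_right_deletion_score = 0
    return a


def _junction_flanks(aln, boundaries: Iterable[int]) -> int:
    """Max over boundaries of min(left, right) aligned read bases."""
    target_blocks, _ = aln.aligned
    best = 0
    for b in boundaries:
        left = sum(
            max(min(t1, b) - t0, 0) for t0, t1 in target_blocks
        )
        right = sum(
            max(t1 - max(t0, b), 0) for t0, t1 in target_blocks
        )
        best = max(best, min(left, right))
    return best


def classify_read(
    read: str,
    refs: IndelReferences,
    min_flank: int = 5,
) -> str:
    """Assign a read to ``deletion``, ``ancestral`` or ``uninformative``.

    The read is semi-globally aligned to both references (match +1,
    mismatch -1, gap open -3, gap extend -1; reference end gaps free).
    It is informative only if its placement crosses the indel junction
    with at least *min_flank* aligned bases on each side. The junction
    coordinate is ``del_start`` on both references (on the ancestral
    one the right flank falls inside the deletable segment), so the
    capture window is identical for the two alleles and the frequency
    estimator stays unbiased. Ties in alignment score are
    uninformative.
    """
    read = read.strip().upper()
    if len(read) < 2 * min_flank:
        return "uninformative"
    aligner = _aligner()
    try:
        anc_aln = aligner.align(refs.anc, read)[0]
        del_aln = aligner.align(refs.deleted, read)[0]
    except (IndexError, ValueError):
        return "uninformative"
    anc_ok = _junction_flanks(anc_aln, (refs.del_start,)) >= min_flank
    del_ok = _junction_flanks(del_aln, (refs.del_start,)) >= min_flank
    if anc_aln.score == del_aln.score:
        return "uninformative"
    if del_aln.score > anc_aln.score:
        return "deletion" if del_ok else "uninformative"
    return "ancestral" if anc_ok else "uninformative"


def classify_pool(
    reads: Iterable[str],
    refs: IndelReferences,
    min_flank: int = 5,
) -> PooledCounts:
    """Tally a pool of reads into deletion/ancestral/dropped classes.

    ``dropped`` counts reads whose best placement covers the junction
    on one reference but whose classification was ambiguous; reads not
    covering the junction at all are excluded from ``informative``
    entirely, mirroring read-count reporting that lists only
    junction-spanning reads.
    """
    del_reads = anc_reads = dropped = 0
    aligner = _aligner()
    for read in reads:
        r = read.strip().upper()
        if len(r) < 2 * min_flank:
            continue
        try:
            anc_aln = aligner.align(refs.anc, r)[0]
            del_aln = aligner.align(refs.deleted, r)[0]
        except (IndexError, ValueError):
            continue
        anc_ok = _junction_flanks(anc_aln, (refs.del_start,)) >= min_flank
        del_ok = _junction_flanks(del_aln, (refs.del_start,)) >= min_flank
        if not (anc_ok or del_ok):
            continue
        if del_aln.score > anc_aln.score and del_ok:
            del_reads += 1
        elif anc_aln.score > del_aln.score and anc_ok:
            anc_reads += 1
        else:
            dropped += 1
    informative = del_reads + anc_reads + dropped
    return PooledCounts(informative, del_reads, anc_reads, dropped)


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (qualities ignored)."""
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [str(r.seq) for r in SeqIO.parse(path, fmt)]
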
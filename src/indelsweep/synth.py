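"""Synthetic data with the statistical structure the analyses assume.

Generators for: neutral coalescent alignments (constant-size or
bottleneck histories, optional recombination), sweep-distorted site
tables drawn from the hitchhiking-escape spectrum itself, clinal
allele-frequency tables with binomial sampling of alleles, and pooled
reads spanning a 49-bp indel junction with uniform sequencing error.
Every generator is seed-deterministic and returns the generating truth
alongside the data so estimator error can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment
from .clr import SiteFrequencySpectrum, SweepSpectrumTransform, neutral_sfs
from .coalescent import (
    DemographicModel,
    drop_mutations_theta,
    simulate_genealogy,
)
from .poolseq import IndelReferences

_BASES = np.array(list("ACGT"))

SCENARIOS = ("neutral-constant", "neutral-bottleneck", "sweep")


@dataclass
class SynthSpec:
    """Parameters of one synthetic scenario.

    Defaults mirror the study design: 12 haploid sequences over a 6-kb
    locus, a sweep (when requested) at the locus midpoint.
    """

    scenario: str = "neutral-constant"
    n: int = 12
    theta: float = 5.0
    rho: float = 0.0
    locus_length: int = 6000
    sweep_alpha: float = 1e-3
    sweep_pos: float | None = None
    model: DemographicModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if min(self.n, self.theta, self.locus_length) <= 0 or self.rho < 0:
            raise ValueError("parameters must be positive (rho >= 0)")
        if self.scenario == "neutral-bottleneck" and self.model is None:
            raise ValueError("bottleneck scenario requires a demographic model")
        if self.sweep_pos is None:
            self.sweep_pos = self.locus_length / 2


@dataclass
class SynthTruth:
    """Generating parameters plus per-item truth labels."""

    params: dict
    labels: pd.DataFrame | None = None


def _matrix_to_alignment(
    hap: np.ndarray,
    positions_bp: np.ndarray,
    locus_length: int,
    rng: np.random.Generator,
    pop: Sequence[str] | None = None,
) -> HaplotypeAlignment:
    """Embed a 0/1 site matrix into nucleotide sequences."""
    n = hap.shape[0]
    anc = rng.choice(_BASES, size=locus_length)
    seqs = np.tile(anc, (n, 1))
    for col, bp in enumerate(positions_bp):
        base = anc[bp - 1]
        derived = rng.choice([b for b in _BASES if b != base])
        carriers = hap[:, col] == 1
        seqs[carriers, bp - 1] = derived
    ids = [f"seq{i:02d}" for i in range(n)]
    return HaplotypeAlignment(
        ids=ids,
        seqs=["".join(row) for row in seqs],
        pop=list(pop) if pop is not None else ["synth"] * n,
    )


def _unique_bp_positions(
    positions: np.ndarray, locus_length: int
) -> np.ndarray:
    """Map unit-interval positions to distinct 1-based bp columns."""
    bp = np.clip((positions * locus_length).astype(int) + 1, 1, locus_length)
    used: set[int] = set()
    out = np.empty_like(bp)
    for i, b in enumerate(bp):
        while b in used and b < locus_length:
            b += 1
        while b in used and b > 1:
            b -= 1
        used.add(b)
        out[i] = b
    return out


def make_alignment(spec: SynthSpec) -> tuple[HaplotypeAlignment, SynthTruth]:
    """Simulate an alignment for the requested scenario.

    Neutral scenarios run the coalescent simulator and embed the
    resulting 0/1 matrix into nucleotide sequences. The sweep scenario
    draws per-site derived counts from the hitchhiking-escape spectrum
    around ``sweep_pos`` (model-consistent with the CLR scan) and
    assigns carriers at random within each count class.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.scenario in ("neutral-constant", "neutral-bottleneck"):
        model = (
            spec.model
            if spec.scenario == "neutral-bottleneck"
            else DemographicModel.constant()
        )
        g = simulate_genealogy(spec.n, model, rho=spec.rho, rng=rng)
        rep = drop_mutations_theta(g, spec.theta, rng=rng)
        bp = _unique_bp_positions(rep.positions, spec.locus_length)
        aln = _matrix_to_alignment(
            rep.haplotypes, bp, spec.locus_length, rng
        )
        truth = SynthTruth(
            params={**spec.__dict__, "model": model.name, "S": rep.segsites},
            labels=pd.DataFrame(
                {"position": bp, "derived_count": rep.haplotypes.sum(axis=0)}
            ),
        )
        return aln, truth

    sites = make_sweep_sites(spec, rng=rng)
    poly = sites[(sites.derived_count > 0) & (sites.derived_count < spec.n)]
    hap = np.zeros((spec.n, len(poly)), dtype=np.int8)
    for col, cnt in enumerate(poly.derived_count.to_numpy()):
        hap[rng.choice(spec.n, size=int(cnt), replace=False), col] = 1
    aln = _matrix_to_alignment(
        hap, poly.position.to_numpy(), spec.locus_length, rng
    )
    truth = SynthTruth(
        params={**spec.__dict__, "model": "sweep-spectrum", "S": len(poly)},
        labels=sites,
    )
    return aln, truth


def make_sweep_sites(
    spec: SynthSpec,
    bg: SiteFrequencySpectrum | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site derived counts sampled from the post-sweep spectrum.

    One site per bp of the locus, each drawn independently from the
    sweep-transformed background at its distance from ``sweep_pos``;
    the background defaults to the standard-neutral expectation at the
    spec's theta. Returns (position, derived_count, distance).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if bg is None:
        bg = neutral_sfs(
            spec.n, spec.theta / spec.locus_length, spec.locus_length
        )
    transform = SweepSpectrumTransform(bg)
    positions = np.arange(1, spec.locus_length + 1)
    d = np.abs(positions - spec.sweep_pos)
    pe = 1.0 - np.exp(-spec.sweep_alpha * d)
    # discretize escape probabilities so each spectrum is computed once
    bins = np.rint(pe * 127).astype(int)
    counts = np.empty(len(positions), dtype=int)
    for b in np.unique(bins):
        probs = transform.spectrum(b / 127)
        probs = probs / probs.sum()
        sel = bins == b
        counts[sel] = rng.choice(spec.n + 1, size=int(sel.sum()), p=probs)
    return pd.DataFrame(
        {"position": positions, "derived_count": counts, "distance": d}
    )


def make_cline_table(
    n_pops: int,
    latitudes: Sequence[float] | None = None,
    intercept: float = -2.0,
    slope: float = 0.08,
    alleles_per_pop: int = 24,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Binomial allele sampling along a logistic latitudinal cline.

    Each population's true deletion frequency is
    ``logistic(intercept + slope * latitude)``; the observed frequency
    is a Binomial(alleles_per_pop, p) draw divided by the allele count
    (two alleles per line, so counts must be even).
    """
    if alleles_per_pop % 2:
        raise ValueError("alleles_per_pop must be even (two per line)")
    rng = np.random.default_rng(seed)
    if latitudes is None:
        latitudes = np.linspace(5.0, 65.0, n_pops)
    lat = np.asarray(latitudes, dtype=float)
    true_p = 1.0 / (1.0 + np.exp(-(intercept + slope * lat)))
    draws = rng.binomial(alleles_per_pop, true_p)
    df = pd.DataFrame(
        {
            "population": [f"pop{i:02d}" for i in range(len(lat))],
            "latitude": lat,
            "n_alleles": alleles_per_pop,
            "del_alleles": draws,
            "frequency": draws / alleles_per_pop,
        }
    )
    truth = SynthTruth(
        params={
            "intercept": intercept,
            "slope": slope,
            "alleles_per_pop": alleles_per_pop,
            "seed": seed,
        },
        labels=pd.DataFrame({"latitude": lat, "true_frequency": true_p}),
    )
    return df, truth


def make_references(
    flank: int = 150,
    del_len: int = 49,
    seed: int | None = None,
) -> IndelReferences:
    """Random ancestral haplotype with a deletable segment mid-locus."""
    rng = np.random.default_rng(seed)
    anc = "".join(rng.choice(_BASES, size=2 * flank + del_len))
    return IndelReferences.from_ancestral(anc, del_start=flank, del_len=del_len)


def make_reads(
    refs: IndelReferences,
    true_freq: float,
    n_reads: int = 500,
    read_len: int = 75,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[str], SynthTruth]:
    """Pooled reads from the two indel haplotypes at *true_freq*.

    Reads start uniformly along their source haplotype (truncated at
    its end) and receive independent per-base substitution errors.
    Truth labels record each read's source allele and whether it spans
    the junction with the default 5-bp flank.
    """
    if not (0 <= true_freq <= 1):
        raise ValueError("true_freq must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    labels = []
    for i in range(n_reads):
        from_del = rng.random() < true_freq
        src = refs.deleted if from_del else refs.anc
        start = int(rng.integers(0, max(len(src) - read_len + 1, 1)))
        seq = list(src[start : start + read_len])
        errs = rng.random(len(seq)) < error_rate
        for j in np.flatnonzero(errs):
            seq[j] = rng.choice([b for b in _BASES if b != seq[j]])
        reads.append("".join(seq))
        end = start + len(seq)
        spans = start + 5 <= refs.del_start <= end - 5
        labels.append(
            {
                "read": f"read{i:04d}",
                "source": "deletion" if from_del else "ancestral",
                "start": start,
                "spans_junction": bool(spans),
            }
        )
    truth = SynthTruth(
        params={
            "true_freq": true_freq,
            "n_reads": n_reads,
            "read_len": read_len,
            "error_rate": error_rate,
            "seed": seed,
        },
        labels=pd.DataFrame(labels),
    )
    return reads, truth
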
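"""Neutral coalescent simulation with demography and recombination.

An ms-style backward-in-time simulator: piecewise-constant population
size histories, Hudson ancestral-recombination-graph construction for
intra-locus recombination, and two mutation modes (Poisson with rate theta per
unit branch length — lengths are in 4N0 units, so the expected number
of segregating sites is theta * a1(n) — or exactly S mutations placed
proportionally to branch length). Time is measured in units of 4N0
generations and positions live on the unit interval, so published model
parameters in the ms convention transcribe directly.

The simulator backs the Hudson haplotype test nulls, CLR threshold
calibration, Tajima's D p-values and the synthetic-data generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised for invalid demographic-model configuration."""


@dataclass(frozen=True)
class Epoch:
    time: float          # start, units of 4N0 generations before present
    size_ratio: float    # N(t) / N0


@dataclass
class DemographicModel:
    """Piecewise-constant population-size history.

    ``epochs`` are ordered by start time (units of 4N0 generations,
    present = 0); within an epoch the coalescence rate for k lineages is
    ``k (k-1) / size_ratio`` per unit time.
    """

    name: str
    epochs: list[Epoch]
    description: str = ""
    placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ConfigError("model needs at least one epoch")
        times = [e.time for e in self.epochs]
        if times[0] != 0.0:
            raise ConfigError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigError("epoch times must be strictly increasing")
        if any(e.size_ratio <= 0 for e in self.epochs):
            raise ConfigError("size ratios must be positive")

    @classmethod
    def constant(cls, ratio: float = 1.0) -> "DemographicModel":
        return cls(name="constant", epochs=[Epoch(0.0, ratio)])

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            name=data["name"],
            epochs=[Epoch(float(t), float(r)) for t, r in data["epochs"]],
            description=data.get("description", ""),
            placeholder=bool(data.get("placeholder", False)),
        )

    def size_at(self, t: float) -> float:
        ratio = self.epochs[0].size_ratio
        for e in self.epochs:
            if e.time <= t:
                ratio = e.size_ratio
            else:
                break
        return ratio

    def next_change_after(self, t: float) -> float:
        for e in self.epochs:
            if e.time > t:
                return e.time
        return float("inf")


class Node:
    """Coalescent tree node; leaves carry sample indices."""

    __slots__ = ("time", "children", "n_samples", "leaf_id")

    def __init__(self, time, children=(), leaf_id=None):
        self.time = time
        self.children = list(children)
        self.leaf_id = leaf_id
        self.n_samples = (
            1 if leaf_id is not None else sum(c.n_samples for c in children)
        )

    def leaves(self) -> list[int]:
        if self.leaf_id is not None:
            return [self.leaf_id]
        out: list[int] = []
        stack = [self]
        while stack:
            v = stack.pop()
            if v.leaf_id is not None:
                out.append(v.leaf_id)
            else:
                stack.extend(v.children)
        return out


def _postorder(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(v.children)
    out.reverse()
    return out


def total_branch_length(root: Node) -> float:
    """Sum of branch lengths below *root* (4N0 units)."""
    total = 0.0
    stack = [root]
    while stack:
        v = stack.pop()
        for c in v.children:
            total += v.time - c.time
            stack.append(c)
    return total


@dataclass
class Genealogy:
    """Marginal coalescent trees over the unit interval.

    ``intervals`` partitions [0, 1) into half-open spans, each with the
    root of its marginal tree. Without recombination there is a single
    interval covering the whole locus.
    """

    n: int
    intervals: list[tuple[float, float, Node]]

    @property
    def tmrca(self) -> float:
        return max(root.time for _, _, root in self.intervals)

    @property
    def root(self) -> Node:
        if len(self.intervals) != 1:
            raise ValueError("multiple marginal trees; no single root")
        return self.intervals[0][2]

    def interval_weights(self) -> np.ndarray:
        """Span x total-branch-length weight per marginal tree."""
        return np.array(
            [(r - l) * total_branch_length(root) for l, r, root in self.intervals]
        )


@dataclass
class SimReplicate:
    """One simulated sample: 0/1 haplotypes plus mutation metadata."""

    haplotypes: np.ndarray          # n x S binary, columns ordered by position
    positions: np.ndarray           # mutation positions in [0, 1)
    genealogy: Genealogy | None = None
    mutation_nodes: list[Node] = field(default_factory=list)

    @property
    def segsites(self) -> int:
        return self.haplotypes.shape[1]


class _Segment:
    __slots__ = ("left", "right", "node")

    def __init__(self, left, right, node):
        self.left = left
        self.right = right
        self.node = node


def _rng_from(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_genealogy(
    n: int,
    model: DemographicModel | None = None,
    rho: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate an ancestral history for *n* samples.

    Parameters
    ----------
    n
        Sample size (>= 2).
    model
        Population-size history; constant size when omitted.
    rho
        Scaled recombination rate 4*N0*r*L for the whole locus;
        breakpoints fall uniformly on the bounding span of each
        lineage's ancestral material (Hudson ARG construction).
    seed, rng
        Either an integer seed or an existing ``numpy`` Generator.

    Returns
    -------
    Genealogy
        Marginal trees per non-recombined interval; a single tree when
        ``rho == 0``.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    model = model or DemographicModel.constant()
    rng = _rng_from(seed, rng)

    lineages: list[list[_Segment]] = [
        [_Segment(0.0, 1.0, Node(0.0, leaf_id=i))] for i in range(n)
    ]
    done: list[tuple[float, float, Node]] = []
    t = 0.0

    while lineages:
        k = len(lineages)
        spans = [(lin[0].left, lin[-1].right) for lin in lineages]
        rec_rates = [rho * (hi - lo) for lo, hi in spans]
        rec_total = float(sum(rec_rates))
        while True:
            ratio = model.size_at(t)
            coal_rate = k * (k - 1) / ratio
            total = coal_rate + rec_total
            wait = rng.exponential(1.0 / total)
            boundary = model.next_change_after(t)
            if t + wait <= boundary:
                t += wait
                break
            t = boundary  # re-draw under the new epoch's rate

        if rng.random() < coal_rate / total:
            i, j = rng.choice(k, size=2, replace=False)
            a = lineages[int(i)]
            b = lineages[int(j)]
            merged = _merge(a, b, t, n, done)
            lineages = [
                lin for idx, lin in enumerate(lineages) if idx not in (i, j)
            ]
            if merged:
                lineages.append(merged)
        else:
            # recombination: pick lineage proportional to its span
            probs = np.asarray(rec_rates) / rec_total
            idx = int(rng.choice(k, p=probs))
            lo, hi = spans[idx]
            x = lo + (hi - lo) * rng.random()
            left_part, right_part = _split(lineages[idx], x)
            if left_part and right_part:
                lineages[idx] = left_part
                lineages.append(right_part)

    done.sort(key=lambda iv: iv[0])
    return Genealogy(n=n, intervals=done)


def _split(
    segments: list[_Segment], x: float
) -> tuple[list[_Segment], list[_Segment]]:
    left: list[_Segment] = []
    right: list[_Segment] = []
    for seg in segments:
        if seg.right <= x:
            left.append(seg)
        elif seg.left >= x:
            right.append(seg)
        else:
            left.append(_Segment(seg.left, x, seg.node))
            right.append(_Segment(x, seg.right, seg.node))
    return left, right


def _merge(
    a: list[_Segment],
    b: list[_Segment],
    t: float,
    n: int,
    done: list[tuple[float, float, Node]],
) -> list[_Segment]:
    """Coalesce two lineages at time *t*.

    Overlapping ancestral material gains a fresh parent node per
    overlapping sub-interval; intervals reaching all *n* samples are
    recorded as finished marginal trees and dropped from the lineage.
    """
    events: list[tuple[float, int, _Segment]] = []
    out: list[_Segment] = []
    ia = ib = 0
    while ia < len(a) and ib < len(b):
        sa, sb = a[ia], b[ib]
        if sa.right <= sb.left:
            out.append(sa)
            ia += 1
            continue
        if sb.right <= sa.left:
            out.append(sb)
            ib += 1
            continue
        # overlap
        lo = max(sa.left, sb.left)
        hi = min(sa.right, sb.right)
        if sa.left < lo:
            out.append(_Segment(sa.left, lo, sa.node))
        if sb.left < lo:
            out.append(_Segment(sb.left, lo, sb.node))
        parent = Node(t, children=[sa.node, sb.node])
        if parent.n_samples == n:
            done.append((lo, hi, parent))
        else:
            out.append(_Segment(lo, hi, parent))
        # keep the trailing pieces for further processing
        if sa.right > hi:
            a[ia] = _Segment(hi, sa.right, sa.node)
        else:
            ia += 1
        if sb.right > hi:
            b[ib] = _Segment(hi, sb.right, sb.node)
        else:
            ib += 1
    out.extend(a[ia:])
    out.extend(b[ib:])
    out.sort(key=lambda s: s.left)
    return out


def _place_mutations(
    g: Genealogy, count: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[Node]]:
    """Place *count* mutations: interval ~ span x length, branch ~ length."""
    weights = g.interval_weights()
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("genealogy has zero branch length")
    probs = weights / wsum
    positions = np.empty(count)
    columns = np.zeros((g.n, count), dtype=np.int8)
    nodes: list[Node] = []
    interval_choice = rng.choice(len(weights), size=count, p=probs)
    for m, iv in enumerate(interval_choice):
        left, right, root = g.intervals[int(iv)]
        positions[m] = left + (right - left) * rng.random()
        node = _choose_branch(root, rng)
        nodes.append(node)
        columns[node.leaves(), m] = 1
    order = np.argsort(positions, kind="stable")
    return columns[:, order], positions[order], [nodes[i] for i in order]


def _choose_branch(root: Node, rng: np.random.Generator) -> Node:
    """Pick a node below *root* with probability ~ its stem length."""
    cand: list[Node] = []
    lens: list[float] = []
    stack = [root]
    while stack:
        v = stack.pop()
        for c in v.children:
            cand.append(c)
            lens.append(v.time - c.time)
            stack.append(c)
    w = np.asarray(lens)
    w = w / w.sum()
    return cand[int(rng.choice(len(cand), p=w))]


def drop_mutations_theta(
    g: Genealogy,
    theta: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimReplicate:
    """Poisson mutations at rate theta per unit branch length.

    Branch lengths are in 4N0 units, so under constant size the
    expected number of segregating sites is ``theta * a1(n)`` with
    ``a1 = sum_{i<n} 1/i``.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = _rng_from(seed, rng)
    mean = theta * float(g.interval_weights().sum())
    count = int(rng.poisson(mean))
    if count == 0:
        return SimReplicate(
            haplotypes=np.zeros((g.n, 0), dtype=np.int8),
            positions=np.empty(0),
            genealogy=g,
        )
    hap, pos, nodes = _place_mutations(g, count, rng)
    return SimReplicate(hap, pos, g, nodes)


def drop_mutations_fixed_s(
    g: Genealogy,
    S: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimReplicate:
    """Exactly *S* mutations, branches chosen proportional to length."""
    if S < 0:
        raise ValueError("S must be non-negative")
    rng = _rng_from(seed, rng)
    if S == 0:
        return SimReplicate(
            haplotypes=np.zeros((g.n, 0), dtype=np.int8),
            positions=np.empty(0),
            genealogy=g,
        )
    hap, pos, nodes = _place_mutations(g, S, rng)
    return SimReplicate(hap, pos, g, nodes)


def simulate_replicates(
    n: int,
    reps: int,
    model: DemographicModel | None = None,
    rho: float = 0.0,
    theta: float | None = None,
    fixed_s: int | None = None,
    seed: int | None = None,
) -> Iterable[SimReplicate]:
    """Stream *reps* independent replicates in one of the two mutation modes."""
    if (theta is None) == (fixed_s is None):
        raise ValueError("specify exactly one of theta / fixed_s")
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        g = simulate_genealogy(n, model, rho=rho, rng=rng)
        if theta is not None:
            yield drop_mutations_theta(g, theta, rng=rng)
        else:
            yield drop_mutations_fixed_s(g, fixed_s, rng=rng)


def write_ms(replicates: Sequence[SimReplicate], fh, command: str = "indelsweep") -> None:
    """Write replicates in ms text format (``//``, segsites, positions, rows)."""
    fh.write(f"{command}\n0 0 0\n")
    for rep in replicates:
        fh.write("\n//\n")
        fh.write(f"segsites: {rep.segsites}\n")
        if rep.segsites:
            pos = " ".join(f"{p:.6f}" for p in rep.positions)
            fh.write(f"positions: {pos}\n")
            for row in rep.haplotypes:
                fh.write("".join(str(int(x)) for x in row) + "\n")
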
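"""Hudson's haplotype test.

Tests whether a subset of sequences (here, the carriers of a focal
indel allele) is too homogeneous under neutrality: conditional on the
total number of segregating sites S in a sample of n, what is the
probability that SOME subset of size i carries p or fewer segregating
sites? Small p-values indicate excess haplotype homogeneity, as
expected after a partial selective sweep.

The null is Monte Carlo: neutral genealogies under a chosen demographic
history, exactly S mutations per replicate, and per replicate the
minimum over all size-i subsets of the number of sites segregating
within the subset — computed exactly by a subtree dynamic program
rather than subset enumeration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .coalescent import (
    DemographicModel,
    Node,
    SimReplicate,
    drop_mutations_fixed_s,
    simulate_genealogy,
)

_INF = float("inf")


def min_subset_segsites(
    root: Node,
    stem_mutations: dict[Node, int] | Counter,
    i: int,
) -> int:
    """Minimum segregating sites over all leaf subsets of size *i*.

    A mutation on branch b segregates within subset T iff T contains
    some but not all of b's subtended leaves. The minimum over all
    C(n, i) subsets is found by a bottom-up dynamic program: f(v, k) is
    the cheapest way to pick k tips inside v's subtree, where picking
    0 < k' < i tips inside a child subtree pays that child's stem
    mutations.
    """
    n = root.n_samples
    if not (1 <= i <= n):
        raise ValueError(f"subset size {i} outside 1..{n}")

    def muts(v: Node) -> int:
        return stem_mutations.get(v, 0)

    def f(v: Node) -> list[float]:
        """Costs of choosing k = 0..min(i, size(v)) tips inside v."""
        cap = min(i, v.n_samples)
        if v.leaf_id is not None:
            return [0.0, 0.0][: cap + 1]
        acc = [0.0]
        for c in v.children:
            child = f(c)
            # stem cost applies when the child holds a proper sub-share
            child_cost = [
                child[k] + (muts(c) if 0 < k < i else 0)
                for k in range(len(child))
            ]
            new_cap = min(i, len(acc) - 1 + len(child_cost) - 1)
            new = [_INF] * (new_cap + 1)
            for k1, v1 in enumerate(acc):
                if v1 == _INF:
                    continue
                for k2, v2 in enumerate(child_cost):
                    k = k1 + k2
                    if k > new_cap:
                        break
                    if v1 + v2 < new[k]:
                        new[k] = v1 + v2
            acc = new
        return acc

    result = f(root)[i]
    assert result < _INF
    return int(result)


def replicate_min_subset_segsites(rep: SimReplicate, i: int) -> int:
    """Subset minimum for a no-recombination simulation replicate."""
    g = rep.genealogy
    if g is None or len(g.intervals) != 1:
        raise ValueError("requires a single-tree (rho=0) replicate")
    counts = Counter(rep.mutation_nodes)
    return min_subset_segsites(g.root, counts, i)


@dataclass(frozen=True)
class HHTObservation:
    """Observed configuration: subset of size i with p segregating sites."""

    n: int
    S_total: int
    i: int
    p: int

    def __post_init__(self) -> None:
        if not (2 <= self.i <= self.n):
            raise ValueError("need 2 <= i <= n")
        if self.S_total < 0:
            raise ValueError("S_total must be non-negative")


@dataclass
class HHTResult:
    """Monte Carlo outcome of the haplotype test."""

    p_value: float
    reps: int
    seed: int | None
    observation: HHTObservation
    model_name: str
    null_minima: np.ndarray = field(repr=False, default=None)

    @property
    def mc_stderr(self) -> float:
        p = self.p_value
        return float(np.sqrt(p * (1 - p) / self.reps))

    def summary(self) -> str:
        o = self.observation
        lines = [
            "Hudson's haplotype test",
            "=" * 42,
            f"sample size n            {o.n}",
            f"total segregating sites  {o.S_total}",
            f"subset size i            {o.i}",
            f"subset segregating sites {o.p}",
            f"demographic model        {self.model_name}",
            f"replicates               {self.reps}",
            f"P(min subset S <= p)     {self.p_value:.4f}",
            f"Monte Carlo s.e.         {self.mc_stderr:.4f}",
        ]
        return "\n".join(lines)


class HudsonHaplotypeTest:
    """Model object for the haplotype-homogeneity test.

    Parameters
    ----------
    n, S_total
        Sample size and its total segregating sites.
    subset_size, subset_segsites
        Size of the focal subset (e.g. deletion carriers) and the number
        of sites segregating within it.
    model
        Demographic null; constant size when omitted.
    """

    def __init__(
        self,
        n: int,
        S_total: int,
        subset_size: int,
        subset_segsites: int,
        model: DemographicModel | None = None,
    ):
        self.observation = HHTObservation(n, S_total, subset_size, subset_segsites)
        self.model = model or DemographicModel.constant()

    def fit(self, reps: int = 10_000, seed: int | None = None) -> HHTResult:
        """Run the Monte Carlo null and return the one-sided p-value."""
        if reps < 1:
            raise ValueError("reps must be >= 1")
        o = self.observation
        rng = np.random.default_rng(seed)
        minima = np.empty(reps, dtype=np.int64)
        for r in range(reps):
            g = simulate_genealogy(o.n, self.model, rho=0.0, rng=rng)
            rep = drop_mutations_fixed_s(g, o.S_total, rng=rng)
            minima[r] = replicate_min_subset_segsites(rep, o.i)
        p_value = float(np.mean(minima <= o.p))
        return HHTResult(
            p_value=p_value,
            reps=reps,
            seed=seed,
            observation=o,
            model_name=self.model.name,
            null_minima=minima,
        )


def brute_force_min_subset_segsites(
    root: Node, stem_mutations: dict[Node, int] | Counter, i: int
) -> int:
    """Exhaustive reference: enumerate all C(n, i) subsets.

    Exponential; used as an independent oracle in tests for small n.
    """
    from itertools import combinations

    leaves = sorted(root.leaves())
    branches: list[tuple[frozenset[int], int]] = []
    stack = [root]
    while stack:
        v = stack.pop()
        for c in v.children:
            m = stem_mutations.get(c, 0)
            if m:
                branches.append((frozenset(c.leaves()), m))
            stack.append(c)
    best = None
    for subset in combinations(leaves, i):
        T = frozenset(subset)
        cost = sum(
            m for below, m in branches if 0 < len(below & T) < i
        )
        if best is None or cost < best:
            best = cost
    return int(best)
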
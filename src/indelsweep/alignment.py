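"""Aligned haplotype panels and site classification.

Sequence panels here are haploid consensus sequences from isofemale lines,
held as a rectangular multiple alignment over ``{A, C, G, T, -, N}``.
Columns are classified into SNPs, indel events, invariant and excluded
sites; alleles are polarized against outgroup sequences by majority vote;
and haplotypes are partitioned by their state at a focal indel.

Coordinates are 1-based and intervals are inclusive throughout, matching
the GenBank-style ranges used for locus annotation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STATES = frozenset("ACGT-N")
#: States that exclude a column from nucleotide-diversity statistics.
MISSING_STATES = frozenset("-N")

UNPOLARIZED = "unpolarized"


class AlignmentError(ValueError):
    """Raised when sequences do not form a rectangular alignment."""


class AmbiguousCarrierError(ValueError):
    """Raised when a sequence is partially gapped across an indel span."""


@dataclass
class HaplotypeAlignment:
    """A rectangular alignment of haploid sequences with population labels.

    Parameters
    ----------
    ids
        Unique sequence labels.
    seqs
        Equal-length uppercase strings over ``{A,C,G,T,-,N}``.
    pop
        Population label per sequence (parallel to *ids*).
    offset
        1-based genomic coordinate of alignment column 1.
    """

    ids: list[str]
    seqs: list[str]
    pop: list[str] = field(default_factory=list)
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment must contain at least one sequence")
        L = len(self.seqs[0])
        if L == 0:
            raise AlignmentError("alignment length must be positive")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence ids must be unique")
        if not self.pop:
            self.pop = ["pop0"] * len(self.ids)
        self.seqs = [s.upper() for s in self.seqs]
        bad = set("".join(self.seqs)) - VALID_STATES
        if bad:
            raise AlignmentError(f"invalid states in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop:
            seen.setdefault(p)
        return list(seen)

    def column(self, col: int) -> str:
        """States at 1-based alignment column *col*, one per sequence."""
        return "".join(s[col - 1] for s in self.seqs)

    def subset(self, ids: Sequence[str]) -> "HaplotypeAlignment":
        """Restrict the alignment to the given sequence ids (order kept)."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        rows = [index[sid] for sid in ids]
        return HaplotypeAlignment(
            ids=[self.ids[i] for i in rows],
            seqs=[self.seqs[i] for i in rows],
            pop=[self.pop[i] for i in rows],
            offset=self.offset,
        )

    def by_population(self, label: str) -> "HaplotypeAlignment":
        ids = [sid for sid, p in zip(self.ids, self.pop) if p == label]
        if not ids:
            raise KeyError(f"no sequences labeled {label!r}")
        return self.subset(ids)

    def slice_columns(self, start: int, end: int) -> "HaplotypeAlignment":
        """Columns *start*..*end* (1-based, inclusive) as a new alignment."""
        if not (1 <= start <= end <= self.length):
            raise AlignmentError(f"column range {start}..{end} out of bounds")
        return HaplotypeAlignment(
            ids=list(self.ids),
            seqs=[s[start - 1 : end] for s in self.seqs],
            pop=list(self.pop),
            offset=self.offset + start - 1,
        )


@dataclass(frozen=True)
class SiteRecord:
    """Classification of one alignment column.

    ``kind`` is one of ``snp``, ``indel``, ``invariant``, ``excluded``;
    ``derived_count`` is an integer when polarization succeeded and the
    string ``"unpolarized"`` otherwise.
    """

    column: int
    kind: str
    alleles: str
    derived_count: int | str
    n_called: int


@dataclass(frozen=True)
class IndelPartition:
    """Haplotypes split by carrier status at a focal indel."""

    carriers: tuple[str, ...]
    non_carriers: tuple[str, ...]
    indel_span: tuple[int, int]


def read_alignment(path, pop_map=None) -> HaplotypeAlignment:
    """Read a FASTA alignment, optionally attaching population labels.

    Parameters
    ----------
    path
        FASTA file (or open handle) of equal-length aligned sequences.
    pop_map
        Mapping of sequence id to population label, or a path to a
        two-column TSV ``(id, pop)``. Ids present in the FASTA but absent
        from the map raise ``KeyError``.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path!r}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if pop_map is None:
        pops = ["pop0"] * len(ids)
    else:
        if not hasattr(pop_map, "get"):
            table = pd.read_csv(pop_map, sep="\t", dtype=str)
            pop_map = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
        missing = [sid for sid in ids if sid not in pop_map]
        if missing:
            raise KeyError(f"ids missing from population map: {missing}")
        pops = [pop_map[sid] for sid in ids]
    return HaplotypeAlignment(ids=ids, seqs=seqs, pop=pops)


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    """Write the alignment as FASTA (inverse of :func:`read_alignment`)."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.ids, aln.seqs)
    ]
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, path, "fasta")


def _ancestral_state(outgroup_states: str) -> str | None:
    """Majority state among non-missing outgroup residues; None on tie."""
    counts: dict[str, int] = {}
    for s in outgroup_states:
        if s not in MISSING_STATES:
            counts[s] = counts.get(s, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    winners = [s for s, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None


def classify_sites(
    aln: HaplotypeAlignment,
    outgroups: HaplotypeAlignment | None = None,
) -> list[SiteRecord]:
    """Classify every alignment column into SNP/indel/invariant/excluded.

    Columns containing any gap or ``N`` in the ingroup are dropped from
    nucleotide statistics (site-wise deletion): they are classified
    ``indel`` when they belong to a contiguous run of two or more gap
    columns sharing the same carrier set (a deletion event, collapsed
    to one event per run by :func:`indel_events`), and ``excluded``
    otherwise (isolated gaps, Ns). Ancestral states come from a
    majority vote over outgroup residues; ties or missing outgroup
    data yield ``derived_count="unpolarized"``.
    """
    if outgroups is not None and outgroups.length != aln.length:
        raise AlignmentError(
            f"outgroup alignment length {outgroups.length} != {aln.length}"
        )
    # carrier set of gapped sequences per column, for indel-run detection
    gap_sets = [
        frozenset(
            i for i, s in enumerate(aln.column(col)) if s == "-"
        )
        for col in range(1, aln.length + 1)
    ]
    run_len = [0] * aln.length
    i = 0
    while i < aln.length:
        if gap_sets[i]:
            j = i
            while j < aln.length and gap_sets[j] == gap_sets[i]:
                j += 1
            for c in range(i, j):
                run_len[c] = j - i
            i = j
        else:
            i += 1
    records: list[SiteRecord] = []
    for col in range(1, aln.length + 1):
        states = aln.column(col)
        called = [s for s in states if s not in MISSING_STATES]
        n_called = len(called)
        alleles = "".join(sorted(set(called)))
        has_missing = n_called < aln.n
        if "-" in states:
            kind = "indel" if run_len[col - 1] >= 2 else "excluded"
        elif has_missing:
            kind = "excluded"
        elif len(set(called)) >= 2:
            kind = "snp"
        else:
            kind = "invariant"

        derived: int | str = UNPOLARIZED
        if outgroups is not None and kind in ("snp", "invariant"):
            anc = _ancestral_state(outgroups.column(col))
            if anc is not None and (anc in alleles or kind == "invariant"):
                if kind == "invariant":
                    derived = 0 if (called and called[0] == anc) else n_called
                else:
                    derived = sum(1 for s in called if s != anc)
        records.append(
            SiteRecord(
                column=col,
                kind=kind,
                alleles=alleles,
                derived_count=derived,
                n_called=n_called,
            )
        )
    return records


def indel_events(records: list[SiteRecord]) -> list[tuple[int, int]]:
    """Collapse contiguous indel columns to ``(start, end)`` events."""
    events: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for rec in records:
        if rec.kind == "indel":
            if run_start is None or prev != rec.column - 1:
                if run_start is not None:
                    events.append((run_start, prev))
                run_start = rec.column
            prev = rec.column
    if run_start is not None:
        events.append((run_start, prev))
    return events


def partition_by_indel(
    aln: HaplotypeAlignment,
    indel_span: tuple[int, int],
    carrier_threshold: float = 0.9,
) -> IndelPartition:
    """Split sequences into deletion carriers and non-carriers.

    A sequence is a carrier iff at least ``carrier_threshold`` (default
    90%) of the span's columns are gaps; sequences falling between 10%
    and the threshold are flagged as ambiguous rather than silently
    assigned.
    """
    start, end = indel_span
    if not (1 <= start <= end <= aln.length):
        raise AlignmentError(f"indel span {indel_span} outside alignment")
    width = end - start + 1
    carriers: list[str] = []
    non_carriers: list[str] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        gaps = seq[start - 1 : end].count("-")
        frac = gaps / width
        if frac >= carrier_threshold:
            carriers.append(sid)
        elif frac <= 1.0 - carrier_threshold:
            non_carriers.append(sid)
        else:
            raise AmbiguousCarrierError(
                f"sequence {sid!r} is {frac:.0%} gapped across the indel "
                f"span {indel_span}; cannot assign carrier status"
            )
    return IndelPartition(
        carriers=tuple(carriers),
        non_carriers=tuple(non_carriers),
        indel_span=(start, end),
    )


def site_table(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Site records as a DataFrame (column, kind, alleles, derived_count, n_called)."""
    return pd.DataFrame(
        [
            {
                "column": r.column,
                "kind": r.kind,
                "alleles": r.alleles,
                "derived_count": r.derived_count,
                "n_called": r.n_called,
            }
            for r in records
        ]
    )


def write_site_table(records: Iterable[SiteRecord], path) -> None:
    site_table(records).to_csv(path, sep="\t", index=False)


def alignment_to_string(aln: HaplotypeAlignment) -> str:
    buf = io.StringIO()
    write_alignment(aln, buf)
    return buf.getvalue()
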
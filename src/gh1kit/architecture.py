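"""Tripartite region partition, AT-hook detection and architecture groups."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqio import DomainHit, ProteinRecord, GH1, MYB

BASIC = set("KR")

# (start, end) 1-based inclusive; None marks an empty region.
Interval = tuple[int, int]


class ArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class RegionPartition:
    """NTD / GH1(s) / CTD intervals on one protein.

    Spans between consecutive GH1 domains are recorded as ``linkers`` and
    belong to neither tail, so region lengths plus linker lengths always
    sum to the protein length.
    """

    protein_id: str
    length: int
    ntd: Interval | None
    gh1s: tuple[Interval, ...]
    ctd: Interval | None
    linkers: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if not self.gh1s:
            raise ArchitectureError(f"{self.protein_id}: not a GH1 protein")
        total = self.ntd_len + sum(e - s + 1 for s, e in self.gh1s)
        total += self.linker_len + self.ctd_len
        if total != self.length:
            raise ArchitectureError(
                f"{self.protein_id}: regions sum to {total}, protein length "
                f"is {self.length}"
            )

    @property
    def ntd_len(self) -> int:
        return 0 if self.ntd is None else self.ntd[1] - self.ntd[0] + 1

    @property
    def ctd_len(self) -> int:
        return 0 if self.ctd is None else self.ctd[1] - self.ctd[0] + 1

    @property
    def gh1_lens(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.gh1s)

    @property
    def linker_len(self) -> int:
        return sum(e - s + 1 for s, e in self.linkers)


@dataclass(frozen=True)
class ATHookMotif:
    protein_id: str
    start: int  # 1-based index of the matched core
    matched: str


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    group: str  # typical_H1_candidate | GH1_Myb | GH1_HMGA | multi_GH1 | other
    n_gh1: int
    has_myb: bool
    n_at_hooks: int


def partition_protein(
    protein: ProteinRecord, hits: Sequence[DomainHit]
) -> RegionPartition:
    """Partition a protein into NTD, GH1 domain(s), linkers and CTD.

    NTD is everything before the first GH1 domain, CTD everything after
    the last; either may be empty. Requires >= 1 non-overlapping GH1 hit
    within the sequence.
    """
    gh1_hits = sorted(
        (h for h in hits if h.protein_id == protein.id and h.domain_name == GH1),
        key=lambda h: h.start,
    )
    if not gh1_hits:
        raise ArchitectureError(f"{protein.id}: not a GH1 protein")
    length = len(protein)
    for h in gh1_hits:
        if h.end > length:
            raise ArchitectureError(
                f"{protein.id}: GH1 hit [{h.start},{h.end}] exceeds protein "
                f"length {length}"
            )
    for prev, nxt in zip(gh1_hits, gh1_hits[1:]):
        if nxt.start <= prev.end:
            raise ArchitectureError(
                f"{protein.id}: overlapping GH1 hits "
                f"[{prev.start},{prev.end}] and [{nxt.start},{nxt.end}]"
            )
    first, last = gh1_hits[0], gh1_hits[-1]
    ntd = (1, first.start - 1) if first.start > 1 else None
    ctd = (last.end + 1, length) if last.end < length else None
    linkers = tuple(
        (prev.end + 1, nxt.start - 1)
        for prev, nxt in zip(gh1_hits, gh1_hits[1:])
        if nxt.start - prev.end > 1
    )
    return RegionPartition(
        protein_id=protein.id,
        length=length,
        ntd=ntd,
        gh1s=tuple((h.start, h.end) for h in gh1_hits),
        ctd=ctd,
        linkers=linkers,
    )


AT_HOOK_CORE = "RGRP"
_FLANK = 4
_MIN_FLANK_BASIC = 2


def find_at_hooks(protein: ProteinRecord) -> list[ATHookMotif]:
    """Find non-overlapping AT-hook motifs, left to right.

    A motif is an R-G-R-P core with at least two additional basic
    residues (K/R) within the 4 residues flanking either side; this
    matches the canonical KRPRGRPKK consensus while rejecting bare GRP
    occurrences without basic context.
    """
    seq = protein.residues
    motifs: list[ATHookMotif] = []
    i = 0
    while True:
        i = seq.find(AT_HOOK_CORE, i)
        if i == -1:
            break
        left = seq[max(0, i - _FLANK):i]
        right = seq[i + len(AT_HOOK_CORE):i + len(AT_HOOK_CORE) + _FLANK]
        n_basic = sum(c in BASIC for c in left + right)
        if n_basic >= _MIN_FLANK_BASIC:
            motifs.append(
                ATHookMotif(protein_id=protein.id, start=i + 1, matched=AT_HOOK_CORE)
            )
            i += len(AT_HOOK_CORE)  # non-overlapping
        else:
            i += 1
    return motifs


def classify_architecture(
    partition: RegionPartition,
    hits: Sequence[DomainHit],
    hooks: Sequence[ATHookMotif],
) -> ArchitectureCall:
    """Assign a domain-architecture group.

    Precedence: any Myb hit -> GH1_Myb; else >= 2 AT-hooks -> GH1_HMGA;
    else >= 2 GH1 domains -> multi_GH1; else typical_H1_candidate.
    """
    pid = partition.protein_id
    has_myb = any(
        h.protein_id == pid and h.domain_name == MYB for h in hits
    )
    n_hooks = sum(m.protein_id == pid for m in hooks)
    n_gh1 = len(partition.gh1s)
    if has_myb:
        group = "GH1_Myb"
    elif n_hooks >= 2:
        group = "GH1_HMGA"
    elif n_gh1 >= 2:
        group = "multi_GH1"
    elif n_gh1 == 1:
        group = "typical_H1_candidate"
    else:  # pragma: no cover - partition guarantees >= 1
        group = "other"
    return ArchitectureCall(
        protein_id=pid,
        group=group,
        n_gh1=n_gh1,
        has_myb=has_myb,
        n_at_hooks=n_hooks,
    )
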
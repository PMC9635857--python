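"""Seeded generators producing inputs with the statistical structure
each pipeline stage assumes: planted proteomes, neutral infinite-sites
coalescent samples, Poisson HKA counts and coding-region populations.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .architecture import AT_HOOK_CORE, find_at_hooks
from .popgen import LocusAlignment, SiteClassAnnotation, classify_coding_sites, \
    snp_effect, HKAData, HKALocus, harmonic, _CODON_TO_AA
from .seqio import AlignmentBlock, DomainHit, ProteinRecord, VariantRecord, GH1, MYB

_NEUTRAL_AA = "ASTPGVNQ"  # no charge, no basics, cannot form an AT-hook core
_BASES = "ACGT"

GH1_LEN = 70
TEMPLATE_ID = "__template__"

# site positions within the GH1 domain (1-based), matching the shipped
# default reference site map
_SITE_POSITIONS = (2, 17, 19, 29, 43, 44, 51, 52, 61, 67)
_SITE_RESIDUES = ("H", "K", "R", "K", "K", "K", "K", "K", "K", "K")

AT_HOOK_UNIT = "KRPRGRPKK"


@dataclass(frozen=True)
class ProteomeTruth:
    records: tuple[ProteinRecord, ...]
    hits: tuple[DomainHit, ...]
    labels: dict[str, str]  # id -> H1 | GH1_Myb | GH1_HMGA | decoy
    gh1_alignment: AlignmentBlock  # includes the TEMPLATE_ID reference row
    n_at_hooks: dict[str, int]
    seed: int


def _rand_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _gh1_template(rng: np.random.Generator) -> str:
    body = list(_rand_seq(rng, GH1_LEN, _NEUTRAL_AA + "LIFYE"))
    for pos, res in zip(_SITE_POSITIONS, _SITE_RESIDUES):
        body[pos - 1] = res
    return "".join(body)


def _mutate_gh1(
    rng: np.random.Generator, template: str, keep_sites: int
) -> str:
    """Copy the template, keep ``keep_sites`` basic site positions and
    neutralize the rest; sprinkle substitutions at non-site columns."""
    body = list(template)
    site_idx = list(rng.permutation(len(_SITE_POSITIONS)))
    for rank, si in enumerate(site_idx):
        if rank >= keep_sites:
            body[_SITE_POSITIONS[si] - 1] = "N"  # basic -> neutral Asn
    non_sites = [i for i in range(GH1_LEN) if (i + 1) not in _SITE_POSITIONS]
    for i in rng.choice(non_sites, size=8, replace=False):
        body[i] = rng.choice(list(_NEUTRAL_AA))
    return "".join(body)


def _h1_ctd(rng: np.random.Generator, length: int) -> str:
    """Lysine-rich (~30%) tail with the basics laid down at a fixed
    stride so every 20-aa window carries positive charge."""
    body = []
    for i in range(length):
        if i % 3 == 0:
            body.append("R" if rng.random() < 0.15 else "K")
        else:
            body.append(rng.choice(list(_NEUTRAL_AA)))
    return "".join(body)


def _acidic_ctd(rng: np.random.Generator, length: int) -> str:
    """Low-lysine tail with an acidic patch (fails the evenness check)."""
    body = [
        "K" if rng.random() < 0.07 else rng.choice(list(_NEUTRAL_AA))
        for _ in range(length)
    ]
    patch = list("DDEEDDEEDD")
    start = int(rng.integers(0, length - len(patch)))
    body[start:start + len(patch)] = patch
    return "".join(body)


def _hmga_ctd(rng: np.random.Generator, n_hooks: int) -> str:
    """Weakly mixed-charge tail with ``n_hooks`` planted AT-hook units,
    separated by neutral spacers containing a small acidic patch."""
    parts = []
    for h in range(n_hooks):
        spacer_len = int(rng.integers(10, 18))
        spacer = list(_rand_seq(rng, spacer_len, _NEUTRAL_AA))
        if h == 0:
            spacer[2:7] = list("DDEED")
        parts.append("".join(spacer))
        parts.append(AT_HOOK_UNIT)
    parts.append(_rand_seq(rng, int(rng.integers(10, 18)), _NEUTRAL_AA))
    return "".join(parts)


def gen_proteome(
    n_h1: int,
    n_myb: int,
    n_hmga: int,
    n_decoy: int,
    seed: int = 0,
) -> ProteomeTruth:
    """Generate a proteome with planted H1-like, GH1-Myb-like,
    GH1-HMGA-like and decoy proteins, plus matching domain hits and a
    trivially alignable GH1-domain block.
    """
    if n_h1 + n_myb + n_hmga + n_decoy < 1:
        raise ValueError("at least one protein required")
    rng = np.random.default_rng(seed)
    template = _gh1_template(rng)
    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    labels: dict[str, str] = {}
    hook_truth: dict[str, int] = {}
    gh1_rows: list[tuple[str, str]] = [(TEMPLATE_ID, template)]

    plan = (
        [("H1", i) for i in range(n_h1)]
        + [("GH1_Myb", i) for i in range(n_myb)]
        + [("GH1_HMGA", i) for i in range(n_hmga)]
        + [("decoy", i) for i in range(n_decoy)]
    )
    for label, i in plan:
        pid = {"H1": "H1", "GH1_Myb": "MYB", "GH1_HMGA": "HMGA",
               "decoy": "DECOY"}[label] + f"_{i + 1:02d}"
        for _attempt in range(50):
            ntd, gh1, ctd, prot_hits, n_hooks = _build_protein(
                rng, pid, label, template
            )
            seq = ntd + gh1 + ctd
            rec = ProteinRecord(id=pid, residues=seq,
                                description=f"synthetic {label}")
            if len(find_at_hooks(rec)) == n_hooks:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not place AT-hooks cleanly for {pid}")
        records.append(rec)
        hits.extend(prot_hits)
        labels[pid] = label
        hook_truth[pid] = n_hooks
        gh1_rows.append((pid, gh1))

    alignment = AlignmentBlock(
        ids=tuple(r[0] for r in gh1_rows),
        rows=tuple(r[1] for r in gh1_rows),
        alphabet="protein",
    )
    return ProteomeTruth(
        records=tuple(records),
        hits=tuple(hits),
        labels=labels,
        gh1_alignment=alignment,
        n_at_hooks=hook_truth,
        seed=seed,
    )


def _build_protein(rng, pid: str, label: str, template: str):
    if label == "H1":
        ntd_len = int(rng.integers(20, 71))
        ntd = "".join(
            "K" if rng.random() < 0.18 else rng.choice(list(_NEUTRAL_AA))
            for _ in range(ntd_len)
        )
        gh1 = _mutate_gh1(rng, template, keep_sites=10)
        ctd = _h1_ctd(rng, int(rng.integers(77, 171)))
        n_hooks = 0
        extra_hits = []
    elif label == "GH1_Myb":
        ntd_len = int(rng.integers(100, 131))
        ntd = "".join(
            "K" if rng.random() < 0.10 else rng.choice(list(_NEUTRAL_AA))
            for _ in range(ntd_len)
        )
        gh1 = _mutate_gh1(rng, template, keep_sites=6)
        ctd = _acidic_ctd(rng, int(rng.integers(90, 121)))
        n_hooks = 0
        extra_hits = [DomainHit(protein_id=pid, domain_name=MYB,
                                start=10, end=min(55, ntd_len))]
    elif label == "GH1_HMGA":
        ntd_len = int(rng.integers(20, 61))
        ntd = _rand_seq(rng, ntd_len, _NEUTRAL_AA)
        gh1 = _mutate_gh1(rng, template, keep_sites=3)
        n_hooks = int(rng.integers(3, 7))
        ctd = _hmga_ctd(rng, n_hooks)
        extra_hits = []
    else:  # decoy
        ntd_len = int(rng.integers(20, 61))
        ntd = _rand_seq(rng, ntd_len, _NEUTRAL_AA)
        gh1 = _mutate_gh1(rng, template, keep_sites=int(rng.integers(0, 4)))
        ctd = _acidic_ctd(rng, int(rng.integers(80, 121)))
        n_hooks = 0
        extra_hits = []
    gh1_start = ntd_len + 1
    hits = [
        DomainHit(protein_id=pid, domain_name=GH1,
                  start=gh1_start, end=gh1_start + GH1_LEN - 1)
    ] + extra_hits
    return ntd, gh1, ctd, hits, n_hooks


# ---------------------------------------------------------------------------
# Neutral coalescent

@dataclass(frozen=True)
class CoalescentSample:
    haplotypes: tuple[str, ...]
    theta: float
    length: int
    total_branch_length: float  # in units of 2N generations
    n_mutations: int
    seed: int

    def to_alignment(self, locus_id: str = "locus") -> LocusAlignment:
        return LocusAlignment(locus_id=locus_id, haplotypes=self.haplotypes)


def gen_coalescent(
    n: int, length: int, theta: float, seed: int = 0
) -> CoalescentSample:
    """Kingman coalescent with infinite-sites mutation mapped into
    ``length`` positions (collisions re-drawn).

    Waiting times are exponential with rate C(k,2) in units of 2N
    generations; the mutation count is Poisson(theta/2 * total branch
    length) and mutations land uniformly on branches.
    """
    if n < 2 or length < 1 or theta <= 0:
        raise ValueError("need n >= 2, length >= 1, theta > 0")
    rng = np.random.default_rng(seed)
    # active lineages: (leaf index set, birth time of the branch below)
    active: list[tuple[frozenset, float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    t = 0.0
    branches: list[tuple[frozenset, float]] = []  # (leaf set, length)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / math.comb(k, 2))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (set_i, born_i) = active[i]
        (set_j, born_j) = active[j]
        branches.append((set_i, t - born_i))
        branches.append((set_j, t - born_j))
        merged = (set_i | set_j, t)
        active = [a for idx, a in enumerate(active) if idx not in (i, j)]
        active.append(merged)
    tbl = sum(b for _, b in branches)
    n_mut = int(rng.poisson(theta / 2.0 * tbl))
    if n_mut > length:
        raise ValueError(
            f"{n_mut} mutations cannot occupy {length} distinct positions"
        )
    ancestral = _rand_seq(rng, length, _BASES)
    rows = [list(ancestral) for _ in range(n)]
    if n_mut:
        lengths = np.array([b for _, b in branches])
        probs = lengths / tbl
        used: set[int] = set()
        for _ in range(n_mut):
            b = int(rng.choice(len(branches), p=probs))
            pos = int(rng.integers(0, length))
            while pos in used:
                pos = int(rng.integers(0, length))
            used.add(pos)
            old = ancestral[pos]
            new = rng.choice([c for c in _BASES if c != old])
            for leaf in branches[b][0]:
                rows[leaf][pos] = new
    return CoalescentSample(
        haplotypes=tuple("".join(r) for r in rows),
        theta=theta,
        length=length,
        total_branch_length=tbl,
        n_mutations=n_mut,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# HKA counts

@dataclass(frozen=True)
class HKACounts:
    loci: tuple[HKALocus, ...]
    focal_id: str
    theta: tuple[float, ...]
    t: float
    k_focal: float
    seed: int

    def to_hka_data(self) -> HKAData:
        return HKAData(loci=self.loci, focal_id=self.focal_id)


def gen_hka_counts(
    theta: Sequence[float],
    t: float,
    k_focal: float,
    n: Sequence[int],
    seed: int = 0,
    focal_index: int = 0,
) -> HKACounts:
    """Draw S_i ~ Poisson(kappa_i theta_i a(n_i)) and
    D_i ~ Poisson(theta_i (T+1)); locus ``focal_index`` carries k."""
    if len(theta) != len(n):
        raise ValueError("theta and n must have equal length")
    if any(th <= 0 for th in theta) or t <= 0 or k_focal <= 0:
        raise ValueError("theta, T and k must all be positive")
    rng = np.random.default_rng(seed)
    loci = []
    for i, (th, ni) in enumerate(zip(theta, n)):
        kappa = k_focal if i == focal_index else 1.0
        s = int(rng.poisson(kappa * th * harmonic(ni)))
        d = int(rng.poisson(th * (t + 1.0)))
        loci.append(HKALocus(locus_id=f"L{i}", s=s, d=d, n=ni))
    return HKACounts(
        loci=tuple(loci),
        focal_id=f"L{focal_index}",
        theta=tuple(float(x) for x in theta),
        t=float(t),
        k_focal=float(k_focal),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Coding-region population

_FLANK = 90


@dataclass(frozen=True)
class CodingPopulation:
    reference: str
    alignment: LocusAlignment
    variants: tuple[VariantRecord, ...]
    annotation: SiteClassAnnotation
    coding_interval: tuple[int, int]
    effect_truth: dict[int, str]  # position -> synonymous | nonsynonymous
    seed: int


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = _rand_seq(rng, 3, _BASES)
        if _CODON_TO_AA[c] != "*":
            codons.append(c)
    return "".join(codons)


def gen_coding_population(
    l_coding: int,
    n: int,
    n_syn: int,
    n_nonsyn: int,
    n_indel: int,
    seed: int = 0,
) -> CodingPopulation:
    """A reference with noncoding flanks and a stop-free ORF, plus a
    haplotype sample carrying planted synonymous/nonsynonymous SNPs and
    indels confined to the flanks.
    """
    if l_coding % 3 != 0:
        raise ValueError("coding length must be divisible by 3")
    rng = np.random.default_rng(seed)
    orf = _random_orf(rng, l_coding // 3)
    reference = (
        _rand_seq(rng, _FLANK, _BASES) + orf + _rand_seq(rng, _FLANK, _BASES)
    )
    coding_iv = (_FLANK + 1, _FLANK + l_coding)
    annotation = classify_coding_sites(reference, [coding_iv])

    coding_positions = list(range(_FLANK + 1, _FLANK + l_coding + 1))
    rng.shuffle(coding_positions)
    planted: dict[int, tuple[str, str]] = {}  # pos -> (alt, effect)
    want = [("synonymous", n_syn), ("nonsynonymous", n_nonsyn)]
    for effect, count in want:
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 200 * (count + 1):
                raise RuntimeError(f"could not place {count} {effect} SNPs")
            if not coding_positions:
                raise RuntimeError("ran out of coding positions")
            pos = coding_positions.pop()
            ref_base = reference[pos - 1]
            alts = [
                b for b in _BASES
                if b != ref_base and snp_effect(annotation, pos, b) == effect
            ]
            if not alts:
                continue
            planted[pos] = (str(rng.choice(alts)), effect)
            placed += 1

    rows = [list(reference) for _ in range(n)]
    variants: list[VariantRecord] = []
    for pos in sorted(planted):
        alt, _effect = planted[pos]
        n_alt = int(rng.integers(1, n))
        carriers = rng.choice(n, size=n_alt, replace=False)
        for c in carriers:
            rows[c][pos - 1] = alt
        variants.append(
            VariantRecord(
                locus_id="locus",
                position=pos,
                ref=reference[pos - 1],
                alt=alt,
                allele_counts=(n - n_alt, n_alt),
            )
        )

    flank_positions = list(range(1, _FLANK - 4)) + list(
        range(_FLANK + l_coding + 1, len(reference) - 4)
    )
    rng.shuffle(flank_positions)
    for _ in range(n_indel):
        pos = flank_positions.pop()
        dlen = int(rng.integers(1, 4))
        ref_allele = reference[pos - 1:pos - 1 + dlen + 1]
        n_alt = int(rng.integers(1, n))
        if rng.random() < 0.5:  # deletion
            ref_a, alt_a = ref_allele, ref_allele[0]
        else:  # insertion
            ins = _rand_seq(rng, dlen, _BASES)
            ref_a, alt_a = reference[pos - 1], reference[pos - 1] + ins
        variants.append(
            VariantRecord(
                locus_id="locus",
                position=pos,
                ref=ref_a,
                alt=alt_a,
                allele_counts=(n - n_alt, n_alt),
            )
        )

    variants.sort(key=lambda v: v.position)
    return CodingPopulation(
        reference=reference,
        alignment=LocusAlignment(
            locus_id="locus", haplotypes=tuple("".join(r) for r in rows)
        ),
        variants=tuple(variants),
        annotation=annotation,
        coding_interval=coding_iv,
        effect_truth={p: e for p, (a, e) in planted.items()},
        seed=seed,
    )
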
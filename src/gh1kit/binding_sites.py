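"""Map the 10 putative basic DNA-binding sites through a GH1 alignment
and count per-protein conservation."""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import AlignmentBlock, SeqioError

BASIC_RESIDUES = set("KRH")  # His counts: the first site is itself a His

# Default site labels/positions in GH1-domain coordinates (castor clade-I
# numbering): 5' of helix I, between helices I and II, helix II, helix
# III, and the beta-hairpin.
DEFAULT_SITES: tuple[tuple[str, str, int], ...] = (
    ("His2", "pre_helix_I", 2),
    ("Lys17", "between_I_II", 17),
    ("Arg19", "between_I_II", 19),
    ("Lys29", "helix_II", 29),
    ("Lys43", "helix_III", 43),
    ("Lys44", "helix_III", 44),
    ("Lys51", "helix_III", 51),
    ("Lys52", "helix_III", 52),
    ("Lys61", "beta_hairpin", 61),
    ("Lys67", "beta_hairpin", 67),
)
DEFAULT_SITE_POSITIONS = tuple(p for _, _, p in DEFAULT_SITES)


@dataclass(frozen=True)
class ReferenceSite:
    label: str
    context: str
    alignment_column: int  # 1-based


@dataclass(frozen=True)
class ReferenceSiteMap:
    sites: tuple[ReferenceSite, ...]

    def __post_init__(self) -> None:
        cols = [s.alignment_column for s in self.sites]
        if len(self.sites) != 10:
            raise ValueError(f"expected exactly 10 sites, got {len(self.sites)}")
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("site columns must be strictly increasing")

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(s.alignment_column for s in self.sites)


@dataclass(frozen=True)
class ConservationReport:
    protein_id: str
    observed: tuple[str, ...]  # residue or '-' at each site column
    is_basic: tuple[bool, ...]
    conserved_count: int


def ungapped_to_column(row: str, position: int) -> int:
    """Convert a 1-based ungapped residue index to its alignment column."""
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            seen += 1
            if seen == position:
                return col
    raise ValueError(
        f"position {position} exceeds ungapped length {seen} of reference row"
    )


def build_site_map(
    alignment: AlignmentBlock,
    reference_id: str,
    reference_positions=DEFAULT_SITE_POSITIONS,
    labels=None,
) -> ReferenceSiteMap:
    """Convert unaligned reference residue indices to alignment columns.

    ``reference_positions`` are 1-based indices into the ungapped
    reference row (defaults to the shipped clade-I numbering).
    """
    row = alignment.row(reference_id)
    if len(reference_positions) != 10:
        raise ValueError("exactly 10 reference positions required")
    if labels is None:
        if tuple(reference_positions) == DEFAULT_SITE_POSITIONS:
            labels = [(lab, ctx) for lab, ctx, _ in DEFAULT_SITES]
        else:
            labels = [(f"site{i + 1}", "unknown") for i in range(10)]
    sites = tuple(
        ReferenceSite(
            label=lab,
            context=ctx,
            alignment_column=ungapped_to_column(row, pos),
        )
        for (lab, ctx), pos in zip(labels, reference_positions)
    )
    return ReferenceSiteMap(sites=sites)


def score_conservation(
    alignment: AlignmentBlock, site_map: ReferenceSiteMap, protein_id: str
) -> ConservationReport:
    """Record the residue at each site column; basic = K/R/H, gap = not
    basic; conservation is class-based, not similarity-based."""
    row = alignment.row(protein_id)  # raises SeqioError for unknown ids
    observed = tuple(row[c - 1] for c in site_map.columns)
    is_basic = tuple(ch in BASIC_RESIDUES for ch in observed)
    return ConservationReport(
        protein_id=protein_id,
        observed=observed,
        is_basic=is_basic,
        conserved_count=sum(is_basic),
    )
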
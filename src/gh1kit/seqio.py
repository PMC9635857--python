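"""Readers and writers for the external formats plus the shared data model.

Coordinates are 1-based and inclusive throughout the package; conversion to
0-based slices happens only at array boundaries inside functions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

log = logging.getLogger(__name__)

AA_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALLOWED = AA_CANONICAL | {"X"}
NT_ALLOWED = set("ACGTN")

GH1 = "GH1"
MYB = "Myb"


class SeqioError(ValueError):
    """Raised for malformed external input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    ``residues`` is uppercase and restricted to the 20 canonical letters
    plus ``X`` (unknown). X residues are carried along but excluded from
    composition statistics downstream.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqioError("protein record requires a non-empty id")
        if len(self.residues) < 1:
            raise SeqioError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideRecord:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqioError("nucleotide record requires a non-empty id")
        if len(self.residues) < 1:
            raise SeqioError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """A domain annotation on one protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SeqioError(
                f"bad coordinates for {self.domain_name} hit on "
                f"{self.protein_id}: start={self.start} end={self.end}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise SeqioError(f"negative e-value on hit {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantRecord:
    """One ref/alt allele pair at a position within a locus.

    Multi-allelic sites are decomposed upstream so each record carries a
    single alternate allele. ``allele_counts`` is (ref count, alt count)
    over sampled haplotypes; missing genotypes are absent haplotypes and
    contribute to neither count.
    """

    locus_id: str
    position: int
    ref: str
    alt: str
    vtype: str = field(init=False)
    allele_counts: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SeqioError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise SeqioError("ref and alt alleles must be non-empty")
        rc, ac = self.allele_counts
        if rc < 0 or ac < 0:
            raise SeqioError("allele counts must be nonnegative")
        if rc == 0 and ac == 0:
            raise SeqioError(
                f"variant {self.locus_id}:{self.position} has no observed alleles"
            )
        vtype = "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        object.__setattr__(self, "vtype", vtype)


@dataclass(frozen=True)
class AlignmentBlock:
    """A gapped multiple alignment; gap character is '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str = "protein"  # or "nucleotide"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SeqioError("ids and rows differ in count")
        if len(self.ids) < 2:
            raise SeqioError("alignment needs at least 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise SeqioError("duplicate ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise SeqioError(f"rows of unequal length: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise SeqioError(f"id {seq_id!r} not in alignment") from None


# ---------------------------------------------------------------------------
# FASTA

def _validate_residues(seq: str, allowed: set[str], rec_id: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SeqioError(
                f"illegal character {ch!r} at position {i} in record {rec_id!r}"
            )
    return seq


def read_fasta(
    path: str | Path, alphabet: str = "protein"
) -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a FASTA file into validated records, order-preserving.

    ``alphabet`` is ``"protein"`` (20 canonical letters + X) or
    ``"nucleotide"`` (ACGTN). Lowercase input is uppercased. Duplicate
    ids, empty sequences and illegal characters raise :class:`SeqioError`.
    """
    if alphabet == "protein":
        allowed, cls = AA_ALLOWED, ProteinRecord
    elif alphabet == "nucleotide":
        allowed, cls = NT_ALLOWED, NucleotideRecord
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqioError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _validate_residues(str(rec.seq), allowed, rec.id)
        if not seq:
            raise SeqioError(f"empty sequence for FASTA id {rec.id!r}")
        desc = rec.description[len(rec.id):].strip()
        records.append(cls(id=rec.id, residues=seq, description=desc))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    bio = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path, alphabet: str = "protein") -> AlignmentBlock:
    """Read a gapped FASTA alignment."""
    allowed = (AA_ALLOWED if alphabet == "protein" else NT_ALLOWED) | {"-"}
    ids: list[str] = []
    rows: list[str] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise SeqioError(f"duplicate FASTA id {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(_validate_residues(str(rec.seq), allowed, rec.id))
    return AlignmentBlock(ids=tuple(ids), rows=tuple(rows), alphabet=alphabet)


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(block.ids, block.rows):
            fh.write(f">{seq_id}\n{row}\n")


# ---------------------------------------------------------------------------
# Domain tables

_DOMTBL_MIN_FIELDS = 23


def read_domain_table(
    path: str | Path, dialect: str = "tsv"
) -> list[DomainHit]:
    """Parse domain hits from a TSV table or HMMER ``--domtblout`` output.

    TSV columns: protein_id, domain_name, start, end[, evalue] with a
    header line. domtblout rows use envelope coordinates and the
    independent e-value; '#' comment lines are skipped.
    """
    if dialect == "tsv":
        return _read_domain_tsv(path)
    if dialect == "hmmer_domtblout":
        return _read_domtblout(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_domain_tsv(path: str | Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("protein_id", "domain_name", "start", "end"):
            if req not in idx:
                raise SeqioError(f"domain TSV missing column {req!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                ev = (
                    float(parts[idx["evalue"]])
                    if "evalue" in idx and parts[idx["evalue"]] != ""
                    else None
                )
                hits.append(
                    DomainHit(
                        protein_id=parts[idx["protein_id"]],
                        domain_name=parts[idx["domain_name"]],
                        start=int(parts[idx["start"]]),
                        end=int(parts[idx["end"]]),
                        evalue=ev,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise SeqioError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _read_domtblout(path: str | Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < _DOMTBL_MIN_FIELDS:
                raise SeqioError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS} "
                    f"whitespace-delimited fields, got {len(parts)}"
                )
            # target name (0) = protein searched; query name (3) = profile;
            # i-Evalue (12); env from/to (19, 20).
            hits.append(
                DomainHit(
                    protein_id=parts[0],
                    domain_name=parts[3],
                    start=int(parts[19]),
                    end=int(parts[20]),
                    evalue=float(parts[12]),
                )
            )
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_name\tstart\tend\tevalue\n")
        for h in hits:
            ev = "" if h.evalue is None else repr(h.evalue)
            fh.write(f"{h.protein_id}\t{h.domain_name}\t{h.start}\t{h.end}\t{ev}\n")


def hits_for(hits: Iterable[DomainHit], protein_id: str) -> list[DomainHit]:
    """All hits on one protein, sorted by start coordinate."""
    return sorted(
        (h for h in hits if h.protein_id == protein_id), key=lambda h: h.start
    )


# ---------------------------------------------------------------------------
# Variant tables (minimal VCF v4.x subset + TSV)

_GT_SPLIT = re.compile(r"[/|]")


def read_variant_table(
    path: str | Path, dialect: str = "vcf"
) -> list[VariantRecord]:
    """Parse variants from a VCF v4.x subset or a plain TSV.

    Only CHROM, POS, REF, ALT and allele counts are used. Counts come
    from per-sample GT fields when present, else from INFO AC/AN.
    Missing genotypes ('.') count as absent haplotypes. Multi-allelic
    sites are decomposed into one record per alternate allele.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _counts_from_genotypes(
    fields: Sequence[str], n_alts: int, where: str
) -> list[tuple[int, int]]:
    ref_n = 0
    alt_n = [0] * n_alts
    for sample in fields:
        gt = sample.split(":", 1)[0]
        for allele in _GT_SPLIT.split(gt):
            if allele in (".", ""):
                continue  # absent haplotype, never ref
            a = int(allele)
            if a == 0:
                ref_n += 1
            elif 1 <= a <= n_alts:
                alt_n[a - 1] += 1
            else:
                raise SeqioError(f"{where}: allele index {a} out of range")
    return [(ref_n, alt_n[i]) for i in range(n_alts)]


def _counts_from_info(info: str, n_alts: int, where: str) -> list[tuple[int, int]]:
    kv = dict(
        item.split("=", 1) if "=" in item else (item, "")
        for item in info.split(";")
        if item
    )
    if "AC" not in kv or "AN" not in kv:
        raise SeqioError(f"{where}: no GT fields and no AC/AN INFO keys")
    acs = [int(x) for x in kv["AC"].split(",")]
    an = int(kv["AN"])
    if len(acs) != n_alts:
        raise SeqioError(f"{where}: AC arity {len(acs)} != {n_alts} ALT alleles")
    if sum(acs) > an:
        raise SeqioError(f"{where}: AC sum {sum(acs)} exceeds AN {an}")
    ref_n = an - sum(acs)
    return [(ref_n, acs[i]) for i in range(n_alts)]


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise SeqioError(f"{path}:{lineno}: fewer than 8 VCF columns")
            chrom, pos, _id, ref, alt_field, _qual, _filt, info = parts[:8]
            where = f"{path}:{lineno}"
            alts = alt_field.split(",")
            if len(parts) >= 10:
                counts = _counts_from_genotypes(parts[9:], len(alts), where)
            else:
                counts = _counts_from_info(info, len(alts), where)
            for alt, cnt in zip(alts, counts):
                if cnt == (0, 0):
                    log.warning("%s: alt %s unobserved, dropped", where, alt)
                    continue
                records.append(
                    VariantRecord(
                        locus_id=chrom,
                        position=int(pos),
                        ref=ref.upper(),
                        alt=alt.upper(),
                        allele_counts=cnt,
                    )
                )
    return records


def _read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("locus_id", "position", "ref", "alt", "ref_count", "alt_count"):
            if req not in idx:
                raise SeqioError(f"variant TSV missing column {req!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            try:
                records.append(
                    VariantRecord(
                        locus_id=p[idx["locus_id"]],
                        position=int(p[idx["position"]]),
                        ref=p[idx["ref"]].upper(),
                        alt=p[idx["alt"]].upper(),
                        allele_counts=(
                            int(p[idx["ref_count"]]),
                            int(p[idx["alt_count"]]),
                        ),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise SeqioError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_variant_table(
    records: Iterable[VariantRecord], path: str | Path
) -> None:
    """Write the TSV dialect (round-trips with ``read_variant_table``)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tposition\tref\talt\tvtype\tref_count\talt_count\n")
        for r in records:
            rc, ac = r.allele_counts
            fh.write(
                f"{r.locus_id}\t{r.position}\t{r.ref}\t{r.alt}\t{r.vtype}"
                f"\t{rc}\t{ac}\n"
            )


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path: str | Path) -> None:
    """Serialize an NJ tree (any object with ``to_newick()``) to a file.

    Negative branch lengths are written as-is with a logged warning.
    """
    newick = tree.to_newick()
    if re.search(r":-", newick):
        log.warning("tree contains negative branch lengths; written as-is")
    with open(path, "w") as fh:
        fh.write(newick + "\n")
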
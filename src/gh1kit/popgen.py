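"""Per-locus diversity statistics by site class, SNP/indel densities,
Tajima's D and the maximum-likelihood HKA likelihood-ratio test.

Gap handling is complete deletion: any column containing a gap in any
haplotype is removed before S, pi and Tajima's D are computed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2
from Bio.Data.CodonTable import standard_dna_table

from .physchem import round_half_up
from .seqio import VariantRecord

log = logging.getLogger(__name__)

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"
_BASES = "ACGT"


@dataclass(frozen=True)
class LocusAlignment:
    """n equal-length haplotype rows for one locus (gaps allowed)."""

    locus_id: str
    haplotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 2:
            raise ValueError("need at least 2 haplotypes")
        widths = {len(h) for h in self.haplotypes}
        if len(widths) != 1:
            raise ValueError("haplotypes of unequal length")
        if self.length < 1:
            raise ValueError("empty alignment")
        object.__setattr__(
            self, "haplotypes", tuple(h.upper() for h in self.haplotypes)
        )

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])


def _ungapped_columns(alignment: LocusAlignment) -> list[int]:
    """0-based indices of columns without any gap (complete deletion)."""
    return [
        c
        for c in range(alignment.length)
        if all(h[c] != "-" for h in alignment.haplotypes)
    ]


def segregating_sites(alignment: LocusAlignment) -> int:
    """Number of polymorphic columns after complete deletion of gaps."""
    count = 0
    for c in _ungapped_columns(alignment):
        if len({h[c] for h in alignment.haplotypes}) >= 2:
            count += 1
    return count


def mean_pairwise_differences(alignment: LocusAlignment) -> float:
    """Average count of differing (gap-free) columns over all pairs."""
    cols = _ungapped_columns(alignment)
    n = alignment.n
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        hi, hj = alignment.haplotypes[i], alignment.haplotypes[j]
        total += sum(hi[c] != hj[c] for c in cols)
    return total / math.comb(n, 2)


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(s: int, n: int, length: float) -> float:
    """Watterson's estimator per site: S / (a1 * L)."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    return s / (harmonic(n) * length)


def tajima_d(alignment: LocusAlignment) -> float | None:
    """Tajima's D with the standard 1989 constants; None when undefined
    (S = 0 or zero variance)."""
    n = alignment.n
    s = segregating_sites(alignment)
    if s == 0 or n < 3:
        return None
    a1 = harmonic(n)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return None
    pi_count = mean_pairwise_differences(alignment)
    return (pi_count - s / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Site classes (Nei-Gojobori 1986, equal pathway weighting)

def _codon_site_fractions(codon: str) -> tuple[float, float, float]:
    """Fraction of synonymous changes at each codon position (0..1)."""
    aa = _CODON_TO_AA[codon]
    fractions = []
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if _CODON_TO_AA[mutant] == aa:
                syn += 1
        fractions.append(syn / 3.0)
    return tuple(fractions)


@dataclass(frozen=True)
class SiteClassAnnotation:
    """Per-position fractional site counts derived from a reference.

    ``syn_sites``/``nonsyn_sites`` are zero outside coding intervals;
    each noncoding position contributes one silent site. ``codon_index``
    is -1 for noncoding positions, else the index of the codon the
    position belongs to; ``codon_pos`` gives the within-codon offset.
    """

    locus_id: str
    length: int
    coding: tuple[tuple[int, int], ...]  # 1-based inclusive intervals
    syn_sites: tuple[float, ...]
    nonsyn_sites: tuple[float, ...]
    codon_index: tuple[int, ...]
    codon_pos: tuple[int, ...]
    codons: tuple[str, ...]  # reference codons, in CDS order

    def is_coding(self, pos0: int) -> bool:
        return self.codon_index[pos0] >= 0


def classify_coding_sites(
    reference: str,
    coding: Sequence[tuple[int, int]],
) -> SiteClassAnnotation:
    """Annotate each reference position with Nei-Gojobori site fractions.

    ``coding`` holds 1-based inclusive plus-strand intervals whose
    concatenation is the CDS; its length must be divisible by 3. An
    internal stop codon triggers a warning; a partial codon is an error.
    """
    reference = reference.upper()
    length = len(reference)
    cds_positions: list[int] = []
    for start, end in coding:
        if not (1 <= start <= end <= length):
            raise ValueError(f"coding interval ({start},{end}) out of range")
        cds_positions.extend(range(start - 1, end))
    if len(cds_positions) % 3 != 0:
        raise ValueError(
            f"coding length {len(cds_positions)} is not divisible by 3"
        )
    syn = [0.0] * length
    nonsyn = [0.0] * length
    codon_index = [-1] * length
    codon_pos = [-1] * length
    codons: list[str] = []
    for ci in range(len(cds_positions) // 3):
        triplet = cds_positions[3 * ci:3 * ci + 3]
        codon = "".join(reference[p] for p in triplet)
        if "N" in codon or "-" in codon:
            raise ValueError(f"ambiguous reference codon {codon!r}")
        aa = _CODON_TO_AA[codon]
        if aa == "*" and ci < len(cds_positions) // 3 - 1:
            log.warning("internal stop codon at codon %d", ci + 1)
        fractions = _codon_site_fractions(codon)
        codons.append(codon)
        for k, p in enumerate(triplet):
            syn[p] = fractions[k]
            nonsyn[p] = 1.0 - fractions[k]
            codon_index[p] = ci
            codon_pos[p] = k
    return SiteClassAnnotation(
        locus_id="",
        length=length,
        coding=tuple((s, e) for s, e in coding),
        syn_sites=tuple(syn),
        nonsyn_sites=tuple(nonsyn),
        codon_index=tuple(codon_index),
        codon_pos=tuple(codon_pos),
        codons=tuple(codons),
    )


def snp_effect(annotation: SiteClassAnnotation, position: int, alt: str) -> str:
    """Effect of a single-base substitution: 'synonymous',
    'nonsynonymous' or 'noncoding'. ``position`` is 1-based."""
    p = position - 1
    ci = annotation.codon_index[p]
    if ci < 0:
        return "noncoding"
    codon = annotation.codons[ci]
    k = annotation.codon_pos[p]
    mutant = codon[:k] + alt.upper() + codon[k + 1:]
    if mutant == codon:
        raise ValueError("alt allele equals the reference base")
    return (
        "synonymous"
        if _CODON_TO_AA[mutant] == _CODON_TO_AA[codon]
        else "nonsynonymous"
    )


def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Nei-Gojobori (sd, nd) between two codons, averaging over all
    mutational pathways with equal weight; steps through or out of stop
    codons count as nonsynonymous."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = c1
        sd = nd = 0
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if _CODON_TO_AA[nxt] == _CODON_TO_AA[current] and \
                    _CODON_TO_AA[nxt] != "*":
                sd += 1
            else:
                nd += 1
            current = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


@dataclass(frozen=True)
class DiversityStats:
    locus_id: str
    n: int
    sites_total: float
    s: int
    pi_total: float
    theta_w: float
    tajima_d: float | None
    pi_sil: float | None = None
    pi_syn: float | None = None
    pi_nonsyn: float | None = None
    zero_site_classes: tuple[str, ...] = ()


def nucleotide_diversity(
    alignment: LocusAlignment,
    annotation: SiteClassAnnotation | None = None,
    site_class: str | None = None,
) -> float:
    """Per-site nucleotide diversity, optionally restricted to a site
    class ('silent', 'synonymous' or 'nonsynonymous').

    Class denominators are fractional Nei-Gojobori site counts from the
    annotation; class-weighted differences come from pathway-averaged
    codon comparisons. A zero site count yields 0.0 (flagged upstream).
    """
    if site_class is None:
        cols = _ungapped_columns(alignment)
        if not cols:
            return 0.0
        n = alignment.n
        total = 0
        for i, j in itertools.combinations(range(n), 2):
            hi, hj = alignment.haplotypes[i], alignment.haplotypes[j]
            total += sum(hi[c] != hj[c] for c in cols)
        return total / (math.comb(n, 2) * len(cols))
    if annotation is None:
        raise ValueError("site_class requires an annotation")
    diffs, sites = _class_differences(alignment, annotation)
    if sites[site_class] == 0:
        return 0.0
    return diffs[site_class] / (
        math.comb(alignment.n, 2) * sites[site_class]
    )


def _class_differences(
    alignment: LocusAlignment, annotation: SiteClassAnnotation
) -> tuple[dict[str, float], dict[str, float]]:
    """Summed pairwise class-weighted differences and class site counts.

    Codons containing any gapped/excluded column are dropped entirely
    from both numerator and denominator.
    """
    if annotation.length != alignment.length:
        raise ValueError("annotation length does not match alignment")
    cols = set(_ungapped_columns(alignment))
    # usable codons: all three positions survive complete deletion
    codon_cols: dict[int, list[int]] = {}
    for p in range(annotation.length):
        ci = annotation.codon_index[p]
        if ci >= 0:
            codon_cols.setdefault(ci, []).append(p)
    usable_codons = {
        ci: ps for ci, ps in codon_cols.items() if all(p in cols for p in ps)
    }
    noncoding_cols = [
        c for c in cols if annotation.codon_index[c] < 0
    ]
    syn_sites = sum(
        annotation.syn_sites[p] for ps in usable_codons.values() for p in ps
    )
    nonsyn_sites = sum(
        annotation.nonsyn_sites[p] for ps in usable_codons.values() for p in ps
    )
    sites = {
        "synonymous": syn_sites,
        "nonsynonymous": nonsyn_sites,
        "silent": len(noncoding_cols) + syn_sites,
    }
    sd_sum = nd_sum = nc_sum = 0.0
    for i, j in itertools.combinations(range(alignment.n), 2):
        hi, hj = alignment.haplotypes[i], alignment.haplotypes[j]
        nc_sum += sum(hi[c] != hj[c] for c in noncoding_cols)
        for ps in usable_codons.values():
            c1 = "".join(hi[p] for p in ps)
            c2 = "".join(hj[p] for p in ps)
            if c1 != c2:
                sd, nd = _codon_pair_differences(c1, c2)
                sd_sum += sd
                nd_sum += nd
    diffs = {
        "synonymous": sd_sum,
        "nonsynonymous": nd_sum,
        "silent": nc_sum + sd_sum,
    }
    return diffs, sites


def diversity_stats(
    alignment: LocusAlignment,
    annotation: SiteClassAnnotation | None = None,
) -> DiversityStats:
    """The per-locus summary row: S, pi by class, theta_w, Tajima's D."""
    cols = _ungapped_columns(alignment)
    s = segregating_sites(alignment)
    sites_total = len(cols)
    pi_total = nucleotide_diversity(alignment)
    theta = watterson_theta(s, alignment.n, sites_total) if sites_total else 0.0
    pi_sil = pi_syn = pi_nonsyn = None
    zero_classes: list[str] = []
    if annotation is not None:
        diffs, sites = _class_differences(alignment, annotation)
        per_class = {}
        for cls in ("silent", "synonymous", "nonsynonymous"):
            if sites[cls] == 0:
                per_class[cls] = 0.0
                zero_classes.append(cls)
            else:
                per_class[cls] = diffs[cls] / (
                    math.comb(alignment.n, 2) * sites[cls]
                )
        pi_sil = per_class["silent"]
        pi_syn = per_class["synonymous"]
        pi_nonsyn = per_class["nonsynonymous"]
    return DiversityStats(
        locus_id=alignment.locus_id,
        n=alignment.n,
        sites_total=sites_total,
        s=s,
        pi_total=pi_total,
        theta_w=theta,
        tajima_d=tajima_d(alignment),
        pi_sil=pi_sil,
        pi_syn=pi_syn,
        pi_nonsyn=pi_nonsyn,
        zero_site_classes=tuple(zero_classes),
    )


# ---------------------------------------------------------------------------
# Variant density

def variant_density(
    variants: Iterable[VariantRecord], total_length: int
) -> tuple[float | None, float | None]:
    """(bp per SNP, bp per indel) to 1 decimal; None for zero counts."""
    if total_length < 1:
        raise ValueError("total_length must be >= 1")
    n_snp = n_indel = 0
    for v in variants:
        if v.vtype == "SNP":
            n_snp += 1
        else:
            n_indel += 1
    bp_snp = round_half_up(total_length / n_snp, 1) if n_snp else None
    bp_indel = round_half_up(total_length / n_indel, 1) if n_indel else None
    return bp_snp, bp_indel


# ---------------------------------------------------------------------------
# ML-HKA

@dataclass(frozen=True)
class HKALocus:
    locus_id: str
    s: int  # segregating sites
    d: int  # divergence differences to the outgroup
    n: int  # sample size (haplotypes)
    length: float | None = None  # bookkeeping only

    def __post_init__(self) -> None:
        if self.s < 0 or self.d < 0:
            raise ValueError("counts must be nonnegative")
        if self.n < 2:
            raise ValueError("sample size must be >= 2")


@dataclass(frozen=True)
class HKAData:
    loci: tuple[HKALocus, ...]
    focal_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.loci) < 2:
            raise ValueError("HKA needs at least 2 loci")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        if self.focal_id is not None and self.focal_id not in ids:
            raise ValueError(f"unknown focal locus {self.focal_id!r}")


@dataclass(frozen=True)
class HKAFit:
    model: str  # "neutral" | "selection"
    theta_hat: dict[str, float]
    t_hat: float
    k_hat: float | None
    lnl: float
    boundary_loci: tuple[str, ...]
    converged: bool


@dataclass(frozen=True)
class HKAResult:
    theta_hat: dict[str, float]
    t_hat: float
    k_hat: float
    lnl_neutral: float
    lnl_selection: float
    lrt: float
    p_value: float


def _log_poisson(x: float, lam: float) -> float:
    if lam <= 0:
        return 0.0 if x == 0 else -np.inf
    return x * math.log(lam) - lam - float(gammaln(x + 1))


def _profile_lnl(data: HKAData, t: float, k: float) -> float:
    """Log-likelihood with each theta_i profiled out in closed form.

    E[S_i] = kappa_i * theta_i * a(n_i), E[D_i] = theta_i * (T + 1);
    the stationarity condition gives
    theta_i = (S_i + D_i) / (kappa_i * a(n_i) + T + 1).
    """
    lnl = 0.0
    for locus in data.loci:
        kappa = k if locus.locus_id == data.focal_id else 1.0
        a = harmonic(locus.n)
        theta = (locus.s + locus.d) / (kappa * a + t + 1.0)
        lnl += _log_poisson(locus.s, kappa * theta * a)
        lnl += _log_poisson(locus.d, theta * (t + 1.0))
    return lnl


def _profiled_thetas(data: HKAData, t: float, k: float) -> dict[str, float]:
    out = {}
    for locus in data.loci:
        kappa = k if locus.locus_id == data.focal_id else 1.0
        a = harmonic(locus.n)
        out[locus.locus_id] = (locus.s + locus.d) / (kappa * a + t + 1.0)
    return out


_T_STARTS = (-3.0, -1.0, 0.0, 1.0, 3.0)  # log T grid for multi-start


def hka_fit(data: HKAData, model: str = "neutral") -> HKAFit:
    """Maximum-likelihood fit of the HKA Poisson model.

    Optimizes in log-parameter space over T (and the focal selection
    factor k under the selection model) from multiple fixed starts; the
    per-locus thetas have a closed-form profile solution.
    """
    if model not in ("neutral", "selection"):
        raise ValueError(f"unknown model {model!r}")
    if model == "selection" and data.focal_id is None:
        raise ValueError("selection model requires a focal locus")

    if model == "neutral":
        def objective(x):
            return -_profile_lnl(data, math.exp(x[0]), 1.0)
        starts = [[t0] for t0 in _T_STARTS]
    else:
        neutral = hka_fit(data, "neutral")

        def objective(x):
            return -_profile_lnl(data, math.exp(x[0]), math.exp(x[1]))
        # warm start at the neutral optimum (k = 1) guarantees
        # lnL_selection >= lnL_neutral by nesting
        starts = [[math.log(neutral.t_hat), 0.0]] + [
            [t0, k0] for t0 in (-1.0, 1.0) for k0 in (-1.0, 1.0)
        ]

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10,
                                "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("HKA fit failed to converge from all starts")
    t_hat = math.exp(best.x[0])
    k_hat = math.exp(best.x[1]) if model == "selection" else None
    thetas = _profiled_thetas(data, t_hat, k_hat if k_hat else 1.0)
    boundary = tuple(
        lid for lid, th in thetas.items() if th == 0.0
    )
    if boundary:
        log.warning("theta at zero boundary for loci: %s", ", ".join(boundary))
    return HKAFit(
        model=model,
        theta_hat=thetas,
        t_hat=t_hat,
        k_hat=k_hat,
        lnl=-float(best.fun),
        boundary_loci=boundary,
        converged=bool(best.success) or np.isfinite(best.fun),
    )


def hka_test(data: HKAData) -> HKAResult:
    """Likelihood-ratio test of the selection model against the neutral
    restriction (k = 1); 2*dlnL against chi-square with 1 df."""
    neutral = hka_fit(data, "neutral")
    selection = hka_fit(data, "selection")
    lrt = max(0.0, 2.0 * (selection.lnl - neutral.lnl))
    p = float(chi2.sf(lrt, df=1))
    return HKAResult(
        theta_hat=selection.theta_hat,
        t_hat=selection.t_hat,
        k_hat=selection.k_hat,
        lnl_neutral=neutral.lnl,
        lnl_selection=selection.lnl,
        lrt=lrt,
        p_value=p,
    )
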
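"""Physicochemical profiling: MW, theoretical pI, lysine content, net
charge and the 20-aa moving-sum charge profile along the terminal tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

from .architecture import RegionPartition

log = logging.getLogger(__name__)

# Average residue (amino acid minus water) masses in daltons, ExPASy values.
RESIDUE_MASS_DA: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153

# Bjellqvist pKa set (the ExPASy convention). Swappable: pass an
# alternative table of the same shape to theoretical_pi.
BJELLQVIST_PKA: Mapping[str, float] = {
    "K": 10.0, "R": 12.0, "H": 5.98,        # positive side chains
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,  # negative side chains
    "Nterm": 7.5, "Cterm": 3.55,
}
POSITIVE = ("K", "R", "H")
NEGATIVE = ("D", "E", "C", "Y")

CHARGE_OF = {"K": 1, "R": 1, "D": -1, "E": -1}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (Table-style formatting, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def molecular_weight(residues: str) -> float:
    """Average molecular weight in kDa (residue masses + one water).

    X residues are excluded from the sum with a warning.
    """
    if not residues:
        raise ValueError("cannot compute MW of an empty sequence")
    n_x = residues.count("X")
    if n_x:
        log.warning("%d X residue(s) excluded from MW", n_x)
    total = sum(RESIDUE_MASS_DA[ch] for ch in residues if ch != "X")
    return (total + WATER_MASS_DA) / 1000.0


def charge_at_ph(residues: str, ph: float,
                 pka: Mapping[str, float] = BJELLQVIST_PKA) -> float:
    """Henderson-Hasselbalch net charge of the full titration model.

    Side chains D/E/C/Y titrate negative, K/R/H positive; both termini
    are included. A single N-terminal pKa is used for every residue so
    the result depends on composition only.
    """
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in POSITIVE:
        charge += residues.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in NEGATIVE:
        charge -= residues.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def theoretical_pi(residues: str,
                   pka: Mapping[str, float] = BJELLQVIST_PKA,
                   tol: float = 1e-4) -> float:
    """pH at which the modeled titration charge is zero.

    Bisection on [0, 14]; the charge function is strictly decreasing in
    pH so the root is unique. Composition-only (permutation invariant up
    to the N-terminal residue identity).
    """
    if not residues:
        raise ValueError("cannot compute pI of an empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = charge_at_ph(residues, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def lysine_content(residues: str) -> float:
    """Percent lysine, rounded half-up to 1 decimal; X excluded from the
    denominator."""
    denom = len(residues) - residues.count("X")
    if denom == 0:
        raise ValueError("no countable residues")
    return round_half_up(100.0 * residues.count("K") / denom, 1)


def net_charge(residues: str) -> int:
    """Integer net charge: (#K + #R) - (#D + #E).

    Histidine and the termini are excluded; this integer convention is
    distinct from the titration model used for pI.
    """
    return sum(CHARGE_OF.get(ch, 0) for ch in residues)


@dataclass(frozen=True)
class RegionStats:
    length: int
    n_lys: int
    lysine_pct: float | None  # None for empty regions (printed as a dash)
    net_charge: int | None


@dataclass(frozen=True)
class PhyschemProfile:
    """The per-protein physicochemical panel."""

    protein_id: str
    mw_kda: float
    pi: float
    total: RegionStats
    ntd: RegionStats
    gh1s: tuple[RegionStats, ...]
    ctd: RegionStats
    linkers: tuple[RegionStats, ...] = ()


def _region_stats(segment: str) -> RegionStats:
    if not segment:
        return RegionStats(length=0, n_lys=0, lysine_pct=None, net_charge=None)
    return RegionStats(
        length=len(segment),
        n_lys=segment.count("K"),
        lysine_pct=lysine_content(segment),
        net_charge=net_charge(segment),
    )


def _slice(residues: str, interval: tuple[int, int] | None) -> str:
    if interval is None:
        return ""
    s, e = interval
    return residues[s - 1:e]


def physchem_profile(partition: RegionPartition, residues: str) -> PhyschemProfile:
    """Build the full panel (MW, pI, per-region lengths/K%/charge)."""
    if len(residues) != partition.length:
        raise ValueError(
            f"{partition.protein_id}: sequence length {len(residues)} does "
            f"not match partition length {partition.length}"
        )
    return PhyschemProfile(
        protein_id=partition.protein_id,
        mw_kda=round_half_up(molecular_weight(residues), 2),
        pi=round_half_up(theoretical_pi(residues), 2),
        total=_region_stats(residues),
        ntd=_region_stats(_slice(residues, partition.ntd)),
        gh1s=tuple(_region_stats(_slice(residues, g)) for g in partition.gh1s),
        ctd=_region_stats(_slice(residues, partition.ctd)),
        linkers=tuple(
            _region_stats(_slice(residues, l)) for l in partition.linkers
        ),
    )


@dataclass(frozen=True)
class ChargeProfile:
    """Moving 20-aa net-charge sums along one tail, anchored at GH1.

    ``sums[0]`` is the window abutting the GH1 boundary; subsequent
    windows slide one residue away from the domain. When the whole
    region is shorter than the window a single truncated window is used.
    """

    protein_id: str
    region: str  # "NTD" or "CTD"
    window: int
    sums: tuple[int, ...]
    min_sum: int
    frac_positive: float


def charge_profile(
    partition: RegionPartition,
    residues: str,
    region: str,
    window: int = 20,
) -> ChargeProfile:
    """Sliding-window net-charge sums for one terminal tail."""
    interval = {"NTD": partition.ntd, "CTD": partition.ctd}.get(region)
    if region not in ("NTD", "CTD"):
        raise ValueError(f"region must be NTD or CTD, got {region!r}")
    if interval is None:
        raise ValueError(f"{partition.protein_id}: {region} is empty")
    segment = _slice(residues, interval)
    charges = [CHARGE_OF.get(ch, 0) for ch in segment]
    m = len(charges)
    w = min(window, m)
    n_windows = max(m - window + 1, 1)
    sums = []
    for i in range(n_windows):
        if region == "CTD":
            block = charges[i:i + w]
        else:  # NTD: first window is the rightmost, sliding leftward
            end = m - i
            block = charges[end - w:end]
        sums.append(sum(block))
    frac_positive = sum(s > 0 for s in sums) / len(sums)
    return ChargeProfile(
        protein_id=partition.protein_id,
        region=region,
        window=window,
        sums=tuple(sums),
        min_sum=min(sums),
        frac_positive=frac_positive,
    )
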
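"""Combine architecture, physicochemical and binding-site evidence into
an H1 verdict; build neighbor-joining trees; assign variant names by
distance to labeled references."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureCall
from .binding_sites import ConservationReport
from .physchem import ChargeProfile, PhyschemProfile
from .seqio import AlignmentBlock


# ---------------------------------------------------------------------------
# H1 classification

@dataclass(frozen=True)
class H1Criteria:
    """Thresholds separating true H1s from the other GH1 groups.

    Defaults sit midway between the contrasts observed for typical
    linker histones (CTD lysine ~29-31%, CTD charge +20..+53, 10/10
    basic sites, uniformly positive tail) and the Myb/HMGA groups
    (lysine <= ~11%, <= 6 sites).
    """

    ctd_lys_min_pct: float = 20.0
    ctd_net_charge_min: int = 20
    min_window_sum_min: int = 1
    binding_min: int = 8
    require_single_gh1: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.ctd_lys_min_pct <= 100):
            raise ValueError("ctd_lys_min_pct out of [0, 100]")
        if not (0 <= self.binding_min <= 10):
            raise ValueError("binding_min out of [0, 10]")


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    verdict: str  # H1 | GH1_Myb | GH1_HMGA | other
    architecture_ok: bool
    ctd_lysine_ok: bool
    ctd_charge_ok: bool
    charge_evenness_ok: bool
    binding_sites_ok: bool


def classify_h1(
    arch: ArchitectureCall,
    profile: PhyschemProfile,
    ctd_charge: ChargeProfile | None,
    sites: ConservationReport,
    criteria: H1Criteria = H1Criteria(),
) -> ClassificationResult:
    """Apply the H1 criteria; architecture group has precedence for the
    Myb and HMGA verdicts. The CTD charge profile may be None only when
    the protein has no CTD (then the verdict cannot be H1)."""
    ids = {arch.protein_id, profile.protein_id, sites.protein_id}
    if ctd_charge is not None:
        ids.add(ctd_charge.protein_id)
    if len(ids) != 1:
        raise ValueError(f"inputs refer to different proteins: {sorted(ids)}")

    architecture_ok = arch.group == "typical_H1_candidate"
    ctd = profile.ctd
    ctd_lysine_ok = (
        ctd.lysine_pct is not None and ctd.lysine_pct >= criteria.ctd_lys_min_pct
    )
    ctd_charge_ok = (
        ctd.net_charge is not None
        and ctd.net_charge >= criteria.ctd_net_charge_min
    )
    charge_evenness_ok = (
        ctd_charge is not None
        and ctd_charge.min_sum >= criteria.min_window_sum_min
    )
    binding_sites_ok = sites.conserved_count >= criteria.binding_min

    if arch.group == "GH1_Myb":
        verdict = "GH1_Myb"
    elif arch.group == "GH1_HMGA":
        verdict = "GH1_HMGA"
    elif (
        architecture_ok
        and ctd_lysine_ok
        and ctd_charge_ok
        and charge_evenness_ok
        and binding_sites_ok
    ):
        verdict = "H1"
    else:
        verdict = "other"
    return ClassificationResult(
        protein_id=arch.protein_id,
        verdict=verdict,
        architecture_ok=architecture_ok,
        ctd_lysine_ok=ctd_lysine_ok,
        ctd_charge_ok=ctd_charge_ok,
        charge_evenness_ok=charge_evenness_ok,
        binding_sites_ok=binding_sites_ok,
    )


def classify_proteins(
    records,
    hits,
    gh1_alignment: AlignmentBlock | None = None,
    reference_id: str | None = None,
    reference_positions=None,
    criteria: H1Criteria = H1Criteria(),
    window: int = 20,
):
    """Run the full per-protein evidence chain over a collection.

    Returns a list of (ClassificationResult, dict-of-metrics) pairs.
    Proteins without a GH1 hit are skipped with a warning. Without a
    GH1 alignment the binding-site criterion cannot pass and no protein
    is called H1 (sites are reported as None).
    """
    import logging

    from .architecture import (
        ArchitectureError, classify_architecture, find_at_hooks,
        partition_protein,
    )
    from .binding_sites import (
        DEFAULT_SITE_POSITIONS, build_site_map, score_conservation,
    )
    from .physchem import charge_profile, physchem_profile

    log = logging.getLogger(__name__)
    site_map = None
    if gh1_alignment is not None:
        if reference_id is None:
            raise ValueError("an alignment requires a reference_id")
        site_map = build_site_map(
            gh1_alignment,
            reference_id,
            reference_positions or DEFAULT_SITE_POSITIONS,
        )
    results = []
    for rec in records:
        try:
            part = partition_protein(rec, hits)
        except ArchitectureError as exc:
            log.warning("skipping %s: %s", rec.id, exc)
            continue
        hooks = find_at_hooks(rec)
        arch = classify_architecture(part, hits, hooks)
        profile = physchem_profile(part, rec.residues)
        ctd_prof = (
            charge_profile(part, rec.residues, "CTD", window=window)
            if part.ctd is not None
            else None
        )
        if site_map is not None and rec.id in gh1_alignment.ids:
            sites = score_conservation(gh1_alignment, site_map, rec.id)
        else:
            from .binding_sites import ConservationReport as _CR

            sites = _CR(
                protein_id=rec.id,
                observed=("-",) * 10,
                is_basic=(False,) * 10,
                conserved_count=0,
            )
        result = classify_h1(arch, profile, ctd_prof, sites, criteria)
        metrics = {
            "group": arch.group,
            "n_gh1": arch.n_gh1,
            "has_myb": arch.has_myb,
            "n_at_hooks": arch.n_at_hooks,
            "length": part.length,
            "ntd_len": part.ntd_len,
            "gh1_len": sum(part.gh1_lens),
            "ctd_len": part.ctd_len,
            "mw_kda": profile.mw_kda,
            "pi": profile.pi,
            "lys_pct_total": profile.total.lysine_pct,
            "lys_pct_ctd": profile.ctd.lysine_pct,
            "net_charge_total": profile.total.net_charge,
            "net_charge_ctd": profile.ctd.net_charge,
            "min_window_sum": None if ctd_prof is None else ctd_prof.min_sum,
            "conserved_sites": (
                sites.conserved_count if site_map is not None else None
            ),
        }
        results.append((result, metrics))
    return results


# ---------------------------------------------------------------------------
# Distances

@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)


def p_distance(alignment: AlignmentBlock, id_a: str, id_b: str) -> float:
    """Proportion of differing sites, pairwise deletion of gapped columns."""
    a, b = alignment.row(id_a), alignment.row(id_b)
    compared = mismatch = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise ValueError(f"no comparable columns between {id_a} and {id_b}")
    return mismatch / compared


def p_distance_matrix(alignment: AlignmentBlock) -> DistanceMatrix:
    n = len(alignment.ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(
                alignment, alignment.ids[i], alignment.ids[j]
            )
    return DistanceMatrix(ids=alignment.ids, values=m)


# ---------------------------------------------------------------------------
# Neighbor joining

@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def _fmt(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:g}"
        inner = ",".join(c._fmt() for c in self.children)
        return f"({inner}){self.name}:{self.length:g}"

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class NJTree:
    root: TreeNode  # trifurcating root of the unrooted tree

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(n.name for n in self.root.leaves()))

    def to_newick(self) -> str:
        inner = ",".join(c._fmt() for c in self.root.children)
        return f"({inner});"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (for additivity checks)."""
        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            merged: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                cm = {k: v + c.length for k, v in collect(c).items()}
                child_maps.append(cm)
                merged.update(cm)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for la, da in child_maps[i].items():
                        for lb, db in child_maps[j].items():
                            key = (min(la, lb), max(la, lb))
                            out[key] = da + db
            return merged

        out: dict[tuple[str, str], float] = {}
        collect(self.root)
        return out


def nj_tree(dist: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion; ties are
    broken by the lexicographically smallest (id, id) pair so the result
    is deterministic. Negative branch lengths are clamped to zero with
    the deficit moved to the sibling branch.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 ids")
    nodes: dict[str, TreeNode] = {
        name: TreeNode(name=name) for name in dist.ids
    }
    d: dict[frozenset, float] = {}
    active = list(dist.ids)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((dist.ids[i], dist.ids[j]))] = dist.values[i, j]

    def dd(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dd(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * dd(a, b) - row_sum[a] - row_sum[b]
                pair = tuple(sorted((a, b)))
                if q < best_q or (q == best_q and pair < best):
                    best_q, best = q, pair
        a, b = best
        dab = dd(a, b)
        la = dab / 2.0 + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        counter += 1
        parent = TreeNode(name="")
        nodes[a].length = la
        nodes[b].length = lb
        parent.children = [nodes[a], nodes[b]]
        new_name = f"\x00internal{counter}"  # sorts before printable ids
        nodes[new_name] = parent
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_name, c))] = (dd(a, c) + dd(b, c) - dab) / 2.0
        active = [c for c in active if c not in (a, b)]
        active.append(new_name)

    # final 3-way join at the trifurcating root
    a, b, c = sorted(active)
    la = (dd(a, b) + dd(a, c) - dd(b, c)) / 2.0
    lb = (dd(a, b) + dd(b, c) - dd(a, c)) / 2.0
    lc = (dd(a, c) + dd(b, c) - dd(a, b)) / 2.0
    lengths = [la, lb, lc]
    order = [a, b, c]
    for i in range(3):
        if lengths[i] < 0:
            deficit = lengths[i]
            lengths[i] = 0.0
            j = min(k for k in range(3) if k != i)
            lengths[j] += deficit
    root = TreeNode(name="")
    for name, ln in zip(order, lengths):
        nodes[name].length = max(ln, 0.0)
        root.children.append(nodes[name])
    return NJTree(root=root)


# ---------------------------------------------------------------------------
# Variant nomenclature

@dataclass(frozen=True)
class VariantAssignment:
    protein_id: str
    variant: str
    mean_distance_per_group: dict[str, float]
    margin: float
    ambiguous: bool


def assign_variant(
    alignment: AlignmentBlock,
    query_id: str,
    labels: dict[str, str],
    epsilon: float = 1e-6,
) -> VariantAssignment:
    """Assign the query to the variant group with minimal mean p-distance.

    ``labels`` maps labeled reference ids (present in the alignment) to
    variant names such as H1.0..H1.4. A margin (runner-up minus winner)
    below ``epsilon`` flags the assignment as ambiguous.
    """
    if not labels:
        raise ValueError("no labeled references supplied")
    groups: dict[str, list[float]] = {}
    for ref_id, variant in labels.items():
        if ref_id == query_id:
            continue
        groups.setdefault(variant, []).append(
            p_distance(alignment, query_id, ref_id)
        )
    if not groups:
        raise ValueError("no labeled references distinct from the query")
    means = {v: float(np.mean(ds)) for v, ds in groups.items()}
    ranked = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    variant, best = ranked[0]
    margin = (ranked[1][1] - best) if len(ranked) > 1 else np.inf
    return VariantAssignment(
        protein_id=query_id,
        variant=variant,
        mean_distance_per_group=means,
        margin=margin,
        ambiguous=margin < epsilon,
    )
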
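"""Ortholog/paralog set construction and selection summaries.

Lineage assignment scores each gene against per-lineage reference proteins
(best global alignment score, normalised by the reference self-score);
ortholog sets take one gene per species (random choice among co-orthologs,
seeded); paralog groups are maximal clades in a lineage gene tree whose
functional tips all belong to one species (two or more of them). Pairwise
dN/dS summaries per group mirror the standard selection table: mean dS and
dN with bootstrap SEs, mean of pairwise dN/dS ratios (pairs with dS = 0
excluded and reported), the count of pairs above 1, and a one-tail paired
t-test of dN > dS for groups of three or more paralogs. Saturation
profiles of dN against dS detect plateaus of nonsynonymous divergence.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .codon_align import CodonAlignment, pairwise_protein_align
from .evodist import (DEFAULT_R, estimate_from_counts, jukes_cantor,
                      ng_column_contributions)
from .gene_models import GeneCall
from .phylo import PhyloTree

__all__ = [
    "OrthologSet",
    "ParalogGroup",
    "SelectionSummary",
    "SaturationProfile",
    "InsufficientDataError",
    "assign_lineage",
    "build_ortholog_set",
    "build_ortholog_pairs",
    "detect_paralog_groups",
    "detect_gene_sorting",
    "selection_summary",
    "saturation_profile",
]


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# lineage assignment and ortholog sets
# ---------------------------------------------------------------------------

def assign_lineage(calls: Sequence[GeneCall], references: dict[str, str],
                   min_relative_score: float = 0.3) -> dict[str, str]:
    """Assign each gene to its best-scoring lineage reference.

    ``references`` maps lineage name to a reference protein. Scores are
    global alignment scores normalised by the reference self-score; genes
    below ``min_relative_score`` fall into ``"Others"`` with a warning.
    """
    if not references:
        raise ValueError("empty reference set")
    self_scores = {lin: pairwise_protein_align(prot, prot)[2]
                   for lin, prot in references.items()}
    out: dict[str, str] = {}
    for call in calls:
        protein = call.protein.replace("*", "X")
        if not protein:
            out[call.record.id] = "Others"
            continue
        best_lin, best_rel = None, -math.inf
        for lin, prot in references.items():
            score = pairwise_protein_align(prot, protein)[2]
            rel = score / self_scores[lin]
            if rel > best_rel:
                best_lin, best_rel = lin, rel
        if best_rel < min_relative_score:
            warnings.warn(f"{call.record.id}: best lineage score "
                          f"{best_rel:.2f} below threshold; assigned 'Others'",
                          stacklevel=2)
            out[call.record.id] = "Others"
        else:
            out[call.record.id] = best_lin
    return out


@dataclass
class OrthologSet:
    """One chosen functional gene per species for a lineage."""

    lineage: str
    members: dict[str, str]  # species code -> gene id
    seed: int

    @property
    def n(self) -> int:
        return len(self.members)


def build_ortholog_set(calls: Sequence[GeneCall], lineage_map: dict[str, str],
                       lineage: str, seed: int = 0) -> OrthologSet:
    """Pick one functional gene per species (seeded random co-ortholog choice)."""
    rng = np.random.default_rng(seed)
    per_species: dict[str, list[str]] = {}
    for call in calls:
        if call.status != "functional":
            continue
        if lineage_map.get(call.record.id) != lineage:
            continue
        per_species.setdefault(call.record.species_code, []).append(call.record.id)
    members = {}
    for sp in sorted(per_species):
        ids = sorted(per_species[sp])
        members[sp] = ids[int(rng.integers(len(ids)))]
    return OrthologSet(lineage=lineage, members=members, seed=seed)


def build_ortholog_pairs(oset: OrthologSet) -> list[tuple[str, str]]:
    """All C(n, 2) unordered pairs of the set's members."""
    ids = [oset.members[sp] for sp in sorted(oset.members)]
    if len(ids) < 2:
        warnings.warn(f"{oset.lineage}: fewer than 2 orthologs; no pairs")
        return []
    return list(itertools.combinations(ids, 2))


# ---------------------------------------------------------------------------
# paralog groups and gene sorting
# ---------------------------------------------------------------------------

@dataclass
class ParalogGroup:
    species: str
    lineage: str
    members: list[str]  # functional gene ids (>= 2), a species-specific clade

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def pair_count(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def group_id(self) -> str:
        return f"{self.species}-{self.lineage}"


def detect_paralog_groups(lineage_tree: PhyloTree, species_of: dict[str, str],
                          functional_of: Optional[dict[str, bool]] = None,
                          lineage: str = "", outgroup: Optional[str] = None,
                          ) -> list[ParalogGroup]:
    """Maximal clades whose functional tips all belong to one species (n >= 2).

    Pseudogene tips may sit inside a group's clade without breaking it; the
    group itself lists functional members only. Unrooted input requires an
    ``outgroup``.
    """
    tree = lineage_tree
    if outgroup is not None:
        tree = tree.rooted_on(outgroup)
    elif not tree.rooted:
        raise ValueError("unrooted tree: an outgroup is required")
    functional_of = functional_of or {}

    def is_functional(label: str) -> bool:
        return functional_of.get(label, not label.endswith("ps"))

    groups: list[ParalogGroup] = []

    def walk(node) -> bool:
        """Returns True when this subtree was absorbed into a group."""
        if node.is_leaf():
            return False
        tips = [leaf.taxon.label for leaf in node.leaf_iter()
                if leaf.taxon is not None]
        if outgroup is not None and outgroup in tips:
            for child in node.child_nodes():
                walk(child)
            return False
        func = [t for t in tips if is_functional(t)]
        species = {species_of[t] for t in func}
        if len(func) >= 2 and len(species) == 1:
            groups.append(ParalogGroup(species=species.pop(), lineage=lineage,
                                       members=sorted(func)))
            return True
        for child in node.child_nodes():
            walk(child)
        return False

    walk(tree.tree.seed_node)
    return groups


def detect_gene_sorting(lineage_tree: PhyloTree, species_pair: tuple[str, str],
                        species_of: dict[str, str],
                        outgroup: Optional[str] = None) -> tuple[bool, dict]:
    """Do the two species' genes interleave in their joint clade?

    True iff, within the smallest clade containing all tips of both
    species, neither species' tips are monophyletic - the signature of
    duplications predating the species split followed by differential
    retention (gene sorting).
    """
    sp1, sp2 = species_pair
    tree = lineage_tree
    if outgroup is not None:
        tree = tree.rooted_on(outgroup)
    elif not tree.rooted:
        raise ValueError("unrooted tree: an outgroup is required")
    tips1 = [t for t in tree.tip_labels() if species_of.get(t) == sp1]
    tips2 = [t for t in tree.tip_labels() if species_of.get(t) == sp2]
    if len(tips1) < 2 or len(tips2) < 2:
        raise ValueError(f"both species need >= 2 tips in the tree "
                         f"({sp1}: {len(tips1)}, {sp2}: {len(tips2)})")
    shared = tree.clade_tips(tips1 + tips2)
    mono1 = tree.clade_tips(tips1) == set(tips1)
    mono2 = tree.clade_tips(tips2) == set(tips2)
    return (not mono1) and (not mono2), {
        "shared_clade": sorted(shared),
        "monophyletic": {sp1: mono1, sp2: mono2},
    }


# ---------------------------------------------------------------------------
# selection summaries
# ---------------------------------------------------------------------------

@dataclass
class SelectionSummary:
    group_id: str
    n: int
    mean_dS: float
    se_dS: float
    mean_dN: float
    se_dN: float
    mean_ratio: Optional[float]  # None = not defined (all pairs dS == 0)
    ratio_pairs: int  # pairs contributing to the ratio mean (dS > 0)
    pairs_gt1: int
    total_pairs: int
    p_value: Optional[float]
    dropped_replicates: int = 0
    pair_estimates: list = field(default_factory=list, repr=False)


def selection_summary(group_id: str, member_ids: Sequence[str],
                      alignment: CodonAlignment, R: float = DEFAULT_R,
                      replicates: int = 1000, seed: int = 0,
                      ratio_mode: str = "mean_of_ratios") -> SelectionSummary:
    """Pairwise dN/dS summary for a paralog group or ortholog set.

    Complete deletion is applied per pair (each pair is compared over its
    own gap-free, unambiguous codon columns). SEs are codon-column
    bootstrap SEs of the group means; the dN > dS test is a one-tail
    paired t-test over pairwise values, applied to groups of three or more
    members only.
    """
    n = len(member_ids)
    if n < 2:
        raise InsufficientDataError("need at least two members")
    sub = alignment.subset(list(member_ids))
    codon_rows = [sub.row_codons(r) for r in range(n)]
    ncol = sub.column_count

    pairs = list(itertools.combinations(range(n), 2))
    contribs = []
    estimates = []
    for i, j in pairs:
        contrib, usable = ng_column_contributions(codon_rows[i], codon_rows[j], R)
        if not usable:
            raise ValueError(f"pair ({member_ids[i]}, {member_ids[j]}): "
                             "no comparable codon columns")
        S, N, Sd, Nd = contrib.sum(axis=0)
        estimates.append(estimate_from_counts(S, N, Sd, Nd, R, len(usable)))
        contribs.append(contrib)

    dS_vals = [e.dS for e in estimates]
    dN_vals = [e.dN for e in estimates]
    mean_dS = float(np.nanmean(dS_vals))
    mean_dN = float(np.nanmean(dN_vals))

    ratios = [e.ratio for e in estimates if e.ratio is not None]
    if ratio_mode == "mean_of_ratios":
        mean_ratio = float(np.mean(ratios)) if ratios else None
    elif ratio_mode == "ratio_of_means":
        mean_ratio = (mean_dN / mean_dS) if mean_dS > 0 else None
    else:
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    pairs_gt1 = sum(1 for r in ratios if r > 1.0)

    # codon-column bootstrap of the two group means
    rng = np.random.default_rng(seed)
    stack = np.stack(contribs)  # (pairs, columns, 4)
    reps_dS = []
    reps_dN = []
    dropped = 0
    for _ in range(max(replicates, 2)):
        cols = rng.integers(0, ncol, size=ncol)
        counts = stack[:, cols, :].sum(axis=1)  # (pairs, 4)
        with np.errstate(divide="ignore", invalid="ignore"):
            pS = np.where(counts[:, 0] > 0, counts[:, 2] / counts[:, 0], 0.0)
            pN = np.where(counts[:, 1] > 0, counts[:, 3] / counts[:, 1], 0.0)
        if (pS >= 0.75).any() or (pN >= 0.75).any():
            dropped += 1
            continue
        reps_dS.append(np.mean(-0.75 * np.log1p(-4.0 * pS / 3.0)))
        reps_dN.append(np.mean(-0.75 * np.log1p(-4.0 * pN / 3.0)))
    se_dS = float(np.std(reps_dS, ddof=1)) if len(reps_dS) > 1 else math.nan
    se_dN = float(np.std(reps_dN, ddof=1)) if len(reps_dN) > 1 else math.nan

    p_value = None
    if n >= 3:
        ok = [k for k in range(len(pairs))
              if not (math.isnan(dN_vals[k]) or math.isnan(dS_vals[k]))]
        if len(ok) >= 2:
            res = stats.ttest_rel([dN_vals[k] for k in ok],
                                  [dS_vals[k] for k in ok],
                                  alternative="greater")
            p_value = float(res.pvalue)

    return SelectionSummary(
        group_id=group_id, n=n, mean_dS=mean_dS, se_dS=se_dS,
        mean_dN=mean_dN, se_dN=se_dN, mean_ratio=mean_ratio,
        ratio_pairs=len(ratios), pairs_gt1=pairs_gt1,
        total_pairs=len(pairs), p_value=p_value,
        dropped_replicates=dropped, pair_estimates=estimates)


# ---------------------------------------------------------------------------
# saturation profiles
# ---------------------------------------------------------------------------

@dataclass
class SaturationProfile:
    lineage: str
    points: list[tuple[float, float]]  # (dS, dN), sorted by dS
    plateau_detected: bool
    plateau_onset_dS: Optional[float]
    lower_slope: float
    upper_slope: float


def saturation_profile(points: Sequence[tuple[float, float]], lineage: str = "",
                       min_points: int = 10,
                       plateau_slope_fraction: float = 0.25
                       ) -> SaturationProfile:
    """Detect a plateau of dN accumulation across ortholog-pair points.

    Points are split at the midpoint of the dS range; a plateau is called
    when the dN-on-dS slope of the upper half falls below
    ``plateau_slope_fraction`` of the lower half's slope (lower slope
    positive). The onset is the breakpoint minimising the two-segment
    least-squares residual.
    """
    pts = sorted((float(a), float(b)) for a, b in points
                 if not (math.isnan(a) or math.isnan(b)))
    if len(pts) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    mid = 0.5 * (x.min() + x.max())
    lower = x <= mid
    upper = ~lower

    def slope(xs, ys) -> float:
        if len(xs) < 2 or np.ptp(xs) == 0:
            return math.nan
        return float(np.polyfit(xs, ys, 1)[0])

    lo = slope(x[lower], y[lower])
    hi = slope(x[upper], y[upper])
    plateau = (not math.isnan(lo) and not math.isnan(hi)
               and lo > 0 and hi < plateau_slope_fraction * lo)

    onset = None
    if plateau:
        best_sse = math.inf
        for k in range(3, len(pts) - 2):
            sse = 0.0
            for xs, ys in ((x[:k], y[:k]), (x[k:], y[k:])):
                coef = np.polyfit(xs, ys, 1)
                sse += float(np.sum((ys - np.polyval(coef, xs)) ** 2))
            if sse < best_sse:
                best_sse = sse
                onset = float(x[k])
    return SaturationProfile(lineage=lineage, points=pts,
                             plateau_detected=plateau, plateau_onset_dS=onset,
                             lower_slope=lo, upper_slope=hi)
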
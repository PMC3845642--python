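"""Gene-family evolution simulator with ground truth.

A birth-death process runs along each branch of a dated species tree:
every live gene copy can duplicate (rate lambda per copy per unit branch
length), be lost (mu), or pseudogenize (psi). Sequences evolve under a
mutation-acceptance codon model: point mutations are proposed with a
transition bias kappa and accepted according to the copy's dN/dS ratio
omega (synonymous changes at relative rate min(1, 1/omega), nonsynonymous
at min(1, omega), so their rate ratio is omega). Pseudogenized copies
evolve neutrally (omega = 1), may accumulate premature stops and
frame-shifting indels, and can still duplicate. The simulator emits FASTA
records named with the project convention (``Ml-RNase1A``, ``ps`` suffix
for pseudogenes), the true gene tree, and an event log, so downstream
classification, tree building, selection scans and reconciliation can be
validated against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np

from .gene_models import GENETIC_CODE, STOP_CODONS, translate
from .phylo import PhyloTree
from .reconcile import SpeciesTree, _branch_label
from .seq_io import SeqRecord

__all__ = [
    "SimParams",
    "SimEvent",
    "SimulationTruth",
    "simulate_family",
    "evolve_codon_sequence",
    "inject_pseudogene_defects",
    "make_root_sequence",
]

_MAX_LIVE_COPIES = 10_000

#: hydrophobic signal peptide used in the root gene (cleaved in vivo)
_SIGNAL = "ALKSLVLLSLLVLVLL"

#: bovine RNase A mature peptide: donates the CKXXNTF motif and cysteines
_MATURE_TEMPLATE = (
    "KETAAAKFERQHMDSSTSAASSSNYCNQMMKSRNLTKDRCKPVNTFVHESLADVQAVCSQ"
    "KNVACKNGQTNCYQSYSTMSITDCRETGSSKYPNCAYKTTQANKHIIVACEGNPYVPVHF"
    "DASV")

_SYN_CODONS: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _SYN_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _SYN_CODONS:
    _SYN_CODONS[_aa].sort()


@dataclass
class SimParams:
    """Study conditions for one simulated gene family.

    Rates are per gene copy per unit species-tree branch length (My for the
    bundled tree). ``omega`` may be a single ratio or a mapping from
    species-tree branch labels to ratios; ``omega_post_dup`` (if set)
    applies to the new copy born at each duplication.
    """

    duplication_rate: float = 0.002
    loss_rate: float = 0.001
    pseudogenization_rate: float = 0.001
    #: optional per-branch duplication-rate overrides (lineage-specific bursts)
    duplication_rate_by_branch: Optional[dict[str, float]] = None
    omega: float | dict[str, float] = 0.6
    omega_post_dup: Optional[float] = None
    kappa: float = 2.0
    subst_rate: float = 0.0015  # proposed mutations per nt site per unit length
    root_codons: int = 130
    pseudogene_defect_rate: float = 3.0  # mean initial lesions at death
    pseudogene_lesion_rate: float = 0.06  # further lesions per unit length
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "loss_rate", "pseudogenization_rate",
                     "kappa", "subst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def branch_omega(self, branch_label: str) -> float:
        if isinstance(self.omega, dict):
            return self.omega.get(branch_label, self.omega.get("default", 0.6))
        return self.omega

    def branch_duplication_rate(self, branch_label: str) -> float:
        if self.duplication_rate_by_branch:
            return self.duplication_rate_by_branch.get(branch_label,
                                                       self.duplication_rate)
        return self.duplication_rate


@dataclass
class SimEvent:
    time: float  # absolute time since the root (same units as branch lengths)
    branch: str  # species-tree branch label
    event: str  # duplication | loss | pseudogenization
    gene_id: int  # internal copy identifier


@dataclass
class SimulationTruth:
    events: list[SimEvent]
    gene_tree: PhyloTree  # true gene tree over extant tips, rooted
    omega_of: dict[str, float]  # tip label -> final omega of that copy
    surviving_duplications: int  # duplication nodes retained in the gene tree
    extant_per_species: dict[str, int]

    def event_counts(self, event: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            if e.event == event:
                out[e.branch] = out.get(e.branch, 0) + 1
        return out


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------

def make_root_sequence(rng: np.random.Generator, n_codons: int = 130) -> str:
    """A stop-free CDS (terminal TAA) with signal peptide, CKXXNTF motif and
    6-8 cysteines, back-translated with random synonymous codons."""
    if n_codons < 60:
        raise ValueError("root gene needs at least 60 codons")
    protein = ("M" + _SIGNAL + _MATURE_TEMPLATE)[: n_codons - 1]
    while len(protein) < n_codons - 1:
        protein += "AS"
    protein = protein[: n_codons - 1]
    codons = [_SYN_CODONS[aa][rng.integers(len(_SYN_CODONS[aa]))]
              for aa in protein]
    return "".join(codons) + "TAA"


def _mutable_length(seq: str, functional: bool) -> int:
    if functional and seq[-3:] in STOP_CODONS:
        return len(seq) - 3  # keep the terminal stop codon fixed
    return len(seq)


def evolve_codon_sequence(seq: str, t: float, omega: float, kappa: float,
                          rng: np.random.Generator | int,
                          functional: bool = True, rate: float = 1.0) -> str:
    """Evolve a CDS for time ``t`` under the mutation-acceptance model.

    ``rate * t`` is the expected number of proposed mutations per site.
    In functional mode stop-creating changes are rejected and the terminal
    stop codon is frozen; omega = 0 admits synonymous changes only.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if t <= 0:
        return seq
    s = list(seq)
    L = _mutable_length(seq, functional)
    # selection preserves the initiation codon of a functional gene
    lo = 3 if functional and seq.startswith("ATG") else 0
    if L - lo <= 0:
        return seq
    n_prop = rng.poisson(rate * t * (L - lo))
    tv = [("C", "G", "T"), ("A", "G", "T"), ("A", "C", "T"), ("A", "C", "G")]
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    p_ts = kappa / (kappa + 2.0)
    for _ in range(n_prop):
        site = int(rng.integers(lo, L))
        old = s[site]
        if old not in "ACGT":
            continue
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        if rng.random() < p_ts:
            new = transitions[old]
        else:
            others = [b for b in tv[base_index[old]] if b != transitions[old]]
            new = others[int(rng.integers(2))]
        frame_start = (site // 3) * 3
        old_codon = "".join(s[frame_start:frame_start + 3])
        new_codon = old_codon[: site - frame_start] + new + old_codon[site - frame_start + 1:]
        if len(new_codon) < 3 or any(c not in "ACGT" for c in new_codon):
            s[site] = new  # partial trailing codon in a frameshifted pseudogene
            continue
        if functional:
            if new_codon in STOP_CODONS:
                continue
            syn = GENETIC_CODE[old_codon] == GENETIC_CODE[new_codon] \
                if old_codon not in STOP_CODONS else False
            if syn:
                accept = min(1.0, 1.0 / omega) if omega > 0 else 1.0
            else:
                accept = min(1.0, omega)
            if rng.random() >= accept:
                continue
        s[site] = new
    return "".join(s)


def _one_lesion(s: str, rng: np.random.Generator) -> str:
    """One ORF-disrupting lesion: a premature stop (60%) or a 1-2 nt indel."""
    if rng.random() < 0.6:
        n_codons = len(s) // 3
        pos = int(rng.integers(1, max(2, n_codons - 1)))
        stop = ("TAA", "TGA", "TAG")[int(rng.integers(3))]
        return s[: 3 * pos] + stop + s[3 * pos + 3:]
    width = int(rng.integers(1, 3))
    pos = int(rng.integers(3, max(4, len(s) - 4)))
    if rng.random() < 0.5:
        return s[:pos] + s[pos + width:]
    ins = "".join("ACGT"[int(rng.integers(4))] for _ in range(width))
    return s[:pos] + ins + s[pos:]


def inject_pseudogene_defects(seq: str, rate: float,
                              rng: np.random.Generator | int) -> str:
    """Introduce ORF-disrupting defects (when rate > 0).

    ``1 + Poisson(rate - 1)`` lesions (premature stops and frame-shifting
    +-1-2 nt indels); the last lesion is always a premature stop written in
    frame 0 of the final sequence, so the result is recognisably defective
    even without a reference alignment.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if rate <= 0:
        return seq
    s = seq
    for _ in range(int(rng.poisson(max(rate - 1.0, 0.0)))):
        s = _one_lesion(s, rng)
    n_codons = len(s) // 3
    pos = int(rng.integers(1, max(2, n_codons - 1)))
    stop = ("TAA", "TGA", "TAG")[int(rng.integers(3))]
    return s[: 3 * pos] + stop + s[3 * pos + 3:]


# ---------------------------------------------------------------------------
# family simulation along the species tree
# ---------------------------------------------------------------------------

@dataclass
class _Copy:
    gid: int
    seq: str
    functional: bool
    omega: float
    node: dendropy.Node  # gene-tree node whose edge is currently growing
    edge_start: float  # absolute time at which the growing edge began


def simulate_family(species_tree: SpeciesTree, params: SimParams,
                    family_name: str = "RNase1"
                    ) -> tuple[list[SeqRecord], SimulationTruth]:
    """Simulate one gene family along the species tree.

    Returns extant FASTA records plus the ground truth (event log, true
    gene tree over extant copies, per-copy omega). Same seed, same output.
    """
    rng = np.random.default_rng(params.seed)
    events: list[SimEvent] = []
    gid_counter = [0]
    live_total = [1]

    root_seq = make_root_sequence(rng, params.root_codons)
    gene_root = dendropy.Node()
    gene_root.event = "root"
    sroot = species_tree.phylo.tree.seed_node
    first = _Copy(gid=0, seq=root_seq, functional=True,
                  omega=params.branch_omega(_branch_label(sroot)),
                  node=gene_root, edge_start=0.0)

    tip_rows: list[tuple[str, str, str, float, bool]] = []
    extant_per_species: dict[str, int] = {}

    def finalize_edge(copy: _Copy, now: float) -> dendropy.Node:
        copy.node.edge.length = max(now - copy.edge_start, 0.0)
        return copy.node

    def recurse(copy: _Copy, snode: dendropy.Node, t0: float) -> None:
        branch = _branch_label(snode)
        blen = snode.edge.length or 0.0
        omega_here = params.branch_omega(branch)
        cps = [replace(copy, omega=(copy.omega if not copy.functional
                                    else omega_here))]
        lam = params.branch_duplication_rate(branch)
        t = 0.0
        # per-copy time of last sequence update, relative to branch start
        last = {cps[0].gid: 0.0}

        def age_copy(c: _Copy, dt: float) -> None:
            c.seq = evolve_codon_sequence(c.seq, dt, c.omega, params.kappa,
                                          rng, functional=c.functional,
                                          rate=params.subst_rate)
            if not c.functional and params.pseudogene_lesion_rate > 0 and dt > 0:
                # dead copies keep decaying: further stops and indels accrue
                for _ in range(int(rng.poisson(
                        params.pseudogene_lesion_rate * dt))):
                    c.seq = _one_lesion(c.seq, rng)
        while True:
            rates = [lam + params.loss_rate
                     + (params.pseudogenization_rate if c.functional else 0.0)
                     for c in cps]
            total = sum(rates)
            if total <= 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= blen:
                break
            t += dt
            k = int(rng.choice(len(cps), p=np.asarray(rates) / total))
            target = cps[k]
            age_copy(target, t - last[target.gid])
            last[target.gid] = t
            r = rng.random() * rates[k]
            dup_cut = lam
            loss_cut = dup_cut + params.loss_rate
            if r < dup_cut:
                live_total[0] += 1
                if live_total[0] > _MAX_LIVE_COPIES:
                    raise RuntimeError(
                        f"explosive growth: more than {_MAX_LIVE_COPIES} live "
                        "copies; lower the duplication rate")
                parent = finalize_edge(target, t0 + t)
                parent.event = "duplication"
                gid_counter[0] += 1
                new_gid = gid_counter[0]
                child_a = dendropy.Node()
                child_b = dendropy.Node()
                parent.add_child(child_a)
                parent.add_child(child_b)
                target.node, target.edge_start = child_a, t0 + t
                new_omega = (params.omega_post_dup
                             if (params.omega_post_dup is not None
                                 and target.functional)
                             else target.omega)
                new_copy = _Copy(gid=new_gid, seq=target.seq,
                                 functional=target.functional,
                                 omega=new_omega, node=child_b,
                                 edge_start=t0 + t)
                cps.append(new_copy)
                last[new_gid] = t
                events.append(SimEvent(t0 + t, branch, "duplication", target.gid))
            elif r < loss_cut:
                live_total[0] -= 1
                node = finalize_edge(target, t0 + t)
                node.event = "loss"
                cps.pop(k)
                events.append(SimEvent(t0 + t, branch, "loss", target.gid))
                if not cps:
                    return
            else:
                target.functional = False
                target.omega = 1.0
                target.seq = inject_pseudogene_defects(
                    target.seq, params.pseudogene_defect_rate, rng)
                events.append(SimEvent(t0 + t, branch, "pseudogenization",
                                       target.gid))
        for c in cps:
            age_copy(c, blen - last[c.gid])
            last[c.gid] = blen
        if snode.is_leaf():
            sp = snode.taxon.label
            for c in cps:
                node = finalize_edge(c, t0 + blen)
                node.event = "extant"
                tip_rows.append((sp, c.seq, "", c.omega, c.functional))
                node.tip_key = len(tip_rows) - 1
                extant_per_species[sp] = extant_per_species.get(sp, 0) + 1
        else:
            for c in cps:
                parent = finalize_edge(c, t0 + blen)
                parent.event = "speciation"
                for schild in snode.child_nodes():
                    child = dendropy.Node()
                    parent.add_child(child)
                    sub = _Copy(gid=c.gid, seq=c.seq, functional=c.functional,
                                omega=c.omega, node=child,
                                edge_start=t0 + blen)
                    if schild is not snode.child_nodes()[0]:
                        gid_counter[0] += 1
                        sub.gid = gid_counter[0]
                        live_total[0] += 1
                    recurse(sub, schild, t0 + blen)

    recurse(first, sroot, 0.0)

    if not tip_rows:
        warnings.warn("family went extinct before the present")

    # name the extant copies per species: letters in traversal order,
    # pseudogenes carry the 'ps' suffix
    per_species_counter: dict[str, int] = {}
    labels: list[str] = []
    for sp, seq, _, om, functional in tip_rows:
        i = per_species_counter.get(sp, 0)
        per_species_counter[sp] = i + 1
        letter = ""
        n = i
        while True:
            letter = chr(ord("A") + n % 26) + letter
            n = n // 26 - 1
            if n < 0:
                break
        label = f"{sp}-{family_name}{letter}" + ("" if functional else "ps")
        labels.append(label)

    # prune extinct lineages from the gene tree and attach tip taxa
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = gene_root
    tree.is_rooted = True
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.leaf_node_iter()):
            if getattr(leaf, "event", None) != "extant" and leaf.parent_node is not None:
                leaf.parent_node.remove_child(leaf)
                changed = True
    tree.suppress_unifurcations()
    for leaf in tree.leaf_node_iter():
        key = getattr(leaf, "tip_key", None)
        if key is None:
            continue
        taxon = taxa.new_taxon(labels[key])
        leaf.taxon = taxon
    surviving_dups = sum(
        1 for node in tree.preorder_internal_node_iter()
        if getattr(node, "event", None) == "duplication")

    records = []
    omega_of = {}
    for label, (sp, seq, _, om, functional) in zip(labels, tip_rows):
        gene_label = label.split("-", 1)[1]
        records.append(SeqRecord(
            id=label, species_code=sp, gene_label=gene_label, sequence=seq,
            declared_status=None if functional else "pseudogene"))
        omega_of[label] = om

    truth = SimulationTruth(events=events, gene_tree=PhyloTree(tree),
                            omega_of=omega_of,
                            surviving_duplications=surviving_dups,
                            extant_per_species=extant_per_species)
    return records, truth
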
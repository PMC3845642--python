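"""Protein-guided codon alignment with complete-deletion site filtering.

Sequences are aligned at the protein level (global affine-gap alignment,
BLOSUM62 by default), back-translated to codon columns, and filtered with
the complete-deletion rule: any codon column containing a gap in one or
more rows is removed before distance computation. Pseudogenes can be
carried through in a stop-masked mode where stop codons translate to 'X'
and are treated as missing data downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .gene_models import STOP_CODONS, translate

__all__ = [
    "CodonAlignment",
    "pairwise_protein_align",
    "progressive_msa",
    "backtranslate_to_codons",
    "complete_deletion",
]

GAP_CODON = "---"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def pairwise_protein_align(a: str, b: str, open_gap: float = 10.0,
                           extend_gap: float = 0.5) -> tuple[str, str, float]:
    """Optimal global protein alignment; returns (row_a, row_b, score).

    Scoring is BLOSUM62 with affine gaps (default open 10, extend 0.5).
    Among co-optimal alignments the aligner's first traceback is taken,
    which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("proteins must be non-empty")
    aligner = _make_aligner(open_gap, extend_gap)
    aln = aligner.align(a.replace("*", "X"), b.replace("*", "X"))
    best = aln[0]
    return str(best[0]), str(best[1]), float(aln.score)


# ---------------------------------------------------------------------------
# progressive multiple alignment (guide order from pairwise distances)
# ---------------------------------------------------------------------------

def _pair_score(x: str, y: str) -> float:
    if x == "-" or y == "-":
        return 0.0
    try:
        return float(_BLOSUM62[x, y])
    except KeyError:
        return 0.0


def _profile_column_score(col_a: Sequence[str], col_b: Sequence[str]) -> float:
    total = 0.0
    for x in col_a:
        for y in col_b:
            total += _pair_score(x, y)
    return total / (len(col_a) * len(col_b))


def _align_profiles(prof_a: list[str], prof_b: list[str],
                    open_gap: float = 10.0, extend_gap: float = 0.5
                    ) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two profiles of gapped rows."""
    cols_a = list(zip(*prof_a))
    cols_b = list(zip(*prof_b))
    n, m = len(cols_a), len(cols_b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in profile B (consume A)
    Y = np.full((n + 1, m + 1), NEG)  # gap in profile A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_gap - extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -open_gap - extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _profile_column_score(cols_a[i - 1], cols_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_gap, X[i - 1, j] - extend_gap)
            Y[i, j] = max(M[i, j - 1] - open_gap, Y[i, j - 1] - extend_gap)
    # traceback, preferring match > delete > insert on ties
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(i - 1)
            out_b.append(j - 1)
            prev = M[i - 1, j - 1] + _profile_column_score(cols_a[i - 1], cols_b[j - 1])
            cand = [("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]), ("Y", Y[i - 1, j - 1])]
            state = max(cand, key=lambda kv: (kv[1], kv[0] == "M", kv[0] == "X"))[0]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
        elif state == "X":
            out_a.append(i - 1)
            out_b.append(None)
            state = "M" if M[i - 1, j] - open_gap >= X[i - 1, j] - extend_gap else "X"
            i -= 1
        else:
            out_a.append(None)
            out_b.append(j - 1)
            state = "M" if M[i, j - 1] - open_gap >= Y[i, j - 1] - extend_gap else "Y"
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
    out_a.reverse()
    out_b.reverse()
    gap_a = "-" * len(prof_a)
    gap_b = "-" * len(prof_b)
    new_a_cols = ["".join(cols_a[k]) if k is not None else gap_a for k in out_a]
    new_b_cols = ["".join(cols_b[k]) if k is not None else gap_b for k in out_b]
    new_a = ["".join(c[r] for c in new_a_cols) for r in range(len(prof_a))]
    new_b = ["".join(c[r] for c in new_b_cols) for r in range(len(prof_b))]
    return new_a, new_b


def progressive_msa(proteins: list[tuple[str, str]],
                    open_gap: float = 10.0, extend_gap: float = 0.5
                    ) -> list[tuple[str, str]]:
    """Progressive multiple protein alignment.

    ``proteins`` is a list of (id, sequence). The join order is a simple
    average-linkage clustering of pairwise alignment distances (mismatch
    fraction over aligned columns); each join aligns profile to profile.
    Two sequences reduce to :func:`pairwise_protein_align`.
    """
    if len(proteins) == 1:
        warnings.warn("single sequence: returned unchanged")
        return list(proteins)
    if len(proteins) == 2:
        (ia, a), (ib, b) = proteins
        ra, rb, _ = pairwise_protein_align(a, b, open_gap, extend_gap)
        return [(ia, ra), (ib, rb)]

    ids = [i for i, _ in proteins]
    seqs = [s for _, s in proteins]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb, _ = pairwise_protein_align(seqs[i], seqs[j], open_gap, extend_gap)
            diffs = sum(1 for x, y in zip(ra, rb) if x != y)
            dist[i, j] = dist[j, i] = diffs / len(ra)

    # average-linkage agglomeration; clusters hold row indices
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    profiles: dict[int, list[str]] = {i: [seqs[i]] for i in range(n)}
    cdist = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (ci, cj) = min(cdist, key=lambda k: (cdist[k], k))
        prof_a, prof_b = _align_profiles(profiles[ci], profiles[cj],
                                         open_gap, extend_gap)
        members = clusters[ci] + clusters[cj]
        for k in (ci, cj):
            del clusters[k], profiles[k]
        cdist = {k: v for k, v in cdist.items() if ci not in k and cj not in k}
        for other in list(clusters):
            da = dist[np.ix_(members, clusters[other])].mean()
            cdist[(min(other, next_id), max(other, next_id))] = da
        clusters[next_id] = members
        profiles[next_id] = prof_a + prof_b
        next_id += 1
    (last,) = clusters
    rows = profiles[last]
    members = clusters[last]
    out = [None] * n
    for row, idx in zip(rows, members):
        out[idx] = (ids[idx], row)
    return [r for r in out if r is not None]


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon-level alignment: rows of equal length, 3-nt columns, site mask."""

    rows: list[tuple[str, str]]  # (record id, aligned codon string with --- gaps)
    site_mask: np.ndarray = field(default=None)  # bool per codon column
    column_count: int = 0

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        ncol = (lengths.pop() // 3) if self.rows else 0
        self.column_count = ncol
        if self.site_mask is None:
            self.site_mask = np.ones(ncol, dtype=bool)
        self.site_mask = np.asarray(self.site_mask, dtype=bool)
        if self.site_mask.shape != (ncol,):
            raise ValueError("site_mask length does not match column count")

    def codon(self, row: int, col: int) -> str:
        return self.rows[row][1][3 * col: 3 * col + 3]

    def row_codons(self, row: int) -> list[str]:
        s = self.rows[row][1]
        return [s[i:i + 3] for i in range(0, len(s), 3)]

    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def ungapped(self, row: int) -> str:
        return self.rows[row][1].replace("-", "")

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        wanted = {i: k for k, (i, _) in enumerate(self.rows)}
        rows = [self.rows[wanted[i]] for i in ids]
        return CodonAlignment(rows=rows, site_mask=self.site_mask.copy())


def backtranslate_to_codons(protein_alignment: list[tuple[str, str]],
                            cds_records: dict[str, str],
                            allow_stops: bool = False) -> CodonAlignment:
    """Map each aligned amino-acid column back to a codon column.

    Every row's gap-stripped protein must equal the translation of its CDS
    (terminal stop codon ignored; with ``allow_stops`` internal stops
    translate to 'X' so pseudogenes can be aligned in stop-masked mode).
    """
    rows = []
    for rec_id, gapped in protein_alignment:
        if rec_id not in cds_records:
            raise KeyError(f"no CDS provided for {rec_id}")
        cds = cds_records[rec_id].upper()
        protein = gapped.replace("-", "")
        prot_cds = translate(cds)
        if prot_cds.endswith("*"):
            prot_cds = prot_cds[:-1]
            cds = cds[: 3 * len(prot_cds)]
        if allow_stops:
            prot_cds = prot_cds.replace("*", "X")
        if len(prot_cds) != len(protein):
            raise ValueError(
                f"{rec_id}: protein row length {len(protein)} does not match "
                f"CDS translation length {len(prot_cds)}")
        for k, (pa, pc) in enumerate(zip(protein, prot_cds)):
            if pa != pc and pa != "X" and pc != "X":
                raise ValueError(
                    f"{rec_id}: translation mismatch at protein position {k}"
                    f" ({pa!r} vs {pc!r})")
        if not allow_stops and "*" in prot_cds:
            raise ValueError(f"{rec_id}: CDS contains an internal stop codon; "
                             "align pseudogenes with allow_stops=True")
        out = []
        pos = 0
        for aa in gapped:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * pos: 3 * pos + 3])
                pos += 1
        rows.append((rec_id, "".join(out)))
    return CodonAlignment(rows=rows)


def complete_deletion(alignment: CodonAlignment,
                      drop_ambiguous: bool = False) -> CodonAlignment:
    """Mask every codon column containing a gap in one or more rows.

    With ``drop_ambiguous`` columns containing stop codons or non-ACGT
    characters are masked too (required before dN/dS counting). Raises when
    no column survives. Idempotent.
    """
    mask = alignment.site_mask.copy()
    for col in range(alignment.column_count):
        if not mask[col]:
            continue
        for r in range(len(alignment.rows)):
            codon = alignment.codon(r, col)
            if "-" in codon:
                mask[col] = False
                break
            if drop_ambiguous and (codon in STOP_CODONS
                                   or any(c not in "ACGT" for c in codon)):
                mask[col] = False
                break
    if not mask.any():
        raise ValueError("no comparable sites: every column contains a gap")
    return CodonAlignment(rows=list(alignment.rows), site_mask=mask)
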
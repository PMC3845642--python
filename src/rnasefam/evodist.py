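"""Evolutionary distances: p-distance, Kimura 2-parameter, and the modified
Nei-Gojobori dN/dS with bootstrap standard errors.

The modified Nei-Gojobori method weights the three possible changes at each
codon position by an assumed transition/transversion ratio R (transition
weight R, each transversion weight 1), so synonymous-site counts reflect
transition bias. Changes that would create a stop codon count as
nonsynonymous, which keeps S + N = 3 x (codon columns compared). Observed
differences between codons are apportioned by averaging over all minimal
mutational pathways, excluding pathways that pass through a stop codon
(falling back to all pathways if every one is blocked). Proportions are
corrected with the Jukes-Cantor formula d = -3/4 ln(1 - 4/3 p).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment, GAP_CODON
from .gene_models import GENETIC_CODE, STOP_CODONS

__all__ = [
    "PairwiseCounts",
    "DnDsEstimate",
    "SaturationError",
    "p_distance",
    "count_nucleotide_pair",
    "k2p_distance",
    "jukes_cantor",
    "syn_site_fraction",
    "count_codon_differences",
    "nei_gojobori_modified",
    "ng_column_contributions",
    "distance_matrix",
    "bootstrap_se",
]

DEFAULT_R = 2.0

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Distance undefined: substitution saturation (log argument <= 0)."""


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


# ---------------------------------------------------------------------------
# nucleotide / protein distances
# ---------------------------------------------------------------------------

def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two gap-free aligned strings."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if not a:
        raise ValueError("zero-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


@dataclass
class PairwiseCounts:
    """Site and difference proportions for one aligned nucleotide pair."""

    L: int
    p: float
    P: float  # transition proportion
    Q: float  # transversion proportion


def count_nucleotide_pair(a: str, b: str) -> PairwiseCounts:
    """Count transition/transversion proportions; non-ACGT sites are skipped."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    L = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        L += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if L == 0:
        raise ValueError("no comparable sites")
    return PairwiseCounts(L=L, p=(ts + tv) / L, P=ts / L, Q=tv / L)


def k2p_distance(counts: PairwiseCounts) -> float:
    """Kimura 2-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={counts.P:.3f}, Q={counts.Q:.3f} (saturated)")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor correction; returns NaN when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# modified Nei-Gojobori
# ---------------------------------------------------------------------------

def syn_site_fraction(codon: str, R: float,
                      code: Optional[dict[str, str]] = None) -> float:
    """Synonymous sites of one codon under transition weight R.

    Each position contributes one site, split between synonymous and
    nonsynonymous according to the weighted fractions of its three possible
    changes (transition weight R, transversions 1). Changes to stop codons
    are nonsynonymous.
    """
    code = code or GENETIC_CODE
    aa = code[codon]
    s = 0.0
    for pos in range(3):
        wsum = 0.0
        wsyn = 0.0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            w = R if is_transition(codon[pos], base) else 1.0
            wsum += w
            neighbor = codon[:pos] + base + codon[pos + 1:]
            if neighbor not in STOP_CODONS and code[neighbor] == aa:
                wsyn += w
        s += wsyn / wsum
    return s


def count_codon_differences(c1: str, c2: str,
                            code: Optional[dict[str, str]] = None
                            ) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons.

    Averages over all minimal mutational pathways; pathways passing through
    a stop codon are excluded (all pathways are used if every one is
    blocked). Returns (sd, nd) with sd + nd equal to the number of
    differing positions.
    """
    code = code or GENETIC_CODE
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a not in STOP_CODONS and b not in STOP_CODONS and code[a] == code[b]:
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


@dataclass
class DnDsEstimate:
    """Site counts, difference counts and corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: Optional[float]  # None when dS == 0 or saturated
    R: float
    codon_columns: int
    saturated_S: bool = False
    saturated_N: bool = False
    se_dS: Optional[float] = None
    se_dN: Optional[float] = None


def _usable_codon_columns(c1: Sequence[str], c2: Sequence[str]) -> list[int]:
    cols = []
    for i, (a, b) in enumerate(zip(c1, c2)):
        if a == GAP_CODON or b == GAP_CODON:
            continue
        if any(ch not in "ACGT" for ch in a + b):
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            raise ValueError(f"stop codon in compared column {i}; apply "
                             "complete_deletion(drop_ambiguous=True) first")
        cols.append(i)
    return cols


def ng_column_contributions(codons1: Sequence[str], codons2: Sequence[str],
                            R: float = DEFAULT_R
                            ) -> tuple[np.ndarray, list[int]]:
    """Per-column (s_sites, n_sites, sd, nd) contributions for one pair.

    Returns an array of shape (columns, 4) over the full column range (zero
    rows for unusable columns) plus the list of usable column indices; the
    sum over rows reproduces the whole-pair counts. This decomposition is
    what makes codon-column bootstrapping cheap.
    """
    ncol = len(codons1)
    out = np.zeros((ncol, 4))
    usable = _usable_codon_columns(codons1, codons2)
    for i in usable:
        a, b = codons1[i], codons2[i]
        s = 0.5 * (syn_site_fraction(a, R) + syn_site_fraction(b, R))
        sd, nd = count_codon_differences(a, b)
        out[i] = (s, 3.0 - s, sd, nd)
    return out, usable


def estimate_from_counts(S: float, N: float, Sd: float, Nd: float,
                         R: float, columns: int) -> DnDsEstimate:
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    sat_S = math.isnan(dS)
    sat_N = math.isnan(dN)
    ratio = None
    if not sat_S and not sat_N and dS > 0:
        ratio = dN / dS
    return DnDsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
                        ratio=ratio, R=R, codon_columns=columns,
                        saturated_S=sat_S, saturated_N=sat_N)


def nei_gojobori_modified(codons1: Sequence[str] | str,
                          codons2: Sequence[str] | str,
                          R: float = DEFAULT_R) -> DnDsEstimate:
    """Modified Nei-Gojobori dN/dS for one pair of aligned codon rows.

    Inputs are codon lists or aligned nucleotide strings (length divisible
    by 3). Gap columns and columns with ambiguous bases are skipped; stop
    codons must have been removed beforehand.
    """
    if isinstance(codons1, str):
        codons1 = [codons1[i:i + 3] for i in range(0, len(codons1), 3)]
    if isinstance(codons2, str):
        codons2 = [codons2[i:i + 3] for i in range(0, len(codons2), 3)]
    if len(codons1) != len(codons2):
        raise ValueError("codon rows differ in length")
    contrib, usable = ng_column_contributions(codons1, codons2, R)
    if not usable:
        raise ValueError("no comparable codon columns")
    S, N, Sd, Nd = contrib.sum(axis=0)
    return estimate_from_counts(S, N, Sd, Nd, R, len(usable))


# ---------------------------------------------------------------------------
# distance matrices and bootstrap
# ---------------------------------------------------------------------------

def _masked_nt(alignment: CodonAlignment, row: int) -> str:
    codons = alignment.row_codons(row)
    return "".join(codons[i] for i in np.flatnonzero(alignment.site_mask))


def distance_matrix(alignment, model: str = "k2p",
                    R: float = DEFAULT_R) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric pairwise distance matrix under the requested model.

    ``alignment`` is a :class:`CodonAlignment` (models ``k2p``, ``dN``,
    ``dS``) or a list of (id, aligned protein) rows (model ``p``). Returns
    (matrix, flags); flagged entries are saturated/undefined and are set to
    NaN. Neighbor joining refuses flagged matrices.
    """
    if model == "p":
        if isinstance(alignment, CodonAlignment):
            ids = alignment.ids()
            seqs = [_masked_nt(alignment, r) for r in range(len(ids))]
        else:
            ids = [i for i, _ in alignment]
            seqs = [s for _, s in alignment]
        fn = lambda i, j: p_distance(seqs[i], seqs[j])
    elif model == "k2p":
        ids = alignment.ids()
        seqs = [_masked_nt(alignment, r) for r in range(len(ids))]
        fn = lambda i, j: k2p_distance(count_nucleotide_pair(seqs[i], seqs[j]))
    elif model in ("dN", "dS"):
        ids = alignment.ids()
        cols = np.flatnonzero(alignment.site_mask)
        rows = [[alignment.row_codons(r)[c] for c in cols]
                for r in range(len(ids))]

        def fn(i, j, _model=model):
            est = nei_gojobori_modified(rows[i], rows[j], R=R)
            d = est.dN if _model == "dN" else est.dS
            if math.isnan(d):
                raise SaturationError(f"{_model} saturated for pair ({i},{j})")
            return d
    else:
        raise ValueError(f"unknown model {model!r}")

    n = len(ids)
    mat = np.zeros((n, n))
    flags = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(i, j)
            except SaturationError:
                d, flagged = math.nan, True
            else:
                flagged = False
            mat[i, j] = mat[j, i] = d
            flags[i, j] = flags[j, i] = flagged
    return (pd.DataFrame(mat, index=ids, columns=ids),
            pd.DataFrame(flags, index=ids, columns=ids))


def bootstrap_se(estimator: Callable[[np.ndarray], dict[str, float] | float],
                 n_columns: int, replicates: int, seed: int,
                 ) -> tuple[dict[str, float], int]:
    """Codon-column bootstrap standard errors.

    ``estimator`` maps an array of resampled column indices to a statistic
    (float or dict of floats). Replicates where the estimator raises or
    returns NaN are dropped and counted. Returns ({name: SE}, dropped).
    Fixed seed gives bit-identical output.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {}
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_columns, size=n_columns)
        try:
            est = estimator(cols)
        except (ValueError, ZeroDivisionError, SaturationError):
            dropped += 1
            continue
        if isinstance(est, (int, float)):
            est = {"value": float(est)}
        if any(math.isnan(v) for v in est.values()):
            dropped += 1
            continue
        for k, v in est.items():
            values.setdefault(k, []).append(v)
    ses = {k: float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
           for k, v in values.items()}
    return ses, dropped
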
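"""Protein isoelectric point and charged-residue statistics.

Net charge at a given pH is the Henderson-Hasselbalch sum over ionizable
groups (side chains D, E, C, Y, H, K, R plus the termini); the isoelectric
point pI is the pH where the net charge crosses zero, found by bisection
on [0, 14]. The default pKa set follows the widely used ExPASy-style
values (Bjellqvist); the table is configurable because published pI values
depend on the pKa source. Secreted RNases are processed, so pI is usually
computed on the mature peptide (signal sequence removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "PkaTable",
    "ChargeProfile",
    "net_charge",
    "isoelectric_point",
    "count_charged_residues",
    "charge_profile",
]


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values.

    Defaults: ExPASy-style side-chain pKa combined with the textbook
    generic terminal pKa (alpha-amino 9.0, alpha-carboxyl 2.1); published
    pI values vary with the pKa source, so the whole table is swappable.
    """

    side_chain: dict[str, float] = field(default_factory=lambda: {
        "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
        "H": 5.98, "K": 10.00, "R": 12.00,
    })
    n_terminus: float = 9.00
    c_terminus: float = 2.10
    #: +1 for basic groups, -1 for acidic groups
    sign: dict[str, int] = field(default_factory=lambda: {
        "D": -1, "E": -1, "C": -1, "Y": -1, "H": +1, "K": +1, "R": +1,
    })

    def __post_init__(self) -> None:
        for name, pka in {**self.side_chain, "Nterm": self.n_terminus,
                          "Cterm": self.c_terminus}.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {name} out of (0, 14): {pka}")


DEFAULT_PKA = PkaTable()

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(protein: str, pH: float, pka: PkaTable = DEFAULT_PKA) -> float:
    """Net protein charge at ``pH`` (Henderson-Hasselbalch summation).

    Basic groups contribute +1/(1+10^(pH-pKa)), acidic groups
    -1/(1+10^(pKa-pH)). Unknown residues are skipped with a warning.
    """
    protein = protein.upper()
    unknown = set(protein) - _STANDARD_AA
    if unknown:
        warnings.warn(f"unknown residues skipped: {sorted(unknown)}",
                      stacklevel=2)
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for aa in protein:
        pk = pka.side_chain.get(aa)
        if pk is None:
            continue
        if pka.sign[aa] > 0:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pk))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(protein: str, pka: PkaTable = DEFAULT_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the zero is unique. If the
    charge does not change sign on [0, 14] the boundary value is returned
    with a warning.
    """
    if not any(aa in _STANDARD_AA for aa in protein.upper()):
        raise ValueError("protein has no standard residues")
    lo, hi = 0.0, 14.0
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        c_lo, c_hi = net_charge(protein, lo, pka), net_charge(protein, hi, pka)
        if c_lo < 0.0 or c_hi > 0.0:
            boundary = lo if c_lo < 0.0 else hi
            warnings.warn(f"net charge does not cross zero on [0, 14]; "
                          f"returning boundary pH {boundary}", stacklevel=2)
            return boundary
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            c = net_charge(protein, mid, pka)
            if abs(c) < tol:
                return mid
            if c > 0.0:
                lo = mid
            else:
                hi = mid
    return 0.5 * (lo + hi)


def count_charged_residues(protein: str) -> tuple[int, int]:
    """(basic R+K, acidic D+E) counts."""
    protein = protein.upper()
    basic = protein.count("R") + protein.count("K")
    acidic = protein.count("D") + protein.count("E")
    return basic, acidic


@dataclass
class ChargeProfile:
    protein_id: str
    basic_count: int
    acidic_count: int
    net_charge_ph7: float
    pI: float


def charge_profile(protein_id: str, protein: str,
                   pka: PkaTable = DEFAULT_PKA,
                   signal_cleavage: int = 0) -> ChargeProfile:
    """Charge statistics of a protein (optionally after signal cleavage)."""
    mature = protein[signal_cleavage:]
    basic, acidic = count_charged_residues(mature)
    return ChargeProfile(protein_id=protein_id, basic_count=basic,
                         acidic_count=acidic,
                         net_charge_ph7=net_charge(mature, 7.0, pka),
                         pI=isoelectric_point(mature, pka))
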
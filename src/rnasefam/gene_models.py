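"""Functional-gene vs pseudogene classification and canonical-RNase features.

A coding sequence is *functional* when it is contained in an uninterrupted
open reading frame of plausible length (RNase A superfamily genes are
intronless, roughly 130 codons). It is a *pseudogene* when the reading frame
is interrupted by one or more premature stop codons, or by frame-shifting
insertions/deletions detected against a functional reference of the same
lineage. Canonical members additionally carry the CKXXNTF signature motif,
the His/Lys/His catalytic triad, and 6-8 cysteines.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable as _CodonTable

from . import seq_io
from .seq_io import LINEAGES, PresenceMatrix, SeqRecord

__all__ = [
    "Defect",
    "GeneCall",
    "FeatureAnnotation",
    "GENETIC_CODE",
    "STOP_CODONS",
    "translate",
    "classify_gene",
    "annotate_canonical_features",
    "census",
]


def _standard_code() -> tuple[dict[str, str], frozenset[str]]:
    table = _CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    for stop in stops:
        code[stop] = "*"
    return code, stops


#: Standard nuclear genetic code (codon -> one-letter amino acid, '*' = stop).
GENETIC_CODE, STOP_CODONS = _standard_code()

#: Default ORF length bounds, in codons (the genes are ~130 amino acids).
DEFAULT_MIN_CODONS = 100
DEFAULT_MAX_CODONS = 160

#: 1-based catalytic-triad coordinates in the bundled RNase A mature profile.
TRIAD_POSITIONS = (12, 41, 119)

_MOTIF_RE = re.compile(r"CK..NTF")


def translate(cds: str, code: Optional[dict[str, str]] = None,
              unknown: str = "X") -> str:
    """Translate a CDS codon-by-codon; incomplete/ambiguous codons -> ``unknown``."""
    code = code or GENETIC_CODE
    return "".join(code.get(cds[i:i + 3], unknown)
                   for i in range(0, len(cds) - len(cds) % 3, 3))


@dataclass
class Defect:
    kind: str  # premature_stop | frameshift | missing_start | truncated
    codon_position: int  # 0-based codon index


@dataclass
class GeneCall:
    record: SeqRecord
    status: str  # functional | pseudogene
    defects: list[Defect]
    protein: str
    frame_used: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if (self.status == "functional") != (len(self.defects) == 0):
            raise ValueError("status must be functional iff defects is empty")
        if self.status == "functional" and "*" in self.protein:
            raise ValueError("functional protein contains an internal stop")


@dataclass
class FeatureAnnotation:
    signature_motif_span: Optional[tuple[int, int]]  # 0-based half-open
    catalytic_triad_present: bool
    cysteine_count: int
    canonical: bool


def _internal_stops(codons: list[str]) -> list[int]:
    """0-based indices of stop codons, the final codon excluded."""
    return [i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]


def _frameshifts_vs_reference(seq: str, ref: str) -> list[Defect]:
    """Detect frame-shifting indels by global nucleotide alignment.

    Runs of gaps whose length is not a multiple of three shift the reading
    frame; each such run is reported at the reference codon where it starts.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(ref, seq)[0]
    ref_row, seq_row = str(aln[0]), str(aln[1])
    defects: list[Defect] = []
    ref_pos = 0
    i = 0
    while i < len(ref_row):
        if ref_row[i] == "-" or seq_row[i] == "-":
            which = 0 if ref_row[i] == "-" else 1
            j = i
            while j < len(ref_row) and (ref_row[j] == "-" if which == 0 else seq_row[j] == "-"):
                j += 1
            run = j - i
            if run % 3 != 0:
                defects.append(Defect("frameshift", ref_pos // 3))
            if which == 1:  # gap in the query: reference advances
                ref_pos += run
            i = j
        else:
            ref_pos += 1
            i += 1
    return defects


def classify_gene(record: SeqRecord, reference: Optional[SeqRecord] = None,
                  min_codons: int = DEFAULT_MIN_CODONS,
                  max_codons: int = DEFAULT_MAX_CODONS,
                  code: Optional[dict[str, str]] = None) -> GeneCall:
    """Classify one coding sequence as functional gene or pseudogene.

    Functional requires: an uninterrupted reading frame (no internal stop),
    an ATG start, and a codon count within ``[min_codons, max_codons]``.
    With a functional same-lineage ``reference``, frame-shifting indels are
    detected by alignment and reported as defects. Without a reference only
    stop-codon, start and length rules apply; if every frame is dominated by
    stops the call is a low-confidence ``truncated`` pseudogene.
    """
    if len(record.sequence) < 60:
        raise ValueError(f"{record.id}: sequence shorter than 60 nt")
    seq = record.sequence.upper()
    code = code or GENETIC_CODE

    # pick the reading frame: fewest internal stops, ties to the lower frame;
    # with a reference the homologous region defines the frame (frame 0)
    frames = {}
    for f in range(3):
        sub = seq[f:]
        codons = [sub[i:i + 3] for i in range(0, len(sub) - len(sub) % 3, 3)]
        frames[f] = (codons, _internal_stops(codons))
    if reference is not None:
        frame_used = 0
    else:
        frame_used = min(range(3), key=lambda f: (len(frames[f][1]), f))
    codons, stops = frames[frame_used]

    defects: list[Defect] = [Defect("premature_stop", i) for i in stops]
    low_confidence = False
    n_codons = len(codons)
    if min(len(frames[f][1]) for f in range(3)) > max(2, n_codons // 10) and reference is None:
        defects.append(Defect("truncated", n_codons))
        low_confidence = True
    else:
        if codons and codons[0] != "ATG":
            defects.append(Defect("missing_start", 0))
        coding = n_codons - (1 if codons and codons[-1] in STOP_CODONS else 0)
        if not (min_codons <= coding <= max_codons):
            defects.append(Defect("truncated", coding))

    if reference is not None:
        defects.extend(_frameshifts_vs_reference(seq, reference.sequence.upper()))

    defects.sort(key=lambda d: (d.codon_position, d.kind))
    status = "functional" if not defects else "pseudogene"
    protein = translate("".join(codons), code)
    if protein.endswith("*"):
        protein = protein[:-1]
    return GeneCall(record=record, status=status, defects=defects,
                    protein=protein, frame_used=frame_used,
                    low_confidence=low_confidence)


def annotate_canonical_features(protein: str,
                                profile: Optional[str] = None,
                                triad_positions: tuple[int, int, int] = TRIAD_POSITIONS,
                                ) -> FeatureAnnotation:
    """Annotate the signature motif, catalytic triad, and cysteine count.

    The triad is assessed by aligning ``protein`` to a canonical reference
    profile (default: the bundled bovine RNase A mature peptide) rather than
    by absolute coordinates, because indels shift positions. Canonical means:
    motif present, triad present, and 6-8 cysteines.
    """
    if "*" in protein:
        raise ValueError("protein contains an internal stop symbol")
    m = _MOTIF_RE.search(protein)
    span = m.span() if m else None
    cys = protein.count("C")

    triad_ok = False
    if len(protein) >= 7:
        if profile is None:
            profile = _load_profile()
        triad_ok = _triad_by_alignment(protein, profile, triad_positions)

    canonical = bool(span) and triad_ok and 6 <= cys <= 8
    return FeatureAnnotation(signature_motif_span=span,
                             catalytic_triad_present=triad_ok,
                             cysteine_count=cys, canonical=canonical)


_PROFILE_CACHE: dict[str, str] = {}


def _load_profile() -> str:
    if "profile" not in _PROFILE_CACHE:
        from Bio import SeqIO
        path = seq_io.data_path("reference_proteins.fasta")
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id.startswith("RNaseA"):
                _PROFILE_CACHE["profile"] = str(rec.seq)
                break
    return _PROFILE_CACHE["profile"]


def _triad_by_alignment(protein: str, profile: str,
                        triad_positions: tuple[int, int, int]) -> bool:
    from .codon_align import pairwise_protein_align

    row_profile, row_protein, _score = pairwise_protein_align(profile, protein)
    # map 1-based profile coordinates through the alignment
    want = {triad_positions[0]: "H", triad_positions[1]: "K",
            triad_positions[2]: "H"}
    ref_pos = 0
    hits = 0
    for a, b in zip(row_profile, row_protein):
        if a != "-":
            ref_pos += 1
            if ref_pos in want and b == want[ref_pos]:
                hits += 1
    return hits == 3


def census(calls: list[GeneCall], lineage_map: dict[str, str],
           lineages: Optional[list[str]] = None) -> PresenceMatrix:
    """Tabulate functional/pseudogene counts per species and lineage.

    Genes without a lineage assignment are counted under ``"Others"`` with a
    warning. Column sums conserve the number of calls.
    """
    lineages = list(lineages) if lineages is not None else list(LINEAGES)
    if "Others" not in lineages:
        lineages.append("Others")
    species = sorted({c.record.species_code for c in calls})
    cells: dict[tuple[str, str], tuple[int, int]] = {
        (sp, lin): (0, 0) for sp in species for lin in lineages}
    for call in calls:
        lin = lineage_map.get(call.record.id)
        if lin is None or lin not in lineages:
            warnings.warn(f"{call.record.id}: no lineage assignment; counted "
                          "under 'Others'", stacklevel=2)
            lin = "Others"
        f, p = cells[(call.record.species_code, lin)]
        if call.status == "functional":
            cells[(call.record.species_code, lin)] = (f + 1, p)
        else:
            cells[(call.record.species_code, lin)] = (f, p + 1)
    return PresenceMatrix(species=species, lineages=lineages, cells=cells)
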
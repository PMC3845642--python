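"""Sequence and table I/O for RNase gene-family analyses.

Gene identifiers follow the ``<species>-<gene>`` convention (first hyphen is
the separator), e.g. ``Ml-RNase4A`` for a little brown bat RNase4 paralog.
A ``ps`` suffix on the gene label marks a pseudogene (``Hs-RNase2ps``).
Presence/absence tables use the cell grammar ``n``, ``n (m)``, ``(m)``, ``0``
where parenthesised counts are pseudogenes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "PresenceMatrix",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "parse_gene_id",
    "load_species_registry",
    "read_presence_matrix",
    "write_presence_matrix",
    "write_report_tables",
    "parse_cell",
    "format_cell",
    "LINEAGES",
    "data_path",
]

#: The 13 ancient eutherian gene lineages plus the catch-all bucket, in the
#: canonical reporting order.
LINEAGES = [
    "RNase1", "RNase2/3", "RNase4", "RNase5", "RNase6", "RNase7/8",
    "RNase9", "RNase10", "RNase11", "RNase12", "RNase13", "RNase14",
    "RNase15", "Others",
]

_IUPAC_NT = set("ACGTRYSWKMBDHVN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the line."""


def data_path(name: str) -> Path:
    """Return the filesystem path of a bundled data file."""
    return Path(resources.files("rnasefam.data") / name)


def load_species_registry(path: Optional[str] = None) -> dict[str, str]:
    """Load the species-code registry (code -> description).

    Defaults to the bundled registry of the 20 study mammals.
    """
    p = Path(path) if path else data_path("species_codes.yaml")
    with open(p) as fh:
        registry = yaml.safe_load(fh)
    if not isinstance(registry, dict):
        raise ValueError(f"species registry {p} is not a mapping")
    return {str(k): str(v) for k, v in registry.items()}


@dataclass
class SeqRecord:
    """A coding nucleotide sequence with its parsed naming convention.

    ``declared_status`` is ``"pseudogene"`` when the gene label carries the
    ``ps`` suffix, else ``None`` (classification decides the real status).
    """

    id: str
    species_code: str
    gene_label: str
    sequence: str
    declared_status: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_gene_id(header: str, registry: Optional[dict[str, str]] = None
                  ) -> tuple[str, str, Optional[str]]:
    """Split ``<species>-<gene>`` at the first hyphen.

    Returns (species_code, gene_label, declared_status). Unknown species
    codes are kept verbatim with a warning when a registry is supplied.
    """
    token = header.split()[0]
    if "-" not in token:
        raise ValueError(
            f"identifier {token!r} does not follow the <species>-<gene> convention")
    species, label = token.split("-", 1)
    if registry is not None and species not in registry:
        warnings.warn(f"unknown species code {species!r} in {token!r}; kept verbatim",
                      stacklevel=2)
    declared = "pseudogene" if label.endswith("ps") else None
    return species, label, declared


def read_fasta(path, registry: Optional[dict[str, str]] = None,
               check_registry: bool = True) -> list[SeqRecord]:
    """Read a FASTA file of coding sequences into :class:`SeqRecord` objects.

    Headers are parsed with :func:`parse_gene_id`; a ``ps`` suffix sets
    ``declared_status="pseudogene"``. Malformed input raises
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    if registry is None and check_registry:
        registry = load_species_registry()
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        species, label, declared = parse_gene_id(rec.id, registry)
        records.append(SeqRecord(id=rec.id, species_code=species,
                                 gene_label=label,
                                 sequence=str(rec.seq).upper(),
                                 declared_status=declared))
    return records


def _validate_fasta_lines(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                seen_header = True
                continue
            if not seen_header:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header")
            bad = set(line.upper()) - _IUPAC_NT - set("-*")
            if bad:
                raise FastaParseError(
                    f"{path}: line {lineno}: non-IUPAC characters {sorted(bad)!r}")


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records as multi-FASTA, sequence wrapped at 60 columns."""
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="")
           for r in records]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# presence/absence + copy-number tables
# ---------------------------------------------------------------------------

_CELL_RE = re.compile(r"^\s*(?:(\d+)\s*)?(?:\(\s*(\d+)\s*\))?\s*$")


def parse_cell(cell: str) -> tuple[int, int]:
    """Parse one census cell: ``"2 (1)"`` -> (2, 1); ``"(1)"`` -> (0, 1)."""
    m = _CELL_RE.match(str(cell))
    if not m or (m.group(1) is None and m.group(2) is None):
        raise ValueError(f"unparseable census cell {cell!r}")
    return int(m.group(1) or 0), int(m.group(2) or 0)


def format_cell(functional: int, pseudogene: int) -> str:
    if pseudogene == 0:
        return str(functional)
    if functional == 0:
        return f"({pseudogene})"
    return f"{functional} ({pseudogene})"


@dataclass
class PresenceMatrix:
    """Per-species, per-lineage functional and pseudogene counts."""

    species: list[str]
    lineages: list[str]
    cells: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in self.species:
            for lin in self.lineages:
                f, p = self.cells.setdefault((sp, lin), (0, 0))
                if f < 0 or p < 0:
                    raise ValueError(f"negative count in cell ({sp}, {lin})")

    def functional(self, species: str, lineage: str) -> int:
        return self.cells[(species, lineage)][0]

    def pseudogene(self, species: str, lineage: str) -> int:
        return self.cells[(species, lineage)][1]

    def present(self, species: str, lineage: str,
                include_pseudogenes: bool = False) -> bool:
        f, p = self.cells[(species, lineage)]
        return f > 0 or (include_pseudogenes and p > 0)

    def totals(self, species: str) -> tuple[int, int]:
        f = sum(self.cells[(species, lin)][0] for lin in self.lineages)
        p = sum(self.cells[(species, lin)][1] for lin in self.lineages)
        return f, p

    def to_frame(self) -> pd.DataFrame:
        data = {lin: [format_cell(*self.cells[(sp, lin)]) for sp in self.species]
                for lin in self.lineages}
        return pd.DataFrame(data, index=pd.Index(self.species, name="Species"))

    def __eq__(self, other) -> bool:  # order-sensitive round-trip identity
        return (isinstance(other, PresenceMatrix)
                and self.species == other.species
                and self.lineages == other.lineages
                and all(self.cells[k] == other.cells[k] for k in self.cells))


def read_presence_matrix(path) -> PresenceMatrix:
    """Read a census TSV (rows species, columns lineages, census cell grammar)."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0).fillna("0")
    species = [str(s) for s in df.index]
    lineages = [str(c) for c in df.columns]
    cells = {}
    for sp in species:
        for lin in lineages:
            try:
                cells[(sp, lin)] = parse_cell(df.loc[sp, lin])
            except ValueError as exc:
                raise ValueError(f"{path}: row {sp!r}, column {lin!r}: {exc}") from exc
    return PresenceMatrix(species=species, lineages=lineages, cells=cells)


def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def load_bundled_census() -> PresenceMatrix:
    """The gene census of the 20 study mammals (13 ancient lineages + Others)."""
    return read_presence_matrix(data_path("gene_census_20mammals.tsv"))


def write_report_tables(census: PresenceMatrix, selection, outdir) -> list[Path]:
    """Emit the census table and the selection-summary table as TSV.

    ``selection`` is an iterable of objects with the SelectionSummary surface
    (group_id, n, mean_dS/mean_dN with SEs, mean_ratio, pairs_gt1,
    total_pairs, p_value). Groups of two paralogs carry no test: their
    p-value cell is written as ``NA``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    census_path = outdir / "census.tsv"
    write_presence_matrix(census, census_path)

    rows = []
    for s in selection:
        rows.append({
            "group": s.group_id,
            "N": s.n,
            "mean_dS (SE)": f"{s.mean_dS:.3f} ({s.se_dS:.3f})",
            "mean_dN (SE)": f"{s.mean_dN:.3f} ({s.se_dN:.3f})",
            "mean_dN/dS": ("inf" if s.mean_ratio is None else f"{s.mean_ratio:.3f}"),
            "P": ("NA" if s.p_value is None else f"{s.p_value:.3g}"),
            "pairs>1": f"{s.pairs_gt1}/{s.total_pairs}",
        })
    sel_path = outdir / "selection.tsv"
    pd.DataFrame(rows, columns=["group", "N", "mean_dS (SE)", "mean_dN (SE)",
                                "mean_dN/dS", "P", "pairs>1"]).to_csv(
        sel_path, sep="\t", index=False)
    return [census_path, sel_path]
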
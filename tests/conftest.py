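import warnings
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import rnasefam as rf
from rnasefam.gene_models import classify_gene, translate
from rnasefam.codon_align import (backtranslate_to_codons, complete_deletion,
                                  progressive_msa)
from rnasefam.synthetic_data import (SimParams, evolve_codon_sequence,
                                     make_root_sequence, simulate_family)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=UserWarning)

#: location where the journal supplementary sequence dataset would live if
#: the user supplies it (it is not redistributable with the package)
SUPPLEMENTARY_DATASET = Path(__file__).resolve().parent.parent / "data" \
    / "supplementary_dataset.fasta"


@pytest.fixture(scope="session")
def species_tree():
    return rf.load_species_tree()


@pytest.fixture(scope="session")
def census():
    return rf.load_bundled_census()


@pytest.fixture(scope="session")
def reference_proteins():
    from Bio import SeqIO
    from rnasefam import seq_io
    path = seq_io.data_path("reference_proteins.fasta")
    return {rec.id.split("_")[0]: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta")}


@pytest.fixture(scope="session")
def sim_family(species_tree):
    """A reference simulated family with duplications and pseudogenes."""
    params = SimParams(seed=3, duplication_rate=0.004)
    records, truth = simulate_family(species_tree, params)
    return records, truth


def aligned_family(seqs: dict[str, str]):
    """Protein-guided, complete-deletion codon alignment of a CDS mapping."""
    prots = []
    for rec_id, cds in seqs.items():
        p = translate(cds)
        if p.endswith("*"):
            p = p[:-1]
        prots.append((rec_id, p.replace("*", "X")))
    msa = progressive_msa(prots)
    aln = backtranslate_to_codons(msa, seqs, allow_stops=True)
    return complete_deletion(aln, drop_ambiguous=True)


def ungapped_alignment(seqs: dict[str, str]):
    """Codon alignment of equal-length, indel-free CDSs (terminal stop
    trimmed), bypassing alignment reconstruction; for estimator tests."""
    from rnasefam.codon_align import CodonAlignment
    from rnasefam.gene_models import STOP_CODONS
    rows = []
    for rec_id, cds in seqs.items():
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        rows.append((rec_id, cds))
    return complete_deletion(CodonAlignment(rows=rows), drop_ambiguous=True)


def simulated_group(omega: float, seed: int, n: int = 6, codons: int = 300,
                    t: float = 0.12, kappa: float = 2.0):
    """n paralog-like copies diverged from one ancestor under a fixed omega."""
    rng = np.random.default_rng(seed)
    anc = make_root_sequence(rng, codons)
    seqs = {}
    for k in range(n):
        seqs[f"Xx-RNase1{chr(65 + k)}"] = evolve_codon_sequence(
            anc, t, omega, kappa, np.random.default_rng(seed * 1000 + k))
    return seqs
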
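"""Study accessions: published fragment coordinates and on-demand statistics.

The analysis rests on five GenBank records (mitochondrial genomes): AY905542
(*Crassostrea virginica*), AF177226 (*C. gigas*), EU672834 and EU266073
(*C. hongkongensis*), and DQ665851 (*Argopecten irradians*, the contiguous-
gene control).  This package does not redistribute the sequences; to run the
accession-based statistics, fetch each record as FASTA (e.g. with NCBI
efetch) and place it at ``<data_dir>/<ACCESSION>.fasta``.

The fragment coordinates below are the published ones (1-based inclusive on
the + strand).  For *C. gigas* two 5' start candidates exist — 5103 (first
base after *trnQ*) and 5117 (extreme 5' transcript position; the one whose
length matches the summary table) — and both are kept, never merged.
"""

from __future__ import annotations

from pathlib import Path

from .boundaries import fragment_separation
from .formats import CircularGenome, read_fasta
from .pcr import Primer, amplify, load_primer_table
from .seqstats import base_content, interval_length, similarity_matrix

__all__ = [
    "FRAGMENTS",
    "AccessionDataMissing",
    "load_accession",
    "fragment_lengths",
    "fragment_base_content",
    "cv_fragment_separation",
    "cv_internal5_amplicons",
    "oyster_similarity_matrix",
]

# accession -> {"frag5": (start, end) or None, "frag3": (start, end) or None}
FRAGMENTS: dict[str, dict] = {
    "AY905542": {  # C. virginica
        "species": "C. virginica",
        "frag5": (8250, 8997),
        "frag3": (1712, 2430),
    },
    "AF177226": {  # C. gigas; 5' start has two published candidates
        "species": "C. gigas",
        "frag5": (5117, 5703),
        "frag5_alt": (5103, 5703),
        "frag3": (17265, 17977),
    },
    "EU672834": {  # C. hongkongensis (Ren et al. sequence)
        "species": "C. hongkongensis",
        "frag5": (7780, 8384),
        "frag3": (1761, 2472),
    },
    "EU266073": {  # C. hongkongensis (Yu et al.; incomplete, no 5' fragment)
        "species": "C. hongkongensis (partial)",
        "frag5": None,
        "frag3": (1764, 2475),
    },
    "DQ665851": {  # A. irradians: contiguous LSU gene, PCR control
        "species": "A. irradians",
        "frag5": None,
        "frag3": None,
    },
}


class AccessionDataMissing(FileNotFoundError):
    """The accession FASTA has not been provided locally."""


def load_accession(accession: str, data_dir="data/accessions") -> CircularGenome:
    path = Path(data_dir) / f"{accession}.fasta"
    if not path.exists():
        raise AccessionDataMissing(
            f"{path} not found: download GenBank record {accession} as FASTA "
            f"and place it there to enable accession-based statistics"
        )
    records = read_fasta(path, alphabet="dna")
    _, seq = records[0]
    return CircularGenome(accession=accession, sequence=seq, is_circular=True)


def fragment_lengths() -> dict[str, dict[str, int]]:
    """Published-coordinate fragment lengths (no sequence data needed)."""
    out: dict[str, dict[str, int]] = {}
    for acc, info in FRAGMENTS.items():
        lengths = {}
        for key in ("frag5", "frag3"):
            if info.get(key):
                lengths[key] = interval_length(*info[key])
        if lengths:
            out[acc] = lengths
    return out


def fragment_base_content(accession: str, data_dir="data/accessions"):
    """(A+T%, G+C%) per fragment of one accession (requires local FASTA)."""
    genome = load_accession(accession, data_dir)
    info = FRAGMENTS[accession]
    out = {}
    for key in ("frag5", "frag3"):
        if info.get(key):
            out[key] = base_content(genome.extract(*info[key]))
    return out


def cv_fragment_separation(data_dir="data/accessions"):
    """Circular gaps between the two *C. virginica* fragments.

    Gap A runs forward from the 5' fragment's end (nt 8997) around the
    origin to the 3' fragment's start (nt 1712).
    """
    genome = load_accession("AY905542", data_dir)
    info = FRAGMENTS["AY905542"]
    return fragment_separation(len(genome), info["frag5"], info["frag3"])


def cv_internal5_amplicons(data_dir="data/accessions"):
    """In-silico PCR of the 5'-portion primer pair on the Cv genome."""
    genome = load_accession("AY905542", data_dir)
    rows = {r["name"]: r for r in load_primer_table()}
    fwd = Primer("mt168-F", rows["mt168-F"]["sequence"], "forward")
    rev = Primer("mt169-R", rows["mt169-R"]["sequence"], "reverse")
    return amplify(genome.sequence, fwd, rev, circular=True,
                   template_id="AY905542")


def oyster_similarity_matrix(data_dir="data/accessions",
                             denominator: str = "alignment_length"):
    """Asymmetric identity matrix over the three oyster species.

    Upper triangle: 5'-fragment identities; lower: 3'-fragment identities.
    Uses EU672834 for *C. hongkongensis* (the record that includes the 5'
    fragment).
    """
    fragment_set = {}
    for acc in ("AY905542", "AF177226", "EU672834"):
        genome = load_accession(acc, data_dir)
        info = FRAGMENTS[acc]
        frag5 = genome.extract(*info["frag5"]) if info["frag5"] else None
        frag3 = genome.extract(*info["frag3"]) if info["frag3"] else None
        fragment_set[info["species"]] = (frag5, frag3)
    return similarity_matrix(fragment_set, denominator=denominator)
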
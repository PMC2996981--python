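"""In-silico PCR with degenerate primers, and the splicing-test logic.

The experimental question: are the two genomic fragments of a gene joined
into one molecule post-transcriptionally?  Three primer pairs answer it —
one internal to the 5' fragment, one internal to the 3' fragment (both are
positive controls that the cDNA preparations work), and one *spanning* pair
whose forward primer sits in the 5' fragment and reverse primer in the 3'
fragment.  A spanning product from cDNA means the transcript is contiguous
(spliced, or encoded by an unfragmented gene, in which case genomic DNA
yields it too); no spanning product from either template, with both internal
controls amplifying, means the fragments are transcribed separately.

Primer sites are matched set-wise against IUPAC degeneracy codes with a
mismatch budget, zero mismatches tolerated at the 3' terminus where the
polymerase extends.  Circular templates are scanned across the origin and
products may wrap it.  Annealing thermodynamics are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Primer",
    "BindingSite",
    "Amplicon",
    "SplicingVerdict",
    "iupac_match",
    "find_sites",
    "amplify",
    "build_cdna",
    "splicing_test",
    "splicing_verdict_from_evidence",
    "load_primer_table",
]

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Primer:
    """An IUPAC-degenerate oligo, written 5'->3'."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward/reverse, got {self.role!r}")
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        bad = set(seq) - set(IUPAC)
        if bad:
            raise ValueError(
                f"primer {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on + strand coordinates.

    ``position`` is the 1-based leftmost template position of the footprint
    (which may exceed the template length conceptually only never — wrapped
    sites are reported modulo the template length).
    """

    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    length: int


@dataclass(frozen=True)
class SplicingVerdict:
    value: str  # spliced_or_contiguous | not_spliced | inconclusive
    evidence: dict


def iupac_match(primer_window: str, template_window: str, max_mismatch: int):
    """Set-wise comparison of a primer window against a template window.

    Returns ``(matches, mismatches)`` where a template base matches a primer
    code iff it belongs to the code's set.
    """
    if len(primer_window) != len(template_window):
        raise ValueError("windows differ in length")
    mismatches = 0
    for p, t in zip(primer_window.upper(), template_window.upper()):
        if p not in IUPAC:
            raise ValueError(f"non-IUPAC primer character {p!r}")
        if t not in "ACGT":
            raise ValueError(f"non-DNA template character {t!r}")
        if t not in IUPAC[p]:
            mismatches += 1
    return mismatches <= max_mismatch, mismatches


def _scan(template: str, pattern: str, max_mismatch: int, exact_3prime: int,
          three_prime_left: bool, circular: bool):
    """Positions (0-based) where *pattern* matches the + strand.

    *three_prime_left* marks patterns whose biological 3' end is the
    leftmost base of the + strand window (reverse primers after reverse
    complementing); the mismatch-free zone is enforced there.
    """
    m = len(pattern)
    search = template + template[: m - 1] if circular else template
    sets = [IUPAC[c] for c in pattern]
    hits = []
    for s in range(len(search) - m + 1):
        if circular and s >= len(template):
            break
        window = search[s : s + m]
        mm = 0
        ok = True
        for k in range(m):
            if window[k] not in sets[k]:
                in_3prime = (k < exact_3prime) if three_prime_left else (
                    k >= m - exact_3prime
                )
                if in_3prime:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            hits.append((s, mm))
    return hits


def find_sites(
    template: str,
    primer: Primer,
    max_mismatch: int = 2,
    circular: bool = False,
    exact_3prime: int = 3,
):
    """All binding sites of *primer* on a template.

    Forward primers are scanned as written on the + strand; reverse primers
    are scanned as their reverse complement on + strand coordinates (they
    bind the - strand).  On circular templates the scan crosses the origin.
    Returns :class:`BindingSite` records with 1-based leftmost positions.
    """
    template = template.upper().replace("U", "T")
    if primer.role == "forward":
        pattern, three_prime_left, strand = primer.sequence, False, "+"
    else:
        pattern = primer.sequence.translate(_IUPAC_COMPLEMENT)[::-1]
        three_prime_left, strand = True, "-"
    return [
        BindingSite(position=s + 1, strand=strand, mismatches=mm)
        for s, mm in _scan(template, pattern, max_mismatch, exact_3prime,
                           three_prime_left, circular)
    ]


def amplify(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 2,
    max_len: int = 5000,
    circular: bool = False,
    template_id: str = "template",
):
    """Predicted products of a primer pair on one template.

    One amplicon per (forward site, reverse site) ordered pair whose length
    — from the forward footprint's 5' start to the reverse footprint's 3'
    end, inclusive, modulo the template length on circular molecules — is at
    least the two primer footprints and at most *max_len*.  An empty list is
    "no product" (a blank gel lane).
    """
    template = template.upper().replace("U", "T")
    n = len(template)
    fwd_sites = find_sites(template, fwd, max_mismatch, circular)
    rev_sites = find_sites(template, rev, max_mismatch, circular)
    min_len = len(fwd) + len(rev)
    out = []
    for fs in fwd_sites:
        for rs in rev_sites:
            rev_end = rs.position + len(rev) - 1  # rightmost footprint base
            length = rev_end - fs.position + 1
            if circular:
                length = (length - 1) % n + 1
            if length < min_len or length > max_len:
                continue
            out.append(
                Amplicon(template_id=template_id, fwd_site=fs, rev_site=rs,
                         length=length)
            )
    return sorted(out, key=lambda a: (a.fwd_site.position, a.length))


def build_cdna(transcript_set):
    """cDNA templates from transcripts: DNA alphabet, poly(A) tail retained."""
    transcripts = list(transcript_set)
    if not transcripts:
        raise ValueError("empty transcript set")
    return [(name, seq.upper().replace("U", "T")) for name, seq in transcripts]


def splicing_verdict_from_evidence(evidence: dict) -> str:
    """Pure decision rule over the amplification-evidence table.

    ``spliced_or_contiguous`` iff the spanning product amplifies from cDNA;
    ``not_spliced`` iff both internal products amplify from cDNA and the
    spanning product amplifies from neither cDNA nor genomic DNA; anything
    else is ``inconclusive`` (controls failed).
    """
    if evidence["spanning_cdna"]:
        return "spliced_or_contiguous"
    if (
        evidence["internal5_cdna"]
        and evidence["internal3_cdna"]
        and not evidence["spanning_genomic"]
    ):
        return "not_spliced"
    return "inconclusive"


def splicing_test(
    genomic_template: tuple[str, str],
    cdna_templates,
    primer_sets: dict,
    max_mismatch: int = 2,
    max_len: int = 5000,
    genomic_circular: bool = True,
) -> SplicingVerdict:
    """Run the three-primer-set splicing test.

    *primer_sets* must contain keys ``internal_5``, ``internal_3`` and
    ``spanning``, each a ``(forward_primer, reverse_primer)`` tuple.
    *genomic_template* is ``(id, sequence)``; *cdna_templates* a list of the
    same.  Evidence records, for every primer set, whether any product
    appears on the genomic template and on any cDNA template.
    """
    for key in ("internal_5", "internal_3", "spanning"):
        if key not in primer_sets:
            raise ValueError(f"missing primer set {key!r}")
    gid, gseq = genomic_template
    evidence: dict = {}
    detail: dict = {}
    for key, short in (("internal_5", "internal5"), ("internal_3", "internal3"),
                       ("spanning", "spanning")):
        fwd, rev = primer_sets[key]
        genomic_products = amplify(
            gseq, fwd, rev, max_mismatch, max_len,
            circular=genomic_circular, template_id=gid,
        )
        cdna_products = []
        for cid, cseq in cdna_templates:
            cdna_products += amplify(
                cseq, fwd, rev, max_mismatch, max_len,
                circular=False, template_id=cid,
            )
        evidence[f"{short}_genomic"] = bool(genomic_products)
        evidence[f"{short}_cdna"] = bool(cdna_products)
        detail[short] = {
            "genomic": [a.length for a in genomic_products],
            "cdna": [a.length for a in cdna_products],
        }
    verdict = splicing_verdict_from_evidence(evidence)
    return SplicingVerdict(value=verdict, evidence={**evidence, "products": detail})


def load_primer_table():
    """The shipped primer table (study primers, Table-1 style TSV).

    Returns a list of dict rows with keys region, name, sequence, role,
    expected_length, annealing_temp_c (informational fields may be empty).
    """
    text = (
        resources.files("oysterlsu.data").joinpath("primers_table.tsv").read_text()
    )
    rows = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if header is None:
            header = cols
            continue
        rows.append(dict(zip(header, cols)))
    return rows
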
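"""Gene-fragment boundary inference from EST evidence, and circular gaps.

The 5' boundary of a transcribed fragment is taken from the extreme 5'-most
position observed among aligned transcripts (optionally snapped to the base
immediately downstream of a known upstream gene); the 3' boundary is the
modal polyadenylation site — the genomic position of the last templated
nucleotide before the non-templated poly(A) tail — required to be supported
by at least a configurable majority of tailed transcripts.

`fragment_separation` measures, on a circular genome, the two inter-fragment
gaps (forward from the 5' fragment's end to the 3' fragment's start, and the
complementary arc); the two gaps plus the two fragment lengths always sum to
the genome length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

from .formats import CircularGenome

__all__ = [
    "EstAlignment",
    "BoundaryCall",
    "AmbiguousEndError",
    "NoPolyAEvidenceError",
    "detect_polya",
    "locate_ests",
    "infer_boundaries",
    "fragment_separation",
    "interval_length_circular",
]


class NoPolyAEvidenceError(ValueError):
    """No EST carries a detectable poly(A) tail; 3' end undefined."""


class AmbiguousEndError(ValueError):
    """No polyadenylation site reaches the required majority."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            "no modal poly(A) site reaches the majority threshold; "
            f"candidates (site, fraction): {candidates}"
        )


@dataclass(frozen=True)
class EstAlignment:
    """A transcript's genomic span on the annotated strand.

    ``polya_site`` is the genomic position of the last templated nucleotide
    (equal to ``genomic_end``) when a tail is present, else ``None``.
    """

    est_id: str
    genomic_start: int
    genomic_end: int
    polya_len: int = 0

    def __post_init__(self) -> None:
        if self.genomic_start > self.genomic_end:
            raise ValueError(
                f"{self.est_id}: start {self.genomic_start} > end "
                f"{self.genomic_end} (unwrap circular spans first)"
            )
        if self.polya_len < 0:
            raise ValueError(f"{self.est_id}: negative poly(A) length")

    @property
    def polya_site(self) -> int | None:
        return self.genomic_end if self.polya_len > 0 else None


@dataclass(frozen=True)
class BoundaryCall:
    """An inferred fragment interval and the evidence behind it."""

    start: int
    end: int
    start_evidence: str  # "extreme_5prime_est" | "downstream_of_feature"
    end_site: int
    end_fraction: float
    n_ests: int
    n_tailed: int


def detect_polya(est_sequence: str, min_run: int = 8, max_mismatch: int = 1):
    """Split an EST into templated part and terminal poly(A) tail.

    The tail is the longest terminal run of A allowing at most
    *max_mismatch* non-A bases, whose 5'-most base is an A and which
    contains at least *min_run* A's; otherwise the tail length is 0.
    Returns ``(templated_length, tail_length)``.
    """
    seq = est_sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    best = 0
    mismatches = 0
    for k in range(1, len(seq) + 1):
        base = seq[-k]
        if base != "A":
            mismatches += 1
            if mismatches > max_mismatch:
                break
            continue
        # suffix of length k starts with an A here
        if (k - mismatches) >= min_run:
            best = k
    return len(seq) - best, best


def _cigar_ops(cigar: str):
    """Parse an edlib extended CIGAR ('=', 'X', 'I', 'D') into (count, op)."""
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def locate_ests(
    genome: CircularGenome,
    est_records,
    min_run: int = 8,
    max_mismatch: int = 1,
    max_edit_fraction: float = 0.1,
    anchor: int = 8,
):
    """Map synthetic ESTs back to the genome (utility for simulated data).

    Each EST is poly(A)-trimmed with :func:`detect_polya`, its templated part
    located on the + strand with edlib (infix alignment; the genome is
    doubled so origin-spanning matches are found), and the 3' boundary then
    extended through templated genomic A's that the trimmer attributed to
    the tail — mirroring how a spliced aligner consumes templated adenines
    before calling the tail.  ESTs whose best hit exceeds
    *max_edit_fraction* edits are dropped.

    The reported start is anchored on the first run of at least *anchor*
    exact matches, so sequencing errors at the EST's 5' terminus shorten
    that EST's span instead of inventing an earlier gene start.
    """
    seq = genome.sequence
    ref = seq + seq[: min(len(seq), 1000)] if genome.is_circular else seq
    out: list[EstAlignment] = []
    for est_id, est_seq in est_records:
        est_seq = est_seq.upper().replace("U", "T")
        templated_len, tail = detect_polya(est_seq, min_run, max_mismatch)
        body = est_seq[:templated_len]
        if not body:
            continue
        hit = edlib.align(body, ref, mode="HW", task="path")
        if hit["editDistance"] < 0 or hit["editDistance"] > max_edit_fraction * len(body):
            continue
        start0, end0 = hit["locations"][0]
        # Anchor the 5' boundary on a solid run of matches: a terminal
        # sequencing error otherwise lets a co-optimal alignment start a
        # base early (stray match + indel), and the fragment start is a
        # minimum over ESTs, so a single such EST would corrupt the call.
        anchored = False
        for count, op in _cigar_ops(hit["cigar"]):
            if op == "=" and count >= anchor:
                anchored = True
                break
            if op in ("=", "X", "D"):
                start0 += count
        if not anchored:
            continue
        # Reclaim templated bases swallowed by the tail trimmer: the
        # detected "tail" may begin with bases that still match the genome
        # (trailing templated A's, plus the odd tolerated non-A); consume
        # them against the genomic continuation before calling the site.
        tail_seq = est_seq[templated_len:]
        while tail > 0 and end0 + 1 < len(ref) and ref[end0 + 1] == tail_seq[len(tail_seq) - tail]:
            end0 += 1
            tail -= 1
        g_start = start0 % len(seq) + 1
        g_end = end0 % len(seq) + 1
        if g_start > g_end:
            # origin-spanning span: report unwrapped coordinates beyond L
            g_end += len(seq)
        out.append(
            EstAlignment(
                est_id=est_id, genomic_start=g_start, genomic_end=g_end,
                polya_len=tail,
            )
        )
    return out


def infer_boundaries(
    est_alignments,
    upstream_feature_end: int | None = None,
    majority_min: float = 0.5,
) -> BoundaryCall:
    """Call a fragment's boundaries from aligned transcripts.

    Start: the minimum observed genomic start — unless the gene is known to
    begin right after an upstream feature whose end+1 lies 5' of every
    transcript, in which case that position is used (transcripts may simply
    be truncated).  End: the modal polyadenylation site among tailed
    transcripts; ties break toward the 3'-most site (conservative against
    truncation artefacts).  The modal site must be supported by at least
    *majority_min* of tailed transcripts.
    """
    ests = list(est_alignments)
    if not ests:
        raise ValueError("need at least one EST alignment")
    min_start = min(e.genomic_start for e in ests)
    if upstream_feature_end is not None and upstream_feature_end + 1 < min_start:
        start, start_evidence = upstream_feature_end + 1, "downstream_of_feature"
    else:
        start, start_evidence = min_start, "extreme_5prime_est"
    tailed = [e for e in ests if e.polya_site is not None]
    if not tailed:
        raise NoPolyAEvidenceError(
            "no EST carries a poly(A) tail; 3' boundary undefined"
        )
    counts = Counter(e.polya_site for e in tailed)
    top = max(counts.values())
    site = max(s for s, c in counts.items() if c == top)  # 3'-most on tie
    fraction = top / len(tailed)
    if fraction < majority_min:
        candidates = sorted(
            ((s, c / len(tailed)) for s, c in counts.items()),
            key=lambda t: (-t[1], -t[0]),
        )
        raise AmbiguousEndError(candidates)
    return BoundaryCall(
        start=start, end=site, start_evidence=start_evidence,
        end_site=site, end_fraction=fraction,
        n_ests=len(ests), n_tailed=len(tailed),
    )


def interval_length_circular(genome_length: int, interval) -> int:
    start, end = interval
    if start <= end:
        return end - start + 1
    return genome_length - start + 1 + end


def fragment_separation(genome_length: int, frag5, frag3):
    """The two circular gaps between disjoint fragment intervals.

    ``gap_a`` counts the nucleotides strictly between ``frag5.end`` and
    ``frag3.start`` going forward around the circle; ``gap_b`` is the
    complementary gap.  Conservation: the two gaps plus the two fragment
    lengths sum to the genome length.
    """
    len5 = interval_length_circular(genome_length, frag5)
    len3 = interval_length_circular(genome_length, frag3)

    def positions(interval):
        s, e = interval
        if s <= e:
            return set(range(s, e + 1))
        return set(range(s, genome_length + 1)) | set(range(1, e + 1))

    if positions(frag5) & positions(frag3):
        raise ValueError(f"fragment intervals {frag5} and {frag3} overlap")
    gap_a = (frag3[0] - frag5[1] - 1) % genome_length
    gap_b = genome_length - gap_a - len5 - len3
    return gap_a, gap_b
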
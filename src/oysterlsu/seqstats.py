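"""Fragment-level sequence statistics: lengths, base content, identity matrix.

These are the numbers summarized per species and fragment in comparative
tables: interval lengths from 1-based inclusive (possibly origin-wrapping)
coordinates, A+T / G+C percentages rounded half-up to integers, and global
pairwise identities arranged in an asymmetric species matrix — the upper
triangle holding 5'-fragment identities and the lower triangle 3'-fragment
identities, so one table carries both halves of a fragmented gene.

Identity is computed on a Needleman-Wunsch global alignment (match +1,
mismatch -1, linear gap -2) as identical columns over the full alignment
length; a config switch computes matches over non-gap aligned columns
instead, since published tables rarely state which convention they used.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from Bio import Align

from .boundaries import interval_length_circular
from .formats import reverse_transcribe

__all__ = [
    "base_content",
    "interval_length",
    "pairwise_identity",
    "similarity_matrix",
    "AllAmbiguousError",
]

MATCH, MISMATCH, GAP_SCORE = 1, -1, -2


class AllAmbiguousError(ValueError):
    """Base content is undefined: no unambiguous A/C/G/T(U) present."""


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def base_content(sequence: str) -> tuple[int, int]:
    """(A+T%, G+C%) as integers, half-up, reconciled to sum to 100.

    U counts as T; ambiguity codes (including N) are excluded from the
    denominator.  Case- and U/T-insensitive.
    """
    seq = reverse_transcribe(sequence)
    at = sum(seq.count(c) for c in "AT")
    gc = sum(seq.count(c) for c in "GC")
    if at + gc == 0:
        raise AllAmbiguousError("sequence has no unambiguous bases")
    at_pct = _round_half_up(100.0 * at / (at + gc))
    return at_pct, 100 - at_pct


def interval_length(start: int, end: int, genome_length: int | None = None) -> int:
    """Length of a 1-based inclusive interval; ``start > end`` wraps the
    origin of a circular genome of *genome_length*."""
    if start < 1 or end < 1:
        raise ValueError(f"coordinates are 1-based, got ({start}, {end})")
    if start <= end:
        return end - start + 1
    if genome_length is None:
        raise ValueError(
            f"start {start} > end {end}: origin-spanning interval needs "
            "genome_length"
        )
    return interval_length_circular(genome_length, (start, end))


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, denominator: str = "alignment_length"
) -> int:
    """Percent identity from a global alignment, rounded half-up.

    ``denominator="alignment_length"`` counts gapped columns against
    identity; ``"aligned_columns"`` divides by non-gap columns only.
    """
    a = reverse_transcribe(seq_a)
    b = reverse_transcribe(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(a, b)[0]
    col_a, col_b = alignment[0], alignment[1]
    matches = sum(x == y and x != "-" for x, y in zip(col_a, col_b))
    if denominator == "alignment_length":
        denom = len(col_a)
    elif denominator == "aligned_columns":
        denom = sum(x != "-" and y != "-" for x, y in zip(col_a, col_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return _round_half_up(100.0 * matches / denom)


def similarity_matrix(
    fragment_set: dict[str, tuple[str | None, str | None]],
    denominator: str = "alignment_length",
) -> pd.DataFrame:
    """Asymmetric identity matrix over species.

    *fragment_set* maps species -> (frag5_seq, frag3_seq); either fragment
    may be ``None`` (e.g. an incomplete accession), in which case the
    corresponding cells are NA.  Upper triangle: 5'-fragment identities;
    lower triangle: 3'-fragment identities; diagonal NA.
    """
    species = list(fragment_set)
    if len(species) < 2:
        raise ValueError("need at least two species")
    df = pd.DataFrame(index=species, columns=species, dtype="float64")
    for ai, a in enumerate(species):
        for bi, b in enumerate(species):
            if ai == bi:
                continue
            frag_index = 0 if ai < bi else 1  # upper = 5', lower = 3'
            sa = fragment_set[a][frag_index]
            sb = fragment_set[b][frag_index]
            if sa is None or sb is None:
                continue
            df.loc[a, b] = pairwise_identity(sa, sb, denominator)
    return df
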
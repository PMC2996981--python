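"""Template-based secondary-structure transfer and domain-presence calls.

Comparative modelling rarely builds a structure de novo: a new sequence
inherits the model of its closest previously-modelled relative through a
pairwise alignment, keeping only the base pairs whose two positions both map
and whose target letters can still pair (Watson-Crick or GU).  On top of the
transferred structure this module calls, per structural domain (I-VI of the
LSU rRNA) or arbitrary named region, whether the domain survives in the
target (present / partial / absent) — the machinery behind statements like
"domain III is absent" or "the fragmentation site falls between domains II
and IV, in a region lining the peptide exit tunnel".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats import FormatError, SecondaryStructure

__all__ = [
    "PairwiseAlignment",
    "DomainMap",
    "MappingReport",
    "map_template",
    "domain_presence",
    "region_overlap_report",
    "fragmentation_site_check",
    "read_domain_map_tsv",
]

CANONICAL = frozenset(["AU", "UA", "GC", "CG", "GU", "UG"])

DROP_REASONS = ("unmapped_i", "unmapped_j", "non_canonical")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A monotone template->target position map from two gapped rows."""

    template_id: str
    target_id: str
    template_row: str
    target_row: str

    def __post_init__(self) -> None:
        if len(self.template_row) != len(self.target_row):
            raise FormatError("aligned rows differ in length")

    @classmethod
    def from_rows(cls, template, target) -> "PairwiseAlignment":
        (tid, trow), (gid, grow) = template, target
        return cls(template_id=tid, target_id=gid,
                   template_row=trow.upper().replace("T", "U"),
                   target_row=grow.upper().replace("T", "U"))

    def position_map(self) -> dict[int, int]:
        """Template position -> target position; gapped positions absent."""
        out: dict[int, int] = {}
        t = g = 0
        for a, b in zip(self.template_row, self.target_row):
            if a != "-":
                t += 1
            if b != "-":
                g += 1
            if a != "-" and b != "-":
                out[t] = g
        return out

    @property
    def template_length(self) -> int:
        return sum(1 for c in self.template_row if c != "-")

    @property
    def target_length(self) -> int:
        return sum(1 for c in self.target_row if c != "-")


@dataclass(frozen=True)
class DomainMap:
    """Named intervals on one declared coordinate system.

    Domain names are conventionally the roman numerals I-VI; arbitrary
    region names (e.g. peptide-exit-tunnel segments) are allowed.  The
    coordinate ``system`` is an opaque label (e.g. "E. coli numbering",
    "template") that must match between inputs; nothing is converted.
    """

    intervals: tuple[tuple[str, int, int], ...]
    system: str = "template"

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(map(tuple, self.intervals)))
        for name, s, e in self.intervals:
            if s > e or s < 1:
                raise FormatError(f"domain {name!r}: bad interval ({s}, {e})")

    def get(self, name: str) -> tuple[int, int]:
        for n, s, e in self.intervals:
            if n == name:
                return s, e
        raise KeyError(name)

    def names(self):
        return [n for n, _, _ in self.intervals]

    def check_disjoint(self) -> None:
        ivs = sorted((s, e, n) for n, s, e in self.intervals)
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"domains {n1!r} and {n2!r} overlap ({s1}-{e1} vs {s2}-{e2})"
                )


def read_domain_map_tsv(path) -> dict[str, DomainMap]:
    """Read 4-column TSV (name, start, end, system) into maps per system."""
    by_system: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            name, s, e, system = cols
            by_system.setdefault(system, []).append((name, int(s), int(e)))
    return {
        system: DomainMap(intervals=tuple(ivs), system=system)
        for system, ivs in by_system.items()
    }


@dataclass
class MappingReport:
    """Bookkeeping of a structure transfer: every template pair is either
    retained or dropped with a reason; the two sets partition the template
    pair set exactly."""

    retained: frozenset = frozenset()
    dropped: dict[tuple[int, int], str] = field(default_factory=dict)
    domain_retention: dict[str, float | None] = field(default_factory=dict)

    @property
    def n_template_pairs(self) -> int:
        return len(self.retained) + len(self.dropped)


def map_template(
    template: SecondaryStructure,
    aln: PairwiseAlignment,
    target_seq: str,
    domain_map: DomainMap | None = None,
):
    """Transfer *template*'s pairs onto *target_seq* through *aln*.

    A pair (i, j) is retained iff both positions map through the alignment
    and the target letters form a canonical (WC/GU) pair; otherwise it is
    dropped with reason ``unmapped_i`` / ``unmapped_j`` / ``non_canonical``.
    A monotone map cannot introduce crossings, so nestedness is preserved.
    Returns ``(target_structure, MappingReport)``; with a *domain_map* (on
    template coordinates) the report carries per-domain retention fractions
    (``None`` for domains containing no template pairs).
    """
    target_seq = target_seq.upper().replace("T", "U")
    if aln.template_length != len(template):
        raise FormatError(
            f"alignment template side has {aln.template_length} positions, "
            f"structure has {len(template)}"
        )
    if aln.target_length != len(target_seq):
        raise FormatError(
            f"alignment target side has {aln.target_length} positions, "
            f"sequence has {len(target_seq)}"
        )
    pos_map = aln.position_map()
    retained_template: set[tuple[int, int]] = set()
    target_pairs: set[tuple[int, int]] = set()
    dropped: dict[tuple[int, int], str] = {}
    for i, j in sorted(template.pairs):
        if i not in pos_map:
            dropped[(i, j)] = "unmapped_i"
            continue
        if j not in pos_map:
            dropped[(i, j)] = "unmapped_j"
            continue
        ti, tj = pos_map[i], pos_map[j]
        if target_seq[ti - 1] + target_seq[tj - 1] not in CANONICAL:
            dropped[(i, j)] = "non_canonical"
            continue
        retained_template.add((i, j))
        target_pairs.add((ti, tj))
    report = MappingReport(
        retained=frozenset(retained_template), dropped=dropped
    )
    if domain_map is not None:
        report.domain_retention = _domain_retention(template, report, domain_map)
    structure = SecondaryStructure(
        sequence=target_seq, pairs=frozenset(target_pairs),
        pseudoknot=template.pseudoknot,
    )
    return structure, report


def _domain_retention(template, report: MappingReport, domain_map: DomainMap):
    """Fraction of each domain's template pairs that survived the transfer.

    A pair belongs to the domain containing its 5' position.  Domains with
    no template pairs get ``None`` (no evidence either way).
    """
    domain_map.check_disjoint()
    out: dict[str, float | None] = {}
    for name, s, e in domain_map.intervals:
        in_dom = [p for p in report.retained if s <= p[0] <= e]
        dropped = [p for p in report.dropped if s <= p[0] <= e]
        total = len(in_dom) + len(dropped)
        out[name] = None if total == 0 else len(in_dom) / total
    return out


def domain_presence(
    report_or_retention,
    domain_map: DomainMap,
    absent_below: float = 0.1,
    present_above: float = 0.9,
) -> dict[str, str]:
    """Call each domain {present, partial, absent} from retention fractions.

    retention < *absent_below* -> absent; retention > *present_above* ->
    present; anything between -> partial.  Domains without pair evidence
    (retention ``None``) are called absent only if the map says so upstream;
    here they are reported as ``"no_pairs"``.
    """
    domain_map.check_disjoint()
    if isinstance(report_or_retention, MappingReport):
        retention = report_or_retention.domain_retention
        if not retention:
            retention = _domain_retention_from_report(report_or_retention, domain_map)
    else:
        retention = dict(report_or_retention)
    calls: dict[str, str] = {}
    for name in domain_map.names():
        r = retention.get(name)
        if r is None:
            calls[name] = "no_pairs"
        elif r < absent_below:
            calls[name] = "absent"
        elif r > present_above:
            calls[name] = "present"
        else:
            calls[name] = "partial"
    return calls


def _domain_retention_from_report(report: MappingReport, domain_map: DomainMap):
    out: dict[str, float | None] = {}
    for name, s, e in domain_map.intervals:
        in_dom = [p for p in report.retained if s <= p[0] <= e]
        dropped = [p for p in report.dropped if s <= p[0] <= e]
        total = len(in_dom) + len(dropped)
        out[name] = None if total == 0 else len(in_dom) / total
    return out


def region_overlap_report(domain_calls: dict[str, str], domain_map: DomainMap,
                          region_map: DomainMap):
    """For each named region, which domains it overlaps and whether any is absent.

    Both maps must be on the same coordinate system; regions are e.g. the
    rRNA segments lining the peptide exit tunnel.
    """
    if domain_map.system != region_map.system:
        raise FormatError(
            f"coordinate systems differ: {domain_map.system!r} vs "
            f"{region_map.system!r}"
        )
    rows = []
    for region, rs, re_ in region_map.intervals:
        overlapping = [
            name for name, ds, de in domain_map.intervals
            if not (re_ < ds or de < rs)
        ]
        any_absent = any(domain_calls.get(d) == "absent" for d in overlapping)
        rows.append({
            "region": region,
            "overlapping_domains": overlapping,
            "any_absent": any_absent,
        })
    return rows


def fragmentation_site_check(
    frag5_interval, frag3_interval, domain_map_on_template: DomainMap
) -> bool:
    """Does the break between the fragments fall strictly between domains II
    and IV (on template coordinates)?

    The break occupies template positions ``frag5.end + 1 .. frag3.start - 1``
    (the material missing between the two fragment images).  The verdict is
    true iff that interval is non-empty, starts strictly after domain II's
    last position and ends strictly before domain IV's first position.
    """
    try:
        _, d2_end = domain_map_on_template.get("II")
        d4_start, _ = domain_map_on_template.get("IV")
    except KeyError as exc:
        raise FormatError(f"domain {exc.args[0]!r} missing from map") from exc
    break_start = frag5_interval[1] + 1
    break_end = frag3_interval[0] - 1
    if break_start > break_end:
        return False
    return break_start > d2_end and break_end < d4_start
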
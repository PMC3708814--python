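"""Placing MREs on reference transcripts and merging them into regions.

An MRE catalog row gives a site sequence and/or coordinates.  Sequences are
placed by perfect full-length exact match on the sense strand
(:func:`locate_mre`); candidate sites can also be nominated by seed
complementarity (:func:`find_seed_matches`).  Co-located sites bound by
different microRNAs are grouped into "MRE regions" when they overlap by at
least 90% of the shorter site (:func:`merge_regions`), and each region is
summarized by the range of its members' repressive ratios; a region whose
maximum ratio reaches 30% is called highly repressive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import MRESite, ReferenceSequence, normalize_sequence

__all__ = [
    "SeedMatch",
    "MRERegion",
    "RegionSummary",
    "RegionReport",
    "locate_mre",
    "find_seed_matches",
    "merge_regions",
    "summarize_region",
    "region_report",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedMatch:
    """A 7-nt target match complementary to microRNA nucleotides 2-8."""

    mirna_id: str
    start: int
    end: int
    heptamer: str

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class MRERegion:
    """A merged group of MRE sites treated as a single locus.

    ``region_index`` is 1-based in ascending start order within one
    reference.  The interval is the union span of the members; supported
    tissues are the union of member annotations.
    """

    region_index: int
    reference_id: str
    start: int
    end: int
    members: tuple[MRESite, ...]
    supported_tissues_cancer: tuple[str, ...] = ()
    supported_tissues_normal: tuple[str, ...] = ()

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class RegionSummary:
    """Repressiveness summary of one region.

    ``available`` is False when no member carries a repressive ratio; the
    min/max are then None and the region is not called highly repressive.
    """

    repression_min: float | None
    repression_max: float | None
    highly_repressive: bool
    n_mirnas: int
    available: bool


@dataclass(frozen=True)
class RegionReport:
    """Aggregate counts over the regions of one gene."""

    n_regions: int
    n_highly_repressive: int
    n_supported_any: int
    n_supported_cancer: int
    n_supported_normal: int
    n_supported_and_highly_repressive: int


def locate_mre(
    reference: ReferenceSequence, site_sequence: str
) -> list[tuple[int, int]]:
    """All perfect full-length occurrences of *site_sequence* on *reference*.

    Matching is exact on the sense strand after U->T / upper-case
    normalization; windows containing ``N`` (on either side) never match.
    Overlapping occurrences are all reported.  Returns 0-based half-open
    intervals, empty if there is no perfect match.
    """
    if not site_sequence or not site_sequence.strip():
        raise ValueError("empty MRE site sequence")
    query = normalize_sequence(site_sequence, context="MRE site sequence")
    if "N" in query:
        return []  # N never matches
    hits: list[tuple[int, int]] = []
    target = reference.sequence
    pos = target.find(query)
    while pos != -1:
        window = target[pos : pos + len(query)]
        if "N" not in window:
            hits.append((pos, pos + len(query)))
        pos = target.find(query, pos + 1)
    return hits


def find_seed_matches(
    mirna_sequence: str,
    target: ReferenceSequence,
    search_interval: tuple[int, int] | None = None,
    mirna_id: str = "",
) -> list[SeedMatch]:
    """Occurrences in *target* of the seed heptamer of *mirna_sequence*.

    The seed is defined as the reverse complement of microRNA nucleotides
    2-8 (1-based from the 5' end), i.e. a 7mer-m8-style match.  Overlapping
    occurrences are all reported; the search can be restricted to
    *search_interval* (0-based half-open, matches must lie fully inside).
    """
    mirna = normalize_sequence(mirna_sequence, context="microRNA sequence")
    if len(mirna) < 8:
        raise ValueError(
            f"microRNA sequence must be at least 8 nt, got {len(mirna)}"
        )
    heptamer = reverse_complement(mirna[1:8])
    lo, hi = (0, target.length) if search_interval is None else search_interval
    region = target.sequence[lo:hi]
    matches: list[SeedMatch] = []
    pos = region.find(heptamer)
    while pos != -1:
        window = region[pos : pos + 7]
        if "N" not in window and "N" not in heptamer:
            matches.append(
                SeedMatch(
                    mirna_id=mirna_id,
                    start=lo + pos,
                    end=lo + pos + 7,
                    heptamer=heptamer,
                )
            )
        pos = region.find(heptamer, pos + 1)
    return matches


def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap normalized by the length of the shorter interval.

    With this denominator a short site fully contained in a longer one
    counts as complete (fraction 1.0) overlap, which is what groups many
    co-located microRNA sites into one region.
    """
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])


def merge_regions(
    sites: list[MRESite], overlap_threshold: float = 0.90
) -> list[MRERegion]:
    """Group sites overlapping by >= *overlap_threshold* into MRE regions.

    The pairwise overlap fraction is |intersection| / min(|a|, |b|); pairs at
    or above the threshold are merged by single-linkage transitive closure,
    so a chain of pairwise-overlapping sites forms one region.  Every input
    site lands in exactly one region; regions are numbered 1..K by ascending
    start.  All sites must share one reference_id.
    """
    if not sites:
        return []
    refs = {s.reference_id for s in sites}
    if len(refs) > 1:
        raise ValueError(
            f"merge_regions requires a single reference, got {sorted(refs)}"
        )
    n = len(sites)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sort by start so the pair scan can stop early; O(n^2) worst case
    order = sorted(range(n), key=lambda i: (sites[i].start, sites[i].end))
    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            if sites[j].start >= sites[i].end:
                break
            if overlap_fraction(sites[i].interval, sites[j].interval) >= overlap_threshold:
                union(i, j)

    groups: dict[int, list[MRESite]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(sites[i])
    clusters = sorted(
        groups.values(), key=lambda g: (min(s.start for s in g), max(s.end for s in g))
    )
    regions: list[MRERegion] = []
    for idx, members in enumerate(clusters, start=1):
        members_sorted = tuple(
            sorted(members, key=lambda s: (s.start, s.end, s.site_id))
        )
        cancer = sorted({t for s in members for t in s.supported_tissues_cancer})
        normal = sorted({t for s in members for t in s.supported_tissues_normal})
        regions.append(
            MRERegion(
                region_index=idx,
                reference_id=members_sorted[0].reference_id,
                start=min(s.start for s in members),
                end=max(s.end for s in members),
                members=members_sorted,
                supported_tissues_cancer=tuple(cancer),
                supported_tissues_normal=tuple(normal),
            )
        )
    return regions


def summarize_region(
    region: MRERegion, repression_threshold: float = 30.0
) -> RegionSummary:
    """Min/max repressive ratio over members and the highly-repressive call.

    The call is inclusive: a region whose maximum member ratio equals the
    threshold (default 30%) is highly repressive.  Regions whose members
    carry no ratio yield an unavailable summary rather than an error.
    """
    ratios = [
        s.repressive_ratio for s in region.members if s.repressive_ratio is not None
    ]
    n_mirnas = len({s.mirna_id for s in region.members})
    if not ratios:
        return RegionSummary(None, None, False, n_mirnas, available=False)
    rmin, rmax = min(ratios), max(ratios)
    return RegionSummary(
        repression_min=rmin,
        repression_max=rmax,
        highly_repressive=rmax >= repression_threshold,
        n_mirnas=n_mirnas,
        available=True,
    )


def region_report(
    regions: list[MRERegion], repression_threshold: float = 30.0
) -> RegionReport:
    """Aggregate counts over one gene's regions: how many are highly
    repressive, how many have tissue support (by stratum), and the overlap
    between the supported and highly repressive sets."""
    n_high = 0
    n_any = 0
    n_cancer = 0
    n_normal = 0
    n_both = 0
    for region in regions:
        summary = summarize_region(region, repression_threshold)
        supported = bool(
            region.supported_tissues_cancer or region.supported_tissues_normal
        )
        if summary.highly_repressive:
            n_high += 1
        if supported:
            n_any += 1
        if region.supported_tissues_cancer:
            n_cancer += 1
        if region.supported_tissues_normal:
            n_normal += 1
        if supported and summary.highly_repressive:
            n_both += 1
    return RegionReport(
        n_regions=len(regions),
        n_highly_repressive=n_high,
        n_supported_any=n_any,
        n_supported_cancer=n_cancer,
        n_supported_normal=n_normal,
        n_supported_and_highly_repressive=n_both,
    )
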
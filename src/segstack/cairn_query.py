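"""Co-alteration queries over one or two genomic regions.

A segment *qualifies* for a query when it overlaps the region by at
least 1 bp and its log2 value passes the direction's threshold
(log2 <= loss_threshold for losses, log2 >= gain_threshold for gains).
Samples are then classified into exactly one of four categories:
``exclusive_a``, ``exclusive_b``, ``coincident``, ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from segstack.genome_model import (
    Cohort,
    GeneRegion,
    GenomeBuild,
    SampleProfile,
    Segment,
    ValidationError,
)

CATEGORIES = ("exclusive_a", "exclusive_b", "coincident", "none")

RegionLike = GeneRegion | tuple[str, int, int]


def as_interval(region: RegionLike) -> tuple[str, int, int]:
    if isinstance(region, GeneRegion):
        return region.interval
    chrom, start, end = region
    if not start < end:
        raise ValidationError(f"region {chrom}:{start}-{end}: start must be < end")
    return (str(chrom), int(start), int(end))


@dataclass(frozen=True)
class RegionQuery:
    """One- or two-region alteration query.

    ``single_segment_coincidence`` restricts coincidence to samples in
    which one segment spans both regions; by default coincidence is a
    per-sample property (two separate qualifying segments count).
    """

    region_a: RegionLike
    region_b: RegionLike | None = None
    direction: str = "loss"
    loss_threshold: float = -0.2
    gain_threshold: float = 0.2
    single_segment_coincidence: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("loss", "gain"):
            raise ValidationError(f"direction must be loss or gain, got {self.direction!r}")
        if not self.loss_threshold < 0 < self.gain_threshold:
            raise ValidationError(
                "thresholds must satisfy loss_threshold < 0 < gain_threshold"
            )
        as_interval(self.region_a)
        if self.region_b is not None:
            as_interval(self.region_b)

    def qualifies(self, segment: Segment, region: RegionLike) -> bool:
        chrom, start, end = as_interval(region)
        if not segment.overlaps(chrom, start, end):
            return False
        if self.direction == "loss":
            return segment.log2 <= self.loss_threshold
        return segment.log2 >= self.gain_threshold

    def swapped(self) -> "RegionQuery":
        """The same query with regions A and B exchanged."""
        if self.region_b is None:
            raise ValidationError("cannot swap a single-region query")
        return RegionQuery(
            self.region_b,
            self.region_a,
            self.direction,
            self.loss_threshold,
            self.gain_threshold,
            self.single_segment_coincidence,
        )


@dataclass
class SampleClassification:
    sample_id: str
    category: str
    supporting_segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.category == "none") != (len(self.supporting_segments) == 0):
            raise ValidationError(
                "category 'none' iff supporting_segments is empty"
            )


def _check_regions_in_build(query: RegionQuery, build: GenomeBuild | None) -> None:
    if build is None:
        return
    for region in (query.region_a, query.region_b):
        if region is None:
            continue
        chrom, _, _ = as_interval(region)
        if chrom not in build:
            raise ValidationError(
                f"query region chromosome {chrom!r} absent from build {build.name!r}"
            )


def classify_sample(
    profile: SampleProfile,
    query: RegionQuery,
    build: GenomeBuild | None = None,
) -> SampleClassification:
    """Classify one sample against the query.

    With two regions: ``coincident`` when both regions have a qualifying
    segment (possibly the same one), ``exclusive_a``/``exclusive_b``
    when exactly one does, ``none`` otherwise.  Under
    ``single_segment_coincidence`` a sample whose two regions are hit
    only by separate segments is classified as exclusive of the region
    carrying its most extreme qualifying segment.
    """
    _check_regions_in_build(query, build)
    hits_a = [s for s in profile.segments if query.qualifies(s, query.region_a)]
    if query.region_b is None:
        if hits_a:
            return SampleClassification(profile.sample_id, "exclusive_a", hits_a)
        return SampleClassification(profile.sample_id, "none", [])
    hits_b = [s for s in profile.segments if query.qualifies(s, query.region_b)]
    if hits_a and hits_b:
        supporting = sorted(set(hits_a) | set(hits_b), key=lambda s: (s.chrom, s.start))
        if not query.single_segment_coincidence:
            return SampleClassification(profile.sample_id, "coincident", supporting)
        spanning = [s for s in hits_a if s in set(hits_b)]
        if spanning:
            return SampleClassification(profile.sample_id, "coincident", spanning)
        # no single spanning segment: attribute to the region with the
        # strongest segment (ties favour region A)
        extreme = min if query.direction == "loss" else max
        best_a = extreme(s.log2 for s in hits_a)
        best_b = extreme(s.log2 for s in hits_b)
        a_wins = best_a <= best_b if query.direction == "loss" else best_a >= best_b
        if a_wins:
            return SampleClassification(profile.sample_id, "exclusive_a", hits_a)
        return SampleClassification(profile.sample_id, "exclusive_b", hits_b)
    if hits_a:
        return SampleClassification(profile.sample_id, "exclusive_a", hits_a)
    if hits_b:
        return SampleClassification(profile.sample_id, "exclusive_b", hits_b)
    return SampleClassification(profile.sample_id, "none", [])


@dataclass
class CohortSummary:
    counts: dict[str, int]
    classifications: list[SampleClassification]
    query: RegionQuery

    @property
    def table(self) -> pd.DataFrame:
        """Per-sample table: sample, category, n_supporting, min_log2."""
        rows = []
        for c in self.classifications:
            rows.append(
                {
                    "sample": c.sample_id,
                    "category": c.category,
                    "n_supporting": len(c.supporting_segments),
                    "min_log2": (
                        min(s.log2 for s in c.supporting_segments)
                        if c.supporting_segments
                        else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows, columns=["sample", "category", "n_supporting", "min_log2"])


def cohort_summary(cohort: Cohort, query: RegionQuery) -> CohortSummary:
    """Classify every sample; counts always partition the cohort."""
    classifications = [
        classify_sample(p, query, cohort.build) for p in cohort.profiles
    ]
    counts = {cat: 0 for cat in CATEGORIES}
    for c in classifications:
        counts[c.category] += 1
    return CohortSummary(counts=counts, classifications=classifications, query=query)


@dataclass(frozen=True)
class TerminalSegment:
    """A qualifying segment with >= 1 endpoint inside the query region."""

    segment: Segment
    start_in_region: bool
    end_in_region: bool


def segments_terminating_in(
    cohort: Cohort,
    region: RegionLike,
    direction: str = "loss",
    loss_threshold: float = -0.2,
    gain_threshold: float = 0.2,
) -> list[TerminalSegment]:
    """Qualifying segments with at least one endpoint inside *region*
    (e.g. telo-centric CNAs ending in a telomeric window)."""
    chrom, start, end = as_interval(region)
    query = RegionQuery(
        region_a=(chrom, start, end),
        direction=direction,
        loss_threshold=loss_threshold,
        gain_threshold=gain_threshold,
    )
    out: list[TerminalSegment] = []
    for profile in cohort.profiles:
        for seg in profile.segments:
            if seg.chrom != chrom:
                continue
            if direction == "loss" and not seg.log2 <= loss_threshold:
                continue
            if direction == "gain" and not seg.log2 >= gain_threshold:
                continue
            s_in = start <= seg.start < end
            e_in = start <= seg.end < end
            if s_in or e_in:
                out.append(TerminalSegment(seg, s_in, e_in))
    return out


# ---------------------------------------------------------------------------
# stacked rendering

_CATEGORY_ORDER = {c: i for i, c in enumerate(CATEGORIES)}

_STYLE = {
    "loss": "#2166ac",
    "gain": "#b2182b",
    "backbone": "#bdbdbd",
    "region": "#252525",
}


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_stack(
    summary: CohortSummary,
    build: GenomeBuild,
    width: int = 960,
    row_height: int = 8,
    row_gap: int = 2,
    margin: int = 40,
) -> str:
    """Render the classified cohort as a deterministic stacked SVG.

    One horizontal bar per qualifying supporting segment, blue for loss
    (log2 < 0) and red for gain, over a grey chromosome backbone with
    the query region(s) marked.  Samples in category ``none`` are not
    drawn.  Byte-identical output for identical input.
    """
    query = summary.query
    chrom_a, a_start, a_end = as_interval(query.region_a)
    regions = [(chrom_a, a_start, a_end)]
    if query.region_b is not None:
        chrom_b, b_start, b_end = as_interval(query.region_b)
        if chrom_b != chrom_a:
            raise ValidationError(
                "regions lie on different chromosomes; a single-chromosome "
                "stacked view is impossible -- render per-chromosome panels"
            )
        regions.append((chrom_b, b_start, b_end))
    if chrom_a not in build:
        raise ValidationError(f"chromosome {chrom_a!r} absent from build")
    chrom_len = build.chrom_lengths[chrom_a]

    def xpos(pos: int) -> float:
        return margin + (width - 2 * margin) * pos / chrom_len

    def row_key(c: SampleClassification):
        directions = {0 if s.log2 < 0 else 1 for s in c.supporting_segments}
        first_start = min(
            (s.start for s in c.supporting_segments if s.chrom == chrom_a),
            default=chrom_len,
        )
        return (_CATEGORY_ORDER[c.category], min(directions), first_start, c.sample_id)

    drawn = sorted(
        (c for c in summary.classifications if c.category != "none"), key=row_key
    )
    height = 2 * margin + 20 + len(drawn) * (row_height + row_gap)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect x="{_fmt(xpos(0))}" y="{margin}" '
        f'width="{_fmt(xpos(chrom_len) - xpos(0))}" height="6" '
        f'fill="{_STYLE["backbone"]}" class="backbone"/>',
    ]
    for i, (chrom, start, end) in enumerate(regions):
        x0, x1 = xpos(start), xpos(end)
        w = max(x1 - x0, 1.0)
        parts.append(
            f'<rect x="{_fmt(x0)}" y="{margin - 6}" width="{_fmt(w)}" '
            f'height="18" fill="none" stroke="{_STYLE["region"]}" '
            f'stroke-width="1" class="region region-{"ab"[i]}"/>'
        )
    y = margin + 20
    for c in drawn:
        for seg in sorted(c.supporting_segments, key=lambda s: (s.start, s.end)):
            if seg.chrom != chrom_a:
                continue
            color = _STYLE["loss"] if seg.log2 < 0 else _STYLE["gain"]
            kind = "loss" if seg.log2 < 0 else "gain"
            x0 = xpos(seg.start)
            w = max(xpos(seg.end) - x0, 0.5)
            parts.append(
                f'<rect x="{_fmt(x0)}" y="{y}" width="{_fmt(w)}" '
                f'height="{row_height}" fill="{color}" '
                f'class="cna {kind}" data-sample="{c.sample_id}"/>'
            )
        y += row_height + row_gap
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
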
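"""Core data types and file I/O for segmented copy-number data.

Internal coordinates are 0-based half-open throughout.  SEG-style
dialects (``seg``, ``tcga``, ``hmmcopy``) are 1-based inclusive on disk
and converted on read/write; BED-like annotation files are 0-based
half-open and pass through unchanged.  Chromosome labels are normalized
to an un-prefixed canonical form (``"17"``, ``"X"``).
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class SegstackError(Exception):
    """Base class for all segstack errors."""


class ParseError(SegstackError):
    """A malformed input row; the message names the offending line."""


class ValidationError(SegstackError):
    """Structurally valid input that violates a domain invariant."""


def normalize_chrom(label: object) -> str:
    """Canonical chromosome label: string, ``chr`` prefix stripped."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise ValidationError("empty chromosome label")
    return s


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Sort numeric chromosomes numerically, then X/Y/M, then the rest."""
    if chrom.isdigit():
        return (0, int(chrom), "")
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if chrom.upper() in special:
        return (0, special[chrom.upper()], "")
    return (1, 0, chrom)


# ---------------------------------------------------------------------------
# coordinate conventions

_ONE_BASED_DIALECTS = frozenset({"seg", "tcga", "hmmcopy"})
_ZERO_BASED_DIALECTS = frozenset({"bed"})
DIALECTS = _ONE_BASED_DIALECTS | _ZERO_BASED_DIALECTS


def to_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    """Convert a (start, end) pair from *dialect* to 0-based half-open."""
    if dialect in _ONE_BASED_DIALECTS:
        return start - 1, end
    if dialect in _ZERO_BASED_DIALECTS:
        return start, end
    raise ValueError(f"unknown dialect: {dialect!r}")


def from_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    """Inverse of :func:`to_internal`."""
    if dialect in _ONE_BASED_DIALECTS:
        return start + 1, end
    if dialect in _ZERO_BASED_DIALECTS:
        return start, end
    raise ValueError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Segment:
    """One contiguous copy-number interval of one sample.

    ``log2`` is the copy-number log2 ratio (0 = reference ploidy);
    coordinates are 0-based half-open.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    log2: float
    n_markers: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start < 0"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if not math.isfinite(self.log2):
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"non-finite log2 {self.log2!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff this segment intersects [start, end) on *chrom* by >= 1 bp."""
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class SampleProfile:
    """All segments of one sample, sorted by (chrom, start), non-overlapping
    within each chromosome."""

    sample_id: str
    segments: list[Segment]
    group: str | None = None

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start)
        )
        prev: Segment | None = None
        for seg in self.segments:
            if seg.sample_id != self.sample_id:
                raise ValidationError(
                    f"segment sample_id {seg.sample_id!r} != profile "
                    f"{self.sample_id!r}"
                )
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on "
                    f"{seg.chrom}: [{prev.start},{prev.end}) and "
                    f"[{seg.start},{seg.end})"
                )
            prev = seg

    def segments_on(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    @property
    def chroms(self) -> list[str]:
        return sorted({s.chrom for s in self.segments}, key=chrom_sort_key)


@dataclass
class Cohort:
    """A set of sample profiles on one genome build."""

    profiles: list[SampleProfile]
    build: GenomeBuild | None = None

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_ids: {dupes}")
        if self.build is not None:
            self.validate_against(self.build)

    def validate_against(self, build: GenomeBuild) -> None:
        for profile in self.profiles:
            for seg in profile.segments:
                if seg.chrom not in build.chrom_lengths:
                    raise ValidationError(
                        f"sample {seg.sample_id}: unknown chromosome "
                        f"{seg.chrom!r} for build {build.name!r}"
                    )
                if seg.end > build.chrom_lengths[seg.chrom]:
                    raise ValidationError(
                        f"sample {seg.sample_id}: segment "
                        f"{seg.chrom}:{seg.start}-{seg.end} exceeds chromosome "
                        f"length {build.chrom_lengths[seg.chrom]}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[SampleProfile]:
        return iter(self.profiles)

    def get(self, sample_id: str) -> SampleProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome names and lengths; free-text build label."""

    name: str
    chrom_lengths: Mapping[str, int]
    coordinates: str = "0-based half-open"

    def __post_init__(self) -> None:
        norm = {normalize_chrom(c): int(l) for c, l in self.chrom_lengths.items()}
        object.__setattr__(self, "chrom_lengths", norm)
        for chrom, length in norm.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom}: length {length} <= 0")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths, key=chrom_sort_key)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class GeneRegion:
    """A gene span (first exon start to last exon end, introns included)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


Interval = tuple[str, int, int]


@dataclass
class GenomeAnnotation:
    """Feature tracks over one genome build.

    ``centromeres`` maps chromosome -> (start, end).  ``fragile_sites``
    and ``stable_sites`` are interval lists.  Telomere windows are
    synthesized per chromosome as [0, W) and [L - W, L) with
    W = ``telomere_window_bp`` (default 2 Mb).
    """

    build: GenomeBuild
    genes: list[GeneRegion] = field(default_factory=list)
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    fragile_sites: list[Interval] = field(default_factory=list)
    stable_sites: list[Interval] = field(default_factory=list)
    telomere_window_bp: int = 2_000_000
    expression: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.telomere_window_bp <= 0:
            raise ValidationError("telomere_window_bp must be > 0")
        offenders = []
        for g in self.genes:
            length = self.build.chrom_lengths.get(g.chrom)
            if length is None or g.end > length or g.start < 0:
                offenders.append(g.gene_id)
        if offenders:
            raise ValidationError(
                f"genes outside chromosome bounds: {sorted(offenders)}"
            )
        for track_name, track in (
            ("centromere", [(c, s, e) for c, (s, e) in self.centromeres.items()]),
            ("fragile", self.fragile_sites),
            ("stable", self.stable_sites),
        ):
            for chrom, start, end in track:
                length = self.build.chrom_lengths.get(chrom)
                if length is None or start < 0 or end > length or start >= end:
                    raise ValidationError(
                        f"{track_name} interval {chrom}:{start}-{end} invalid "
                        f"for build {self.build.name!r}"
                    )

    def telomere_windows(self, chrom: str) -> list[tuple[int, int]]:
        """The two terminal windows [0, W) and [L - W, L), clipped/merged
        for chromosomes shorter than 2 W."""
        length = self.build.chrom_lengths[chrom]
        w = self.telomere_window_bp
        if length <= 2 * w:
            return [(0, length)]
        return [(0, w), (length - w, length)]

    def genes_on(self, chrom: str) -> list[GeneRegion]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene(self, gene_id: str) -> GeneRegion:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# segment file I/O

_SEG_COLUMNS = {
    "sample": ("sample", "sample_id", "id", "samplename"),
    "chrom": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc.start", "start_position"),
    "end": ("end", "loc.end", "end_position"),
    "n_markers": ("num_probes", "num.mark", "num_mark", "n_probes", "probes"),
    "log2": ("segment_mean", "seg.mean", "log2", "mean", "median", "segmean"),
}

_HMMCOPY_COLUMNS = {
    "chrom": ("chr", "chrom", "chromosome"),
    "start": ("start",),
    "end": ("end",),
    "state": ("state",),
    "log2": ("median", "log2", "copy"),
}


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _resolve_columns(
    header: Sequence[str],
    wanted: Mapping[str, tuple[str, ...]],
    required: Iterable[str],
    column_map: Mapping[str, str] | None,
    path: object,
) -> dict[str, int]:
    lower = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    column_map = column_map or {}
    for logical, aliases in wanted.items():
        if logical in column_map:
            name = column_map[logical].lower()
            if name not in lower:
                raise ParseError(
                    f"{path}: mapped column {column_map[logical]!r} for "
                    f"{logical!r} not found in header"
                )
            out[logical] = lower.index(name)
            continue
        for alias in aliases:
            if alias in lower:
                out[logical] = lower.index(alias)
                break
    missing = [c for c in required if c not in out]
    if missing:
        raise ParseError(
            f"{path}: header does not match dialect; missing columns for "
            f"{missing} in {list(header)}"
        )
    return out


def _parse_int(token: str, what: str, line: int, path: object) -> int:
    try:
        return int(float(token)) if "." in token or "e" in token.lower() else int(token)
    except ValueError:
        raise ParseError(f"{path}: line {line}: non-numeric {what} {token!r}") from None


def _parse_float(token: str, what: str, line: int, path: object) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}: line {line}: non-numeric {what} {token!r}") from None


def read_segments(
    path: str | Path,
    dialect: str = "seg",
    build: GenomeBuild | None = None,
    sample_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
    resolve_overlaps: bool = False,
) -> Cohort:
    """Read a segmented copy-number file into a :class:`Cohort`.

    Parameters
    ----------
    path:
        Tab-delimited file, optionally gzip-compressed.
    dialect:
        ``"seg"`` / ``"tcga"``: Sample, Chromosome, Start, End,
        [Num_Probes], Segment_Mean; 1-based inclusive coordinates.
        ``"tcga"`` additionally accepts a ``column_map`` so GDC-release
        column-name drift does not require code changes.
        ``"hmmcopy"``: chr, start, end, state, median (one sample per
        file; ``sample_id`` defaults to the file stem).
    build:
        If given, chromosome names and bounds are validated; unknown
        chromosomes raise :class:`ValidationError`.
    resolve_overlaps:
        Overlapping segments within one sample are rejected by default
        (they indicate corrupt input); with ``True`` they are resolved
        by splitting at breakpoints and taking the marker-weighted mean.
    """
    if dialect not in {"seg", "tcga", "hmmcopy"}:
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segment file not found: {path}")
    rows: list[tuple[str, str, int, int, float, int | None]] = []
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: empty file (no header)")
        header = header_line.rstrip("\n").split("\t")
        if dialect == "hmmcopy":
            cols = _resolve_columns(
                header, _HMMCOPY_COLUMNS, ("chrom", "start", "end", "log2"),
                column_map, path,
            )
            default_sample = sample_id or path.name.removesuffix(".gz").rsplit(".", 1)[0]
        else:
            cols = _resolve_columns(
                header, _SEG_COLUMNS, ("sample", "chrom", "start", "end", "log2"),
                column_map, path,
            )
            default_sample = sample_id
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields_ = raw.rstrip("\n").split("\t")
            if len(fields_) < max(cols.values()) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least "
                    f"{max(cols.values()) + 1} columns, got {len(fields_)}"
                )
            sid = fields_[cols["sample"]] if "sample" in cols else default_sample
            chrom = normalize_chrom(fields_[cols["chrom"]])
            start = _parse_int(fields_[cols["start"]], "start", lineno, path)
            end = _parse_int(fields_[cols["end"]], "end", lineno, path)
            if end < start:
                raise ParseError(
                    f"{path}: line {lineno}: end {end} < start {start}"
                )
            log2_token = fields_[cols["log2"]].strip()
            if log2_token == "" or log2_token.upper() in {"NA", "NAN", "NULL"}:
                raise ParseError(
                    f"{path}: line {lineno}: missing log2 value (no imputation)"
                )
            log2 = _parse_float(log2_token, "log2", lineno, path)
            if not math.isfinite(log2):
                raise ParseError(f"{path}: line {lineno}: non-finite log2")
            n_markers: int | None = None
            if "n_markers" in cols and cols["n_markers"] < len(fields_):
                token = fields_[cols["n_markers"]].strip()
                if token and token.upper() not in {"NA", "NAN", ""}:
                    n_markers = _parse_int(token, "marker count", lineno, path)
            istart, iend = to_internal(start, end, dialect)
            if istart < 0:
                raise ParseError(f"{path}: line {lineno}: start < 1")
            rows.append((str(sid), chrom, istart, iend, log2, n_markers))

    by_sample: dict[str, list[tuple]] = {}
    for row in rows:
        by_sample.setdefault(row[0], []).append(row)
    profiles = []
    for sid, sample_rows in by_sample.items():
        segs = [
            Segment(sid, chrom, s, e, log2, nm)
            for _, chrom, s, e, log2, nm in sample_rows
        ]
        if resolve_overlaps:
            segs = _resolve_overlapping(sid, segs)
        profiles.append(SampleProfile(sid, segs))
    return Cohort(profiles, build=build)


def _resolve_overlapping(sample_id: str, segs: list[Segment]) -> list[Segment]:
    """Split overlapping segments at breakpoints; value per piece is the
    marker-weighted mean of covering segments (length-weighted when marker
    counts are absent)."""
    out: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_segs in by_chrom.items():
        bps = sorted({s.start for s in chrom_segs} | {s.end for s in chrom_segs})
        for lo, hi in zip(bps, bps[1:]):
            covering = [s for s in chrom_segs if s.start <= lo and hi <= s.end]
            if not covering:
                continue
            weights = np.array(
                [s.n_markers if s.n_markers is not None else s.length
                 for s in covering],
                dtype=float,
            )
            value = float(
                np.average([s.log2 for s in covering], weights=weights)
            )
            out.append(Segment(sample_id, chrom, lo, hi, value))
    return out


def write_segments(cohort: Cohort, path: str | Path, dialect: str = "seg") -> None:
    """Write a cohort as a tab-delimited SEG file (1-based inclusive).

    ``read_segments`` inverts the output exactly (log2 values are written
    with round-trip float precision)."""
    if dialect != "seg":
        raise ValueError(f"write_segments supports the 'seg' dialect, got {dialect!r}")
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for profile in cohort.profiles:
            for seg in profile.segments:
                start, end = from_internal(seg.start, seg.end, dialect)
                markers = "" if seg.n_markers is None else str(seg.n_markers)
                fh.write(
                    f"{seg.sample_id}\t{seg.chrom}\t{start}\t{end}\t"
                    f"{markers}\t{seg.log2!r}\n"
                )


# ---------------------------------------------------------------------------
# annotation I/O


def _read_tsv(path: str | Path, n_min_cols: int, what: str) -> list[list[str]]:
    out = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields_ = re.split(r"\t", line)
            if len(fields_) < n_min_cols:
                raise ParseError(
                    f"{path}: line {lineno}: {what} needs >= {n_min_cols} columns"
                )
            out.append(fields_)
    return out


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column chromosome-length table (chrom<TAB>length)."""
    lengths: dict[str, int] = {}
    for fields_ in _read_tsv(path, 2, "chromosome lengths"):
        if fields_[1].strip().lower() in {"length", "size"}:
            continue  # tolerant of a header row
        lengths[normalize_chrom(fields_[0])] = int(fields_[1])
    return lengths


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """BED-like 3+ column interval list (0-based half-open)."""
    return [
        (normalize_chrom(f[0]), int(f[1]), int(f[2]))
        for f in _read_tsv(path, 3, "interval")
    ]


def read_gene_bed(path: str | Path) -> list[GeneRegion]:
    """BED-like 4+ column gene file: chrom, start, end, gene_id."""
    return [
        GeneRegion(f[3], normalize_chrom(f[0]), int(f[1]), int(f[2]))
        for f in _read_tsv(path, 4, "gene")
    ]


def read_expression(path: str | Path) -> dict[str, float]:
    """Two-column gene_id<TAB>expression table.  Genes absent from the
    table simply have no expression value (never imputed to zero)."""
    expr: dict[str, float] = {}
    for f in _read_tsv(path, 2, "expression"):
        try:
            expr[f[0]] = float(f[1])
        except ValueError:
            continue  # header row
    return expr


def load_annotation(
    chrom_lengths_path: str | Path,
    genes_path: str | Path | None = None,
    centromere_path: str | Path | None = None,
    fragile_path: str | Path | None = None,
    stable_path: str | Path | None = None,
    expression_path: str | Path | None = None,
    telomere_window_bp: int = 2_000_000,
    build_name: str = "custom",
) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from plain-text track files.

    Centromeres are read as BED-like intervals, one per chromosome.
    All tracks are validated against the chromosome lengths.
    """
    build = GenomeBuild(build_name, read_chrom_lengths(chrom_lengths_path))
    genes = read_gene_bed(genes_path) if genes_path else []
    centromeres: dict[str, tuple[int, int]] = {}
    if centromere_path:
        for chrom, start, end in read_bed_intervals(centromere_path):
            if chrom in centromeres:
                old = centromeres[chrom]
                centromeres[chrom] = (min(old[0], start), max(old[1], end))
            else:
                centromeres[chrom] = (start, end)
    fragile = read_bed_intervals(fragile_path) if fragile_path else []
    stable = read_bed_intervals(stable_path) if stable_path else []
    expression = read_expression(expression_path) if expression_path else None
    return GenomeAnnotation(
        build=build,
        genes=genes,
        centromeres=centromeres,
        fragile_sites=fragile,
        stable_sites=stable,
        telomere_window_bp=telomere_window_bp,
        expression=expression,
    )
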
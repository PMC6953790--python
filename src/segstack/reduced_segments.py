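"""Cross-sample reduced-segment matrix and differential CNA calling.

The reduced-segment tiling is the union of all samples' segment
breakpoints: every sample then has exactly one log2 value (or a missing
marker) per tile, which makes profiles directly comparable across
samples.  Differential calls are deviations from a control-mean
baseline of at least a fixed magnitude (0.2 log2 units by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from segstack.genome_model import (
    Cohort,
    SampleProfile,
    Segment,
    SegstackError,
    ValidationError,
    chrom_sort_key,
)

FOCAL_MAX_BP = 100_000
LARGE_MIN_BP = 1_000_000


def size_class(length_bp: int) -> str:
    """Event size class: focal (< 100 kb), large (> 1 Mb), else intermediate."""
    if length_bp < FOCAL_MAX_BP:
        return "focal"
    if length_bp > LARGE_MIN_BP:
        return "large"
    return "intermediate"


@dataclass
class ReducedMatrix:
    """Samples x reduced-segments table of log2 values.

    ``values`` has one row per sample and one column per reduced
    segment (NaN where the sample has no covering segment);
    ``segment_index`` maps column position -> (chrom, start, end).
    """

    boundaries: dict[str, np.ndarray]
    values: pd.DataFrame
    segment_index: list[tuple[str, int, int]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_segments(self) -> int:
        return len(self.segment_index)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.segment_index], dtype=np.int64)

    def tiles_on(self, chrom: str) -> list[int]:
        return [i for i, (c, _, _) in enumerate(self.segment_index) if c == chrom]

    def to_cohort(self) -> Cohort:
        """Re-express the matrix as a segment cohort (tiles with values)."""
        profiles = []
        for sid in self.sample_ids:
            row = self.values.loc[sid].to_numpy()
            segs = [
                Segment(sid, c, s, e, float(v))
                for (c, s, e), v in zip(self.segment_index, row)
                if math.isfinite(v)
            ]
            profiles.append(SampleProfile(sid, segs))
        return Cohort(profiles)


def reduce(cohort: Cohort) -> ReducedMatrix:
    """Build the reduced-segment matrix of a cohort.

    Per chromosome, breakpoints are the union over samples of all
    segment starts and ends; tiles between consecutive breakpoints are
    kept when covered by at least one sample.  Because tile boundaries
    include every original breakpoint, a tile lies entirely inside or
    entirely outside any original segment, so each sample contributes
    at most one (unique) value per tile.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot reduce an empty cohort")
    chroms = sorted(
        {s.chrom for p in cohort for s in p.segments}, key=chrom_sort_key
    )
    sample_ids = cohort.sample_ids
    segment_index: list[tuple[str, int, int]] = []
    boundaries: dict[str, np.ndarray] = {}
    columns: list[np.ndarray] = []
    for chrom in chroms:
        per_sample = {p.sample_id: p.segments_on(chrom) for p in cohort}
        bps = sorted(
            {s.start for segs in per_sample.values() for s in segs}
            | {s.end for segs in per_sample.values() for s in segs}
        )
        boundaries[chrom] = np.array(bps, dtype=np.int64)
        starts = {
            sid: np.array([s.start for s in segs], dtype=np.int64)
            for sid, segs in per_sample.items()
        }
        for lo, hi in zip(bps, bps[1:]):
            col = np.full(len(sample_ids), np.nan)
            covered = False
            for row_i, sid in enumerate(sample_ids):
                segs = per_sample[sid]
                if not segs:
                    continue
                j = int(np.searchsorted(starts[sid], lo, side="right")) - 1
                if j >= 0 and segs[j].end >= hi:
                    col[row_i] = segs[j].log2
                    covered = True
            if covered:
                segment_index.append((chrom, lo, hi))
                columns.append(col)
    values = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0)),
        index=sample_ids,
    )
    return ReducedMatrix(boundaries=boundaries, values=values, segment_index=segment_index)


def baseline(matrix: ReducedMatrix, control_ids: Sequence[str]) -> pd.Series:
    """Unweighted per-tile mean over the control samples.

    A tile missing in any control is missing in the baseline (no
    silent imputation)."""
    if len(control_ids) == 0:
        raise ValidationError("empty control set")
    missing = [c for c in control_ids if c not in matrix.values.index]
    if missing:
        raise ValidationError(f"control ids not in matrix: {missing}")
    return matrix.values.loc[list(control_ids)].mean(axis=0, skipna=False)


@dataclass
class CnaCall:
    """One differential CNA event of one sample.

    ``delta`` is the (length-weighted mean) log2 deviation from
    baseline; ``tiles`` records the constituent reduced-segment column
    indices so sharedness can be evaluated on the common segment frame.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    delta: float
    direction: str
    size_class: str = ""
    tiles: tuple[int, ...] = ()
    shared: bool | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValidationError(f"direction {self.direction!r}")
        if (self.direction == "gain") != (self.delta > 0):
            raise ValidationError("direction sign must match delta sign")
        if not self.size_class:
            self.size_class = size_class(self.end - self.start)

    @property
    def length(self) -> int:
        return self.end - self.start


def call_differential(
    matrix: ReducedMatrix,
    baseline_values: pd.Series,
    threshold: float = 0.2,
    merge: bool = True,
) -> list[CnaCall]:
    """Call per-sample CNAs where |value - baseline| >= threshold.

    With ``merge`` on (default), adjacent called tiles of one sample
    with the same direction and no coordinate gap merge into one call;
    missing tiles always break merges.  Size classes are assigned from
    the merged span.
    """
    if not threshold > 0:
        raise ValidationError("threshold must be > 0")
    base = baseline_values.to_numpy(dtype=float)
    calls: list[CnaCall] = []
    for sid in matrix.sample_ids:
        row = matrix.values.loc[sid].to_numpy(dtype=float)
        delta = row - base
        called = np.isfinite(delta) & (np.abs(delta) >= threshold)
        run: list[int] = []

        def flush(run_tiles: list[int]) -> None:
            if not run_tiles:
                return
            chrom, start, _ = matrix.segment_index[run_tiles[0]]
            end = matrix.segment_index[run_tiles[-1]][2]
            lengths = np.array(
                [matrix.segment_index[t][2] - matrix.segment_index[t][1] for t in run_tiles],
                dtype=float,
            )
            d = float(np.average(delta[run_tiles], weights=lengths))
            calls.append(
                CnaCall(
                    sample_id=sid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    delta=d,
                    direction="gain" if d > 0 else "loss",
                    tiles=tuple(run_tiles),
                )
            )

        for i in range(matrix.n_segments):
            if not called[i]:
                flush(run)
                run = []
                continue
            if not merge:
                flush([i])
                continue
            if run:
                p_chrom, _, p_end = matrix.segment_index[run[-1]]
                chrom, start, _ = matrix.segment_index[i]
                contiguous = chrom == p_chrom and start == p_end
                same_dir = (delta[i] > 0) == (delta[run[-1]] > 0)
                if not (contiguous and same_dir):
                    flush(run)
                    run = []
            run.append(i)
        flush(run)
    return calls


def count_events_per_chromosome(
    profile: SampleProfile,
    threshold: float = 0.2,
    chroms: Iterable[str] | None = None,
) -> dict[str, int]:
    """Count discrete CNA events per chromosome in a (windowed or
    segmented) profile already normalized against a matched reference.

    Consecutive coordinate-contiguous windows/segments exceeding the
    threshold in the same direction merge into one event.  ``chroms``
    extends the result with explicit zeros for unaltered chromosomes
    (defaults to the chromosomes present in the profile).
    """
    if not threshold > 0:
        raise ValidationError("threshold must be > 0")
    counts: dict[str, int] = {}
    if chroms is not None:
        counts = {c: 0 for c in chroms}
    for chrom in profile.chroms:
        counts.setdefault(chrom, 0)
        prev: Segment | None = None
        for seg in profile.segments_on(chrom):
            qualifying = abs(seg.log2) >= threshold
            if qualifying:
                extends = (
                    prev is not None
                    and prev.end == seg.start
                    and (prev.log2 > 0) == (seg.log2 > 0)
                )
                if not extends:
                    counts[chrom] += 1
                prev = seg
            else:
                prev = None
    return counts


# ---------------------------------------------------------------------------
# call-table I/O (plain TSV; consumed by the breakpoint module and CLI)

_CALL_COLUMNS = [
    "sample", "chrom", "start", "end", "delta", "direction", "size_class", "shared",
]


def write_calls(calls: Sequence[CnaCall], path: str | Path) -> None:
    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "delta": repr(c.delta),
            "direction": c.direction,
            "size_class": c.size_class,
            "shared": "" if c.shared is None else str(c.shared),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[CnaCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    calls = []
    for _, r in df.iterrows():
        shared = None
        if "shared" in df.columns and isinstance(r.get("shared"), str):
            shared = r["shared"] == "True"
        elif "shared" in df.columns and r.get("shared") in (True, False):
            shared = bool(r["shared"])
        calls.append(
            CnaCall(
                sample_id=str(r["sample"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                delta=float(r["delta"]),
                direction=str(r["direction"]),
                size_class=str(r.get("size_class", "")) or size_class(int(r["end"]) - int(r["start"])),
                shared=shared,
            )
        )
    return calls
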
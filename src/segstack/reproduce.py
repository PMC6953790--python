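"""Real-data reproduction pipelines.

These helpers run the package's operations against externally obtained
datasets (TCGA PanCanAtlas segment tables and the study's supplementary
segment tables), none of which ship with the package.  They are used by
``scripts/acceptance.py`` and the corresponding acceptance tests when
the files are present under ``data/external/``.

Expected files
--------------
``data/external/tcga_ov.seg``
    Tab-delimited PanCanAtlas-dialect segment rows (Sample, Chromosome,
    Start, End, Num_Probes, Segment_Mean) restricted to the ovarian
    (OV) cohort, hg19 coordinates.
``data/external/mouse_tumors.seg`` + ``data/external/mouse_groups.tsv``
    SEG-format per-segment log2(tumor/normal) values for the eight
    murine tumors, and a sample<TAB>group table (groups ``BTAg`` and
    ``TAg``).
``data/external/skov3_reduced.tsv``
    Wide reduced-segment matrix: columns chrom, start, end then one
    column per SKOV3 isolate, values = log2 difference from the shScr
    mean.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from segstack.cairn_query import RegionQuery, cohort_summary
from segstack.drift_stats import unique_shared
from segstack.genome_model import GeneRegion, normalize_chrom, read_segments
from segstack.reduced_segments import (
    CnaCall,
    ReducedMatrix,
    count_events_per_chromosome,
)

# Gene spans (first exon start to last exon end), 1-based inclusive as
# printed by the UCSC browser, converted to internal 0-based half-open.
GENE_COORDS = {
    "hg19": {
        "BECN1": GeneRegion("BECN1", "17", 40_962_146 - 1, 40_976_312),
        "BRCA1": GeneRegion("BRCA1", "17", 41_196_312 - 1, 41_277_500),
    },
    "hg38": {
        "BECN1": GeneRegion("BECN1", "17", 42_810_132 - 1, 42_824_278),
        "BRCA1": GeneRegion("BRCA1", "17", 43_044_295 - 1, 43_125_483),
    },
}

# Declared calibration grid for the loss threshold used on PanCanAtlas
# segment means (the published counts' exact threshold is not printed).
THRESHOLD_GRID = (-0.1, -0.15, -0.2, -0.25, -0.3)

MOUSE_CHROMS = tuple(str(i) for i in range(1, 20)) + ("X",)


def coalteration_counts(
    seg_path: str | Path,
    build_name: str = "hg19",
    thresholds: Sequence[float] = THRESHOLD_GRID,
) -> dict[float, dict[str, int]]:
    """Exclusive/coincident deletion counts for BECN1 vs BRCA1 over a
    cohort segment file, at every threshold of the calibration grid."""
    cohort = read_segments(seg_path, dialect="tcga")
    genes = GENE_COORDS[build_name]
    out: dict[float, dict[str, int]] = {}
    for t in thresholds:
        query = RegionQuery(
            region_a=genes["BECN1"],
            region_b=genes["BRCA1"],
            direction="loss",
            loss_threshold=t,
        )
        summary = cohort_summary(cohort, query)
        out[t] = dict(summary.counts, total=len(cohort))
    return out


def mouse_events_per_chromosome(
    seg_path: str | Path,
    groups_path: str | Path,
    threshold: float = 0.2,
    chroms: Sequence[str] = MOUSE_CHROMS,
) -> dict[str, float]:
    """Mean merged CNA events per chromosome, per group, at |log2| >= 0.2."""
    cohort = read_segments(seg_path, dialect="seg")
    groups: dict[str, list[str]] = {}
    for line in Path(groups_path).read_text().splitlines():
        if not line.strip() or line.startswith("sample\t"):
            continue
        sid, group = line.split("\t")[:2]
        groups.setdefault(group, []).append(sid)
    means: dict[str, float] = {}
    for group, ids in groups.items():
        per_chrom: list[int] = []
        for sid in ids:
            counts = count_events_per_chromosome(
                cohort.get(sid), threshold=threshold, chroms=chroms
            )
            per_chrom.extend(counts[c] for c in chroms)
        means[group] = float(np.mean(per_chrom))
    return means


def _matrix_from_wide_table(path: str | Path) -> ReducedMatrix:
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip() for c in df.columns]
    coord_cols = [c for c in df.columns if c.lower() in ("chrom", "chromosome", "chr", "start", "end")]
    sample_cols = [c for c in df.columns if c not in coord_cols]
    chrom_col = next(c for c in coord_cols if c.lower() in ("chrom", "chromosome", "chr"))
    start_col = next(c for c in coord_cols if c.lower() == "start")
    end_col = next(c for c in coord_cols if c.lower() == "end")
    segment_index = [
        (normalize_chrom(r[chrom_col]), int(r[start_col]), int(r[end_col]))
        for _, r in df.iterrows()
    ]
    values = pd.DataFrame(
        df[sample_cols].to_numpy(dtype=float).T, index=sample_cols
    )
    boundaries: dict[str, np.ndarray] = {}
    for chrom in {c for c, _, _ in segment_index}:
        bps = sorted(
            {s for c, s, _ in segment_index if c == chrom}
            | {e for c, _, e in segment_index if c == chrom}
        )
        boundaries[chrom] = np.array(bps, dtype=np.int64)
    return ReducedMatrix(boundaries=boundaries, values=values, segment_index=segment_index)


def unique_shared_ratios(
    matrix_path: str | Path,
    groups: Mapping[str, Sequence[str]],
    threshold: float = 0.2,
    scope: str = "within-group",
) -> dict[str, float]:
    """Unique/shared call ratio per group from a wide reduced-segment
    matrix of log2 differences from the control mean (baseline 0)."""
    matrix = _matrix_from_wide_table(matrix_path)
    calls: list[CnaCall] = []
    for sid in matrix.sample_ids:
        row = matrix.values.loc[sid].to_numpy(dtype=float)
        for i, v in enumerate(row):
            if np.isfinite(v) and abs(v) >= threshold:
                chrom, start, end = matrix.segment_index[i]
                calls.append(
                    CnaCall(
                        sample_id=sid, chrom=chrom, start=start, end=end,
                        delta=float(v), direction="gain" if v > 0 else "loss",
                        tiles=(i,),
                    )
                )
    ratios: dict[str, float] = {}
    if scope == "cohort":
        all_ids = [sid for ids in groups.values() for sid in ids]
        pooled = unique_shared(calls, all_ids)
        for group, ids in groups.items():
            members = [c for c in pooled.calls if c.sample_id in set(ids)]
            shared = sum(1 for c in members if c.shared)
            uniq = len(members) - shared
            ratios[group] = float("nan") if shared == 0 else uniq / shared
    else:
        for group, ids in groups.items():
            result = unique_shared(calls, ids)
            ratios[group] = result.ratio
    return ratios
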
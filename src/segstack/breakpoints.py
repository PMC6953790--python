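"""Breakpoint feature classification and the iso-chromosomal
permutation null.

Every CNA call contributes two edges (its start and end breakpoints).
Edges are flagged -- non-exclusively -- as telomeric (within the
telomere window of a chromosome end), centromeric (within the
centromere interval expanded by the same window on both flanks),
intragenic (inside a gene span), fragile or stable (inside the
corresponding site tracks).  The null model relocates each call to a
uniform random position on its own chromosome, preserving its exact
length, and re-classifies the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from segstack.genome_model import GenomeAnnotation, SegstackError, ValidationError
from segstack.reduced_segments import CnaCall

CATEGORIES = ("telomeric", "centromeric", "intragenic", "fragile", "stable")


@dataclass
class EdgeClassification:
    call: CnaCall
    which: str  # "start" or "end"
    position: int
    telomeric: bool = False
    centromeric: bool = False
    intragenic: bool = False
    fragile: bool = False
    stable: bool = False
    genes_hit: tuple[str, ...] = ()

    def flags(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in CATEGORIES}


class _ChromTracks:
    """Per-chromosome numpy interval arrays for fast point classification."""

    __slots__ = (
        "length", "telomeric", "centromeric", "gene_starts", "gene_ends",
        "gene_ids", "gene_lengths", "fragile", "stable",
    )

    def __init__(self, ann: GenomeAnnotation, chrom: str) -> None:
        self.length = ann.build.chrom_lengths[chrom]
        self.telomeric = np.array(ann.telomere_windows(chrom), dtype=np.int64)
        w = ann.telomere_window_bp
        if chrom in ann.centromeres:
            cs, ce = ann.centromeres[chrom]
            self.centromeric = np.array(
                [[max(cs - w, 0), min(ce + w, self.length)]], dtype=np.int64
            )
        else:
            self.centromeric = np.empty((0, 2), dtype=np.int64)
        genes = ann.genes_on(chrom)
        self.gene_starts = np.array([g.start for g in genes], dtype=np.int64)
        self.gene_ends = np.array([g.end for g in genes], dtype=np.int64)
        self.gene_ids = [g.gene_id for g in genes]
        self.gene_lengths = self.gene_ends - self.gene_starts
        self.fragile = np.array(
            [[s, e] for c, s, e in ann.fragile_sites if c == chrom], dtype=np.int64
        ).reshape(-1, 2)
        self.stable = np.array(
            [[s, e] for c, s, e in ann.stable_sites if c == chrom], dtype=np.int64
        ).reshape(-1, 2)

    def in_track(self, positions: np.ndarray, track: np.ndarray) -> np.ndarray:
        """Membership of each position in any [start, end) of *track*."""
        if track.size == 0:
            return np.zeros(len(positions), dtype=bool)
        pos = positions[:, None]
        return ((pos >= track[None, :, 0]) & (pos < track[None, :, 1])).any(axis=1)

    def gene_hits(self, position: int) -> list[int]:
        if self.gene_starts.size == 0:
            return []
        mask = (self.gene_starts <= position) & (position < self.gene_ends)
        return list(np.nonzero(mask)[0])


def _tracks_for(ann: GenomeAnnotation) -> dict[str, _ChromTracks]:
    cache = getattr(ann, "_segstack_tracks", None)
    if cache is None:
        cache = {c: _ChromTracks(ann, c) for c in ann.build.chroms}
        ann._segstack_tracks = cache  # annotation objects are mutable dataclasses
    return cache


def classify_points(
    chrom: str, positions: np.ndarray, ann: GenomeAnnotation
) -> dict[str, np.ndarray]:
    """Vectorized flag arrays for many edge positions on one chromosome."""
    tr = _tracks_for(ann)[chrom]
    intragenic = (
        np.zeros(len(positions), dtype=bool)
        if tr.gene_starts.size == 0
        else (
            (positions[:, None] >= tr.gene_starts[None, :])
            & (positions[:, None] < tr.gene_ends[None, :])
        ).any(axis=1)
    )
    return {
        "telomeric": tr.in_track(positions, tr.telomeric),
        "centromeric": tr.in_track(positions, tr.centromeric),
        "intragenic": intragenic,
        "fragile": tr.in_track(positions, tr.fragile),
        "stable": tr.in_track(positions, tr.stable),
    }


def classify_edges(
    calls: Sequence[CnaCall], annotation: GenomeAnnotation
) -> list[EdgeClassification]:
    """Classify both edges of every call independently against all tracks."""
    tracks = _tracks_for(annotation)
    out: list[EdgeClassification] = []
    for call in calls:
        if call.chrom not in annotation.build:
            raise ValidationError(
                f"call chromosome {call.chrom!r} absent from annotation build "
                f"{annotation.build.name!r}"
            )
        tr = tracks[call.chrom]
        for which, pos in (("start", call.start), ("end", call.end)):
            flags = classify_points(call.chrom, np.array([pos]), annotation)
            hits = tr.gene_hits(pos)
            out.append(
                EdgeClassification(
                    call=call,
                    which=which,
                    position=pos,
                    telomeric=bool(flags["telomeric"][0]),
                    centromeric=bool(flags["centromeric"][0]),
                    intragenic=bool(flags["intragenic"][0]),
                    fragile=bool(flags["fragile"][0]),
                    stable=bool(flags["stable"][0]),
                    genes_hit=tuple(tr.gene_ids[i] for i in hits),
                )
            )
    return out


def category_counts(classifications: Sequence[EdgeClassification]) -> dict[str, int]:
    """Number of edges carrying each flag (an edge can count in several)."""
    return {
        c: sum(1 for e in classifications if getattr(e, c)) for c in CATEGORIES
    }


def genes_at_edges(
    classifications: Sequence[EdgeClassification],
    annotation: GenomeAnnotation,
) -> tuple[list[int], list[float]]:
    """Lengths (bp) and, where available, expression of genes overlapped
    by intragenic edges; multi-gene hits emit every gene."""
    gene_by_id = {g.gene_id: g for g in annotation.genes}
    sizes: list[int] = []
    expressions: list[float] = []
    expr = annotation.expression or {}
    for edge in classifications:
        for gid in edge.genes_hit:
            sizes.append(gene_by_id[gid].length)
            if gid in expr:
                expressions.append(expr[gid])
    return sizes, expressions


@dataclass
class PermutationNull:
    """Per-permutation edge-category counts and overlapped-gene summaries
    from iso-chromosomal random relocation of the observed calls."""

    n_permutations: int
    seed: int
    category_counts: pd.DataFrame  # n_permutations x categories
    gene_sizes: list[np.ndarray]
    expressions: list[np.ndarray]
    n_calls: int
    starts: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int64))
    call_lengths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    call_chroms: tuple[str, ...] = ()


def permute_isochromosomal(
    calls: Sequence[CnaCall],
    annotation: GenomeAnnotation,
    n: int = 1000,
    seed: int = 0,
    permute_edges_independently: bool = False,
) -> PermutationNull:
    """Iso-chromosomal permutation null for the observed calls.

    Each permutation relocates every call to a uniform random start in
    [0, chrom_length - call_length] on its own chromosome (whole-segment
    moves by default; ``permute_edges_independently`` relocates each
    edge on its own instead).  Edges are re-classified per permutation
    and per-category counts plus overlapped gene size / expression lists
    are recorded.  Fully reproducible for a fixed seed.
    """
    tracks = _tracks_for(annotation)
    lengths = []
    for call in calls:
        if call.chrom not in annotation.build:
            raise ValidationError(f"call chromosome {call.chrom!r} not in build")
        chrom_len = annotation.build.chrom_lengths[call.chrom]
        if call.length > chrom_len:
            raise ValidationError(
                f"call {call.sample_id} {call.chrom}:{call.start}-{call.end} "
                f"is longer than its chromosome ({chrom_len} bp)"
            )
        lengths.append(call.length)
    rng = np.random.default_rng(seed)
    n_calls = len(calls)
    # draw all starts call-by-call so adding permutations extends, not
    # reshuffles, the stream
    starts = np.empty((n, n_calls), dtype=np.int64)
    for j, call in enumerate(calls):
        chrom_len = annotation.build.chrom_lengths[call.chrom]
        high = chrom_len - call.length
        starts[:, j] = rng.integers(0, high, size=n, endpoint=True)
    if permute_edges_independently:
        edge_starts = np.empty((n, n_calls), dtype=np.int64)
        for j, call in enumerate(calls):
            chrom_len = annotation.build.chrom_lengths[call.chrom]
            edge_starts[:, j] = rng.integers(0, chrom_len, size=n, endpoint=False)

    gene_by_id = {g.gene_id: g for g in annotation.genes}
    expr = annotation.expression or {}
    chrom_of = np.array([c.chrom for c in calls])
    counts = np.zeros((n, len(CATEGORIES)), dtype=np.int64)
    gene_sizes: list[np.ndarray] = []
    expressions: list[np.ndarray] = []
    for p in range(n):
        s = starts[p]
        if permute_edges_independently:
            edge_pos = np.concatenate([edge_starts[p], s + np.array(lengths)])
        else:
            edge_pos = np.concatenate([s, s + np.array(lengths)])
        edge_chrom = np.concatenate([chrom_of, chrom_of])
        perm_sizes: list[int] = []
        perm_expr: list[float] = []
        for chrom in np.unique(edge_chrom):
            mask = edge_chrom == chrom
            pos = edge_pos[mask]
            flags = classify_points(chrom, pos, annotation)
            for k, cat in enumerate(CATEGORIES):
                counts[p, k] += int(flags[cat].sum())
            tr = tracks[chrom]
            if tr.gene_starts.size:
                hit = (pos[:, None] >= tr.gene_starts[None, :]) & (
                    pos[:, None] < tr.gene_ends[None, :]
                )
                for gi in np.nonzero(hit.any(axis=0))[0]:
                    n_hits = int(hit[:, gi].sum())
                    perm_sizes.extend([int(tr.gene_lengths[gi])] * n_hits)
                    gid = tr.gene_ids[gi]
                    if gid in expr:
                        perm_expr.extend([expr[gid]] * n_hits)
        gene_sizes.append(np.array(perm_sizes, dtype=np.int64))
        expressions.append(np.array(perm_expr, dtype=float))
    return PermutationNull(
        n_permutations=n,
        seed=seed,
        category_counts=pd.DataFrame(counts, columns=list(CATEGORIES)),
        gene_sizes=gene_sizes,
        expressions=expressions,
        n_calls=n_calls,
        starts=starts,
        call_lengths=np.array(lengths, dtype=np.int64),
        call_chroms=tuple(c.chrom for c in calls),
    )


def enrichment(
    observed: Sequence[EdgeClassification],
    null: PermutationNull,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Empirical per-category enrichment against the permutation null.

    p = (1 + #{permutations with null count >= observed}) / (n + 1)
    for the enrichment direction; ``alternative="two-sided"`` doubles
    the smaller tail (capped at 1).  Also reports per-Mb rates using the
    genome-wide extent of each category track.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    obs = category_counts(observed)
    n = null.n_permutations
    rows = []
    for cat in CATEGORIES:
        null_counts = null.category_counts[cat].to_numpy()
        o = obs[cat]
        p_greater = (1 + int((null_counts >= o).sum())) / (n + 1)
        p_less = (1 + int((null_counts <= o).sum())) / (n + 1)
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2 * min(p_greater, p_less))
        rows.append(
            {
                "category": cat,
                "observed": o,
                "null_mean": float(null_counts.mean()),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def track_extent_bp(annotation: GenomeAnnotation) -> dict[str, int]:
    """Genome-wide bp covered by each category track (for per-Mb rates)."""
    tracks = _tracks_for(annotation)
    out = {c: 0 for c in CATEGORIES}
    for chrom in annotation.build.chroms:
        tr = tracks[chrom]
        out["telomeric"] += int((tr.telomeric[:, 1] - tr.telomeric[:, 0]).sum())
        if tr.centromeric.size:
            out["centromeric"] += int(
                (tr.centromeric[:, 1] - tr.centromeric[:, 0]).sum()
            )
        out["fragile"] += int((tr.fragile[:, 1] - tr.fragile[:, 0]).sum()) if tr.fragile.size else 0
        out["stable"] += int((tr.stable[:, 1] - tr.stable[:, 0]).sum()) if tr.stable.size else 0
        if tr.gene_starts.size:
            # merged genic extent (genes may overlap)
            order = np.argsort(tr.gene_starts)
            covered = 0
            cur_s = cur_e = None
            for i in order:
                s, e = int(tr.gene_starts[i]), int(tr.gene_ends[i])
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                covered += cur_e - cur_s
            out["intragenic"] += covered
    return out
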
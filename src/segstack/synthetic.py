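"""Ground-truthed synthetic cohort generators.

Every generator is deterministic for a fixed seed, and each sample's
random stream is derived from (seed, sample_id) so adding a sample
never perturbs the others' data.  At zero noise every planted event is
exactly recoverable by the corresponding analysis stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from segstack.genome_model import (
    Cohort,
    GenomeAnnotation,
    GenomeBuild,
    SampleProfile,
    Segment,
    ValidationError,
    chrom_sort_key,
)
from segstack.reduced_segments import CnaCall

DEFAULT_GENOME = {"1": 100_000_000, "2": 80_000_000, "3": 60_000_000}


def _rng(seed: int, *keys: object) -> np.random.Generator:
    """Independent generator keyed on (seed, *keys)."""
    entropy = [int(seed) & 0xFFFFFFFF]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            entropy.append(int(key) & 0xFFFFFFFF)
        else:
            digest = hashlib.sha256(str(key).encode()).digest()
            entropy.append(int.from_bytes(digest[:4], "little"))
    return np.random.default_rng(entropy)


@dataclass
class SimConfig:
    """Shared knobs for all generators; unused fields are ignored by
    generators that do not need them."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    seed: int = 0
    noise_sd: float = 0.0

    # --- co-alteration cohorts
    region_a: tuple[str, int, int] = ("1", 30_000_000, 30_100_000)
    region_b: tuple[str, int, int] = ("1", 40_000_000, 40_100_000)
    composition: tuple[int, int, int, int] = (0, 0, 0, 0)
    direction: str = "loss"
    event_amplitude: float = 0.5
    coincident_two_segments: bool = False

    # --- drift experiments
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "groupA": 4, "groupB": 4}
    )
    control_group: str = "control"
    unique_rate: float = 3.0
    shared_rate: float = 1.0
    control_rate: float = 0.0
    event_length_range: tuple[int, int] = (10_000, 10_000_000)
    amplitude_choices: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    n_ancestral: int = 3

    # --- windowed profiles
    events_per_chrom: int = 2
    window_amplitude: float = 0.5

    # --- breakpoint bias
    n_breakpoint_events: int = 60
    bias_track: str = "telomeric"
    bias_weight: float = 1.0

    def __post_init__(self) -> None:
        for rate in (self.unique_rate, self.shared_rate, self.control_rate):
            if rate < 0:
                raise ValidationError("rates must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def build(self, name: str = "sim") -> GenomeBuild:
        return GenomeBuild(name, self.chrom_lengths)


@dataclass(frozen=True)
class PlantedEvent:
    sample_id: str
    chrom: str
    start: int
    end: int
    delta: float
    direction: str
    label: str  # unique | shared | ancestral | planted
    group: str | None = None


@dataclass
class GroundTruth:
    events: list[PlantedEvent] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)
    per_chrom_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def events_of(self, sample_id: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.sample_id == sample_id]


def _profile_from_events(
    sample_id: str,
    build: GenomeBuild,
    events: Sequence[tuple[str, int, int, float]],
    base: Mapping[str, Sequence[tuple[int, int, float]]] | None,
    noise_sd: float,
    rng: np.random.Generator,
) -> SampleProfile:
    """Tile each chromosome at all base/event boundaries; the value of a
    tile is base + sum of deltas of covering events (+ optional jitter)."""
    segs: list[Segment] = []
    for chrom in build.chroms:
        length = build.chrom_lengths[chrom]
        base_pieces = list(base.get(chrom, [(0, length, 0.0)])) if base else [
            (0, length, 0.0)
        ]
        ev = [(s, e, d) for c, s, e, d in events if c == chrom]
        bps = sorted(
            {p for s, e, _ in base_pieces for p in (s, e)}
            | {p for s, e, _ in ev for p in (s, e)}
        )
        base_starts = np.array([s for s, _, _ in base_pieces])
        for lo, hi in zip(bps, bps[1:]):
            j = int(np.searchsorted(base_starts, lo, side="right")) - 1
            if j < 0 or base_pieces[j][1] < hi:
                continue  # outside base coverage
            value = base_pieces[j][2]
            value += sum(d for s, e, d in ev if s <= lo and hi <= e)
            if noise_sd > 0:
                value += float(rng.normal(0.0, noise_sd))
            segs.append(Segment(sample_id, chrom, lo, hi, value))
    return SampleProfile(sample_id, segs)


# ---------------------------------------------------------------------------
# co-alteration cohorts


def _overlapping_interval(
    region: tuple[str, int, int],
    chrom_len: int,
    forbidden: tuple[str, int, int] | None,
    rng: np.random.Generator,
    pad: int = 2_000_000,
) -> tuple[int, int]:
    """A random interval overlapping *region* but not *forbidden*."""
    chrom, r_start, r_end = region
    lo_min = max(0, r_start - pad)
    hi_max = min(chrom_len, r_end + pad)
    if forbidden is not None and forbidden[0] == chrom:
        f_start, f_end = forbidden[1], forbidden[2]
        if f_end <= r_start:
            lo_min = max(lo_min, f_end)
        elif f_start >= r_end:
            hi_max = min(hi_max, f_start)
        else:
            raise ValidationError(
                "query regions overlap; an exclusive alteration is infeasible"
            )
    lo = int(rng.integers(lo_min, r_start, endpoint=True))
    hi = int(rng.integers(r_end, hi_max, endpoint=True))
    if hi <= lo:
        hi = lo + 1
    return lo, hi


def simulate_coalteration_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """A cohort realizing exactly the configured category composition
    (exclusive_a, exclusive_b, coincident, none) over the two query
    regions; alterations are planted at +/- ``event_amplitude``."""
    build = config.build()
    a, b = config.region_a, config.region_b
    for chrom, start, end in (a, b):
        if chrom not in build or end > build.chrom_lengths[chrom] or start >= end:
            raise ValidationError(f"query region {chrom}:{start}-{end} infeasible")
    n_a, n_b, n_co, n_none = config.composition
    sign = -1.0 if config.direction == "loss" else 1.0
    delta = sign * abs(config.event_amplitude)
    truth = GroundTruth()
    profiles = []
    categories = (
        ["exclusive_a"] * n_a
        + ["exclusive_b"] * n_b
        + ["coincident"] * n_co
        + ["none"] * n_none
    )
    for i, category in enumerate(categories):
        sid = f"S{i:03d}"
        rng = _rng(config.seed, "coalt", sid)
        events: list[tuple[str, int, int, float]] = []
        if category == "exclusive_a":
            lo, hi = _overlapping_interval(a, build.chrom_lengths[a[0]], b, rng)
            events.append((a[0], lo, hi, delta))
        elif category == "exclusive_b":
            lo, hi = _overlapping_interval(b, build.chrom_lengths[b[0]], a, rng)
            events.append((b[0], lo, hi, delta))
        elif category == "coincident":
            if a[0] == b[0] and not config.coincident_two_segments:
                first, second = (a, b) if a[1] <= b[1] else (b, a)
                lo = int(rng.integers(max(0, first[1] - 2_000_000), first[1], endpoint=True))
                hi = int(
                    rng.integers(
                        second[2],
                        min(build.chrom_lengths[a[0]], second[2] + 2_000_000),
                        endpoint=True,
                    )
                )
                events.append((a[0], lo, hi, delta))
            else:
                lo_a, hi_a = _overlapping_interval(a, build.chrom_lengths[a[0]], b, rng)
                lo_b, hi_b = _overlapping_interval(b, build.chrom_lengths[b[0]], a, rng)
                events.append((a[0], lo_a, hi_a, delta))
                events.append((b[0], lo_b, hi_b, delta))
        for chrom, lo, hi, d in events:
            truth.events.append(
                PlantedEvent(sid, chrom, lo, hi, d, config.direction, "planted")
            )
        truth.categories[sid] = category
        profiles.append(
            _profile_from_events(
                sid, build, events, None, config.noise_sd, rng
            )
        )
    return Cohort(profiles, build=build), truth


# ---------------------------------------------------------------------------
# drift experiments


def _draw_event(
    rng: np.random.Generator,
    config: SimConfig,
    build: GenomeBuild,
    occupied: list[tuple[str, int, int]],
    max_tries: int = 200,
) -> tuple[str, int, int, float]:
    """One random event disjoint from all *occupied* intervals: chromosome
    proportional to length, log-uniform length, uniform placement,
    amplitude drawn from ``amplitude_choices`` with random sign."""
    chroms = build.chroms
    lengths = np.array([build.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    lo_len, hi_len = config.event_length_range
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        chrom_len = build.chrom_lengths[chrom]
        max_len = min(hi_len, chrom_len // 4)
        length = int(np.exp(rng.uniform(np.log(lo_len), np.log(max(max_len, lo_len + 1)))))
        length = max(lo_len, min(length, max_len))
        start = int(rng.integers(0, chrom_len - length, endpoint=True))
        end = start + length
        clash = any(
            c == chrom and start < e and s < end for c, s, e in occupied
        )
        if not clash:
            magnitude = float(rng.choice(config.amplitude_choices))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            return chrom, start, end, sign * magnitude
    raise ValidationError("could not place a disjoint event; genome too crowded")


def simulate_drift_experiment(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Serial-passage drift cohort: all samples share an ancestral
    profile; non-control samples gain Poisson(unique_rate) private
    events, each non-control group gains Poisson(shared_rate) events
    copied into >= 2 of its samples, controls gain
    Poisson(control_rate) private events.  All planted (non-ancestral)
    events are mutually disjoint, so at zero noise and control_rate 0
    the reduced-segment caller recovers them exactly.
    """
    if config.control_group not in config.group_sizes:
        raise ValidationError(
            f"control group {config.control_group!r} not in group_sizes"
        )
    build = config.build()
    anc_rng = _rng(config.seed, "ancestral")
    occupied: list[tuple[str, int, int]] = []
    ancestral: list[tuple[str, int, int, float]] = []
    for _ in range(config.n_ancestral):
        chrom, start, end, delta = _draw_event(anc_rng, config, build, occupied)
        occupied.append((chrom, start, end))
        ancestral.append((chrom, start, end, delta))
    base: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in build.chroms:
        length = build.chrom_lengths[chrom]
        bps = sorted(
            {0, length}
            | {p for c, s, e, _ in ancestral if c == chrom for p in (s, e)}
        )
        pieces = []
        for lo, hi in zip(bps, bps[1:]):
            value = sum(d for c, s, e, d in ancestral if c == chrom and s <= lo and hi <= e)
            pieces.append((lo, hi, value))
        base[chrom] = pieces

    truth = GroundTruth()
    for c, s, e, d in ancestral:
        truth.events.append(
            PlantedEvent("*", c, s, e, d, "gain" if d > 0 else "loss", "ancestral")
        )
    # planted events from every sample/group share one disjointness registry
    # (ancestral intervals included) so recovery is unambiguous
    sample_events: dict[str, list[tuple[str, int, int, float]]] = {}
    for group, size in config.group_sizes.items():
        ids = [f"{group}_{i + 1}" for i in range(size)]
        truth.groups[group] = ids
        for sid in ids:
            sample_events[sid] = []
        is_control = group == config.control_group
        rate = config.control_rate if is_control else config.unique_rate
        for sid in ids:
            rng = _rng(config.seed, "drift", sid)
            for _ in range(int(rng.poisson(rate))):
                chrom, start, end, delta = _draw_event(rng, config, build, occupied)
                occupied.append((chrom, start, end))
                sample_events[sid].append((chrom, start, end, delta))
                truth.events.append(
                    PlantedEvent(
                        sid, chrom, start, end, delta,
                        "gain" if delta > 0 else "loss", "unique", group,
                    )
                )
        if not is_control and size >= 2:
            grng = _rng(config.seed, "drift-shared", group)
            for _ in range(int(grng.poisson(config.shared_rate))):
                chrom, start, end, delta = _draw_event(grng, config, build, occupied)
                occupied.append((chrom, start, end))
                n_copies = int(grng.integers(2, size, endpoint=True))
                members = [ids[k] for k in grng.choice(size, n_copies, replace=False)]
                for sid in sorted(members):
                    sample_events[sid].append((chrom, start, end, delta))
                    truth.events.append(
                        PlantedEvent(
                            sid, chrom, start, end, delta,
                            "gain" if delta > 0 else "loss", "shared", group,
                        )
                    )
    profiles = []
    for group, ids in truth.groups.items():
        for sid in ids:
            noise_rng = _rng(config.seed, "drift-noise", sid)
            profile = _profile_from_events(
                sid, build, sample_events[sid], base, config.noise_sd, noise_rng
            )
            profile.group = group
            profiles.append(profile)
    return Cohort(profiles, build=build), truth


# ---------------------------------------------------------------------------
# windowed tumor/normal profiles


def simulate_windowed_profile(
    config: SimConfig, window_bp: int = 500_000
) -> tuple[SampleProfile, SampleProfile, GroundTruth]:
    """Windowed tumor/normal log2 profile with ``events_per_chrom``
    planted events per chromosome (magnitude ``window_amplitude``,
    runs of 1-3 windows separated by quiet windows) plus Gaussian
    window noise.  The normal profile is centred at 0.  The tumor
    profile is already expressed as log2(tumor/normal)."""
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    build = config.build()
    k = int(config.events_per_chrom)
    truth = GroundTruth()
    tumor_segs: list[Segment] = []
    normal_segs: list[Segment] = []
    counts: dict[str, int] = {}
    for chrom in build.chroms:
        n_windows = build.chrom_lengths[chrom] // window_bp
        rng = _rng(config.seed, "windowed", chrom)
        deltas = np.zeros(n_windows)
        planted = 0
        if k > 0:
            block = n_windows // k
            if block < 3:
                raise ValidationError(
                    f"chromosome {chrom}: too many events ({k}) for "
                    f"{n_windows} windows"
                )
            for b in range(k):
                run_len = int(rng.integers(1, min(3, block - 2), endpoint=True))
                offset = int(rng.integers(0, block - run_len - 1, endpoint=True))
                w0 = b * block + offset
                sign = 1.0 if rng.random() < 0.5 else -1.0
                deltas[w0 : w0 + run_len] = sign * abs(config.window_amplitude)
                planted += 1
                truth.events.append(
                    PlantedEvent(
                        "tumor", chrom, w0 * window_bp, (w0 + run_len) * window_bp,
                        sign * abs(config.window_amplitude),
                        "gain" if sign > 0 else "loss", "planted",
                    )
                )
        counts[chrom] = planted
        tumor_noise = (
            rng.normal(0.0, config.noise_sd, n_windows)
            if config.noise_sd > 0
            else np.zeros(n_windows)
        )
        normal_noise = (
            rng.normal(0.0, config.noise_sd, n_windows)
            if config.noise_sd > 0
            else np.zeros(n_windows)
        )
        for w in range(n_windows):
            start, end = w * window_bp, (w + 1) * window_bp
            tumor_segs.append(
                Segment("tumor", chrom, start, end, float(deltas[w] + tumor_noise[w]))
            )
            normal_segs.append(
                Segment("normal", chrom, start, end, float(normal_noise[w]))
            )
    truth.per_chrom_counts["tumor"] = counts
    return (
        SampleProfile("tumor", tumor_segs),
        SampleProfile("normal", normal_segs),
        truth,
    )


# ---------------------------------------------------------------------------
# breakpoint-biased call sets


def simulate_biased_breakpoint_calls(
    config: SimConfig, annotation: GenomeAnnotation
) -> tuple[list[CnaCall], GroundTruth]:
    """CNA calls whose start edges are biased toward one feature track.

    Placement is rejection-sampled: a uniform candidate is accepted
    with probability 1 when its start edge lies in ``bias_track``,
    else 1/``bias_weight``, so in-track starts are ``bias_weight``-fold
    enriched relative to uniform placement.
    """
    from segstack.breakpoints import CATEGORIES, classify_points

    if config.bias_track not in CATEGORIES:
        raise ValidationError(f"unknown bias track {config.bias_track!r}")
    if config.bias_weight < 1:
        raise ValidationError("bias_weight must be >= 1")
    build = annotation.build
    chroms = build.chroms
    lengths = np.array([build.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    rng = _rng(config.seed, "breakpoint-bias")
    lo_len, hi_len = config.event_length_range
    calls: list[CnaCall] = []
    truth = GroundTruth()
    for i in range(config.n_breakpoint_events):
        while True:
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            chrom_len = build.chrom_lengths[chrom]
            max_len = min(hi_len, chrom_len // 4)
            length = int(
                np.exp(rng.uniform(np.log(lo_len), np.log(max(max_len, lo_len + 1))))
            )
            length = max(lo_len, min(length, max_len))
            start = int(rng.integers(0, chrom_len - length, endpoint=True))
            in_track = bool(
                classify_points(chrom, np.array([start]), annotation)[
                    config.bias_track
                ][0]
            )
            accept_p = 1.0 if in_track else 1.0 / config.bias_weight
            if rng.random() < accept_p:
                break
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta = sign * 0.5
        calls.append(
            CnaCall(
                sample_id="sim",
                chrom=chrom,
                start=start,
                end=start + length,
                delta=delta,
                direction="gain" if sign > 0 else "loss",
            )
        )
        truth.events.append(
            PlantedEvent(
                "sim", chrom, start, start + length, delta,
                "gain" if sign > 0 else "loss",
                "in_track" if in_track else "background",
            )
        )
    return calls, truth
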
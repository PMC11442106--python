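"""Candidate QTL region calling and allele-specific marker nomination.

A region is called where both criteria hold simultaneously:

1. the directional QTL variant count (number of window variants whose Δ
   exceeds the simulated null threshold, split by sign of Δ) stays above a
   count threshold (default 20) across a run of consecutive windows spanning
   at least 2 Mb, in one direction only; and
2. variants with an SNP-index of exactly 0 cluster across at least 2 Mb in
   one bulk but not the other.

The direction of criterion 1 and the bulk of criterion 2 must be polarity
consistent: a trait-increasing (up) region depletes the donor allele from
the low bulk, so the zero cluster must sit in the low bulk, and vice versa.
Inside a called region, marker candidates are sites whose SNP-index is ~0
in one bulk and near the expected donor fraction (plexity/ploidy, 0.167 for
a hexaploid simplex) in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scan import ScoredVariant, WindowStat, frame_to_windows

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class CountInterval:
    """A run of windows satisfying the directional count criterion."""

    chrom: str
    start: int
    end: int
    direction: str  # "up" or "down"
    windows: tuple[WindowStat, ...]

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ZeroInterval:
    """A run of windows where zero-index variants cluster in one bulk."""

    chrom: str
    start: int
    end: int
    bulk: str  # "low" or "high"
    windows: tuple[WindowStat, ...]

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QtlRegion:
    """A called candidate interval satisfying both criteria."""

    chrom: str
    start: int
    end: int
    direction: str
    criterion1_met: bool
    criterion2_met: bool
    zero_cluster_bulk: str
    peak_window: WindowStat | None
    n_support_windows: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MarkerCandidate:
    """A scored variant nominated as an allele-specific marker site."""

    scored: ScoredVariant | dict
    expected_index: float
    near_zero_bulk: str  # "low" or "high"
    score: tuple

    def __getitem__(self, key):  # convenience for dict-backed candidates
        if isinstance(self.scored, dict):
            return self.scored[key]
        raise TypeError("scored is not a mapping")


def _as_window_list(windows) -> list[WindowStat]:
    if isinstance(windows, pd.DataFrame):
        return frame_to_windows(windows)
    return list(windows)


def _runs(mask: np.ndarray):
    """Yield (i, j) index pairs of maximal True runs (j exclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e]) + 1


def call_count_criterion(
    windows,
    count_threshold: int = 20,
    min_span_bp: int = 2_000_000,
    confidence: int = 95,
    min_fraction: float = 1.0,
) -> list[CountInterval]:
    """Criterion 1: sustained one-directional QTL variant counts.

    For each chromosome and direction, find maximal runs of consecutive
    windows whose directional count exceeds ``count_threshold`` and whose
    opposite-direction count does not (a window exceeding the threshold both
    ways is bidirectional and breaks the run); a run qualifies if it spans
    at least ``min_span_bp`` (first window start to last window end).  By
    construction no window in a returned run exceeds the threshold in the
    opposite direction.  ``min_fraction`` < 1 enables a lenient mode in
    which qualifying runs separated by sub-threshold gaps are merged, as
    long as the exceeding fraction of the merged run stays at or above it
    and no gap window violates the opposite direction.
    """
    if confidence not in (95, 99):
        raise ValueError("confidence must be 95 or 99")
    wlist = _as_window_list(windows)
    out: list[CountInterval] = []
    for chrom in dict.fromkeys(w.chrom for w in wlist):
        cw = [w for w in wlist if w.chrom == chrom]
        counts = {
            UP: np.array([getattr(w, f"count{confidence}_up") for w in cw]),
            DOWN: np.array([getattr(w, f"count{confidence}_down") for w in cw]),
        }
        for direction, opposite in ((UP, DOWN), (DOWN, UP)):
            violate = counts[opposite] > count_threshold
            eligible = (counts[direction] > count_threshold) & ~violate
            runs = list(_runs(eligible))
            if min_fraction < 1.0 and runs:
                runs = _merge_runs(runs, eligible, violate, min_fraction)
            for i, j in runs:
                start, end = cw[i].start, cw[j - 1].end
                if end - start + 1 >= min_span_bp:
                    out.append(
                        CountInterval(chrom, start, end, direction, tuple(cw[i:j]))
                    )
    return out


def _merge_runs(runs, eligible: np.ndarray, violate: np.ndarray, min_fraction: float):
    """Greedy left-to-right merge of threshold runs through small gaps.

    Merging never bridges a window that exceeds the threshold in the
    opposite direction.
    """
    merged = [list(runs[0])]
    for i, j in runs[1:]:
        a, b = merged[-1]
        if not violate[b:i].any() and eligible[a:j].mean() >= min_fraction:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    return [tuple(r) for r in merged]


def call_zero_cluster_criterion(
    windows,
    zero_min: int = 10,
    dominance_ratio: float = 5.0,
    min_span_bp: int = 2_000_000,
) -> list[ZeroInterval]:
    """Criterion 2: zero-SNP-index variants clustered in one bulk only.

    A window supports bulk ``b`` when its zero count there is at least
    ``zero_min`` and at least ``dominance_ratio`` times the other bulk's.
    Maximal supporting runs spanning ``min_span_bp`` are returned.
    """
    wlist = _as_window_list(windows)
    out: list[ZeroInterval] = []
    for chrom in dict.fromkeys(w.chrom for w in wlist):
        cw = [w for w in wlist if w.chrom == chrom]
        zl = np.array([w.zeros_low for w in cw], dtype=float)
        zh = np.array([w.zeros_high for w in cw], dtype=float)
        for bulk, zb, zo in (("low", zl, zh), ("high", zh, zl)):
            mask = (zb >= zero_min) & (zb >= dominance_ratio * zo)
            for i, j in _runs(mask):
                start, end = cw[i].start, cw[j - 1].end
                if end - start + 1 >= min_span_bp:
                    out.append(ZeroInterval(chrom, start, end, bulk, tuple(cw[i:j])))
    return out


#: Direction of trait effect implied by where the zero cluster sits: a
#: trait-increasing allele is depleted from the low bulk.
_POLARITY = {UP: "low", DOWN: "high"}


def call_regions(
    count_intervals: Sequence[CountInterval],
    zero_intervals: Sequence[ZeroInterval],
) -> list[QtlRegion]:
    """Intersect criterion-1 and criterion-2 intervals into called regions.

    A region is emitted for every same-chromosome overlap whose polarity is
    consistent (up ↔ zero cluster in low bulk; down ↔ high bulk).  Region
    bounds are the intersection; the peak window is the member window with
    the largest |mean Δ|.
    """
    regions: list[QtlRegion] = []
    for ci in count_intervals:
        for zi in zero_intervals:
            if ci.chrom != zi.chrom:
                continue
            if _POLARITY[ci.direction] != zi.bulk:
                continue
            start = max(ci.start, zi.start)
            end = min(ci.end, zi.end)
            if start > end:
                continue
            members = [
                w for w in ci.windows
                if w.start <= end and w.end >= start and w.n_variants > 0
            ]
            peak = None
            if members:
                peak = max(members, key=lambda w: abs(w.mean_delta))
            regions.append(
                QtlRegion(
                    chrom=ci.chrom, start=start, end=end, direction=ci.direction,
                    criterion1_met=True, criterion2_met=True,
                    zero_cluster_bulk=zi.bulk, peak_window=peak,
                    n_support_windows=len(members),
                )
            )
    return regions


def select_marker_candidates(
    scored,
    region: QtlRegion,
    zero_tol: float = 0.02,
    simplex_tol: float = 0.05,
    top_k: int = 10,
    ploidy: int = 6,
    plexity: int = 1,
) -> list[MarkerCandidate]:
    """Nominate marker SNPs inside a called region.

    Candidates have one bulk's SNP-index at (or within ``zero_tol`` of) zero
    and the other within ``simplex_tol`` of the expected donor fraction
    plexity/ploidy, with the near-zero bulk matching the region's polarity.
    Ranked by total bulk depth (descending), then |Δ| (descending).
    """
    expected = plexity / ploidy
    near_zero_bulk = _POLARITY[region.direction]
    if isinstance(scored, pd.DataFrame):
        rows = scored.to_dict("records")
        get = lambda r, k: r[k]
        backing = rows
    else:
        backing = list(scored)
        def get(sv, k):
            rec = sv.classified.record
            mapping = {
                "chrom": rec.chrom, "pos": rec.pos,
                "idx_low": sv.idx_low, "idx_high": sv.idx_high, "delta": sv.delta,
                "low_ref": rec.depths["BULK_LOW"][0], "low_alt": rec.depths["BULK_LOW"][1],
                "high_ref": rec.depths["BULK_HIGH"][0], "high_alt": rec.depths["BULK_HIGH"][1],
            }
            return mapping[k]
    candidates = []
    for item in backing:
        if get(item, "chrom") != region.chrom:
            continue
        if not (region.start <= get(item, "pos") <= region.end):
            continue
        idx_low, idx_high = get(item, "idx_low"), get(item, "idx_high")
        zero_idx, other_idx = (
            (idx_low, idx_high) if near_zero_bulk == "low" else (idx_high, idx_low)
        )
        if zero_idx > zero_tol:
            continue
        if abs(other_idx - expected) > simplex_tol:
            continue
        depth = (
            get(item, "low_ref") + get(item, "low_alt")
            + get(item, "high_ref") + get(item, "high_alt")
        )
        candidates.append(
            MarkerCandidate(
                scored=item, expected_index=expected,
                near_zero_bulk=near_zero_bulk,
                score=(int(depth), abs(get(item, "delta"))),
            )
        )
    candidates.sort(key=lambda c: c.score, reverse=True)
    return candidates[:top_k]


def regions_to_frame(regions: Sequence[QtlRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "direction": r.direction,
                "peak_window_start": r.peak_window.start if r.peak_window else -1,
                "n_support_windows": r.n_support_windows,
                "zero_cluster_bulk": r.zero_cluster_bulk,
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "direction",
            "peak_window_start", "n_support_windows", "zero_cluster_bulk",
        ],
    )


def markers_to_frame(markers: Sequence[MarkerCandidate]) -> pd.DataFrame:
    rows = []
    for rank, m in enumerate(markers, start=1):
        if isinstance(m.scored, dict):
            s = m.scored
            rows.append(
                {
                    "chrom": s["chrom"], "pos": s["pos"],
                    "ref": s.get("ref", "."), "alt": s.get("alt", "."),
                    "idx_low": s["idx_low"], "idx_high": s["idx_high"],
                    "delta": s["delta"], "rank": rank,
                }
            )
        else:
            rec = m.scored.classified.record
            rows.append(
                {
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref_allele, "alt": rec.alt_allele,
                    "idx_low": m.scored.idx_low, "idx_high": m.scored.idx_high,
                    "delta": m.scored.delta, "rank": rank,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "idx_low", "idx_high", "delta", "rank"]
    )
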
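"""Per-variant scoring and the sliding-window genome scan.

Every classified variant is scored with its two bulk SNP-indexes, their
difference Δ = idx(high) − idx(low), and an empirical P value against the
plexity-matched no-QTL null at the variant's own read depths.  Scores are
then aggregated into 100-kb windows advanced in 20-kb steps, tracking the
directional QTL-variant counts (significant variants split by the sign of
Δ) and the counts of exact-zero SNP-indexes per bulk that feed the region
caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nullmodel import NullModel
from .plexity import ClassifiedVariant, parent_allele_fraction
from .vcf_io import FRAME_COLUMNS

#: SNP-index of one sample: alt reads over total reads (same contract as the
#: parental allele fraction; shared implementation).
snp_index = parent_allele_fraction

SCORED_COLUMNS = FRAME_COLUMNS + [
    "donor", "plexity", "donor_index",
    "idx_low", "idx_high", "delta", "p", "sig95", "sig99",
    "zero_in_low", "zero_in_high",
]

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_variants",
    "mean_idx_low", "mean_idx_high", "mean_delta", "mean_neglog10p",
    "count95_up", "count95_down", "count99_up", "count99_down",
    "zeros_low", "zeros_high",
]


@dataclass(frozen=True)
class ScoredVariant:
    """A classified variant with bulk indexes, Δ, and null-model statistics."""

    classified: ClassifiedVariant
    idx_low: float
    idx_high: float
    delta: float
    p: float
    sig95: bool
    sig99: bool

    def __post_init__(self) -> None:
        assert abs(self.delta - (self.idx_high - self.idx_low)) < 1e-12

    @property
    def zero_in_low(self) -> bool:
        return self.idx_low == 0.0

    @property
    def zero_in_high(self) -> bool:
        return self.idx_high == 0.0


@dataclass(frozen=True)
class WindowStat:
    """Aggregate over one sliding window (1-based inclusive interval)."""

    chrom: str
    start: int
    end: int
    n_variants: int
    mean_idx_low: float
    mean_idx_high: float
    mean_delta: float
    mean_neglog10p: float
    count95_up: int
    count95_down: int
    count99_up: int
    count99_down: int
    zeros_low: int
    zeros_high: int


def score_frame(classified: pd.DataFrame, null_model: NullModel) -> pd.DataFrame:
    """Vectorised scoring of a donor-oriented classified variant table.

    Adds bulk indexes, Δ, the empirical P value and significance flags from
    the null at each variant's (low depth, high depth) pair, and the
    exact-zero flags per bulk.  Input order is preserved.
    """
    out = classified.copy()
    low_tot = (out["low_ref"] + out["low_alt"]).to_numpy()
    high_tot = (out["high_ref"] + out["high_alt"]).to_numpy()
    if (low_tot < 1).any() or (high_tot < 1).any():
        raise ValueError("bulk depths must be >= 1 after filtering")
    idx_low = out["low_alt"].to_numpy() / low_tot
    idx_high = out["high_alt"].to_numpy() / high_tot
    delta = idx_high - idx_low
    p, sig95, sig99 = null_model.score(delta, low_tot, high_tot)
    out["idx_low"] = idx_low
    out["idx_high"] = idx_high
    out["delta"] = delta
    out["p"] = p
    out["sig95"] = sig95
    out["sig99"] = sig99
    out["zero_in_low"] = idx_low == 0.0
    out["zero_in_high"] = idx_high == 0.0
    return out


def score_variants(
    classified: Sequence[ClassifiedVariant], null_model: NullModel
) -> list[ScoredVariant]:
    """Score a donor-oriented classified set; order preserved."""
    out = []
    for cv in classified:
        lr, la = cv.record.depths["BULK_LOW"]
        hr, ha = cv.record.depths["BULK_HIGH"]
        idx_low = snp_index(lr, la)
        idx_high = snp_index(hr, ha)
        delta = idx_high - idx_low
        nd = null_model.get(lr + la, hr + ha)
        pv = nd.p_value(delta)
        out.append(
            ScoredVariant(
                classified=cv, idx_low=idx_low, idx_high=idx_high, delta=delta,
                p=pv.p, sig95=pv.sig95, sig99=pv.sig99,
            )
        )
    return out


def scored_to_frame(scored: Sequence[ScoredVariant]) -> pd.DataFrame:
    """Flatten ScoredVariant objects into the scan table layout."""
    rows = []
    for sv in scored:
        rec = sv.classified.record
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "variant_length": rec.variant_length,
                "p1_ref": rec.depths["P1"][0], "p1_alt": rec.depths["P1"][1],
                "p2_ref": rec.depths["P2"][0], "p2_alt": rec.depths["P2"][1],
                "low_ref": rec.depths["BULK_LOW"][0], "low_alt": rec.depths["BULK_LOW"][1],
                "high_ref": rec.depths["BULK_HIGH"][0], "high_alt": rec.depths["BULK_HIGH"][1],
                "donor": sv.classified.donor,
                "plexity": sv.classified.plexity,
                "donor_index": sv.classified.donor_parent_index,
                "idx_low": sv.idx_low, "idx_high": sv.idx_high, "delta": sv.delta,
                "p": sv.p, "sig95": sv.sig95, "sig99": sv.sig99,
                "zero_in_low": sv.zero_in_low, "zero_in_high": sv.zero_in_high,
            }
        )
    return pd.DataFrame(rows, columns=SCORED_COLUMNS)


def _window_grid(length: int, window_bp: int, step_bp: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp - 1, length)
    return starts, ends


def _spread_indices(k_lo: np.ndarray, k_hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-variant window ranges [k_lo, k_hi] into flat index arrays.

    Returns (window indices, variant indices) with one entry per membership.
    """
    counts = k_hi - k_lo + 1
    total = int(counts.sum())
    var_idx = np.repeat(np.arange(k_lo.size), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    win_idx = np.repeat(k_lo, counts) + offsets
    return win_idx, var_idx


def window_table(
    scored: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 100_000,
    step_bp: int = 20_000,
) -> pd.DataFrame:
    """Aggregate scored variants into the sliding-window table.

    Windows start at 1, 1+step, ... on every chromosome in ``chrom_lengths``
    (in that order), with the last window clipped at the chromosome end.
    Membership is pos ∈ [start, end] inclusive.  Empty windows carry NaN
    means and zero counts.  Scored input must be position-sorted within each
    chromosome.
    """
    if window_bp < 1 or step_bp < 1:
        raise ValueError("window_bp and step_bp must be >= 1")
    frames = []
    neglogp_all = None
    if len(scored):
        neglogp_all = -np.log10(scored["p"].to_numpy())
    for chrom, length in chrom_lengths.items():
        starts, ends = _window_grid(int(length), window_bp, step_bp)
        n_win = starts.size
        agg = {
            "n": np.zeros(n_win, dtype=np.int64),
            "sum_idx_low": np.zeros(n_win), "sum_idx_high": np.zeros(n_win),
            "sum_delta": np.zeros(n_win), "sum_neglogp": np.zeros(n_win),
            "count95_up": np.zeros(n_win, dtype=np.int64),
            "count95_down": np.zeros(n_win, dtype=np.int64),
            "count99_up": np.zeros(n_win, dtype=np.int64),
            "count99_down": np.zeros(n_win, dtype=np.int64),
            "zeros_low": np.zeros(n_win, dtype=np.int64),
            "zeros_high": np.zeros(n_win, dtype=np.int64),
        }
        sub_mask = scored["chrom"].to_numpy() == chrom if len(scored) else np.array([], bool)
        if sub_mask.any():
            pos = scored["pos"].to_numpy()[sub_mask]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"scored variants not position-sorted on {chrom}")
            if pos.size and (pos[0] < 1 or pos[-1] > length):
                raise ValueError(f"variant position outside {chrom} bounds")
            k_lo = np.maximum(0, np.ceil((pos - window_bp) / step_bp).astype(np.int64))
            k_hi = np.minimum(n_win - 1, (pos - 1) // step_bp)
            win_idx, var_idx = _spread_indices(k_lo, k_hi)
            sub = scored.loc[sub_mask]
            delta = sub["delta"].to_numpy()[var_idx]
            sig95 = sub["sig95"].to_numpy()[var_idx]
            sig99 = sub["sig99"].to_numpy()[var_idx]
            np.add.at(agg["n"], win_idx, 1)
            np.add.at(agg["sum_idx_low"], win_idx, sub["idx_low"].to_numpy()[var_idx])
            np.add.at(agg["sum_idx_high"], win_idx, sub["idx_high"].to_numpy()[var_idx])
            np.add.at(agg["sum_delta"], win_idx, delta)
            np.add.at(agg["sum_neglogp"], win_idx, neglogp_all[sub_mask][var_idx])
            np.add.at(agg["count95_up"], win_idx, (sig95 & (delta > 0)).astype(np.int64))
            np.add.at(agg["count95_down"], win_idx, (sig95 & (delta < 0)).astype(np.int64))
            np.add.at(agg["count99_up"], win_idx, (sig99 & (delta > 0)).astype(np.int64))
            np.add.at(agg["count99_down"], win_idx, (sig99 & (delta < 0)).astype(np.int64))
            np.add.at(agg["zeros_low"], win_idx,
                      sub["zero_in_low"].to_numpy()[var_idx].astype(np.int64))
            np.add.at(agg["zeros_high"], win_idx,
                      sub["zero_in_high"].to_numpy()[var_idx].astype(np.int64))
        with np.errstate(invalid="ignore", divide="ignore"):
            n = agg["n"].astype(float)
            mean = lambda s: np.where(agg["n"] > 0, agg[s] / np.where(n > 0, n, 1), np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom, "start": starts, "end": ends,
                        "n_variants": agg["n"],
                        "mean_idx_low": mean("sum_idx_low"),
                        "mean_idx_high": mean("sum_idx_high"),
                        "mean_delta": mean("sum_delta"),
                        "mean_neglog10p": mean("sum_neglogp"),
                        "count95_up": agg["count95_up"],
                        "count95_down": agg["count95_down"],
                        "count99_up": agg["count99_up"],
                        "count99_down": agg["count99_down"],
                        "zeros_low": agg["zeros_low"],
                        "zeros_high": agg["zeros_high"],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)[WINDOW_COLUMNS]


def sliding_windows(
    scored,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 100_000,
    step_bp: int = 20_000,
) -> list[WindowStat]:
    """Window scan returning :class:`WindowStat` objects.

    Accepts either a sequence of :class:`ScoredVariant` or a scored table.
    """
    if not isinstance(scored, pd.DataFrame):
        scored = scored_to_frame(list(scored))
    table = window_table(scored, chrom_lengths, window_bp=window_bp, step_bp=step_bp)
    return frame_to_windows(table)


def frame_to_windows(table: pd.DataFrame) -> list[WindowStat]:
    return [
        WindowStat(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            n_variants=int(row.n_variants),
            mean_idx_low=float(row.mean_idx_low),
            mean_idx_high=float(row.mean_idx_high),
            mean_delta=float(row.mean_delta),
            mean_neglog10p=float(row.mean_neglog10p),
            count95_up=int(row.count95_up), count95_down=int(row.count95_down),
            count99_up=int(row.count99_up), count99_down=int(row.count99_down),
            zeros_low=int(row.zeros_low), zeros_high=int(row.zeros_high),
        )
        for row in table.itertuples(index=False)
    ]


def windows_to_frame(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows], columns=WINDOW_COLUMNS)


def write_window_tsv(windows, path) -> None:
    table = windows if isinstance(windows, pd.DataFrame) else windows_to_frame(windows)
    out = table.copy()
    for col in ("mean_idx_low", "mean_idx_high", "mean_delta", "mean_neglog10p"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)
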
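"""Model/Results interface to the polyploid QTL-seq scan.

:class:`PolyploidQtlScan` is constructed from variant data (a VCF or an
in-memory variant table) plus chromosome lengths and a :class:`RunConfig`;
:meth:`PolyploidQtlScan.fit` executes filter → plexity classification →
per-variant scoring against the polysomic null → sliding-window scan →
two-criterion region calling → marker nomination for one donor orientation
and returns a :class:`QtlScanResults` carrying all intermediate tables, the
called regions, and a text ``summary()``.  Both orientations (parents
swapped) are fitted with :meth:`fit_both`, mirroring the practice of
repeating the analysis with the parents exchanged so QTLs from either
parent are detected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .nullmodel import NullModel, SegregationModel
from .plexity import classify_frame
from .regions import (
    QtlRegion,
    call_count_criterion,
    call_regions,
    call_zero_cluster_criterion,
    markers_to_frame,
    regions_to_frame,
    select_marker_candidates,
)
from .scan import score_frame, window_table, write_window_tsv
from .vcf_io import (
    filter_frame,
    read_chrom_lengths,
    read_variants,
    records_to_frame,
    write_scored_tsv,
)


class PolyploidQtlScan:
    """Bulked-segregant genome scan for an autopolyploid F1 cross.

    Parameters
    ----------
    variants
        Flat variant table (see ``vcf_io.FRAME_COLUMNS``) or a sequence of
        :class:`~polybsa.vcf_io.VariantRecord`.
    chrom_lengths
        Mapping chromosome name -> length in bp, in plotting order.
    config
        Scan parameters; defaults follow the published method (minDepth 50,
        simplex window 0.08-0.25, 100-kb/20-kb windows, count threshold 20
        over 2 Mb).
    """

    def __init__(
        self,
        variants,
        chrom_lengths: Mapping[str, int],
        config: RunConfig | None = None,
    ) -> None:
        if not isinstance(variants, pd.DataFrame):
            variants = records_to_frame(list(variants))
        self.variants = variants
        self.chrom_lengths = dict(chrom_lengths)
        self.config = config or RunConfig()
        self._null_model: NullModel | None = None

    @classmethod
    def from_vcf(
        cls,
        vcf_path: str | Path,
        chrom_lengths: str | Path | Mapping[str, int],
        config: RunConfig | None = None,
        sample_map: Mapping[str, str] | None = None,
    ) -> "PolyploidQtlScan":
        config = config or RunConfig()
        sm = sample_map or config.sample_map
        records = read_variants(
            vcf_path, sm, multiallelic_policy=config.filter.multiallelic_policy
        )
        if not isinstance(chrom_lengths, Mapping):
            chrom_lengths = read_chrom_lengths(chrom_lengths)
        return cls(records_to_frame(records), chrom_lengths, config)

    @property
    def null_model(self) -> NullModel:
        if self._null_model is None:
            cfg = self.config
            self._null_model = NullModel(
                SegregationModel(cfg.plexity.ploidy, cfg.plexity.n_plex),
                n_low=cfg.bulk_size_low,
                n_high=cfg.bulk_size_high,
                replicates=cfg.replicates,
                seed=cfg.seed,
            )
        return self._null_model

    def fit(self, donor: str = "P1") -> "QtlScanResults":
        """Run the scan for one donor orientation ("P1" or "P2")."""
        if donor not in ("P1", "P2"):
            raise ValueError("donor must be 'P1' or 'P2'")
        cfg = self.config
        stage_counts = {"parsed": len(self.variants)}
        filtered = filter_frame(self.variants, cfg.filter)
        stage_counts["filtered"] = len(filtered)
        classified = classify_frame(filtered, cfg.plexity)
        oriented = classified.loc[classified["donor"] == donor].reset_index(drop=True)
        stage_counts["classified"] = len(oriented)
        scored = score_frame(oriented, self.null_model)
        windows = window_table(
            scored, self.chrom_lengths, window_bp=cfg.window_bp, step_bp=cfg.step_bp
        )
        count_ivs = call_count_criterion(
            windows,
            count_threshold=cfg.count_threshold,
            min_span_bp=cfg.min_span_bp,
            confidence=cfg.confidence,
            min_fraction=cfg.min_run_fraction,
        )
        zero_ivs = call_zero_cluster_criterion(
            windows,
            zero_min=cfg.zero_min,
            dominance_ratio=cfg.dominance_ratio,
            min_span_bp=cfg.min_span_bp,
        )
        regions = call_regions(count_ivs, zero_ivs)
        markers = {
            i: select_marker_candidates(
                scored, reg,
                zero_tol=cfg.zero_tol, simplex_tol=cfg.simplex_tol,
                top_k=cfg.top_k, ploidy=cfg.plexity.ploidy,
                plexity=cfg.plexity.n_plex,
            )
            for i, reg in enumerate(regions)
        }
        return QtlScanResults(
            model=self,
            donor=donor,
            scored=scored,
            windows=windows,
            count_intervals=count_ivs,
            zero_intervals=zero_ivs,
            regions=regions,
            markers=markers,
            stage_counts=stage_counts,
        )

    def fit_both(self) -> dict[str, "QtlScanResults"]:
        """Fit both donor orientations (parents swapped)."""
        return {donor: self.fit(donor) for donor in ("P1", "P2")}


@dataclass
class QtlScanResults:
    """Fitted scan for one donor orientation."""

    model: PolyploidQtlScan
    donor: str
    scored: pd.DataFrame
    windows: pd.DataFrame
    count_intervals: list
    zero_intervals: list
    regions: list[QtlRegion]
    markers: Mapping[int, list]
    stage_counts: Mapping[str, int]

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def median_depth_thresholds(self) -> dict[float, tuple[float, float]]:
        """Null Δ confidence bands at the median (low, high) depth pair."""
        if len(self.scored) == 0:
            dl = dh = max(1, int(round(100)))
        else:
            dl = int(np.median(self.scored["low_ref"] + self.scored["low_alt"]))
            dh = int(np.median(self.scored["high_ref"] + self.scored["high_alt"]))
        return dict(self.model.null_model.thresholds(dl, dh))

    def summary(self) -> str:
        cfg = self.config
        lines = []
        add = lines.append
        add("Polyploid QTL-seq scan")
        add("=" * 60)
        add(f"donor orientation : {self.donor}")
        add(f"ploidy / plexity  : {cfg.plexity.ploidy} / {cfg.plexity.n_plex}")
        add(f"donor index range : [{cfg.plexity.range[0]:.2f}, {cfg.plexity.range[1]:.2f}]")
        add(f"bulk sizes (low/high): {cfg.bulk_size_low} / {cfg.bulk_size_high}")
        add(f"window / step     : {cfg.window_bp} / {cfg.step_bp} bp")
        add(f"null replicates   : {cfg.replicates} (seed {cfg.seed})")
        add("stage counts      : "
            + ", ".join(f"{k}={v}" for k, v in self.stage_counts.items()))
        thr = self.median_depth_thresholds()
        for level, (lo, hi) in sorted(thr.items()):
            add(f"ΔSNP-index {int(level * 100)}% band (median depth): "
                f"[{lo:+.4f}, {hi:+.4f}]")
        add(f"significant variants: sig95={int(self.scored['sig95'].sum())}, "
            f"sig99={int(self.scored['sig99'].sum())}"
            if len(self.scored) else "significant variants: none scored")
        add("-" * 60)
        if self.regions:
            add(f"{'chrom':<12}{'start':>12}{'end':>12}{'dir':>6}{'zeros':>7}{'windows':>9}")
            for r in self.regions:
                add(f"{r.chrom:<12}{r.start:>12}{r.end:>12}{r.direction:>6}"
                    f"{r.zero_cluster_bulk:>7}{r.n_support_windows:>9}")
        else:
            add("no candidate QTL regions called")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # persistence

    def to_tsv(self, outdir: str | Path) -> dict[str, Path]:
        """Write scored/window/region/marker tables (+ metadata JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scored": outdir / "scored.tsv",
            "windows": outdir / "windows.tsv",
            "regions": outdir / "regions.tsv",
            "markers": outdir / "markers.tsv",
            "metadata": outdir / "run_metadata.json",
        }
        write_scored_tsv(self.scored, paths["scored"])
        write_window_tsv(self.windows, paths["windows"])
        regions_to_frame(self.regions).to_csv(paths["regions"], sep="\t", index=False)
        all_markers = []
        for i, reg in enumerate(self.regions):
            mf = markers_to_frame(self.markers.get(i, []))
            mf.insert(0, "region", i)
            all_markers.append(mf)
        if all_markers:
            pd.concat(all_markers, ignore_index=True).to_csv(
                paths["markers"], sep="\t", index=False
            )
        else:
            markers_to_frame([]).assign(region=[]).to_csv(
                paths["markers"], sep="\t", index=False
            )
        meta = {
            "package_version": __version__,
            "donor": self.donor,
            "stage_counts": dict(self.stage_counts),
            "config": self.config.to_dict(),
            "chrom_lengths": self.model.chrom_lengths,
            "median_depth_thresholds": {
                str(k): list(v) for k, v in self.median_depth_thresholds().items()
            },
        }
        with open(paths["metadata"], "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    def plot_chromosome(self, chrom: str, out_path: str | Path | None = None):
        from .plotting import plot_chromosome

        return plot_chromosome(
            self.windows, self.scored, self.median_depth_thresholds(),
            chrom, out_path=out_path,
            count_threshold=self.config.count_threshold,
        )
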
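"""Read multi-sample VCFs into the internal variant model and write scored tables.

A polyploid QTL-seq run consumes one VCF carrying four samples: the two
parents of the F1 cross (``P1``, ``P2``) and the two phenotype-extreme
progeny bulks (``BULK_LOW``, ``BULK_HIGH``).  Only per-sample allele depths
are used downstream; genotype calls, if present, are ignored because
genotyping a hexaploid from short reads is exactly what this method avoids.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sample roles expected in every run, in canonical order.
ROLES = ("P1", "P2", "BULK_LOW", "BULK_HIGH")

#: Column layout of the internal variant table (one row per biallelic site).
FRAME_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_length",
    "p1_ref", "p1_alt", "p2_ref", "p2_alt",
    "low_ref", "low_alt", "high_ref", "high_alt",
]

_DEPTH_COLS = {
    "P1": ("p1_ref", "p1_alt"),
    "P2": ("p2_ref", "p2_alt"),
    "BULK_LOW": ("low_ref", "low_alt"),
    "BULK_HIGH": ("high_ref", "high_alt"),
}


class ConfigurationError(ValueError):
    """A run configuration references samples, paths or values that do not exist."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic VCF site with per-role (ref, alt) read depths."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    depths: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for role, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth for {role} at {self.chrom}:{self.pos}")

    @property
    def variant_length(self) -> int:
        """Absolute ref/alt length difference in bp (0 for a SNP)."""
        return abs(len(self.ref_allele) - len(self.alt_allele))

    def total_depth(self, role: str) -> int:
        r, a = self.depths[role]
        return r + a


@dataclass(frozen=True)
class FilterConfig:
    """Site-level filters applied after parsing.

    ``min_depth`` is required in *all four* roles (the strictest reading; a
    per-role override is available for the bulks-only interpretation).
    ``max_indel_length`` of 71 retains In/Dels shorter than 72 bp.
    """

    min_depth: int = 50
    max_indel_length: int = 71
    multiallelic_policy: str = "drop"  # or "split"
    min_depth_per_role: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_indel_length < 0:
            raise ValueError("max_indel_length must be >= 0")
        if self.multiallelic_policy not in ("drop", "split"):
            raise ValueError("multiallelic_policy must be 'drop' or 'split'")

    def role_min_depth(self, role: str) -> int:
        if self.min_depth_per_role and role in self.min_depth_per_role:
            return int(self.min_depth_per_role[role])
        return self.min_depth


def _allele_depths(sample) -> Sequence[int] | None:
    """Per-allele read depths for one sample, or None if unavailable.

    Prefers the allelic-depth field (``AD``); falls back to summing
    genotype-supporting counts (``RO``/``AO``, freebayes style).
    """
    try:
        ad = sample.get("AD")
    except KeyError:
        ad = None
    if ad is not None and ad != (None,) and not all(v is None for v in ad):
        return [0 if v is None else int(v) for v in ad]
    ro = sample.get("RO") if "RO" in sample else None
    ao = sample.get("AO") if "AO" in sample else None
    if ro is not None and ao is not None:
        if not isinstance(ao, (tuple, list)):
            ao = (ao,)
        return [int(ro)] + [0 if v is None else int(v) for v in ao]
    return None


def read_variants(
    vcf_path: str | Path,
    sample_map: Mapping[str, str],
    multiallelic_policy: str = "drop",
) -> list[VariantRecord]:
    """Parse a VCF into :class:`VariantRecord` objects, sorted by (chrom, pos).

    ``sample_map`` maps each role in :data:`ROLES` to a sample name in the VCF
    header.  Chromosomes are ordered as in the VCF header.  A sample with no
    usable depth field at a site yields (0, 0) for that role only when *some*
    role has usable depths; a site where no role has depths is skipped.
    """
    missing_roles = [r for r in ROLES if r not in sample_map]
    if missing_roles:
        raise ConfigurationError(f"sample_map missing roles: {missing_roles}")

    with pysam.VariantFile(str(vcf_path)) as vf:
        header_samples = list(vf.header.samples)
        for role in ROLES:
            if sample_map[role] not in header_samples:
                raise ConfigurationError(
                    f"sample {sample_map[role]!r} (role {role}) not in VCF header"
                )
        contig_order = {name: i for i, name in enumerate(vf.header.contigs)}
        records: list[VariantRecord] = []
        for rec in vf:
            if rec.alts is None:
                continue
            alts = [a for a in rec.alts if a not in ("*", "<NON_REF>")]
            if len(alts) > 1 and multiallelic_policy == "drop":
                continue
            depths_by_role: dict[str, Sequence[int] | None] = {}
            for role in ROLES:
                depths_by_role[role] = _allele_depths(rec.samples[sample_map[role]])
            if all(v is None for v in depths_by_role.values()):
                logger.warning(
                    "no allele-depth field at %s:%d in any sample; site skipped",
                    rec.chrom, rec.pos,
                )
                continue
            for alt_i, alt in enumerate(alts, start=1):
                depths: dict[str, tuple[int, int]] = {}
                malformed = False
                for role in ROLES:
                    ad = depths_by_role[role]
                    if ad is None:
                        depths[role] = (0, 0)
                        continue
                    if len(ad) <= alt_i:
                        malformed = True
                        break
                    depths[role] = (int(ad[0]), int(ad[alt_i]))
                if malformed:
                    logger.warning(
                        "malformed depth field at %s:%d alt %s; site skipped",
                        rec.chrom, rec.pos, alt,
                    )
                    continue
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        depths=depths,
                    )
                )
    records.sort(key=lambda r: (contig_order.get(r.chrom, len(contig_order)), r.pos))
    return records


def filter_variants(
    records: Iterable[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Retain sites with adequate depth in all roles and short enough alleles.

    Order is preserved; the operation is idempotent.
    """
    out = []
    for rec in records:
        if rec.variant_length > cfg.max_indel_length:
            continue
        if all(rec.total_depth(role) >= cfg.role_min_depth(role) for role in ROLES):
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# DataFrame carrier used by the vectorised pipeline


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Pack records into the flat table the scan pipeline operates on."""
    data = {
        "chrom": [r.chrom for r in records],
        "pos": np.asarray([r.pos for r in records], dtype=np.int64),
        "ref": [r.ref_allele for r in records],
        "alt": [r.alt_allele for r in records],
        "variant_length": np.asarray([r.variant_length for r in records], dtype=np.int64),
    }
    for role, (rc, ac) in _DEPTH_COLS.items():
        data[rc] = np.asarray([r.depths[role][0] for r in records], dtype=np.int64)
        data[ac] = np.asarray([r.depths[role][1] for r in records], dtype=np.int64)
    return pd.DataFrame(data, columns=FRAME_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[VariantRecord]:
    records = []
    for row in frame.itertuples(index=False):
        depths = {
            role: (int(getattr(row, rc)), int(getattr(row, ac)))
            for role, (rc, ac) in _DEPTH_COLS.items()
        }
        records.append(
            VariantRecord(
                chrom=row.chrom, pos=int(row.pos),
                ref_allele=row.ref, alt_allele=row.alt, depths=depths,
            )
        )
    return records


def filter_frame(frame: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Vectorised :func:`filter_variants` over the flat variant table."""
    keep = frame["variant_length"].to_numpy() <= cfg.max_indel_length
    for role, (rc, ac) in _DEPTH_COLS.items():
        total = frame[rc].to_numpy() + frame[ac].to_numpy()
        keep &= total >= cfg.role_min_depth(role)
    return frame.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tabular output

SCORED_TSV_COLUMNS = [
    "chrom", "pos", "donor", "plexity", "idx_low", "idx_high",
    "delta", "p_value", "sig95", "sig99",
]


def write_scored_tsv(scored, path: str | Path) -> None:
    """Write scored variants as TSV with floats at 4 decimals.

    ``scored`` may be a sequence of :class:`polybsa.scan.ScoredVariant` or a
    DataFrame carrying at least the scored columns.
    """
    if isinstance(scored, pd.DataFrame):
        df = scored
    else:
        from .scan import scored_to_frame

        df = scored_to_frame(scored)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "donor": df["donor"],
            "plexity": df["plexity"],
            "idx_low": df["idx_low"].map(lambda v: f"{v:.4f}"),
            "idx_high": df["idx_high"].map(lambda v: f"{v:.4f}"),
            "delta": df["delta"].map(lambda v: f"{v:.4f}"),
            "p_value": df["p"].map(lambda v: f"{v:.4f}"),
            "sig95": df["sig95"].astype(bool),
            "sig99": df["sig99"].astype(bool),
        }
    )
    out.columns = SCORED_TSV_COLUMNS
    out.to_csv(path, sep="\t", index=False)


def read_scored_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["sig95"] = df["sig95"].astype(bool)
    df["sig99"] = df["sig99"].astype(bool)
    return df


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chromosome name, length in bp) -> ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    if df["length"].isna().any() or (df["length"] <= 0).any():
        raise ConfigurationError(f"invalid chromosome length table: {path}")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{int(length)}\n")
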
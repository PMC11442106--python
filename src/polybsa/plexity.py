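"""Classify variants by donor parent and allele plexity from parental read fractions.

In an autohexaploid F1 cross the informative variants are those present on a
known number of the donor parent's six homologs (simplex = 1, duplex = 2,
triplex = 3) and absent from the other parent (nulliplex).  With unbiased
sequencing the donor's alt-read fraction concentrates near plexity/ploidy
(1/6 ~ 0.167 for a simplex), so dosage is called by windowing that fraction:
0.08-0.25 (simplex), 0.22-0.45 (duplex), 0.38-0.62 (triplex) by default.
A run classifies at a single target plexity; the three dosage classes are
analysed in separate runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .vcf_io import VariantRecord

#: Default donor allele-fraction windows per target plexity.
DEFAULT_DONOR_INDEX_RANGES: dict[int, tuple[float, float]] = {
    1: (0.08, 0.25),
    2: (0.22, 0.45),
    3: (0.38, 0.62),
}

REASON_FRACTION = "fraction_out_of_range"
REASON_NULLIPLEX = "other_parent_not_nulliplex"
REASON_AMBIGUOUS = "ambiguous_donor"


@dataclass(frozen=True)
class PlexityConfig:
    """Parameters of a single-plexity classification run."""

    ploidy: int = 6
    n_plex: int = 1
    donor_index_range: tuple[float, float] | None = None
    max_other_alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 4 or self.ploidy % 2:
            raise ValueError("ploidy must be even and >= 4")
        if self.n_plex not in (1, 2, 3):
            raise ValueError("n_plex must be 1, 2 or 3")
        lo, hi = self.range
        if not (0 <= lo < hi <= 1):
            raise ValueError("donor_index_range must satisfy 0 <= lo < hi <= 1")
        if self.max_other_alt_reads < 0:
            raise ValueError("max_other_alt_reads must be >= 0")

    @property
    def range(self) -> tuple[float, float]:
        if self.donor_index_range is not None:
            return self.donor_index_range
        return DEFAULT_DONOR_INDEX_RANGES[self.n_plex]


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant attributed to one donor parent at the run's target plexity."""

    record: VariantRecord
    donor: str  # "P1" or "P2"
    plexity: int
    donor_parent_index: float

    @property
    def other_parent(self) -> str:
        return "P2" if self.donor == "P1" else "P1"


@dataclass(frozen=True)
class Rejection:
    """Why a variant was not classified in a given donor orientation."""

    record: VariantRecord
    donor: str
    reason: str


def parent_allele_fraction(ref_depth: int, alt_depth: int) -> float:
    """Alt-read fraction alt/(ref+alt); the SNP-index of a single sample.

    Full precision is kept; rounding happens only at presentation.
    """
    total = ref_depth + alt_depth
    if total < 1:
        raise ValueError("allele fraction undefined at zero total depth")
    return alt_depth / total


def classify_variant(
    record: VariantRecord, donor: str, cfg: PlexityConfig
) -> ClassifiedVariant | Rejection:
    """Accept the variant as donor-derived at cfg.n_plex, or reject with a reason.

    Acceptance requires the donor parent's alt-read fraction inside the
    plexity window AND the other parent effectively nulliplex (alt reads at
    most ``max_other_alt_reads``).
    """
    other = "P2" if donor == "P1" else "P1"
    ref_d, alt_d = record.depths[donor]
    if ref_d + alt_d < 1:
        return Rejection(record, donor, REASON_FRACTION)
    frac = parent_allele_fraction(ref_d, alt_d)
    lo, hi = cfg.range
    if not (lo <= frac <= hi):
        return Rejection(record, donor, REASON_FRACTION)
    if record.depths[other][1] > cfg.max_other_alt_reads:
        return Rejection(record, donor, REASON_NULLIPLEX)
    return ClassifiedVariant(record, donor, cfg.n_plex, frac)


@dataclass
class ClassificationResult:
    """Disjoint donor-oriented sets plus the rejections for bookkeeping."""

    p1: list[ClassifiedVariant]
    p2: list[ClassifiedVariant]
    rejections: list[Rejection]

    def donor_set(self, donor: str) -> list[ClassifiedVariant]:
        return self.p1 if donor == "P1" else self.p2


def classify_all(
    records: Iterable[VariantRecord], cfg: PlexityConfig
) -> ClassificationResult:
    """Classify every record in both donor orientations.

    A site accepted in both orientations has no unambiguous segregating
    source and is discarded from both sets (reason ``ambiguous_donor``).
    """
    p1_set: list[ClassifiedVariant] = []
    p2_set: list[ClassifiedVariant] = []
    rejections: list[Rejection] = []
    for rec in records:
        as_p1 = classify_variant(rec, "P1", cfg)
        as_p2 = classify_variant(rec, "P2", cfg)
        ok1 = isinstance(as_p1, ClassifiedVariant)
        ok2 = isinstance(as_p2, ClassifiedVariant)
        if ok1 and ok2:
            rejections.append(Rejection(rec, "P1", REASON_AMBIGUOUS))
            rejections.append(Rejection(rec, "P2", REASON_AMBIGUOUS))
        elif ok1:
            p1_set.append(as_p1)
        elif ok2:
            p2_set.append(as_p2)
        else:
            rejections.append(as_p1)
            rejections.append(as_p2)
    return ClassificationResult(p1_set, p2_set, rejections)


def classify_frame(frame: pd.DataFrame, cfg: PlexityConfig) -> pd.DataFrame:
    """Vectorised :func:`classify_all` over the flat variant table.

    Returns a copy with ``donor`` ("P1"/"P2"/"" for unclassified), ``plexity``
    and ``donor_index`` columns appended.  Ambiguous-donor sites are left
    unclassified, mirroring :func:`classify_all`.
    """
    lo, hi = cfg.range
    p1_tot = (frame["p1_ref"] + frame["p1_alt"]).to_numpy()
    p2_tot = (frame["p2_ref"] + frame["p2_alt"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(p1_tot > 0, frame["p1_alt"].to_numpy() / p1_tot, np.nan)
        f2 = np.where(p2_tot > 0, frame["p2_alt"].to_numpy() / p2_tot, np.nan)
    in1 = (f1 >= lo) & (f1 <= hi)
    in2 = (f2 >= lo) & (f2 <= hi)
    null1 = frame["p1_alt"].to_numpy() <= cfg.max_other_alt_reads
    null2 = frame["p2_alt"].to_numpy() <= cfg.max_other_alt_reads
    ok_p1 = in1 & null2
    ok_p2 = in2 & null1
    ambiguous = ok_p1 & ok_p2
    ok_p1 &= ~ambiguous
    ok_p2 &= ~ambiguous
    out = frame.copy()
    donor = np.full(len(frame), "", dtype=object)
    donor[ok_p1] = "P1"
    donor[ok_p2] = "P2"
    out["donor"] = donor
    out["plexity"] = np.where(donor != "", cfg.n_plex, 0)
    out["donor_index"] = np.where(ok_p1, f1, np.where(ok_p2, f2, np.nan))
    return out
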
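"""Synthetic hexaploid F1 crosses with planted QTLs, bulks and read counts.

The generator emulates the experimental design behind a polyploid QTL-seq
run: two heterozygous hexaploid parents, each contributing variants present
on 1-3 of their six homologs (simplex/duplex/triplex) and absent from the
other parent; an F1 population segregating polysomically (each progeny
receives ploidy/2 homologs per parent, drawn uniformly without
replacement); an additive quantitative trait with Gaussian noise driven by
planted QTL homologs; phenotype-extreme bulks; and per-sample read counts
with Poisson depth and binomial allele sampling.  Output is either an
in-memory variant table, or a VCF v4.2 plus plain-text truth tables, so the
whole scan pipeline is testable without external sequencing data.

Whole homologs are transmitted intact by default (no recombination), which
maximises linkage signal and makes truth evaluation exact; an optional
Poisson-crossover mode (random bivalent pairing, crossovers at a
centimorgan-per-megabase rate) is available for more realistic decay of
linkage along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .vcf_io import FRAME_COLUMNS, write_chrom_lengths

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QtlSpec:
    """One planted QTL: a marked homolog set of one donor with additive effect."""

    chrom: str
    pos: int
    donor: str  # "P1" or "P2"
    effect_size: float
    plexity: int = 1


@dataclass
class CrossConfig:
    """Study design of the simulated cross.

    Defaults mirror the mapping design this package targets: a hexaploid
    cross with 126 F1 progenies, extreme bulks of 10 (low) and 21 (high)
    individuals, and ~100x read depth per sample.
    """

    ploidy: int = 6
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr01": 30_000_000}
    )
    variant_density: float = 1 / 5000
    plexity_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)
    n_progeny: int = 126
    qtls: Sequence[QtlSpec] = ()
    phenotype_noise_sd: float = 5.0
    bulk_low_n: int = 10
    bulk_high_n: int = 21
    depth_mean: float = 100.0
    seed: int = 0
    crossover_cm_per_mb: float = 0.0
    donor_split: float = 0.5
    indel_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.ploidy < 4 or self.ploidy % 2:
            raise ValueError("ploidy must be even and >= 4")
        if abs(sum(self.plexity_mix) - 1.0) > 1e-9 or min(self.plexity_mix) < 0:
            raise ValueError("plexity_mix proportions must be non-negative and sum to 1")
        if self.bulk_low_n + self.bulk_high_n > self.n_progeny:
            raise ValueError("bulk sizes must not exceed n_progeny")
        for q in self.qtls:
            if q.chrom not in self.chrom_lengths:
                raise ValueError(f"QTL chromosome {q.chrom!r} not in chrom_lengths")
            if not 1 <= q.pos <= self.chrom_lengths[q.chrom]:
                raise ValueError(f"QTL position {q.pos} outside {q.chrom}")
            if q.donor not in ("P1", "P2"):
                raise ValueError("QTL donor must be 'P1' or 'P2'")
            if not 1 <= q.plexity <= self.ploidy // 2:
                raise ValueError("QTL plexity out of range")


class _Mosaic:
    """One transmitted gamete: 3 tracks of (breakpoints, source homolog ids)."""

    __slots__ = ("tracks",)

    def __init__(self, tracks):
        self.tracks = tracks  # list of (breakpoints ndarray, sources ndarray)

    def sources_at(self, pos: np.ndarray) -> np.ndarray:
        """[n_tracks, len(pos)] source homolog id at each position."""
        out = np.empty((len(self.tracks), pos.size), dtype=np.int64)
        for t, (bp, src) in enumerate(self.tracks):
            out[t] = src[np.searchsorted(bp, pos, side="right")]
        return out


class Cross:
    """Realised cross state: parental variant placement and progeny inheritance."""

    def __init__(self, cfg: CrossConfig, variants: pd.DataFrame,
                 marks: dict[str, np.ndarray], inheritance: dict,
                 qtl_marks: list[np.ndarray]) -> None:
        self.cfg = cfg
        #: chrom, pos, ref, alt, donor, plexity; sorted by (chrom order, pos)
        self.variants = variants
        #: chrom -> bool [n_variants_on_chrom, ploidy] marked-homolog matrix
        self.marks = marks
        #: (chrom, parent) -> bool [n_progeny, ploidy] (no recombination) or
        #: list of _Mosaic per progeny (crossover mode)
        self.inheritance = inheritance
        #: aligned with cfg.qtls: bool [ploidy] marked homologs
        self.qtl_marks = qtl_marks

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def _chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())

    def _dose_sums(self, chrom: str, parent: str, mark: np.ndarray,
                   members: np.ndarray) -> np.ndarray:
        """Summed allele dose over ``members`` for each marked set row."""
        inh = self.inheritance[(chrom, parent)]
        if isinstance(inh, np.ndarray):
            cnt = inh[members].sum(axis=0)  # per-homolog transmission counts
            return mark @ cnt
        pos = self.variants["pos"].to_numpy()[self._chrom_index(chrom)]
        total = np.zeros(mark.shape[0], dtype=np.int64)
        vidx = np.arange(mark.shape[0])
        for m in members:
            src = inh[m].sources_at(pos)  # [3, V]
            for t in range(src.shape[0]):
                total += mark[vidx, src[t]]
        return total

    def member_alt_dose_sums(self, members: np.ndarray) -> np.ndarray:
        """Per-variant summed allele dose over a member set (whole genome).

        The dose of a progeny at a variant is the number of marked donor
        homologs it inherited from the donor parent.
        """
        members = np.asarray(members)
        out = np.zeros(self.n_variants, dtype=np.int64)
        for chrom in dict.fromkeys(self.variants["chrom"]):
            idx = self._chrom_index(chrom)
            mark = self.marks[chrom]
            donors = self.variants["donor"].to_numpy()[idx]
            for parent in ("P1", "P2"):
                sel = donors == parent
                if sel.any():
                    out[idx[sel]] = self._dose_sums(chrom, parent, mark[sel], members)
        return out

    def progeny_doses(self, chrom: str) -> np.ndarray:
        """[n_progeny, n_variants_on_chrom] allele dose matrix (small runs only)."""
        idx = self._chrom_index(chrom)
        mark = self.marks[chrom]
        donors = self.variants["donor"].to_numpy()[idx]
        n = self.cfg.n_progeny
        out = np.zeros((n, idx.size), dtype=np.int64)
        pos = self.variants["pos"].to_numpy()[idx]
        for parent in ("P1", "P2"):
            sel = donors == parent
            if not sel.any():
                continue
            inh = self.inheritance[(chrom, parent)]
            if isinstance(inh, np.ndarray):
                out[:, sel] = inh.astype(np.int64) @ mark[sel].T
            else:
                vidx = np.flatnonzero(sel)
                for m in range(n):
                    src = inh[m].sources_at(pos[sel])
                    for t in range(src.shape[0]):
                        out[m, vidx] += mark[vidx, src[t]]
        return out

    def qtl_dose_matrix(self) -> np.ndarray:
        """[n_progeny, n_qtls] planted-QTL doses per progeny."""
        n = self.cfg.n_progeny
        qtls = list(self.cfg.qtls)
        out = np.zeros((n, len(qtls)), dtype=np.int64)
        for j, (q, qmark) in enumerate(zip(qtls, self.qtl_marks)):
            inh = self.inheritance[(q.chrom, q.donor)]
            if isinstance(inh, np.ndarray):
                out[:, j] = inh.astype(np.int64) @ qmark
            else:
                for m in range(n):
                    src = inh[m].sources_at(np.array([q.pos]))
                    out[m, j] = int(qmark[src[:, 0]].sum())
        return out

    def qtl_linked_mask(self) -> np.ndarray:
        """Variants sharing a marked homolog with a same-donor, same-chromosome QTL."""
        linked = np.zeros(self.n_variants, dtype=bool)
        donors = self.variants["donor"].to_numpy()
        for q, qmark in zip(self.cfg.qtls, self.qtl_marks):
            idx = self._chrom_index(q.chrom)
            share = (self.marks[q.chrom] & qmark[None, :]).any(axis=1)
            linked[idx] |= share & (donors[idx] == q.donor)
        return linked


def _stage_rng(cfg: CrossConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage,)))


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    if n <= 0:
        return np.array([], dtype=np.int64)
    draw = rng.integers(1, length + 1, size=int(n * 1.1) + 8)
    pos = np.unique(draw)
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _make_alleles(rng: np.random.Generator, n: int, indel_fraction: float):
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    refs = _BASES[ref_i].astype(object)
    alts = _BASES[alt_i].astype(object)
    is_indel = rng.random(n) < indel_fraction
    ins_len = rng.integers(1, 9, size=n)
    for i in np.flatnonzero(is_indel):
        insert = "".join(_BASES[rng.integers(0, 4, size=ins_len[i])])
        alts[i] = str(refs[i]) + insert  # short insertion
    return refs.astype(str), alts.astype(str)


def _gamete_mosaic(rng: np.random.Generator, ploidy: int, length: int,
                   lam: float) -> _Mosaic:
    homologs = rng.permutation(ploidy)
    tracks = []
    for pair in homologs.reshape(-1, 2):
        n_co = rng.poisson(lam)
        bp = np.sort(rng.integers(1, length, size=n_co)).astype(np.int64)
        start = rng.integers(0, 2)
        src = pair[(start + np.arange(n_co + 1)) % 2]
        tracks.append((bp, src))
    return _Mosaic(tracks)


def make_cross(cfg: CrossConfig) -> Cross:
    """Place parental variants on homologs and realise progeny inheritance."""
    rng = _stage_rng(cfg, 0)
    ploidy = cfg.ploidy
    var_frames = []
    marks: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_var = int(round(cfg.variant_density * length))
        pos = _draw_positions(rng, int(length), n_var)
        refs, alts = _make_alleles(rng, n_var, cfg.indel_fraction)
        donor = np.where(rng.random(n_var) < cfg.donor_split, "P1", "P2")
        plexity = rng.choice([1, 2, 3], size=n_var, p=cfg.plexity_mix)
        ranks = np.argsort(rng.random((n_var, ploidy)), axis=1).argsort(axis=1)
        mark = ranks < plexity[:, None]
        marks[chrom] = mark
        var_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": refs, "alt": alts,
                 "donor": donor, "plexity": plexity}
            )
        )
    variants = (
        pd.concat(var_frames, ignore_index=True)
        if var_frames else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "donor", "plexity"])
    )

    qtl_marks = []
    for q in cfg.qtls:
        homs = rng.choice(ploidy, size=q.plexity, replace=False)
        qm = np.zeros(ploidy, dtype=bool)
        qm[homs] = True
        qtl_marks.append(qm)

    inheritance: dict = {}
    for chrom, length in cfg.chrom_lengths.items():
        for parent in ("P1", "P2"):
            if cfg.crossover_cm_per_mb > 0:
                lam = cfg.crossover_cm_per_mb * (length / 1e6) / 100.0
                inheritance[(chrom, parent)] = [
                    _gamete_mosaic(rng, ploidy, int(length), lam)
                    for _ in range(cfg.n_progeny)
                ]
            else:
                ranks = np.argsort(
                    rng.random((cfg.n_progeny, ploidy)), axis=1
                ).argsort(axis=1)
                inheritance[(chrom, parent)] = ranks < ploidy // 2
    return Cross(cfg, variants, marks, inheritance, qtl_marks)


def assign_phenotypes(cross: Cross, cfg: CrossConfig | None = None) -> np.ndarray:
    """Additive trait: sum of QTL dose x effect plus Gaussian noise."""
    cfg = cfg or cross.cfg
    rng = _stage_rng(cfg, 1)
    pheno = np.zeros(cfg.n_progeny)
    if cfg.qtls:
        doses = cross.qtl_dose_matrix()
        effects = np.array([q.effect_size for q in cfg.qtls])
        pheno += doses @ effects
    if cfg.phenotype_noise_sd > 0:
        pheno += rng.normal(0.0, cfg.phenotype_noise_sd, size=cfg.n_progeny)
    return pheno


def make_bulks(
    phenotypes: np.ndarray, cfg: CrossConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Lowest / highest phenotype ranks; ties broken by progeny index."""
    order = np.argsort(phenotypes, kind="stable")
    low = np.sort(order[: cfg.bulk_low_n])
    high = np.sort(order[len(order) - cfg.bulk_high_n:])
    return low, high


def sample_reads(
    cross: Cross,
    bulks: tuple[np.ndarray, np.ndarray],
    cfg: CrossConfig | None = None,
) -> pd.DataFrame:
    """Draw per-sample read depths for every variant (in-memory variant table).

    Depths are Poisson(depth_mean) floored at 1.  Parental alt reads are
    binomial at the true parental allele fraction (plexity/ploidy for the
    donor, 0 for the nulliplex parent); bulk alt reads are binomial at the
    bulk allele frequency (summed member doses over ploidy x members).
    """
    cfg = cfg or cross.cfg
    rng = _stage_rng(cfg, 2)
    low, high = bulks
    nv = cross.n_variants
    plexity = cross.variants["plexity"].to_numpy()
    donor = cross.variants["donor"].to_numpy()

    def depths(n):
        return np.maximum(rng.poisson(cfg.depth_mean, size=n), 1)

    d_p1, d_p2, d_low, d_high = (depths(nv) for _ in range(4))
    donor_frac = plexity / cfg.ploidy
    p1_alt = np.where(donor == "P1", rng.binomial(d_p1, donor_frac), 0)
    p2_alt = np.where(donor == "P2", rng.binomial(d_p2, donor_frac), 0)
    low_freq = cross.member_alt_dose_sums(low) / (cfg.ploidy * low.size)
    high_freq = cross.member_alt_dose_sums(high) / (cfg.ploidy * high.size)
    low_alt = rng.binomial(d_low, low_freq)
    high_alt = rng.binomial(d_high, high_freq)

    frame = pd.DataFrame(
        {
            "chrom": cross.variants["chrom"],
            "pos": cross.variants["pos"].astype(np.int64),
            "ref": cross.variants["ref"],
            "alt": cross.variants["alt"],
            "variant_length": np.abs(
                cross.variants["ref"].str.len() - cross.variants["alt"].str.len()
            ).astype(np.int64),
            "p1_ref": d_p1 - p1_alt, "p1_alt": p1_alt,
            "p2_ref": d_p2 - p2_alt, "p2_alt": p2_alt,
            "low_ref": d_low - low_alt, "low_alt": low_alt,
            "high_ref": d_high - high_alt, "high_alt": high_alt,
        }
    )
    return frame[FRAME_COLUMNS]


@dataclass
class TruthTable:
    """Ground truth behind one simulated dataset."""

    variants: pd.DataFrame   # chrom, pos, donor, plexity, qtl_linked
    progeny: pd.DataFrame    # progeny, phenotype, dose_<i> per QTL
    bulks: pd.DataFrame      # role, member

    def write(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        self.variants.to_csv(prefix + ".variants.tsv", sep="\t", index=False)
        self.progeny.to_csv(prefix + ".progeny.tsv", sep="\t", index=False)
        self.bulks.to_csv(prefix + ".bulks.tsv", sep="\t", index=False)


def build_truth(
    cross: Cross, phenotypes: np.ndarray, bulks: tuple[np.ndarray, np.ndarray]
) -> TruthTable:
    variants = cross.variants[["chrom", "pos", "donor", "plexity"]].copy()
    variants["qtl_linked"] = cross.qtl_linked_mask()
    prog = pd.DataFrame({"progeny": np.arange(cross.cfg.n_progeny),
                         "phenotype": phenotypes})
    if cross.cfg.qtls:
        doses = cross.qtl_dose_matrix()
        for j in range(doses.shape[1]):
            prog[f"qtl{j}_dose"] = doses[:, j]
    low, high = bulks
    bulk_df = pd.DataFrame(
        {
            "role": ["BULK_LOW"] * low.size + ["BULK_HIGH"] * high.size,
            "member": np.concatenate([low, high]),
        }
    )
    return TruthTable(variants, prog, bulk_df)


SIM_SAMPLES = ("P1", "P2", "BULK_LOW", "BULK_HIGH")


def write_vcf(frame: pd.DataFrame, chrom_lengths: Mapping[str, int],
              path: str | Path) -> None:
    """Write a variant table as VCF v4.2 with AD/DP per sample."""
    header = pysam.VariantHeader()
    for name, length in chrom_lengths.items():
        header.contigs.add(name, length=int(length))
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    for s in SIM_SAMPLES:
        header.add_sample(s)
    cols = {
        "P1": ("p1_ref", "p1_alt"), "P2": ("p2_ref", "p2_alt"),
        "BULK_LOW": ("low_ref", "low_alt"), "BULK_HIGH": ("high_ref", "high_alt"),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in frame.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            for s, (rc, ac) in cols.items():
                r, a = int(getattr(row, rc)), int(getattr(row, ac))
                rec.samples[s]["AD"] = (r, a)
                rec.samples[s]["DP"] = r + a
            out.write(rec)


def emit_vcf(
    cross: Cross,
    bulks: tuple[np.ndarray, np.ndarray],
    cfg: CrossConfig,
    out_path: str | Path,
    truth_prefix: str | Path | None = None,
    phenotypes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample reads, write the VCF (+ truth tables), return the variant table."""
    frame = sample_reads(cross, bulks, cfg)
    write_vcf(frame, cfg.chrom_lengths, out_path)
    if truth_prefix is not None:
        if phenotypes is None:
            phenotypes = assign_phenotypes(cross, cfg)
        build_truth(cross, phenotypes, bulks).write(truth_prefix)
    return frame


def simulate_dataset(cfg: CrossConfig):
    """Convenience: cross -> phenotypes -> bulks -> read table, all in memory.

    Returns (variant table, truth table, cross).
    """
    cross = make_cross(cfg)
    phenotypes = assign_phenotypes(cross, cfg)
    bulks = make_bulks(phenotypes, cfg)
    frame = sample_reads(cross, bulks, cfg)
    truth = build_truth(cross, phenotypes, bulks)
    return frame, truth, cross
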
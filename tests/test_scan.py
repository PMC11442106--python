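"""Variant scoring and the sliding-window aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polybsa.nullmodel import NullModel, SegregationModel
from polybsa.plexity import PlexityConfig, classify_all
from polybsa.scan import (
    score_frame,
    score_variants,
    scored_to_frame,
    sliding_windows,
    snp_index,
    window_table,
)

from conftest import make_record


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ref,alt,printed",
        [(128, 38, 0.23), (124, 54, 0.30), (100, 0, 0.0)],
    )
    def test_printed_examples(self, ref, alt, printed):
        assert round(snp_index(ref, alt), 2) == printed


def _null_model(replicates=4000, seed=2):
    return NullModel(SegregationModel(6, 1), 10, 21, replicates=replicates, seed=seed)


class TestScoreVariants:
    def test_full_separation_is_significant(self):
        # deep coverage, idx_high = 1/6, idx_low = 0: the QTL-limit Δ of 0.167
        rec = make_record(p1=(500, 100), p2=(600, 0),
                          low=(3000, 0), high=(2500, 500))
        cv = classify_all([rec], PlexityConfig()).p1[0]
        (sv,) = score_variants([cv], _null_model())
        assert sv.delta == pytest.approx(1 / 6, abs=1e-3)
        assert sv.sig99 and sv.sig95
        assert sv.zero_in_low and not sv.zero_in_high

    def test_equal_indexes_not_significant(self):
        rec = make_record(p1=(500, 100), p2=(600, 0),
                          low=(1100, 100), high=(1100, 100))
        cv = classify_all([rec], PlexityConfig()).p1[0]
        (sv,) = score_variants([cv], _null_model())
        assert sv.delta == 0.0
        assert sv.p > 0.5
        assert not sv.sig95

    def test_null_variants_flag_at_nominal_rate(self):
        # 100 no-QTL variants: doses drawn from the segregation model itself,
        # so ~5 should breach the 95% thresholds (binomial expectation)
        rng = np.random.default_rng(31)
        m = SegregationModel(6, 1)
        records = []
        for i in range(100):
            f_low = rng.multinomial(10, m.progeny_pmf) @ m.doses / 60
            f_high = rng.multinomial(21, m.progeny_pmf) @ m.doses / 126
            la = rng.binomial(100, f_low)
            ha = rng.binomial(100, f_high)
            records.append(make_record(pos=i + 1, p1=(100, 20), p2=(100, 0),
                                       low=(100 - la, la), high=(100 - ha, ha)))
        cvs = classify_all(records, PlexityConfig()).p1
        scored = score_variants(cvs, _null_model(replicates=10_000))
        n_sig = sum(sv.sig95 for sv in scored)
        assert 0 <= n_sig <= 13  # ~Binomial(100, 0.05)

    def test_frame_scoring_matches_record_path(self):
        records = [
            make_record(pos=p, p1=(100, 20), p2=(100, 0),
                        low=(90, 10), high=(110, 15))
            for p in (10, 20, 30)
        ]
        cvs = classify_all(records, PlexityConfig()).p1
        via_records = scored_to_frame(score_variants(cvs, _null_model()))
        from polybsa.plexity import classify_frame
        from polybsa.vcf_io import records_to_frame
        cf = classify_frame(records_to_frame(records), PlexityConfig())
        via_frame = score_frame(cf[cf.donor == "P1"], _null_model())
        np.testing.assert_allclose(via_frame["p"], via_records["p"])
        np.testing.assert_allclose(via_frame["delta"], via_records["delta"])
        np.testing.assert_array_equal(via_frame["sig95"], via_records["sig95"])


def _scored_frame(rows):
    """rows: (pos, delta, sig95, sig99[, chrom]) with synthetic indexes."""
    recs = []
    for row in rows:
        pos, delta, sig95, sig99 = row[:4]
        chrom = row[4] if len(row) > 4 else "chr1"
        idx_low = max(0.0, -delta)
        idx_high = max(0.0, delta)
        recs.append(
            dict(chrom=chrom, pos=pos, idx_low=idx_low, idx_high=idx_high,
                 delta=delta, p=0.01 if sig95 else 0.5, sig95=sig95, sig99=sig99,
                 zero_in_low=idx_low == 0, zero_in_high=idx_high == 0)
        )
    return pd.DataFrame(recs)


class TestSlidingWindows:
    def test_variant_at_150kb_falls_in_five_windows(self):
        scored = _scored_frame([(150_000, 0.05, False, False)])
        table = window_table(scored, {"chr1": 1_000_000})
        hit = table[table.n_variants > 0]
        assert list(hit.start) == [60_001, 80_001, 100_001, 120_001, 140_001]
        assert (hit.n_variants == 1).all()

    def test_directional_counts(self):
        scored = _scored_frame(
            [(50_000, 0.1, True, False),
             (50_010, -0.1, True, False),
             (50_020, 0.2, True, True)]
        )
        table = window_table(scored, {"chr1": 100_000})
        w = table.iloc[0]
        assert (w.count95_up, w.count95_down, w.count99_up, w.count99_down) == (2, 1, 1, 0)

    def test_empty_chromosome_emits_empty_windows(self):
        table = window_table(_scored_frame([]), {"chrEmpty": 250_000})
        assert len(table) == 13  # starts 1, 20001, ..., 240001
        assert (table.n_variants == 0).all()
        assert table.mean_delta.isna().all()
        assert (table.count95_up == 0).all()

    def test_window_grid_clipped_at_chromosome_end(self):
        table = window_table(_scored_frame([]), {"c": 130_000})
        assert table.end.max() == 130_000
        assert (table.end - table.start + 1 <= 100_000).all()

    def test_unsorted_input_rejected(self):
        scored = _scored_frame([(500, 0.0, False, False), (100, 0.0, False, False)])
        with pytest.raises(ValueError, match="sorted"):
            window_table(scored, {"chr1": 10_000})

    def test_windowstat_objects_from_scored_variants(self):
        rec = make_record(pos=150_000, p1=(100, 20), p2=(100, 0),
                          low=(95, 5), high=(90, 10))
        cvs = classify_all([rec], PlexityConfig()).p1
        scored = score_variants(cvs, _null_model())
        windows = sliding_windows(scored, {"chr1": 200_000})
        populated = [w for w in windows if w.n_variants]
        assert len(populated) == 5
        assert all(w.start <= 150_000 <= w.end for w in populated)

    @given(
        positions=st.lists(st.integers(1, 999_000), min_size=1, max_size=60,
                           unique=True),
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_membership_count_matches_interval_arithmetic(self, positions):
        positions = sorted(positions)
        scored = _scored_frame([(p, 0.01, False, False) for p in positions])
        length, window, step = 999_000, 100_000, 20_000
        table = window_table(scored, {"chr1": length}, window, step)
        n_win = (length - 1) // step + 1
        expected = 0
        for p in positions:
            k_lo = max(0, -(-(p - window) // step))
            k_hi = min(n_win - 1, (p - 1) // step)
            expected += k_hi - k_lo + 1
        assert table.n_variants.sum() == expected

    def test_mean_delta_bounded_by_member_extremes(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 500_000), 200, replace=False))
        deltas = rng.normal(0, 0.05, 200)
        scored = _scored_frame(
            [(int(p), float(d), False, False) for p, d in zip(pos, deltas)]
        )
        table = window_table(scored, {"chr1": 500_000})
        for row in table.itertuples():
            if row.n_variants == 0:
                continue
            member = scored[(scored.pos >= row.start) & (scored.pos <= row.end)]
            assert member.delta.min() - 1e-12 <= row.mean_delta <= member.delta.max() + 1e-12

    def test_zero_index_counts_per_bulk(self):
        scored = _scored_frame(
            [(10_000, 0.15, True, False), (10_100, 0.0, False, False)]
        )
        # delta 0.15 -> idx_low 0 (zero in low); delta 0 -> zero in both
        table = window_table(scored, {"chr1": 100_000})
        w = table.iloc[0]
        assert w.zeros_low == 2 and w.zeros_high == 1
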
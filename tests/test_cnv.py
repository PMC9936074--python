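"""Normalization and consecutive-probe CNV calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rplca import (
    CoverageMatrix, ValidationError,
    call_cnvs, gen_panel, normalize, overlay_deletion_check,
)


def _matrix(values, panel, n_ntc=0):
    n_samples, n_probes = values.shape
    samples = [f"P{i:02d}" for i in range(n_samples - n_ntc)] + \
              [f"NTC{i}" for i in range(n_ntc)]
    roles = {s: ("NTC" if s.startswith("NTC") else "proband")
             for s in samples}
    counts = pd.DataFrame(values, index=samples,
                          columns=[p.probe_id for p in panel])
    return CoverageMatrix(counts, roles)


def brute_force_calls(values_row, min_run, predicate):
    """Oracle: probes in any qualifying window, grouped consecutively."""
    n = len(values_row)
    member = set()
    for i in range(n):
        for j in range(i + min_run - 1, n):
            window = values_row[i:j + 1]
            if all(not np.isnan(v) and predicate(v) for v in window):
                member.update(range(i, j + 1))
    spans = []
    for k in sorted(member):
        if spans and k == spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], k)
        else:
            spans.append((k, k))
    return spans


class TestNormalize:
    def test_constant_matrix_all_ones(self, small_panel):
        m = _matrix(np.full((10, 40), 80), small_panel)
        norm = normalize(m)
        assert np.allclose(norm.values.to_numpy(), 1.0)

    def test_per_probe_median_is_one(self, small_panel):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(50, 150, size=(11, 40)), small_panel)
        norm = normalize(m)
        medians = np.median(
            norm.values.loc[norm.non_ntc_samples()].to_numpy(), axis=0)
        assert np.allclose(medians, 1.0, atol=1e-9)

    def test_half_coverage_sample(self, small_panel):
        values = np.full((9, 40), 100)
        values[0, 5] = 50
        norm = normalize(_matrix(values, small_panel))
        # median over 9 samples at probe 5 is 100, so P00 sits at 0.5
        assert norm.values.iloc[0, 5] == pytest.approx(0.5)

    def test_zero_median_probe_flagged_and_excluded(self, small_panel):
        values = np.full((9, 40), 100)
        values[:, 7] = 0
        norm = normalize(_matrix(values, small_panel))
        probe = small_panel[7].probe_id
        assert norm.excluded_probes == [probe]
        assert norm.values[probe].isna().all()

    def test_small_run_guard(self, small_panel):
        m = _matrix(np.full((5, 40), 100), small_panel)
        with pytest.raises(ValidationError, match="non-NTC"):
            normalize(m)

    def test_ntc_excluded_from_reference(self, small_panel):
        values = np.full((10, 40), 100)
        values[9, :] = 0   # the NTC well
        norm = normalize(_matrix(values, small_panel, n_ntc=1))
        assert np.allclose(
            norm.values.loc[norm.non_ntc_samples()].to_numpy(), 1.0)


class TestCallCnvs:
    def _setup(self, values, n_probes=40):
        panel = gen_panel(n_probes)
        # one-chromosome panel keeps runs uninterrupted for rule tests
        from rplca import SmMipRecord
        panel = [SmMipRecord(p.probe_id, p.gene, "chr1",
                             p.capture_start, p.capture_end, i)
                 for i, p in enumerate(panel)]
        norm = normalize(_matrix(values, panel))
        return norm, panel

    def test_six_probes_at_half_is_het_deletion(self):
        values = np.full((9, 40), 100)
        values[0, 10:16] = 50
        norm, panel = self._setup(values)
        calls = call_cnvs(norm, panel)
        assert len(calls) == 1
        c = calls[0]
        assert (c.sample_id, c.type, c.zygosity) == \
            ("P00", "deletion", "heterozygous")
        assert (c.first_probe_index, c.last_probe_index) == (10, 15)

    def test_five_probes_never_called(self):
        values = np.full((9, 40), 100)
        values[0, 10:15] = 10
        norm, panel = self._setup(values)
        assert call_cnvs(norm, panel) == []

    def test_seven_probes_near_zero_is_hom_or_hemi(self):
        values = np.full((9, 40), 100)
        values[0, 10:17] = 5
        norm, panel = self._setup(values)
        calls = call_cnvs(norm, panel)
        assert len(calls) == 1
        assert calls[0].zygosity == "homozygous_or_hemizygous"

    def test_duplication_called_without_zygosity(self):
        values = np.full((9, 40), 100)
        values[2, 20:27] = 150
        norm, panel = self._setup(values)
        calls = call_cnvs(norm, panel)
        assert len(calls) == 1
        assert calls[0].type == "duplication"
        assert calls[0].zygosity is None

    def test_thresholds_inclusive(self):
        values = np.full((9, 40), 100)
        values[0, 0:6] = 65     # exactly 0.65 normalized
        values[1, 10:16] = 120  # exactly 1.20 normalized
        norm, panel = self._setup(values)
        kinds = {(c.sample_id, c.type) for c in call_cnvs(norm, panel)}
        assert kinds == {("P00", "deletion"), ("P01", "duplication")}

    def test_runs_do_not_cross_chromosomes(self):
        from rplca import chromosome_blocks
        panel = gen_panel(40)
        # plant a 6-probe low run straddling the first block boundary
        boundary = chromosome_blocks(panel)[0][2]
        values = np.full((9, 40), 100)
        values[0, boundary - 3:boundary + 3] = 40
        norm = normalize(_matrix(values, panel))
        assert call_cnvs(norm, panel) == []

    def test_overlapping_windows_merge_into_maximal_call(self):
        values = np.full((9, 40), 100)
        values[0, 5:15] = 30    # 10 consecutive probes -> one call
        norm, panel = self._setup(values)
        calls = call_cnvs(norm, panel)
        assert len(calls) == 1
        assert calls[0].n_probes == 10

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(5)
        values = rng.integers(60, 140, size=(9, 40))
        values[3, 8:16] = 30
        norm, panel = self._setup(values)
        calls = call_cnvs(norm, panel)
        perm = rng.permutation(9)
        m2 = _matrix(values, panel)
        shuffled = CoverageMatrix(m2.counts.iloc[perm], m2.roles)
        calls2 = call_cnvs(normalize(shuffled), panel)
        assert calls == calls2

    @settings(max_examples=120)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 50))
    def test_matches_window_oracle(self, seed, n_probes):
        rng = np.random.default_rng(seed)
        values = rng.integers(20, 180, size=(9, n_probes))
        norm, panel = self._setup(values, n_probes=n_probes)
        calls = call_cnvs(norm, panel)
        for sample_pos, sample in enumerate(norm.values.index):
            row = norm.values.loc[sample].to_numpy(dtype=float)
            for kind, pred in (("deletion", lambda v: v <= 0.65),
                               ("duplication", lambda v: v >= 1.20)):
                expected = brute_force_calls(row, 6, pred)
                got = [(c.first_probe_index, c.last_probe_index)
                       for c in calls
                       if c.sample_id == sample and c.type == kind]
                assert got == expected


class TestOverlayDeletionCheck:
    def _calls_and_panel(self):
        values = np.full((9, 40), 100)
        values[0, 2:10] = 40
        panel = gen_panel(40)
        from rplca import SmMipRecord
        panel = [SmMipRecord(p.probe_id, p.gene, "chr1",
                             p.capture_start, p.capture_end, i)
                 for i, p in enumerate(panel)]
        calls = call_cnvs(normalize(_matrix(values, panel)), panel)
        assert len(calls) == 1
        return calls, panel

    def test_hom_variant_inside_het_deletion_flagged(self):
        calls, panel = self._calls_and_panel()
        probe = next(p for p in panel if p.panel_index == 5)
        pos = probe.capture_start + 10  # 1-based pos inside the span
        assert overlay_deletion_check(calls, panel, "P00", "chr1", pos + 1)

    def test_other_sample_not_flagged(self):
        calls, panel = self._calls_and_panel()
        probe = next(p for p in panel if p.panel_index == 5)
        assert not overlay_deletion_check(calls, panel, "P01", "chr1",
                                          probe.capture_start + 11)

    def test_other_chromosome_not_flagged(self):
        calls, panel = self._calls_and_panel()
        assert not overlay_deletion_check(calls, panel, "P00", "chr2", 500)

    def test_no_calls_false(self):
        _, panel = self._calls_and_panel()
        assert not overlay_deletion_check([], panel, "P00", "chr1", 100)
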
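from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import candidate_matches, panel_subsets
from phthalscreen.chem_core import DiagnosticIonSet
from phthalscreen.msdata_io import AcquisitionRun, SpectrumRecord
from phthalscreen.prioritize import (
    FilterConfig,
    PrecursorCandidate,
    REASON_INTENSITY,
    STATUS_CANDIDATE,
    STATUS_FALSE_POSITIVE,
    STATUS_FILTERED,
    blank_filter,
    candidates_to_frame,
    confirm_candidates,
    diagnostic_ion_match,
    export_inclusion_list,
    prioritize_dda,
    prioritize_dia,
)
from phthalscreen.synth import SimulationConfig, default_panel, simulate_dda, simulate_dia

DIAG = DiagnosticIonSet()


def ms2(fragments, precursor=277.1445, rt=1.0, idx=0):
    mz = np.sort(np.array([m for m, _ in fragments]))
    inten = np.array([i for _, i in sorted(fragments)])
    return SpectrumRecord(idx, rt, 2, mz, inten, precursor_mz=precursor)


class TestDiagnosticIonMatch:
    def test_two_of_three_matched(self):
        spec = ms2([(121.0295, 1e5), (165.0193, 5e4)])
        matched = diagnostic_ion_match(spec, DIAG.native_trio, 5.0)
        assert set(matched) == {121.0295, 165.0193}

    def test_empty_spectrum(self):
        spec = SpectrumRecord(0, 1.0, 2, np.array([]), np.array([]),
                              precursor_mz=300.0)
        assert diagnostic_ion_match(spec, DIAG.native_trio, 5.0) == {}

    def test_most_intense_centroid_wins_inside_window(self):
        spec = ms2([(121.02948, 1e4), (121.02953, 9e4)])
        matched = diagnostic_ion_match(spec, (121.0295,), 5.0)
        assert matched[121.0295][1] == pytest.approx(9e4)

    def test_supplementary_ion_flags_alkyl_subclass(self, sim_config):
        run, _ = simulate_dda(sim_config)
        cands = prioritize_dda(run)
        alkyl = [c for c in cands if c.supplementary_flag]
        assert alkyl  # pure-alkyl monoesters carry the m/z 134.0377 channel
        hydroxy_mz = next(
            a.anion_mz for a in sim_config.panel
            if a.name == "mono-5-hydroxyhexyl phthalate"
        )
        for c in cands:
            if abs(c.mz - hydroxy_mz) <= 5e-6 * hydroxy_mz:
                assert not c.supplementary_flag


class TestDdaPrioritization:
    def test_two_of_three_rule_sets_status(self, sim_config):
        run, _ = simulate_dda(sim_config)
        cands = prioritize_dda(run, sample_id="qc")
        natives, decoys, _ = panel_subsets(sim_config)
        for a in natives:
            assert candidate_matches(a, cands, STATUS_CANDIDATE), a.name
        for d in decoys:
            assert not candidate_matches(d, cands, STATUS_CANDIDATE), d.name
            assert candidate_matches(d, cands, STATUS_FALSE_POSITIVE), d.name

    def test_no_candidate_below_two_matches(self, sim_config):
        run, _ = simulate_dda(sim_config)
        for c in prioritize_dda(run):
            if c.status == STATUS_CANDIDATE:
                assert len(set(c.matched_diagnostic_ions)
                           & set(DIAG.native_trio)) >= 2

    def test_filter_reasons_account_for_all_drops(self, sim_config):
        run, _ = simulate_dda(sim_config)
        cands = prioritize_dda(run)
        dropped = [c for c in cands if c.status == STATUS_FILTERED]
        assert all(c.filter_reason for c in dropped)
        statuses = {c.status for c in cands}
        assert statuses <= {STATUS_CANDIDATE, STATUS_FALSE_POSITIVE,
                            STATUS_FILTERED}

    def test_low_intensity_analyte_filtered_with_reason(self):
        panel = [replace(default_panel()[0], ms1_apex_intensity=4e5)]
        cfg = SimulationConfig(panel=panel, run_length_min=5.0,
                               n_matrix_interferents=0)
        run, _ = simulate_dda(cfg)
        cands = prioritize_dda(run)
        target = [
            c for c in cands
            if abs(c.mz - panel[0].anion_mz) <= 5e-6 * panel[0].anion_mz
        ]
        assert target
        assert all(c.status == STATUS_FILTERED for c in target)
        assert all(c.filter_reason == REASON_INTENSITY for c in target)

    def test_requires_ms2_scans(self):
        run = AcquisitionRun(
            [SpectrumRecord(0, 0.0, 1, np.array([200.0]), np.array([1.0]))],
            mode="DDA",
        )
        with pytest.raises(ValueError, match="MS2"):
            prioritize_dda(run)


class TestDiaPrioritization:
    def test_provisional_then_confirmed(self, sim_config):
        runs = simulate_dia(sim_config)
        prov = prioritize_dia(runs[0.0], {20.0: runs[20.0], 40.0: runs[40.0]})
        assert all(
            c.status in {"provisional", STATUS_FILTERED} for c in prov
        )
        natives, decoys, _ = panel_subsets(sim_config)
        for a in natives:
            assert candidate_matches(a, prov, "provisional"), a.name
        targeted, _ = simulate_dda(sim_config, seed=sim_config.seed + 1)
        conf = confirm_candidates(prov, targeted)
        for a in natives:
            assert candidate_matches(a, conf, STATUS_CANDIDATE), a.name
        for d in decoys:
            assert not candidate_matches(d, conf, STATUS_CANDIDATE), d.name

    def test_all_blank_run_gives_no_precursors(self):
        cfg = SimulationConfig(panel=[], run_length_min=3.0,
                               n_matrix_interferents=0)
        runs = simulate_dia(cfg)
        prov = prioritize_dia(runs[0.0], {20.0: runs[20.0], 40.0: runs[40.0]})
        assert [c for c in prov if c.status == "provisional"] == []

    def test_missing_ce0_channel_is_an_error(self, sim_config):
        runs = simulate_dia(sim_config)
        with pytest.raises(ValueError, match="CE = 0"):
            prioritize_dia(runs[20.0], {40.0: runs[40.0]})

    def test_unconfirmed_provisionals_warn(self, sim_config):
        prov = [PrecursorCandidate(mz=300.0, rt_min=5.0, intensity=1e6,
                                   mode="DIA")]
        empty = AcquisitionRun([], mode="DDA")
        with pytest.warns(UserWarning, match="provisional"):
            confirm_candidates(prov, empty)
        assert prov[0].status == "provisional"


class TestBlankFilter:
    @pytest.mark.parametrize(
        "feature, blanks, keep",
        [
            (3.0e6, [1.0e6, 1.0e6, 1.0e6], True),   # exactly 3x: kept
            (2.9e6, [1.0e6, 1.0e6, 1.0e6], False),
            (1.0e3, [], True),                       # absent from blanks
            (1.0e3, [0.0, 0.0, 0.0], True),
        ],
    )
    def test_three_times_rule(self, feature, blanks, keep):
        assert blank_filter(feature, blanks, ratio=3.0) is keep

    def test_max_aggregation_is_stricter(self):
        blanks = [1.0e6, 2.0e6, 3.0e6]
        assert blank_filter(6.5e6, blanks, 3.0, aggregate="mean")
        assert not blank_filter(6.5e6, blanks, 3.0, aggregate="max")

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            blank_filter(1.0, [1.0], ratio=0.0)


class TestInclusionList:
    def test_single_candidate_row(self, tmp_path):
        cand = PrecursorCandidate(mz=321.1709, rt_min=12.66, intensity=1e6,
                                  mode="DIA")
        df = export_inclusion_list([cand], tmp_path / "incl.csv")
        assert len(df) == 1
        row = df.iloc[0]
        assert row.Mass == pytest.approx(321.1709)
        assert row.Start == pytest.approx(12.16)
        assert row.End == pytest.approx(13.16)
        assert row.Species == "[M-H]-" and row.Polarity == "Negative"

    def test_rt_window_clipped_at_zero(self, tmp_path):
        cand = PrecursorCandidate(mz=200.0, rt_min=0.2, intensity=1e6,
                                  mode="DIA")
        df = export_inclusion_list([cand], tmp_path / "incl.csv")
        assert df.iloc[0].Start == 0.0

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "incl.csv"
        export_inclusion_list([], path)
        back = pd.read_csv(path)
        assert list(back.columns) == [
            "Mass", "Formula", "Species", "CS", "Polarity", "Start", "End"
        ]
        assert back.empty

    def test_row_count_matches_provisionals(self, sim_config, tmp_path):
        runs = simulate_dia(sim_config)
        prov = prioritize_dia(runs[0.0], {20.0: runs[20.0], 40.0: runs[40.0]})
        provisional = [c for c in prov if c.status == "provisional"]
        df = export_inclusion_list(provisional, tmp_path / "incl.csv")
        assert len(df) == len(provisional)


class TestModeAgreement:
    def test_dda_and_dia_recover_the_same_analyte_set(self, sim_config):
        """Both acquisition modes confirm the same planted monophthalates."""
        natives, _, _ = panel_subsets(sim_config)
        run, _ = simulate_dda(sim_config)
        dda_set = {
            a.name for a in natives
            if candidate_matches(a, prioritize_dda(run), STATUS_CANDIDATE)
        }
        runs = simulate_dia(sim_config)
        prov = prioritize_dia(runs[0.0], {20.0: runs[20.0], 40.0: runs[40.0]})
        targeted, _ = simulate_dda(sim_config, seed=sim_config.seed + 1)
        conf = confirm_candidates(prov, targeted)
        dia_set = {
            a.name for a in natives
            if candidate_matches(a, conf, STATUS_CANDIDATE)
        }
        assert dda_set == dia_set == {a.name for a in natives}


class TestLabelledStandardQC:
    def test_spiked_standards_fully_identified(self, sim_config):
        """All 14 spiked labelled standards recovered via the labelled trio."""
        from phthalscreen.stats_compare import identification_efficiency

        _, _, labelled = panel_subsets(sim_config)
        run, _ = simulate_dda(sim_config)
        cands = prioritize_dda(run, trio="labelled")
        identified = [
            a.name for a in labelled
            if candidate_matches(a, cands, STATUS_CANDIDATE)
        ]
        out = identification_efficiency([a.name for a in labelled], identified)
        assert out["efficiency"] == 1.0
        assert out["false_positive_rate"] == 0.0


def test_candidate_frame_is_tabular(sim_config):
    run, _ = simulate_dda(sim_config)
    df = candidates_to_frame(prioritize_dda(run))
    assert {"mz", "rt_min", "status", "top_formula", "ppm_error"} <= set(df.columns)
    assert (df.status == STATUS_CANDIDATE).any()
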
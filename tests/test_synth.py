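from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import panel_subsets
from phthalscreen.chem_core import ElementalFormula
from phthalscreen.msdata_io import extract_eic, read_mzml, write_mzml
from phthalscreen.synth import (
    SimulatedAnalyte,
    SimulationConfig,
    default_panel,
    make_study_fixture,
    simulate_dda,
    simulate_dia,
)


def no_noise_config(panel=None, **kw):
    return SimulationConfig(
        panel=panel if panel is not None else default_panel(),
        noise_peaks_per_scan=0.0,
        noise_floor_intensity=1e-9,
        n_matrix_interferents=0,
        **kw,
    )


class TestDeterminism:
    def test_same_seed_same_mzml_bytes(self, tmp_path, sim_config):
        paths = []
        for i in range(2):
            run, _ = simulate_dda(sim_config)
            d = tmp_path / f"call{i}"
            d.mkdir()
            p = d / "run.mzML"
            write_mzml(run, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seed_differs(self, sim_config):
        r1, _ = simulate_dda(sim_config, seed=1)
        r2, _ = simulate_dda(sim_config, seed=2)
        assert any(
            not np.array_equal(a.mz, b.mz)
            for a, b in zip(r1.spectra, r2.spectra)
        )

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(panel=[], seed=None)


class TestDiaSimulation:
    def test_empty_panel_zero_noise_gives_zero_tic(self):
        cfg = no_noise_config(panel=[], run_length_min=2.0)
        runs = simulate_dia(cfg)
        for run in runs.values():
            assert all(s.total_intensity == 0.0 for s in run.spectra)

    def test_ion_current_conserved_across_fragmentation(self):
        """Intact + fragment intensity equals the CE=0 intensity per scan."""
        cfg = no_noise_config(run_length_min=4.0)
        runs = simulate_dia(cfg)
        analyte = cfg.panel[1]  # monoethyl phthalate, fragments all in range
        ce0 = extract_eic(runs[0.0], analyte.anion_mz, 5.0)
        for ce in (20.0, 40.0):
            run = runs[ce]
            intact = extract_eic(run, analyte.anion_mz, 5.0)
            frag_sum = np.zeros_like(intact.intensity)
            for fmz in analyte.fragmentation_template:
                frag_sum = frag_sum + extract_eic(run, fmz, 5.0).intensity
            total = intact.intensity + frag_sum
            mask = ce0.intensity > 1e3
            np.testing.assert_allclose(
                total[mask], ce0.intensity[mask], rtol=1e-6
            )

    def test_fragment_fraction_grows_with_ce(self):
        cfg = no_noise_config(run_length_min=4.0)
        runs = simulate_dia(cfg)
        analyte = cfg.panel[1]
        apex20 = extract_eic(runs[20.0], analyte.anion_mz, 5.0).intensity.max()
        apex40 = extract_eic(runs[40.0], analyte.anion_mz, 5.0).intensity.max()
        assert apex40 < apex20  # more current moved to fragments at 40 V

    def test_channel_scan_ranges(self, sim_config):
        runs = simulate_dia(sim_config)
        assert runs[0.0].scan_range == (150.0, 1000.0)
        assert runs[20.0].scan_range == (50.0, 500.0)
        for s in runs[20.0].spectra:
            if s.mz.size:
                assert s.mz.min() >= 50.0 and s.mz.max() <= 500.0


class TestDdaSimulation:
    def test_event_log_honors_top_n(self, sim_config):
        _, events = simulate_dda(sim_config)
        per_cycle: dict[int, int] = {}
        for e in events:
            per_cycle[e["cycle"]] = per_cycle.get(e["cycle"], 0) + 1
        assert max(per_cycle.values()) <= sim_config.dda.top_n

    def test_event_log_honors_trigger_threshold(self, sim_config):
        _, events = simulate_dda(sim_config)
        assert min(e["ms1_intensity"] for e in events) >= (
            sim_config.dda.trigger_threshold
        )

    def test_event_log_honors_dynamic_exclusion(self, sim_config):
        _, events = simulate_dda(sim_config)
        excl_min = sim_config.dda.dynamic_exclusion_s / 60.0
        by_time = sorted(events, key=lambda e: e["selected_at_rt_min"])
        for i, e1 in enumerate(by_time):
            for e2 in by_time[i + 1:]:
                gap = e2["selected_at_rt_min"] - e1["selected_at_rt_min"]
                if gap >= excl_min:
                    break
                assert (
                    abs(e1["precursor_mz"] - e2["precursor_mz"])
                    > 5e-6 * e1["precursor_mz"]
                ), (e1, e2)

    def test_single_analyte_fragmented_at_first_eligible_scan(self):
        cfg = no_noise_config(panel=default_panel()[:1], run_length_min=4.0)
        run, events = simulate_dda(cfg)
        analyte = cfg.panel[0]
        assert events
        first = min(events, key=lambda e: e["rt_min"])
        # first selection as soon as the rising flank crosses the trigger
        z = np.sqrt(2 * np.log(analyte.ms1_apex_intensity
                               / cfg.dda.trigger_threshold))
        t_cross = analyte.rt_min - z * analyte.peak_sigma_min
        assert first["rt_min"] >= t_cross - 1e-9
        assert first["rt_min"] <= t_cross + 2 * cfg.scan_interval_s / 60.0

    def test_analyte_below_trigger_never_fragmented(self):
        weak = replace(default_panel()[0], ms1_apex_intensity=1.5e5)
        cfg = no_noise_config(panel=[weak], run_length_min=4.0)
        _, events = simulate_dda(cfg)
        assert events == []

    def test_coeluting_burst_all_fragmented_across_cycles(self):
        """7 co-eluting precursors > TopN all get MS2 within the elution."""
        panel = [
            SimulatedAnalyte(
                name=f"co-{i}",
                neutral_formula=ElementalFormula(12 + i, 14 + 2 * i, 4),
                rt_min=5.0,
                ms1_apex_intensity=5e6,
                fragmentation_template={121.0295: 1.0, 147.0088: 0.5},
            )
            for i in range(7)
        ]
        cfg = no_noise_config(panel=panel, run_length_min=8.0)
        run, events = simulate_dda(cfg)
        per_cycle: dict[int, int] = {}
        for e in events:
            per_cycle[e["cycle"]] = per_cycle.get(e["cycle"], 0) + 1
        assert max(per_cycle.values()) <= cfg.dda.top_n
        selected = set()
        for e in events:
            for a in panel:
                if abs(e["precursor_mz"] - a.anion_mz) <= 5e-6 * a.anion_mz:
                    selected.add(a.name)
        assert selected == {a.name for a in panel}

    def test_decoy_must_emit_exactly_one_trio_ion(self):
        with pytest.raises(ValueError, match="exactly one"):
            SimulatedAnalyte(
                name="bad-decoy",
                neutral_formula=ElementalFormula(12, 14, 4),
                rt_min=5.0,
                ms1_apex_intensity=1e6,
                fragmentation_template={121.0295: 1.0, 147.0088: 0.5},
                is_decoy=True,
            )


class TestStudyFixture:
    def test_layout_and_truth_tables(self, study):
        assert len(study["runs"]) >= 10
        panel = pd.read_csv(study["truth"]["panel"])
        assert panel.is_decoy.sum() == 5
        assert panel.labelled.sum() == 14
        assert (~panel.is_decoy & ~panel.labelled).sum() == 10
        diff = pd.read_csv(study["truth"]["differential"])
        assert set(diff.expected_label) == {"up", "down", "unchanged"}

    def test_blanks_carry_only_contamination(self, study, sim_config):
        run = read_mzml(study["runs"]["dda_blank_1"])
        natives, decoys, labelled = panel_subsets(sim_config)
        a = natives[1]
        trace = extract_eic(run, a.anion_mz, 5.0)
        blank_apex = trace.intensity.max()
        assert blank_apex < 0.1 * a.ms1_apex_intensity
        assert blank_apex > 0  # carryover planted
        lab_trace = extract_eic(run, labelled[0].anion_mz, 5.0)
        assert lab_trace.intensity.max() < 1e4  # no labelled spike in blanks

    def test_zero_contamination_blanks_are_clean(self, tmp_path, sim_config):
        cfg = replace(
            sim_config,
            panel=sim_config.panel[:2],
            run_length_min=5.0,
            blank_contamination_fraction=0.0,
        )
        man = make_study_fixture(cfg, tmp_path / "fx")
        run = read_mzml(man["runs"]["dda_blank_1"])
        for a in cfg.panel:
            trace = extract_eic(run, a.anion_mz, 5.0)
            assert trace.intensity.max() < 1e4

    def test_replicate_truth_matches_written_runs(self, study):
        reps = pd.read_csv(study["truth"]["replicates"])
        row = reps[(reps.run == "dda_groupA_1")].iloc[0]
        run = read_mzml(study["runs"]["dda_groupA_1"])
        trace = extract_eic(run, row.mz, 5.0)
        assert trace.intensity.max() == pytest.approx(
            row.apex_intensity, rel=0.05
        )
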
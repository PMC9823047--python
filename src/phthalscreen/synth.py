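"""Synthetic Q-Exactive-style acquisitions of a monophthalate panel.

The simulator emulates the two acquisition geometries used for non-targeted
screening of phthalate metabolites in urine:

* DIA: full-scan runs repeated at in-source collision energies 0/20/40 V
  (scan range 150-1000 m/z at 0 V, 50-500 m/z at elevated energies). At
  CE > 0 a fraction of each analyte's ion current is redistributed from the
  intact [M-H]- into its diagnostic-fragment template.
* DDA: interleaved full-scan MS1 + TopN ddMS2 (TopN 5, 1.5 m/z isolation,
  2e5 trigger threshold, 3.0 s dynamic exclusion, NCE 15/35/50 summed into
  one MS2 spectrum).

Analytes elute as Gaussian peaks; the panel includes native monophthalates,
ring-labelled (13C4) internal standards whose fragments fall on the labelled
diagnostic trio, and decoy interferents that emit exactly one diagnostic ion
(the failure mode the two-of-three rule exists to reject). Runs are written
as standard centroid mzML, and every generated quantity is recorded in
ground-truth tables, so each downstream stage can be verified against what
was planted. All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_core import ElementalFormula, anion_mz
from .msdata_io import AcquisitionRun, SpectrumRecord, write_mzml

__all__ = [
    "SimulatedAnalyte",
    "DdaSettings",
    "DiaSettings",
    "SimulationConfig",
    "default_panel",
    "simulate_dia",
    "simulate_dda",
    "make_study_fixture",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20221108

NATIVE_TRIO = (121.0295, 147.0088, 165.0193)
SUPPLEMENTARY_ION = 134.0377
LABELLED_TRIO = (124.0397, 151.0223, 169.0329)


@dataclass(frozen=True)
class SimulatedAnalyte:
    """One compound planted in the simulation.

    ``fragmentation_template`` maps fragment m/z to relative intensity in
    [0, 1]; weights are normalized at simulation time so that the fragment
    channels share the fragmented ion current. Decoys carry exactly one
    nonzero native-trio fragment.
    """

    name: str
    neutral_formula: ElementalFormula
    rt_min: float
    ms1_apex_intensity: float
    fragmentation_template: dict[float, float]
    peak_sigma_min: float = 0.05
    labelled: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if any(not (0.0 <= w <= 1.0) for w in self.fragmentation_template.values()):
            raise ValueError("template intensities must lie in [0, 1]")
        if self.labelled and self.neutral_formula.n_carbon13 == 0:
            raise ValueError("labelled analytes must carry 13C substitutions")
        if self.is_decoy:
            trio_hits = sum(
                1 for m in self.fragmentation_template if m in NATIVE_TRIO
            )
            if trio_hits != 1:
                raise ValueError(
                    "decoys must emit exactly one native-trio diagnostic ion"
                )

    @property
    def anion_mz(self) -> float:
        return anion_mz(self.neutral_formula.deprotonated())

    def intensity_at(self, t: np.ndarray | float) -> np.ndarray | float:
        z = (np.asarray(t) - self.rt_min) / self.peak_sigma_min
        return self.ms1_apex_intensity * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class DdaSettings:
    top_n: int = 5
    trigger_threshold: float = 2e5
    dynamic_exclusion_s: float = 3.0
    isolation_width_mz: float = 1.5
    nce_levels: tuple[float, ...] = (15.0, 35.0, 50.0)
    scan_range_ms1: tuple[float, float] = (150.0, 800.0)
    scan_range_ms2: tuple[float, float] = (50.0, 500.0)


@dataclass(frozen=True)
class DiaSettings:
    ce_levels_v: tuple[float, ...] = (0.0, 20.0, 40.0)
    scan_range_ce0: tuple[float, float] = (150.0, 1000.0)
    scan_range_frag: tuple[float, float] = (50.0, 500.0)
    ce_saturation_v: float = 40.0  # fraction fragmented = CE / saturation, capped at 1


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample."""

    panel: list[SimulatedAnalyte]
    run_length_min: float = 12.0
    scan_interval_s: float = 1.0
    noise_floor_intensity: float = 1e3
    noise_peaks_per_scan: float = 15.0
    n_matrix_interferents: int = 20
    blank_contamination_fraction: float = 0.02
    replicates_per_group: int = 3
    seed: int = DEFAULT_SEED
    dda: DdaSettings = field(default_factory=DdaSettings)
    dia: DiaSettings = field(default_factory=DiaSettings)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory; all outputs are reproducible")
        if self.dda.top_n < 1 or self.dda.dynamic_exclusion_s < 0:
            raise ValueError("invalid DDA settings")


# ---------------------------------------------------------------------------
# Default panel: 10 native monophthalates, 5 decoys, 14 labelled standards.


def _mono(name, c, h, o, rt, apex, alkyl=False, sigma=0.05):
    template = {NATIVE_TRIO[0]: 1.0, NATIVE_TRIO[1]: 0.6, NATIVE_TRIO[2]: 0.35}
    if alkyl:
        template[SUPPLEMENTARY_ION] = 0.25
    return SimulatedAnalyte(
        name=name,
        neutral_formula=ElementalFormula(c, h, o),
        rt_min=rt,
        ms1_apex_intensity=apex,
        fragmentation_template=template,
        peak_sigma_min=sigma,
    )


def _decoy(name, c, h, o, rt, apex, ion=NATIVE_TRIO[0]):
    return SimulatedAnalyte(
        name=name,
        neutral_formula=ElementalFormula(c, h, o),
        rt_min=rt,
        ms1_apex_intensity=apex,
        fragmentation_template={ion: 1.0},
        is_decoy=True,
    )


def _labelled(name, c, h, o, rt, apex, n13=4):
    return SimulatedAnalyte(
        name=name,
        neutral_formula=ElementalFormula(c, h, o, n_carbon13=n13),
        rt_min=rt,
        ms1_apex_intensity=apex,
        fragmentation_template={
            LABELLED_TRIO[0]: 1.0,
            LABELLED_TRIO[1]: 0.6,
            LABELLED_TRIO[2]: 0.35,
        },
        labelled=True,
    )


def default_panel() -> list[SimulatedAnalyte]:
    """The default study panel (RTs in minutes, apexes in counts)."""
    natives = [
        _mono("monomethyl phthalate", 9, 8, 4, 2.90, 6.0e6, alkyl=True),
        _mono("monoethyl phthalate", 10, 10, 4, 3.80, 8.0e6, alkyl=True),
        _mono("monoisobutyl phthalate", 12, 14, 4, 5.30, 4.5e6, alkyl=True),
        _mono("monobutyl phthalate", 12, 14, 4, 5.75, 9.0e6, alkyl=True),
        _mono("mono-5-hydroxyhexyl phthalate", 14, 18, 5, 6.50, 3.0e6),
        _mono("monohexyl phthalate", 14, 18, 4, 7.40, 5.0e6, alkyl=True),
        _mono("mono-2-ethyl-5-oxohexyl phthalate", 16, 20, 5, 8.45, 2.5e6),
        _mono("monoheptyl phthalate", 15, 20, 4, 9.20, 4.0e6, alkyl=True),
        _mono("monobenzyl phthalate", 15, 12, 4, 9.80, 7.0e6),
        _mono("mono-2-ethylhexyl phthalate", 16, 22, 4, 10.40, 1.2e7, alkyl=True),
    ]
    decoys = [
        _decoy("decoy-1 (hydroxycinnamate ester)", 13, 16, 4, 4.50, 3.0e6),
        _decoy("decoy-2 (dicarboxy aromatic)", 14, 16, 5, 6.05, 2.5e6,
               ion=NATIVE_TRIO[1]),
        _decoy("decoy-3 (aryl glucuronide-like)", 15, 18, 6, 7.00, 2.0e6),
        _decoy("decoy-4 (alkylresorcinol acid)", 12, 12, 4, 3.30, 4.0e6,
               ion=NATIVE_TRIO[2]),
        _decoy("decoy-5 (furanone conjugate)", 16, 20, 7, 11.00, 3.5e6),
    ]
    labelled_specs = [
        ("13C4-monomethyl phthalate", 9, 8, 4, 2.90),
        ("13C4-monoethyl phthalate", 10, 10, 4, 3.80),
        ("13C4-monopropyl phthalate", 11, 12, 4, 4.70),
        ("13C4-monoisobutyl phthalate", 12, 14, 4, 5.30),
        ("13C4-monobutyl phthalate", 12, 14, 4, 5.75),
        ("13C4-monopentyl phthalate", 13, 16, 4, 6.30),
        ("13C4-mono-5-hydroxyhexyl phthalate", 14, 18, 5, 6.50),
        ("13C4-monohexyl phthalate", 14, 18, 4, 7.40),
        ("13C4-mono-5-oxohexyl phthalate", 14, 16, 5, 7.85),
        ("13C4-mono-2-ethyl-5-oxohexyl phthalate", 16, 20, 5, 8.45),
        ("13C4-monoheptyl phthalate", 15, 20, 4, 9.20),
        ("13C4-monobenzyl phthalate", 15, 12, 4, 9.80),
        ("13C4-mono-2-ethylhexyl phthalate", 16, 22, 4, 10.40),
        ("13C4-monooctyl phthalate", 16, 22, 4, 11.30),
    ]
    labelled = [
        _labelled(name, c, h, o, rt, 1.2e6)
        for name, c, h, o, rt in labelled_specs
    ]
    return natives + decoys + labelled


# ---------------------------------------------------------------------------
# Spectrum assembly helpers


def _make_interferents(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[float, float, float, float]]:
    """Random matrix peaks: (mz, rt, apex, sigma)."""
    n = config.n_matrix_interferents
    return list(
        zip(
            rng.uniform(160.0, 780.0, n),
            rng.uniform(0.5, config.run_length_min - 0.5, n),
            10 ** rng.uniform(4.0, 6.0, n),
            np.full(n, 0.05),
        )
    )


def _noise_peaks(
    rng: np.random.Generator,
    config: SimulationConfig,
    scan_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    n = rng.poisson(config.noise_peaks_per_scan)
    mz = rng.uniform(scan_range[0], scan_range[1], n)
    inten = rng.exponential(config.noise_floor_intensity, n) + 1.0
    return mz, inten


def _assemble(mz_parts, int_parts) -> tuple[np.ndarray, np.ndarray]:
    mz = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in mz_parts])
    it = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in int_parts])
    order = np.argsort(mz, kind="stable")
    return mz[order], it[order]

_MIN_EMIT = 1.0  # counts; Gaussian tails below this are not emitted


def _normalized_template(a: SimulatedAnalyte) -> list[tuple[float, float]]:
    total = sum(a.fragmentation_template.values())
    return [(mz, w / total) for mz, w in a.fragmentation_template.items()]


# ---------------------------------------------------------------------------
# DIA


def simulate_dia(
    config: SimulationConfig, seed: int | None = None
) -> dict[float, AcquisitionRun]:
    """Simulate one DIA acquisition set: one full-scan run per CE channel.

    At CE = 0 analytes appear as intact [M-H]- centroids; at CE > 0 a
    fraction CE/``ce_saturation_v`` (capped at 1) of each analyte's current
    moves into its fragment template, the remainder staying on the intact
    ion. Before noise, intact + fragment intensity equals the CE = 0
    intensity in every scan (ion-current conservation). Analytes whose
    precursor falls outside a channel's scan range are skipped in that
    channel with a warning.
    """
    seed = config.seed if seed is None else seed
    times = np.arange(
        0.0, config.run_length_min, config.scan_interval_s / 60.0
    )
    runs: dict[float, AcquisitionRun] = {}
    for ce in config.dia.ce_levels_v:
        rng = np.random.default_rng((seed, int(ce * 1000), 7))
        scan_range = (
            config.dia.scan_range_ce0 if ce == 0 else config.dia.scan_range_frag
        )
        interferents = _make_interferents(config, rng)
        frac = min(ce / config.dia.ce_saturation_v, 1.0) if ce > 0 else 0.0
        spectra = []
        for i, t in enumerate(times):
            mz_parts, int_parts = [], []
            for a in config.panel:
                inten = float(a.intensity_at(t))
                if inten < _MIN_EMIT:
                    continue
                prec = a.anion_mz
                intact = inten * (1.0 - frac)
                if scan_range[0] <= prec <= scan_range[1] and intact >= _MIN_EMIT:
                    mz_parts.append(prec)
                    int_parts.append(intact)
                if frac > 0:
                    for fmz, w in _normalized_template(a):
                        fi = inten * frac * w
                        if (
                            scan_range[0] <= fmz <= scan_range[1]
                            and fi >= _MIN_EMIT
                        ):
                            mz_parts.append(fmz)
                            int_parts.append(fi)
            if ce == 0:
                for imz, irt, iapex, isig in interferents:
                    ii = iapex * math.exp(-0.5 * ((t - irt) / isig) ** 2)
                    if ii >= _MIN_EMIT and scan_range[0] <= imz <= scan_range[1]:
                        mz_parts.append(imz)
                        int_parts.append(ii)
            nmz, nint = _noise_peaks(rng, config, scan_range)
            mz_parts.append(nmz)
            int_parts.append(nint)
            mz, inten = _assemble(mz_parts, int_parts)
            spectra.append(
                SpectrumRecord(
                    scan_index=i, rt_min=float(t), ms_level=1,
                    mz=mz, intensity=inten, in_source_ce_v=float(ce),
                )
            )
        runs[ce] = AcquisitionRun(
            spectra=spectra,
            mode="DIA_channel",
            channel_ce_v=float(ce),
            scan_range=scan_range,
            metadata={"resolution": "70000" if ce == 0 else "35000"},
        )
    return runs


# ---------------------------------------------------------------------------
# DDA


def simulate_dda(
    config: SimulationConfig,
    seed: int | None = None,
    fragment_efficiency: float = 0.85,
) -> tuple[AcquisitionRun, list[dict]]:
    """Simulate a full-scan ddMS2 (TopN) acquisition.

    After each MS1 scan, up to ``top_n`` centroids above the trigger
    threshold that are not on the dynamic-exclusion list are isolated in
    decreasing intensity order; each yields one MS2 spectrum combining the
    fragment templates of every panel analyte inside the isolation window
    (the NCE levels are summed into a single spectrum, as acquired).
    Selected precursors are excluded for ``dynamic_exclusion_s`` seconds.
    Returns the run and an event log with one record per isolation.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng((seed, 11))
    s = config.dda
    dt_min = config.scan_interval_s / 60.0
    times = np.arange(0.0, config.run_length_min, dt_min)
    interferents = _make_interferents(config, rng)

    spectra: list[SpectrumRecord] = []
    events: list[dict] = []
    exclusion: list[tuple[float, float]] = []  # (mz, time_selected_min)
    scan_index = 0
    for cycle, t in enumerate(times):
        mz_parts, int_parts = [], []
        for a in config.panel:
            inten = float(a.intensity_at(t))
            prec = a.anion_mz
            if inten >= _MIN_EMIT and s.scan_range_ms1[0] <= prec <= s.scan_range_ms1[1]:
                mz_parts.append(prec)
                int_parts.append(inten)
        for imz, irt, iapex, isig in interferents:
            ii = iapex * math.exp(-0.5 * ((t - irt) / isig) ** 2)
            if ii >= _MIN_EMIT and s.scan_range_ms1[0] <= imz <= s.scan_range_ms1[1]:
                mz_parts.append(imz)
                int_parts.append(ii)
        nmz, nint = _noise_peaks(rng, config, s.scan_range_ms1)
        mz_parts.append(nmz)
        int_parts.append(nint)
        mz, inten = _assemble(mz_parts, int_parts)
        spectra.append(
            SpectrumRecord(
                scan_index=scan_index, rt_min=float(t), ms_level=1,
                mz=mz, intensity=inten,
            )
        )
        scan_index += 1

        # TopN selection
        excl_window_min = s.dynamic_exclusion_s / 60.0
        order = np.argsort(inten)[::-1]
        n_selected = 0
        ms2_dt = dt_min / (s.top_n + 1)
        for j in order:
            if n_selected >= s.top_n:
                break
            if inten[j] < s.trigger_threshold:
                break
            cand_mz = mz[j]
            tol = 5e-6 * cand_mz
            if any(
                abs(cand_mz - emz) <= tol and (t - et) < excl_window_min
                for emz, et in exclusion
            ):
                continue
            n_selected += 1
            ms2_rt = t + n_selected * ms2_dt
            exclusion.append((cand_mz, t))
            events.append(
                {
                    "cycle": cycle,
                    "rt_min": float(ms2_rt),
                    "selected_at_rt_min": float(t),
                    "precursor_mz": float(cand_mz),
                    "ms1_intensity": float(inten[j]),
                }
            )
            fmz_parts, fint_parts = [], []
            half = s.isolation_width_mz / 2.0
            for a in config.panel:
                if abs(a.anion_mz - cand_mz) > half:
                    continue
                ai = float(a.intensity_at(ms2_rt))
                if ai < _MIN_EMIT:
                    continue
                for fmz, w in _normalized_template(a):
                    fi = ai * fragment_efficiency * w
                    if fi >= _MIN_EMIT and s.scan_range_ms2[0] <= fmz <= s.scan_range_ms2[1]:
                        fmz_parts.append(fmz)
                        fint_parts.append(fi)
                residual = ai * (1.0 - fragment_efficiency)
                if (
                    residual >= _MIN_EMIT
                    and s.scan_range_ms2[0] <= a.anion_mz <= s.scan_range_ms2[1]
                ):
                    fmz_parts.append(a.anion_mz)
                    fint_parts.append(residual)
            n_noise = rng.poisson(3)
            fmz_parts.append(rng.uniform(*s.scan_range_ms2, n_noise))
            fint_parts.append(
                rng.exponential(config.noise_floor_intensity / 2, n_noise) + 1.0
            )
            fmz, fint = _assemble(fmz_parts, fint_parts)
            spectra.append(
                SpectrumRecord(
                    scan_index=scan_index,
                    rt_min=float(ms2_rt),
                    ms_level=2,
                    mz=fmz,
                    intensity=fint,
                    precursor_mz=float(cand_mz),
                    isolation_width_mz=s.isolation_width_mz,
                    nce=s.nce_levels,
                )
            )
            scan_index += 1
        # prune stale exclusion entries
        exclusion = [
            (emz, et) for emz, et in exclusion if (t - et) < excl_window_min
        ]

    run = AcquisitionRun(
        spectra=spectra,
        mode="DDA",
        scan_range=s.scan_range_ms1,
        metadata={"top_n": str(s.top_n),
                  "trigger_threshold": str(s.trigger_threshold),
                  "dynamic_exclusion_s": str(s.dynamic_exclusion_s)},
    )
    return run, events


# ---------------------------------------------------------------------------
# Study fixture


#: Group-B / group-A intensity fold changes planted in the default fixture.
DEFAULT_FOLD_CHANGES = {
    "monomethyl phthalate": 25.0,
    "mono-5-hydroxyhexyl phthalate": 2.5,
    "monohexyl phthalate": 2.5,
    "monoethyl phthalate": 0.4,
}

_REPLICATE_CV = 0.05  # lognormal replicate scatter


def _perturbed_panel(
    panel: list[SimulatedAnalyte],
    rng: np.random.Generator,
    fold: dict[str, float],
    include_labelled: bool,
    scale: float = 1.0,
) -> list[SimulatedAnalyte]:
    out = []
    for a in panel:
        if a.labelled and not include_labelled:
            continue
        f = fold.get(a.name, 1.0)
        rep = float(rng.lognormal(mean=0.0, sigma=_REPLICATE_CV))
        out.append(
            replace(a, ms1_apex_intensity=a.ms1_apex_intensity * f * rep * scale)
        )
    return out


def make_study_fixture(
    config: SimulationConfig | None = None,
    outdir: str | Path = "fixture",
    fold_changes: dict[str, float] | None = None,
) -> dict:
    """Write the full synthetic study to ``outdir`` and return a manifest.

    Layout mirrors the study design: three DDA replicates per pooled-urine
    group (A = fertile, B = infertile with the configured fold changes),
    three procedural blanks carrying ``blank_contamination_fraction`` of
    each native analyte, one spiked QC run, one DIA channel set plus its
    targeted ddMS2 re-run, and ground-truth CSVs (panel, per-replicate
    intensities, expected differential labels). Labelled standards are
    spiked into every non-blank run.
    """
    config = config if config is not None else SimulationConfig(panel=default_panel())
    fold = DEFAULT_FOLD_CHANGES if fold_changes is None else fold_changes
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng((config.seed, 99))

    manifest: dict = {"runs": {}, "truth": {}, "seed": config.seed}
    replicate_rows = []

    def _write(tag: str, panel: list[SimulatedAnalyte], sub_seed: int,
               dia: bool = False) -> None:
        cfg = replace(config, panel=panel)
        if dia:
            runs = simulate_dia(cfg, seed=sub_seed)
            for ce, run in runs.items():
                p = outdir / f"{tag}_ce{int(ce)}.mzML"
                write_mzml(run, p)
                manifest["runs"][f"{tag}_ce{int(ce)}"] = str(p)
            targeted, _ = simulate_dda(cfg, seed=sub_seed + 1)
            p = outdir / f"{tag}_targeted_ms2.mzML"
            write_mzml(targeted, p)
            manifest["runs"][f"{tag}_targeted_ms2"] = str(p)
        else:
            run, events = simulate_dda(cfg, seed=sub_seed)
            p = outdir / f"{tag}.mzML"
            write_mzml(run, p)
            manifest["runs"][tag] = str(p)
            manifest.setdefault("event_logs", {})[tag] = events
        for a in panel:
            replicate_rows.append(
                {
                    "run": tag,
                    "name": a.name,
                    "mz": a.anion_mz,
                    "rt_min": a.rt_min,
                    "apex_intensity": a.ms1_apex_intensity,
                }
            )

    for rep in range(1, config.replicates_per_group + 1):
        rng = np.random.default_rng((config.seed, 1, rep))
        _write(f"dda_groupA_{rep}",
               _perturbed_panel(config.panel, rng, {}, include_labelled=True),
               sub_seed=config.seed + 100 + rep)
    for rep in range(1, config.replicates_per_group + 1):
        rng = np.random.default_rng((config.seed, 2, rep))
        _write(f"dda_groupB_{rep}",
               _perturbed_panel(config.panel, rng, fold, include_labelled=True),
               sub_seed=config.seed + 200 + rep)
    for rep in range(1, config.replicates_per_group + 1):
        rng = np.random.default_rng((config.seed, 3, rep))
        blank_panel = _perturbed_panel(
            [a for a in config.panel if not a.is_decoy],
            rng, {}, include_labelled=False,
            scale=config.blank_contamination_fraction,
        )
        _write(f"dda_blank_{rep}", blank_panel, sub_seed=config.seed + 300 + rep)

    rng = np.random.default_rng((config.seed, 4))
    qc_panel = _perturbed_panel(config.panel, rng, {}, include_labelled=True)
    _write("dda_qc_spiked", qc_panel, sub_seed=config.seed + 400)
    _write("dia_qc", qc_panel, sub_seed=config.seed + 500, dia=True)

    # ground truth
    panel_df = pd.DataFrame(
        [
            {
                "name": a.name,
                "neutral_formula": a.neutral_formula.hill(),
                "anion_mz": a.anion_mz,
                "rt_min": a.rt_min,
                "base_apex_intensity": a.ms1_apex_intensity,
                "labelled": a.labelled,
                "is_decoy": a.is_decoy,
                "fold_change_b_over_a": fold.get(a.name, 1.0),
            }
            for a in config.panel
        ]
    )
    diff_df = panel_df[~panel_df.is_decoy & ~panel_df.labelled].copy()
    diff_df["expected_label"] = np.select(
        [diff_df.fold_change_b_over_a > 2.0, diff_df.fold_change_b_over_a < 0.5],
        ["up", "down"],
        default="unchanged",
    )
    reps_df = pd.DataFrame(replicate_rows)
    for key, df in [
        ("panel", panel_df), ("replicates", reps_df), ("differential", diff_df)
    ]:
        p = outdir / f"truth_{key}.csv"
        df.to_csv(p, index=False)
        manifest["truth"][key] = str(p)
    return manifest
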
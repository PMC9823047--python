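"""Precursor prioritization under the diagnostic-fragment-ion rules.

The screening logic, common to both acquisition modes:

1. the three diagnostic fragments of the monophthalate skeleton locate
   candidate retention times (EICs of the fragment channels in DIA;
   fragment matches inside ddMS2 spectra in DDA);
2. the precursor ion intensity in full-scan data must exceed 5e5 counts;
3. the accurate mass must admit at least one CHO formula inside the
   monophthalate elemental restrictions;
4. a precursor is *confirmed* as a candidate only if its MS/MS spectrum
   contains at least two of the three diagnostic ions — available
   immediately in DDA, but only after a targeted MS/MS re-run for DIA.

Precursors failing step 4 are recorded as false positives; precursors
removed at steps 2-3 carry a machine-readable filter reason. The
supplementary ion m/z 134.0377 flags the pure-alkyl-chain subclass but
never counts toward the two-of-three rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_core import (
    CompositionConstraints,
    DiagnosticIonSet,
    FormulaMatch,
    enumerate_formulas,
)
from .msdata_io import AcquisitionRun, SpectrumRecord, extract_eic
from .peaks import align_across_channels, detect_peaks

__all__ = [
    "PrecursorCandidate",
    "FilterConfig",
    "diagnostic_ion_match",
    "prioritize_dia",
    "prioritize_dda",
    "confirm_candidates",
    "blank_filter",
    "export_inclusion_list",
    "candidates_to_frame",
]

STATUS_PROVISIONAL = "provisional"
STATUS_CANDIDATE = "candidate"
STATUS_FALSE_POSITIVE = "false_positive"
STATUS_FILTERED = "filtered"

REASON_INTENSITY = "intensity_threshold"
REASON_FORMULA = "formula_restriction"


@dataclass
class FilterConfig:
    """Thresholds of the prioritization filters."""

    tic_intensity_threshold: float = 5e5
    dda_match_tol_ppm: float = 5.0
    blank_ratio: float = 3.0
    require_two_of_three: bool = True
    #: floor below which full-scan centroids are not even nominated
    min_nominate_intensity: float = 1e4
    #: DDA duplicate-precursor merge windows
    merge_rt_min: float = 0.1
    merge_tol_ppm: float = 5.0
    #: minimum number of co-eluting diagnostic-ion EICs required before a
    #: DIA consensus RT is pursued (1 = any single diagnostic EIC suffices)
    dia_min_coeluting_ions: int = 1
    blank_aggregate: str = "mean"  # or "max"

    def __post_init__(self) -> None:
        if min(self.tic_intensity_threshold, self.dda_match_tol_ppm,
               self.blank_ratio) <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class PrecursorCandidate:
    """A prioritized [M-H]- precursor with its evidence and filter history."""

    mz: float
    rt_min: float
    intensity: float
    mode: str  # "DIA" | "DDA"
    sample_id: str = ""
    matched_diagnostic_ions: dict[float, tuple[float, float]] = field(
        default_factory=dict
    )  # reference m/z -> (observed m/z, intensity)
    supplementary_flag: bool = False
    formulas: list[FormulaMatch] = field(default_factory=list)
    status: str = STATUS_PROVISIONAL
    filter_reason: str | None = None

    def n_trio_matches(self, diag: DiagnosticIonSet) -> int:
        return len(set(self.matched_diagnostic_ions) & set(diag.native_trio)) or len(
            set(self.matched_diagnostic_ions) & set(diag.labelled_trio)
        )

    def validate(self, diag: DiagnosticIonSet, require_formula: bool = True) -> None:
        if self.status == STATUS_CANDIDATE:
            if self.n_trio_matches(diag) < 2:
                raise ValueError(
                    f"candidate at m/z {self.mz:.4f} has fewer than two "
                    "diagnostic-trio matches"
                )
            if require_formula and not self.formulas:
                raise ValueError(
                    f"candidate at m/z {self.mz:.4f} has no surviving formula"
                )
        if self.status == STATUS_FILTERED and not self.filter_reason:
            raise ValueError("filtered precursor lacks a filter reason")

    @property
    def top_formula(self) -> FormulaMatch | None:
        return self.formulas[0] if self.formulas else None


def diagnostic_ion_match(
    spectrum: SpectrumRecord,
    ions: tuple[float, ...],
    tol_ppm: float = 5.0,
) -> dict[float, tuple[float, float]]:
    """Match diagnostic ions against a spectrum's centroids.

    For each reference ion, returns the most intense centroid within the
    closed ppm window, as ``reference -> (observed m/z, intensity)``.
    """
    out: dict[float, tuple[float, float]] = {}
    mz, inten = spectrum.mz, spectrum.intensity
    for ion in ions:
        half = tol_ppm * ion / 1e6
        lo = np.searchsorted(mz, ion - half, side="left")
        hi = np.searchsorted(mz, ion + half, side="right")
        if hi > lo:
            j = lo + int(np.argmax(inten[lo:hi]))
            out[ion] = (float(mz[j]), float(inten[j]))
    return out


def _nearest_ms1(run: AcquisitionRun, rt: float) -> SpectrumRecord:
    ms1 = run.ms1_spectra()
    rts = np.array([s.rt_min for s in ms1])
    return ms1[int(np.argmin(np.abs(rts - rt)))]


def prioritize_dia(
    ce0_run: AcquisitionRun,
    fragment_channel_runs: dict[float, AcquisitionRun],
    diag: DiagnosticIonSet | None = None,
    constraints: CompositionConstraints | None = None,
    filters: FilterConfig | None = None,
    sample_id: str = "",
    trio: str = "native",
    rt_align_tol_min: float = 0.1,
) -> list[PrecursorCandidate]:
    """Prioritize provisional precursors from a DIA channel set.

    Diagnostic-ion EICs in each elevated-CE channel are peak-picked and
    aligned across channels; at every consensus RT the nearest CE = 0 full
    scan nominates its centroids, which then pass the intensity threshold
    and the elemental-restriction formula screen. The two-of-three MS/MS
    rule cannot be evaluated from channel data alone, so survivors are
    returned ``provisional``; :func:`confirm_candidates` finalizes them from
    the targeted MS/MS re-run. ``trio`` selects the native or the labelled
    diagnostic trio.
    """
    diag = diag if diag is not None else DiagnosticIonSet()
    constraints = constraints if constraints is not None else CompositionConstraints()
    filters = filters if filters is not None else FilterConfig()
    if ce0_run is None or ce0_run.channel_ce_v not in (0, 0.0, None):
        raise ValueError("prioritize_dia requires the CE = 0 channel run")
    if not fragment_channel_runs:
        raise ValueError("at least one fragment channel (CE > 0) is required")

    trio_mzs = diag.native_trio if trio == "native" else diag.labelled_trio
    all_peaks = []
    for ce, run in fragment_channel_runs.items():
        for ion in trio_mzs:
            trace = extract_eic(run, ion, diag.match_tol_ppm, ms_level=1)
            all_peaks.extend(
                detect_peaks(
                    trace,
                    min_intensity=0.0,
                    snr_min=constraints.snr_min,
                    ion_mz=ion,
                    channel_ce_v=ce,
                )
            )
    groups = [
        g
        for g in align_across_channels(all_peaks, rt_align_tol_min)
        if g.n_distinct_diagnostic_ions >= filters.dia_min_coeluting_ions
    ]

    out: list[PrecursorCandidate] = []
    seen: list[tuple[float, float]] = []
    for g in groups:
        ms1 = _nearest_ms1(ce0_run, g.consensus_rt_min)
        evidence = {
            p.ion_mz: (p.ion_mz, p.apex_intensity)
            for p in g.member_peaks
            if p.ion_mz is not None
        }
        for mz, inten in zip(ms1.mz, ms1.intensity):
            if inten < filters.min_nominate_intensity:
                continue
            if any(
                abs(mz - smz) <= filters.merge_tol_ppm * mz / 1e6
                and abs(g.consensus_rt_min - srt) <= filters.merge_rt_min
                for smz, srt in seen
            ):
                continue
            cand = PrecursorCandidate(
                mz=float(mz),
                rt_min=g.consensus_rt_min,
                intensity=float(inten),
                mode="DIA",
                sample_id=sample_id,
                matched_diagnostic_ions=dict(evidence),
            )
            if inten < filters.tic_intensity_threshold:
                cand.status = STATUS_FILTERED
                cand.filter_reason = REASON_INTENSITY
            elif trio == "native":
                cand.formulas = enumerate_formulas(float(mz), constraints)
                if not cand.formulas:
                    cand.status = STATUS_FILTERED
                    cand.filter_reason = REASON_FORMULA
            seen.append((float(mz), g.consensus_rt_min))
            out.append(cand)
    out.sort(key=lambda c: (c.rt_min, c.mz))
    return out


def prioritize_dda(
    run: AcquisitionRun,
    diag: DiagnosticIonSet | None = None,
    constraints: CompositionConstraints | None = None,
    filters: FilterConfig | None = None,
    sample_id: str = "",
    trio: str = "native",
) -> list[PrecursorCandidate]:
    """Prioritize precursors directly from ddMS2 spectra.

    Every MS2 scan showing at least one diagnostic-trio match nominates its
    precursor; nominations within the merge windows are pooled (diagnostic
    evidence unioned, maximum full-scan intensity retained). The intensity
    threshold, the formula screen and the two-of-three rule are then applied
    — MS2 spectra are already in hand, so the status is decided immediately.
    """
    diag = diag if diag is not None else DiagnosticIonSet()
    constraints = constraints if constraints is not None else CompositionConstraints()
    filters = filters if filters is not None else FilterConfig()
    ms2 = run.ms2_spectra()
    if not ms2:
        raise ValueError("prioritize_dda requires a run containing MS2 scans")
    trio_mzs = diag.native_trio if trio == "native" else diag.labelled_trio

    nominations: list[dict] = []
    for spec in ms2:
        matched = diagnostic_ion_match(spec, trio_mzs, filters.dda_match_tol_ppm)
        if not matched:
            continue
        supp = diagnostic_ion_match(
            spec, (diag.supplementary,), filters.dda_match_tol_ppm
        )
        merged = False
        for nom in nominations:
            if (
                abs(spec.precursor_mz - nom["mz"]) <= filters.merge_tol_ppm * nom["mz"] / 1e6
                and abs(spec.rt_min - nom["rt"]) <= filters.merge_rt_min
            ):
                for ion, hit in matched.items():
                    if ion not in nom["matched"] or hit[1] > nom["matched"][ion][1]:
                        nom["matched"][ion] = hit
                nom["supp"] = nom["supp"] or bool(supp)
                nom["rt"] = min(nom["rt"], spec.rt_min)
                merged = True
                break
        if not merged:
            nominations.append(
                {
                    "mz": spec.precursor_mz,
                    "rt": spec.rt_min,
                    "matched": dict(matched),
                    "supp": bool(supp),
                }
            )

    out: list[PrecursorCandidate] = []
    for nom in nominations:
        ms1 = _nearest_ms1(run, nom["rt"])
        hit = diagnostic_ion_match(ms1, (nom["mz"],), filters.merge_tol_ppm)
        ms1_intensity = hit[nom["mz"]][1] if hit else 0.0
        cand = PrecursorCandidate(
            mz=float(nom["mz"]),
            rt_min=float(nom["rt"]),
            intensity=float(ms1_intensity),
            mode="DDA",
            sample_id=sample_id,
            matched_diagnostic_ions=nom["matched"],
            supplementary_flag=nom["supp"],
        )
        if ms1_intensity < filters.tic_intensity_threshold:
            cand.status = STATUS_FILTERED
            cand.filter_reason = REASON_INTENSITY
        else:
            # The elemental restriction describes unlabelled CHO compositions;
            # the labelled-trio QC screen rests on the diagnostic EICs alone.
            if trio == "native":
                cand.formulas = enumerate_formulas(cand.mz, constraints)
            if trio == "native" and not cand.formulas:
                cand.status = STATUS_FILTERED
                cand.filter_reason = REASON_FORMULA
            elif filters.require_two_of_three:
                n = len(set(nom["matched"]) & set(trio_mzs))
                cand.status = (
                    STATUS_CANDIDATE if n >= 2 else STATUS_FALSE_POSITIVE
                )
            else:
                cand.status = STATUS_CANDIDATE
        cand.validate(diag, require_formula=trio == "native")
        out.append(cand)
    out.sort(key=lambda c: (c.rt_min, c.mz))
    return out


def confirm_candidates(
    provisional: list[PrecursorCandidate],
    targeted_ms2_run: AcquisitionRun,
    diag: DiagnosticIonSet | None = None,
    filters: FilterConfig | None = None,
    rt_window_min: float = 0.5,
    trio: str = "native",
) -> list[PrecursorCandidate]:
    """Finalize DIA provisional precursors against a targeted MS/MS re-run.

    For each provisional precursor, all MS2 scans within the precursor ppm
    tolerance and RT window are pooled and the two-of-three rule evaluated
    on the union of their diagnostic matches. Precursors for which no MS2
    was acquired stay provisional, with a warning.
    """
    diag = diag if diag is not None else DiagnosticIonSet()
    filters = filters if filters is not None else FilterConfig()
    trio_mzs = diag.native_trio if trio == "native" else diag.labelled_trio
    ms2 = targeted_ms2_run.ms2_spectra()
    unconfirmed = 0
    for cand in provisional:
        if cand.status != STATUS_PROVISIONAL:
            continue
        tol = filters.dda_match_tol_ppm * cand.mz / 1e6
        scans = [
            s
            for s in ms2
            if abs(s.precursor_mz - cand.mz) <= tol
            and abs(s.rt_min - cand.rt_min) <= rt_window_min
        ]
        if not scans:
            unconfirmed += 1
            continue
        matched: dict[float, tuple[float, float]] = {}
        supp = False
        for s in scans:
            for ion, hit in diagnostic_ion_match(
                s, trio_mzs, filters.dda_match_tol_ppm
            ).items():
                if ion not in matched or hit[1] > matched[ion][1]:
                    matched[ion] = hit
            supp = supp or bool(
                diagnostic_ion_match(
                    s, (diag.supplementary,), filters.dda_match_tol_ppm
                )
            )
        cand.matched_diagnostic_ions = matched
        cand.supplementary_flag = cand.supplementary_flag or supp
        n = len(set(matched) & set(trio_mzs))
        cand.status = STATUS_CANDIDATE if n >= 2 else STATUS_FALSE_POSITIVE
        cand.validate(diag, require_formula=trio == "native")
    if unconfirmed:
        warnings.warn(
            f"{unconfirmed} provisional precursor(s) had no targeted MS2 "
            "acquired and remain provisional"
        )
    return provisional


def blank_filter(
    feature_intensity: float,
    blank_intensities: list[float] | np.ndarray,
    ratio: float = 3.0,
    aggregate: str = "mean",
) -> bool:
    """Keep a feature only if it exceeds ``ratio`` times the blank level.

    The blank level is the mean (or max) over procedural-blank replicates;
    a feature absent from every blank is kept. The boundary is inclusive:
    exactly ``ratio`` times the blank level is kept.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    blanks = np.asarray(blank_intensities, dtype=float)
    blanks = blanks[np.isfinite(blanks)]
    if blanks.size == 0 or np.all(blanks <= 0):
        return True
    level = float(blanks.max() if aggregate == "max" else blanks.mean())
    return feature_intensity >= ratio * level


def export_inclusion_list(
    candidates: list[PrecursorCandidate],
    path: str | Path,
    rt_half_window_min: float = 0.5,
) -> pd.DataFrame:
    """Write the targeted-MS/MS inclusion list CSV for provisional precursors.

    Columns follow the usual targeted-acquisition template: Mass, Formula,
    Species, CS (charge state), Polarity, Start and End RT (apex +/- half
    window, clipped at zero). An empty candidate set yields a header-only
    file.
    """
    rows = []
    for c in sorted(candidates, key=lambda c: (c.rt_min, c.mz)):
        top = c.top_formula
        rows.append(
            {
                "Mass": round(c.mz, 5),
                "Formula": top.formula.hill() if top else "",
                "Species": "[M-H]-",
                "CS": 1,
                "Polarity": "Negative",
                "Start": max(c.rt_min - rt_half_window_min, 0.0),
                "End": c.rt_min + rt_half_window_min,
            }
        )
    df = pd.DataFrame(
        rows, columns=["Mass", "Formula", "Species", "CS", "Polarity", "Start", "End"]
    )
    df.to_csv(path, index=False)
    return df


def candidates_to_frame(candidates: list[PrecursorCandidate]) -> pd.DataFrame:
    """Tabular rendering of a candidate list (one row per precursor)."""
    rows = []
    for c in candidates:
        top = c.top_formula
        rows.append(
            {
                "mz": c.mz,
                "rt_min": c.rt_min,
                "intensity": c.intensity,
                "mode": c.mode,
                "sample_id": c.sample_id,
                "n_diagnostic_ions": len(c.matched_diagnostic_ions),
                "matched_ions": ";".join(
                    f"{k:.4f}" for k in sorted(c.matched_diagnostic_ions)
                ),
                "supplementary": c.supplementary_flag,
                "top_formula": top.formula.hill() if top else "",
                "ppm_error": top.ppm_error if top else np.nan,
                "status": c.status,
                "filter_reason": c.filter_reason or "",
            }
        )
    return pd.DataFrame(rows)
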
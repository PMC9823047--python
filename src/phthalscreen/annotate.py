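"""Structure annotation and identification-confidence levels.

Confirmed candidates are matched against a standards library (reference
compounds with observed retention times), screened against a suspect mass
list of phthalate metabolites, and assigned Schymanski-style confidence
levels:

* level 1 — accurate mass matches a reference standard and the observed RT
  agrees with the standard's RT (and the candidate carries at least two
  diagnostic ions);
* level 2 — probable structure: no standard, but the RT predicted for the
  proposed structure agrees with the observed RT within 0.2 min;
* level 3 — tentative candidate: formula plus diagnostic evidence, isomer
  unresolved.

The shipped standards library and 75-entry mass list are synthetic
reconstructions assembled from common monophthalates and their oxidized
metabolites (the fixture the pipeline is exercised against, not reference
ground truth). The retention-time predictor is pluggable: the default
surrogate is a linear model on a hydrophobicity-proxy descriptor fitted to
the standards library, exact on compounds present in that library;
externally computed predictions can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_core import (
    DiagnosticIonSet,
    ElementalFormula,
    MASS_PROTON,
    monoisotopic_mass,
)
from .prioritize import STATUS_CANDIDATE, PrecursorCandidate

__all__ = [
    "StandardEntry",
    "MassListEntry",
    "Annotation",
    "load_standards",
    "load_mass_list",
    "SurrogateRTPredictor",
    "screen_mass_list",
    "collapse_replicate_rts",
    "assign_level",
    "annotations_to_frame",
]


@dataclass(frozen=True)
class StandardEntry:
    """A reference standard with its observed retention time."""

    name: str
    neutral_formula: ElementalFormula
    rt_min: float
    labelled: bool = False

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ValueError("standard rt_min must be positive")
        if self.labelled and self.neutral_formula.n_carbon13 == 0:
            raise ValueError("labelled standards must carry 13C substitutions")

    @property
    def anion_mz(self) -> float:
        return (
            monoisotopic_mass(self.neutral_formula.deprotonated())
            + 0.00054857990
        )


@dataclass(frozen=True)
class MassListEntry:
    """A suspect-list compound (name, formula, neutral monoisotopic mass)."""

    name: str
    neutral_formula: ElementalFormula
    neutral_monoisotopic_mass: float

    def __post_init__(self) -> None:
        expected = monoisotopic_mass(self.neutral_formula)
        if abs(expected - self.neutral_monoisotopic_mass) > 1e-4:
            raise ValueError(
                f"{self.name}: listed mass {self.neutral_monoisotopic_mass} "
                f"inconsistent with formula ({expected:.5f})"
            )


@dataclass
class Annotation:
    """A candidate with a proposed structure and a confidence level."""

    candidate: PrecursorCandidate
    proposed_name: str
    level: int
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")


def _data_path(name: str) -> Path:
    return Path(resources.files("phthalscreen").joinpath("data", name))


def load_standards(path: str | Path | None = None) -> pd.DataFrame:
    """Load the standards library table (synthetic default if no path)."""
    df = pd.read_csv(path if path is not None else _data_path("synthetic_standards.csv"))
    df["neutral_mass"] = [
        monoisotopic_mass(
            ElementalFormula.parse(f) if n13 == 0 else _labelled_formula(f, n13)
        )
        for f, n13 in zip(df.neutral_formula, df.n_carbon13)
    ]
    return df


def _labelled_formula(hill: str, n13: int) -> ElementalFormula:
    base = ElementalFormula.parse(hill)
    return ElementalFormula(base.n_carbon, base.n_hydrogen, base.n_oxygen, n13)


def load_mass_list(path: str | Path | None = None) -> pd.DataFrame:
    """Load the suspect mass list (synthetic 75-entry default if no path)."""
    df = pd.read_csv(path if path is not None else _data_path("synthetic_mass_list.csv"))
    if df.empty:
        raise ValueError("mass list is empty")
    for row in df.itertuples():
        MassListEntry(
            getattr(row, "name"),
            ElementalFormula.parse(row.neutral_formula),
            row.neutral_monoisotopic_mass,
        )
    return df


class SurrogateRTPredictor:
    """Linear retention-time model on a hydrophobicity-proxy descriptor.

    Fitted by least squares to the (descriptor, RT) pairs of the unlabelled
    standards. Compounds present in the standards library return their
    library RT exactly; other compounds with a descriptor get the linear
    prediction; compounds without a descriptor get ``None``.
    """

    def __init__(
        self,
        standards: pd.DataFrame | None = None,
        descriptors: pd.DataFrame | None = None,
    ) -> None:
        std = standards if standards is not None else load_standards()
        desc = descriptors if descriptors is not None else load_mass_list()
        native = std[~std.labelled]
        x = native.logp_proxy.to_numpy(dtype=float)
        y = native.rt_min.to_numpy(dtype=float)
        A = np.column_stack([np.ones_like(x), x])
        self.coef_, *_ = np.linalg.lstsq(A, y, rcond=None)
        self._train_rt = dict(zip(native["name"], native.rt_min))
        self._proxy = dict(zip(desc["name"], desc.logp_proxy))
        self._proxy.update(dict(zip(native["name"], native.logp_proxy)))

    def predict(self, name: str) -> float | None:
        if name in self._train_rt:
            return float(self._train_rt[name])
        proxy = self._proxy.get(name)
        if proxy is None:
            return None
        return float(self.coef_[0] + self.coef_[1] * proxy)


def screen_mass_list(
    features: pd.DataFrame | list[PrecursorCandidate],
    mass_list: pd.DataFrame,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Match features against a suspect mass list by neutral accurate mass.

    ``features`` is either a DataFrame with ``mz``/``rt_min`` columns or a
    candidate list. Every list entry within ``tol_ppm`` of a feature's
    reconstructed neutral mass (mz + proton mass) is reported, so one
    feature may hit several isomers and one compound may recur at several
    retention times.
    """
    if mass_list is None or len(mass_list) == 0:
        raise ValueError("mass list is empty")
    if isinstance(features, list):
        feats = pd.DataFrame(
            [{"mz": c.mz, "rt_min": c.rt_min, "intensity": c.intensity}
             for c in features]
        )
    else:
        feats = features
    rows = []
    masses = mass_list.neutral_monoisotopic_mass.to_numpy(dtype=float)
    for feat in feats.itertuples(index=True):
        neutral = feat.mz + MASS_PROTON
        ppm = (neutral - masses) / masses * 1e6
        for j in np.flatnonzero(np.abs(ppm) <= tol_ppm):
            rows.append(
                {
                    "feature_index": feat.Index,
                    "mz": feat.mz,
                    "rt_min": feat.rt_min,
                    "proposed_name": mass_list["name"].iloc[j],
                    "neutral_formula": mass_list.neutral_formula.iloc[j],
                    "ppm_error": float(ppm[j]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_index", "mz", "rt_min", "proposed_name",
            "neutral_formula", "ppm_error",
        ],
    )


def collapse_replicate_rts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Collapse mass-list hits to unique compounds with their RT lists.

    A compound annotated at nine retention times counts once here, with
    multiplicity 9 — the distinction between annotated features and
    annotatable compounds.
    """
    if annotations.empty:
        return pd.DataFrame(columns=["proposed_name", "rt_list", "multiplicity"])
    grouped = (
        annotations.groupby("proposed_name")["rt_min"]
        .agg(lambda s: sorted(set(round(v, 4) for v in s)))
        .reset_index()
        .rename(columns={"rt_min": "rt_list"})
    )
    grouped["multiplicity"] = annotations.groupby("proposed_name")["rt_min"].count().values
    return grouped


def assign_level(
    candidate: PrecursorCandidate,
    standards: pd.DataFrame,
    rt_predictor: SurrogateRTPredictor | None = None,
    proposed_name: str | None = None,
    diag: DiagnosticIonSet | None = None,
    rt_match_tol_min: float = 0.1,
    rt_pred_tol_min: float = 0.2,
    mass_tol_ppm: float = 5.0,
) -> Annotation:
    """Assign an identification-confidence level to a confirmed candidate.

    Level 1 requires an exact-mass standard match with RT agreement within
    ``rt_match_tol_min``; level 2 requires a predicted RT for the proposed
    structure within ``rt_pred_tol_min`` of the observed RT; otherwise
    level 3. Without an RT predictor levels are capped at 3 (with a
    warning) unless a standard match grants level 1.
    """
    diag = diag if diag is not None else DiagnosticIonSet()
    if candidate.status != STATUS_CANDIDATE:
        raise ValueError("only confirmed candidates can be annotated")
    evidence: dict = {
        "n_diagnostic_ions": candidate.n_trio_matches(diag),
        "mass_list_hit": proposed_name is not None,
    }

    # level 1: standard with matching accurate mass and RT
    std_mass = standards.neutral_mass.to_numpy(dtype=float)
    neutral = candidate.mz + MASS_PROTON
    ppm = np.abs(neutral - std_mass) / std_mass * 1e6
    close = np.flatnonzero(ppm <= mass_tol_ppm)
    best = None
    for j in close:
        delta = abs(candidate.rt_min - float(standards.rt_min.iloc[j]))
        if best is None or delta < best[1]:
            best = (j, delta)
    if best is not None:
        j, delta = best
        evidence["standard_name"] = standards["name"].iloc[j]
        evidence["standard_rt_delta_min"] = delta
        if delta <= rt_match_tol_min:
            return Annotation(
                candidate, str(standards["name"].iloc[j]), 1, evidence
            )

    name = proposed_name or evidence.get("standard_name")
    if name is None:
        top = candidate.top_formula
        name = top.neutral.hill() if top else f"m/z {candidate.mz:.4f}"

    if rt_predictor is None:
        warnings.warn("no RT predictor available; level capped at 3")
        return Annotation(candidate, str(name), 3, evidence)

    predicted = rt_predictor.predict(str(name))
    if predicted is not None:
        evidence["predicted_rt_min"] = predicted
        evidence["predicted_rt_delta_min"] = abs(predicted - candidate.rt_min)
        if abs(predicted - candidate.rt_min) < rt_pred_tol_min:
            return Annotation(candidate, str(name), 2, evidence)
    return Annotation(candidate, str(name), 3, evidence)


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "mz": a.candidate.mz,
                "rt_min": a.candidate.rt_min,
                "proposed_name": a.proposed_name,
                "level": a.level,
                **{k: v for k, v in a.evidence.items()},
            }
        )
    return pd.DataFrame(rows)
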
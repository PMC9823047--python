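# phthalscreen

Non-targeted screening of phthalate metabolites in LC-HRMS data.

Human exposure to phthalate plasticizers is monitored through their urinary
monoester metabolites (monophthalates), but targeted assays cover only the
few metabolites with analytical standards. Non-targeted analysis (NTA)
widens that window: monophthalates share a skeleton that fragments, in
negative electrospray, into a characteristic trio of diagnostic anions —
m/z 121.0295 (C7H5O2⁻), 147.0088 (C8H3O3⁻) and 165.0193 (C8H5O4⁻), plus
m/z 134.0377 for pure-alkyl-chain esters — so any [M−H]⁻ precursor whose
MS/MS shows at least two of the three is a strong monophthalate candidate,
known or not.

`phthalscreen` implements this workflow end to end, for both acquisition
geometries used in practice, and ships a synthetic acquisition simulator so
every stage is testable against known ground truth:

- **chem_core** — exact-mass arithmetic with ¹³C support and brute-force CHO
  formula enumeration under the monophthalate elemental restrictions
  (C 8–30, H 6–60, O 4–10, neutral RDBE 6–12, 5 ppm, even-electron [M−H]⁻);
- **msdata_io** — centroid mzML 1.1 read/write, TIC and EIC extraction;
- **peaks** — EIC peak detection (MAD-based S/N) and co-elution grouping of
  diagnostic-ion peaks across in-source collision-energy channels;
- **prioritize** — DIA and DDA precursor prioritization: intensity threshold
  (5×10⁵ counts), formula restriction, the two-of-three diagnostic-ion rule,
  3× procedural-blank filtering, targeted-MS/MS inclusion lists and
  confirmation;
- **annotate** — standards library and suspect mass-list screening,
  pluggable retention-time prediction, Schymanski-style confidence levels
  1/2/3;
- **stats_compare** — replicate RSD, labelled-standard identification
  efficiency, false-positive rates, fold-change + Welch-test differential
  analysis, per-mode comparison reports;
- **synth** — Q-Exactive-style simulation of DIA (in-source CE 0/20/40 V)
  and DDA (TopN 5 ddMS2, 2×10⁵ trigger, 3.0 s dynamic exclusion) runs of a
  configurable monophthalate panel with labelled standards, one-ion decoys,
  blanks and noise, written as standard mzML with ground-truth tables.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

A complete synthetic study — 10 monophthalates, 5 one-diagnostic-ion decoys,
14 ¹³C₄-labelled standards, two sample groups with planted fold changes,
blanks and a QC run — then both screening routes:

```sh
phthalscreen simulate -o fixture --seed 20221108
phthalscreen prioritize --mode dda fixture/dda_qc_spiked.mzML -o dda_candidates.csv
phthalscreen confirm fixture/dia_qc_ce0.mzML fixture/dia_qc_ce20.mzML \
    fixture/dia_qc_ce40.mzML --targeted fixture/dia_qc_targeted_ms2.mzML \
    -o dia_confirmed.csv
phthalscreen annotate dda_candidates.csv -o dda_annotated.csv
phthalscreen report DDA:qc:dda_candidates.csv:dda_annotated.csv -o report.csv
```

prints

```
fixture written to fixture (14 runs)
37 precursors -> dda_candidates.csv {'filtered': 18, 'candidate': 14, 'false_positive': 5}
35 precursors -> dia_confirmed.csv {'filtered': 20, 'candidate': 10, 'false_positive': 5}
14 annotations -> dda_annotated.csv (levels: {1: 10, 2: 3, 3: 1})
mode sample  n_precursor_ions  n_candidate_ions  n_level1  n_level2  n_level3
 DDA     qc                19                14        10         3         1
```

Reading the numbers: the DDA route nominates 37 precursors from ddMS2
diagnostic-ion matches; 18 fail the intensity threshold or the elemental
restriction, the 5 decoys are caught by the two-of-three rule
(`false_positive`), and the candidates cover all 10 planted monophthalates
(the count above 10 comes from peak-tail re-selections of the same
analytes, which analyte-level comparisons merge). The DIA route, which
needs the targeted MS/MS re-run for confirmation, agrees on exactly the
same 10 analytes and rejects the same 5 decoys. Annotation identifies the
panel compounds present in the standards library at level 1 and
demotes the rest to probable (level 2) or tentative (level 3) structures.

The same machinery is available as a library:

```python
from phthalscreen.chem_core import enumerate_formulas

for m in enumerate_formulas(321.1709):
    print(m.formula.hill(), round(m.ppm_error, 2))
# C18H25O5 -0.47
```

— the unique CHO ion composition within 5 ppm of m/z 321.1709 under the
monophthalate restrictions, i.e. the anion of a hydroxylated C10-chain
monophthalate (neutral C18H26O5).

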
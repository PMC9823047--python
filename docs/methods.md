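# Methods

`phthalscreen` implements a non-targeted LC-HRMS screening workflow for
phthalate monoester (monophthalate) metabolites in negative electrospray,
together with a synthetic acquisition generator that provides ground truth
for every stage. This note describes the models, the parameters that matter,
the numerical choices, and what the synthetic data does and does not show.

## The screening model

Monophthalates share an aromatic diester-derived skeleton that fragments
into a small set of diagnostic anions regardless of the ester chain:
m/z 121.0295 (C7H5O2-), 147.0088 (C8H3O3-) and 165.0193 (C8H5O4-), with
m/z 134.0377 as a supplementary ion specific to pure-alkyl-chain monoesters.
The pipeline turns this chemistry into a prioritization rule:

1. **Locate** candidate retention times from the diagnostic ions — EIC peaks
   of the fragment channels in DIA, or fragment matches inside ddMS2 spectra
   in DDA.
2. **Threshold**: the precursor's full-scan centroid intensity must reach
   5×10^5 counts.
3. **Restrict**: the accurate mass must admit at least one CHO ion
   composition with C 8–30, H 6–60, O 4–10, neutral RDBE 6–12, within 5 ppm,
   deprotonated from an even-electron neutral.
4. **Confirm**: the MS/MS spectrum must contain at least two of the three
   diagnostic ions; precursors failing this are recorded as false positives.
   In DDA the MS2 evidence is already in hand; in DIA the survivors of
   steps 1–3 are provisional, exported as a targeted-MS/MS inclusion list,
   and confirmed from the re-run.

Ring-labelled (13C4) internal standards are traced the same way through the
labelled diagnostic trio (124.0397/151.0223/169.0329). Those three values
are configured constants rather than derived masses: a uniform 13C3/13C4
substitution computes ~0.0001 below each, and the labelling positions behind
the printed values are not specified, so the constants are taken as given.
The elemental restriction is not applied on the labelled QC route — it
describes unlabelled CHO compositions, and labelled-standard identification
rests on the diagnostic EICs alone.

## Mass arithmetic and formula enumeration

Monoisotopic masses use 12C = 12 exactly, 1H = 1.00782503207,
16O = 15.99491461956, 13C = 13.00335483507 Da; anion m/z adds the electron
mass (5.4857990×10^-4 Da). These precisions are required to reproduce
four-decimal diagnostic masses. Enumeration scans the full (C, H, O) grid —
about 9×10^3 compositions — with the hydrogen bound applied to the ion and
the RDBE window to the reconstructed neutral (ion + H). The even-electron
condition is operationalized as "the ion is the deprotonation product of an
even-electron neutral", i.e. odd ion hydrogen count; for CHO-only anions
this is the only reading consistent with [M-H]- species. Evaluating RDBE on
the neutral makes monoethyl phthalate score exactly 6 (ring 4 + two
carbonyls), the lower edge of the window. Matches are ranked by |ppm error|
with ties broken by fewer oxygens, then lexicographic (C, H); the tie-break
is a convention, ties being vanishingly rare at 5 ppm. An isotope-pattern
fit score ("minimum spectral fit") used by some vendor software is carried
in the constraints as metadata but never evaluated — its algorithm is not
public.

## mzML handling

Runs are modelled as RT-ordered centroid spectra; retention times are
minutes end-to-end (seconds are converted on read). Reading accepts plain or
indexed mzML 1.1, gzipped or not, 32/64-bit float arrays, zlib or no
compression; profile-mode spectra are rejected rather than centroided.
Writing produces plain 64-bit uncompressed mzML so simulated fixtures
round-trip bit-faithfully. Both directions are implemented in this package
on lxml. EIC windows are closed intervals (a centroid at exactly ±tol is
included) and multiple centroids inside one window in one spectrum are
summed — the conservative choice for S/N.

## Peak detection and alignment

EIC traces are smoothed with a 3-point moving average; local maxima are
extended to flanking valleys; noise is the median absolute deviation of the
off-peak raw trace scaled by 1.4826 (floor 1 count); S/N is apex/noise. The
scheme is deliberately parameter-light and deterministic — shoulders are not
deconvolved. Peaks across diagnostic ions and CE channels are grouped by
single-linkage clustering on apex RT with a 0.1-min tolerance; the consensus
RT is the intensity-weighted mean (unweighted differs negligibly at this
tolerance). Both the tolerance and whether a single diagnostic EIC suffices
to pursue a DIA consensus RT (`dia_min_coeluting_ions`, default 1) are
configuration choices: requiring co-elution of two ions already at the DIA
stage is stricter than confirming two ions only at MS/MS, and both
behaviours are supported.

## Filters and their boundary semantics

"At least three times the procedural blank" is implemented as ≥ 3× the mean
over blank replicates (max available via config); a feature absent from all
blanks is kept. The 5×10^5 threshold is applied to the nominated ion's own
full-scan centroid intensity — the only actionable per-ion reading of a
threshold entered into chromatogram extraction. DDA nominations within
0.1 min and 5 ppm are merged (evidence unioned, maximum intensity kept);
tail re-selections of a wide peak outside that window appear as separate
nominations of the same compound, which is why analyte-level comparisons
dedupe by m/z and RT. Inclusion-list RT windows are apex ± 0.5 min, clipped
at zero. The supplementary ion never counts toward two-of-three; it only
flags the alkyl subclass.

## Annotation and confidence levels

Level 1 requires an exact-mass standard match (5 ppm) with |ΔRT| ≤ 0.1 min
and ≥ 2 diagnostic ions; level 2 requires a predicted RT for the proposed
structure within 0.2 min of observation; otherwise level 3. The 0.2-min
level-2 criterion is the workflow's stated rule; the 0.1-min level-1
tolerance is this package's choice (standards RT matching is usually
tighter than prediction). The retention-time predictor is a pluggable
interface; the shipped surrogate is a least-squares linear model on a
hydrophobicity-proxy descriptor (a logP-like score increasing with ester
chain length, decreasing with polar substitution), exact by lookup on
compounds in the standards library. It stands in for descriptor-based
regression models used in practice, which are not reproduced here; users
with such a model can supply its predictions directly. When two isomers
both predict within 0.2 min the annotation is ambiguous and both are
reported rather than tie-broken.

The shipped standards library (24 native + 14 labelled entries) and the
75-entry suspect mass list are synthetic reconstructions from common
monophthalates and their oxidized metabolites; they are fixtures that make
the pipeline testable, not reference data, and their filenames say so.

## Statistics

Replicate RSD is 100·sd/mean (sample sd, one decimal). False-positive
percentages round half-up, to one decimal for labelled-standard rates and
to integers for feature-level rates — the two reporting styles in use.
Differential analysis takes fold change as the ratio of raw replicate means
and significance from a two-sided Welch t-test on log10 intensities (the
log-transform makes multiplicative noise additive, so type-I error is
calibrated on log-normal data); labels are up/down only when both the fold
threshold (default 2) and p < 0.05 hold. No multiple-testing correction is
applied by default, matching the plain p < 0.05 reporting convention;
features present in only one group get an infinite/zero fold with no
p-value rather than a fabricated variance. Fold changes are ratios of
replicate means, not of single pooled measurements.

## The simulator and what it shows

The generator emulates a Q-Exactive-style negative-mode acquisition:
Gaussian elution (σ = 0.05 min default), DIA as one full-scan run per
in-source CE (0/20/40 V; 150–1000 m/z at 0 V, 50–500 above), DDA as TopN 5
ddMS2 with 1.5 m/z isolation, 2×10^5 trigger, 3.0 s dynamic exclusion and
NCE 15/35/50 summed into one MS2 spectrum (per-NCE output would be a
straightforward extension; the summed form is what the instrument writes).
In-source fragmentation moves a fraction CE/40 (capped at 1) of each
analyte's current into its fragment template — a linear response invented
for the simulator and configurable per analyte; before noise, intact +
fragment current is conserved per scan. Noise is sparse uniform-m/z
centroids with exponential intensities around a 10^3-count floor, plus
random Gaussian matrix interferents. Isotope envelopes, chromatographic
tailing and ion suppression are not modelled.

The default study panel is 10 native monophthalates (apexes 2.5×10^6 to
1.2×10^7 counts, i.e. well above both mode thresholds), 5 decoys that emit
exactly one diagnostic ion (the designed failure mode of one-ion screening),
and 14 ring-labelled standards at 1.2×10^6 counts spiked into every
non-blank run. The study fixture mirrors the design of a two-group
biomonitoring comparison: 3 DDA replicates per group with planted fold
changes (25×, 2.5×, 2.5×, 0.4×; replicate CV 5% log-normal), 3 procedural
blanks carrying 2% analyte carryover, a spiked QC run, and one DIA channel
set with its targeted ddMS2 re-run. Default run length is 12 min at 1 scan/s
— long enough for the panel's RT range (2.9–11.3 min) while keeping a full
fixture build in a few seconds. All randomness flows from one mandatory
seed (default 20221108); identical config and seed give byte-identical
mzML.

Passing tests on this fixture demonstrate the *logic* of the workflow —
thresholds, rules, bookkeeping, recovery and rejection under known truth —
not its performance on real urine, where matrix effects, co-elution,
in-source artifacts and isotope interference are harsher than anything the
generator emulates.

## Known limitations

- Only [M-H]- singly charged CHO species; no adducts, multimers or other
  elements.
- No spectral-library (MS/MS cosine) matching; "database hit" means suspect
  mass-list hit.
- Peak detection does not deconvolve shoulders; analytes closer than the
  alignment tolerance would merge.
- The RT surrogate is a one-descriptor linear model; its predictions
  outside the calibrated homologous series are extrapolations.
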
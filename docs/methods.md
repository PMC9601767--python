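# Methods

## The model behind the scores

A predicted structure model is treated as a *proxy observation* of the
disorder-to-structure continuum. Three per-residue scores in [0, 1] are
derived from it:

**Confidence score.** `s_pLDDT = 1 − pLDDT/100`. pLDDT is read from the
B-factor / isotropic-displacement column (mandatory input; files without it
are rejected). The per-residue value is taken from the Cα atom, with the
mean over the residue's atoms as a fallback — model files write identical
values on every atom of a residue, so the rule only disambiguates hand-made
inputs. The default decision threshold 0.312 corresponds to calling
residues with pLDDT < 68.8% disordered.

**Accessibility score.** Disordered regions surround the folded core as
exposed ribbons, so relative solvent accessibility averaged over a local
window tracks disorder. Per-residue RSA = ASA / maxASA(aa), clamped to
[0, 1]; `s_RSA` is the mean of RSA over a centred window of 25 residues
(±12). Near the termini, out-of-range indices are reflected about the
terminal residue without duplicating it (0-based index −k → +k and
N−1+k → N−1−k, applied recursively when the window overhangs the whole
chain). The alternative edge-duplicating convention is available as
`ScoreConfig(mirror="edge")` for parity experiments. Default threshold
0.581.

**Conditional-folding score.** Regions that are simultaneously accessible
and confidently modelled behave like disordered binding regions (they fold
on binding):

```
s_Bind = s_RSA                       if s_RSA ≤ T
       = T + (pLDDT/100) · (1 − T)   otherwise,      T = 0.581
```

The rescaling of the pLDDT fraction onto (T, 1] keeps the output in [0, 1].
The pLDDT operand is the raw per-residue fraction, not window-smoothed: only
the accessibility signal is windowed. The score is deliberately
discontinuous at s_RSA = T (boundary takes the ≤ branch); no smoothing is
applied on top of it. Default threshold 0.773.

Binary calls use the ≥ rule at every threshold, so a residue exactly on a
threshold is called positive.

## SASA engine and its dialects

ASA is computed by an internal Shrake–Rupley engine rather than DSSP: each
atom's solvent-expanded sphere (r_vdw + 1.4 Å probe) is sampled on a
golden-spiral lattice (default 100 points/atom; 960 in the verification
tests) and SASA = exposed-fraction × 4π(r+probe)², with neighbour search
restricted to atoms within r_i + r_j + 2·probe. Per-residue ASA sums the
residue's heavy atoms (hydrogens excluded). Van der Waals radii default to
C 1.70, N 1.55, O 1.52, S 1.80 Å (unknown elements 1.8 Å); all radii, the
probe and the point count are configurable. Absolute ASA from this engine
differs from DSSP's by a few percent, which matters only through the RSA
threshold; for exact parity studies a reader for the DSSP per-residue ACC
column is provided as an alternative ASA source.

Max-ASA normalisation uses extended Gly-X-Gly values; the default dialect is
the Sander table, with the Wilke and Miller tables selectable
(`max_asa_dialect`). Unknown residues map to 'X' and normalise by the
glycine maximum — glycine has the smallest maximum, so RSA of unknown
residues is never underestimated. RSA is clamped at 1.0, which is what
guarantees the Bind formula's [0, 1] range.

Numerical caveat: the sample lattice is fixed in the lab frame, so SASA is
exactly translation-invariant but only rotation-invariant up to the
quadrature error, O(1/n_points) — about 2% of a sphere area at 960 points.
No finite fixed lattice can do better; tests check translation at 1e-9 and
rotation at the quadrature tolerance. The quadrature error also does not
shrink monotonically at every doubling of the point count (lattice points
shift relative to occlusion caps); it shrinks on average, which is what the
convergence test asserts against a two-sphere spherical-cap closed form.

## Evaluation and calibration conventions

Residues from all matched targets are pooled into a single confusion matrix
before any metric (dataset-level Fmax — the headline benchmark convention);
per-target F1 at the Fmax threshold is reported secondarily. Residues with
unknown reference labels ('-') are excluded from pooling; targets without
predictions affect only coverage = |predicted ∩ reference| / |reference|
(reported to 2 decimals, e.g. 489/645 → 0.76). Fmax evaluates F1 at every
distinct pooled score value plus {0, 1}, which contains the exact optimum
under the ≥ rule; ties break toward the smallest threshold (favours
sensitivity, deterministic). AUC is the rank statistic
P(score_pos > score_neg) + ½·P(tie). F1 conventions: precision and recall
are 0 when their denominators vanish, F1 is 0 when precision + recall = 0.

Threshold calibration maximises pooled F1 over the distinct-score grid (a
fixed-step grid, e.g. 0.001, is available for parity with assessments that
discretise). Window calibration grid-searches odd windows (even values are
skipped with a warning — a centred ±h window is odd by construction),
scoring each window by its Fmax after re-smoothing every profile; ties go to
the smaller window. Single-class label sets are rejected as degenerate
rather than scored 0.

A protein is called *fully disordered* when ≥ 95% of its residues are called
positive. The fraction is a configurable dialect: assessments differ on the
exact criterion, and the confidence- and accessibility-based scores sit on
opposite sides of it (the first under-calls, the second over-calls).

## What the synthetic generators emulate

`benchmark_suite` builds single-chain backbone-only (N, Cα, C, O) models
from four archetypes — fully ordered cores, cores with disordered tails,
two cores joined by a disordered linker, and cores carrying an exposed
high-pLDDT (conditionally folding) segment. Collapsed cores snake through a
3.8 Å cubic lattice so interior residues are genuinely occluded; extended
segments use ~3.5 Å/residue; helices use ideal α-helix Cα geometry (2.3 Å
radius, 1.5 Å rise, 100°/residue). Segment pLDDT is written to every atom's
B-factor. All-glycine sequences avoid side-chain bias in the max-ASA
normalisation. A seeded ±0.1 Å jitter avoids degenerate exact contacts;
builds with atoms closer than 1 Å are retried with fresh jitter and fail
loudly after 50 attempts. Generation is bit-stable for a given seed.

These fixtures deliberately exaggerate the buried/exposed and
confident/uncertain contrast and contain no side chains, no real secondary
structure, no pLDDT noise within segments, and no ambiguous annotation.
Passing the end-to-end tests therefore demonstrates that the pipeline wiring
and the score definitions are correct and that the qualitative ordering
(accessibility separates disorder; the combined score — and neither
ingredient alone — elevates binding regions) is reproduced under the model's
assumptions; it says nothing about absolute performance on real proteomes,
where benchmark references and model downloads are required.

`noisy_block_profiles` generates labelled per-residue RSA profiles for
window calibration: disordered blocks of 18–27 residues on an ordered
background (gaps 40–70), baseline RSA 0.41 (ordered) vs 0.59 (disordered),
plus AR(1) noise (sd 0.15, lag-1 correlation 0.70). The weak per-residue
contrast reflects that raw accessibility of folded domains includes many
exposed surface residues — it is exactly why window averaging is needed —
and the autocorrelation reflects that sequence neighbours share a burial
environment. Under white per-residue noise the optimal window collapses to
3–9 regardless of block length; with correlated noise the F1-by-window curve
plateaus around the block-length scale (roughly windows 15–31), mirroring
the plateau observed when calibrating on real benchmark data.

## Other design choices

* Structure parsing (gemmi) keeps only ATOM records (waters/hetero dropped);
  alternate locations resolve to the highest-occupancy conformer, ties by
  altloc order. Non-standard residues map to 'X'. Positions are 1-based and
  must be strictly increasing within a chain.
* The default chain is the first one (database models are single-chain);
  SASA is computed over all chains so inter-chain occlusion counts, then
  aggregated over the requested chain.
* TSV and CAID outputs render scores with 3 decimals (Python float
  formatting: round-half-even on the decimal expansion); coverage reports
  with 2.
* B-factors are rounded to 4 decimals at parse time: the parser backend
  stores float32, and pLDDT values are written with at most 2 decimals.
* Scores and calls are fully deterministic functions of the input file and
  the configuration; the only randomness in the package lives in the
  synthetic generators, which take explicit seeds.

## Problem sizes

The test-suite and the reproduction script use a 20-target synthetic suite
(~1,500 residues, ~6,000 atoms at 100 sample points/atom), 1,000 random
sequences for the smoothing oracle, 10⁵ random pairs for the Bind-score
property checks, and 20 profiles of ~280 residues for the window search —
sizes at which every quantity recomputes in seconds while all constructed
contrasts remain far from threshold boundaries.

## Known limitations

* Absolute SASA is a dialect: numbers differ slightly from DSSP/other
  engines and radii sets; the RSA threshold 0.581 was calibrated against a
  specific accessibility pipeline, so exact-parity studies should use the
  DSSP adapter.
* The calibrated constants (0.312 / 0.581 / 0.773, window 25) are
  benchmark-derived defaults, not re-derived here: re-deriving them requires
  the curated disorder references and the model database. The *procedure*
  (F1 maximisation, window grid search) is implemented and tested.
* No multi-model (NMR-style) ensembles, no gzipped batch input, no network
  access, no bootstrap confidence intervals.
* The Bind score inherits the printed formula's discontinuity at RSA = T;
  smoothing it is explicitly out of scope.
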
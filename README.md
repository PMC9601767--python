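# afdisorder

Per-residue **intrinsic disorder** and **conditional folding** prediction
from AlphaFold-style predicted structure models, with the CAID-style
evaluation and calibration machinery used to select its constants.

Intrinsically disordered regions (IDRs) lack a fixed tertiary structure;
predicted structure models nevertheless carry a strong disorder signal:
low-confidence (pLDDT) regions drape around the folded core as exposed
"ribbons", and sub-regions that are highly accessible *yet* confidently
modelled tend to be disordered binding regions that fold upon binding a
partner. `afdisorder` turns a model file (PDB or mmCIF with pLDDT in the
B-factor column, 0–100) into three per-residue scores in [0, 1]:

| score | definition | default threshold |
|---|---|---|
| `pLDDT` | 1 − pLDDT/100 | 0.312 (i.e. pLDDT < 68.8%) |
| `RSA` | relative solvent accessibility, mean over a 25-residue window (±12, mirrored termini) | 0.581 |
| `Bind` | RSA-score if ≤ T, else T + (pLDDT/100)·(1 − T), with T = 0.581 | 0.773 |

RSA is Shrake–Rupley SASA (internal engine, probe 1.4 Å) normalised by the
maximum accessibility of X in an extended Gly-X-Gly tripeptide (Sander
table by default) and clamped to [0, 1]. Binary calls use the ≥ rule at each
threshold. See `docs/methods.md` for assumptions, dialects and limitations.

The package also ships:

* **caid_eval** — pooled confusion counts, F1, Fmax over all thresholds,
  ROC AUC, target coverage, fully-disordered-protein calls,
* **calibration** — threshold selection by pooled-F1 maximisation and
  window-size grid search (odd windows, 1–50),
* **synthetic_structures** — seeded generators for small single-chain models
  with known ground truth (buried cores, disordered tails/linkers,
  exposed-confident binding segments) and for labelled noisy RSA profiles,
  so the whole pipeline is testable without any downloads.

## Worked example

```sh
python examples/predict_disorder.py
```

builds a 152-residue synthetic model (15-residue low-pLDDT tail, 125-residue
buried core, 12-residue exposed high-pLDDT segment) and prints:

```
pos  aa  pLDDT   rsa    s_pLDDT s_RSA  s_Bind  calls
  1  G    30.0  1.000  0.700   0.959  0.707   110
 71  G    92.0  0.195  0.080   0.171  0.171   000
152  G    90.0  1.000  0.100   0.919  0.958   011
```

The calls column is `pLDDT/RSA/Bind`: the tail is disordered by both single
scores but its Bind score (0.581 + 0.30·0.419 = 0.707) stays below 0.773 —
exposed *and* low-confidence is plain disorder, not binding. Core residues
are negative throughout. The exposed high-confidence segment scores
0.581 + 0.90·0.419 ≈ 0.958 and is called a conditional-folding/binding
region (011).

`python examples/evaluate_benchmark.py` scores a seeded 20-target suite and
pools residues into dataset-level metrics:

```
variant  reference  Fmax   AUC    coverage
pLDDT    disorder   0.976  0.993  1.00
RSA      disorder   0.974  0.999  1.00
Bind     binding    0.528  0.896  1.00
```

`python examples/calibrate_window_and_thresholds.py` re-runs the calibration
procedure on noisy block-disorder RSA profiles and prints the F1-by-window
curve and the selected threshold.

## Command line

```sh
afdisorder make-fixtures -n 20 --seed 1 -o fixtures/
afdisorder predict fixtures/ -o pred/                 # TSV + CAID files
afdisorder evaluate --pred pred/ --ref fixtures/reference_disorder.txt
afdisorder calibrate --pred pred/ --ref fixtures/reference_disorder.txt
```

`predict` accepts a single model file or a directory, writes one per-residue
TSV and three CAID-format prediction files per target, and exposes every
method constant as a flag (`--window`, `--thr-rsa`, `--n-points`,
`--max-asa-dialect`, ...) or via `--config key=value` files.

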
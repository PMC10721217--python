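# synspread

Models and simulators for the efficiency of retrograde monosynaptic tracing.
Given that a tracer crosses each individual synaptic contact independently
with probability `U` (unitary synaptic efficiency), the package relates the
fraction of synaptic contacts labeled on a starter neuron (`SF`) to the
fraction of its input neurons labeled (`IF`), corrects for inputs shared
between nearby starter cells, and provides a stochastic circuit simulator
plus a synthetic puncta-colocalization pipeline so every stage is testable
without any experimental data.

## Modules

- `synspread.spread_model` — closed-form two-population model
  (`p = 1 − (1 − U)^M`, `IF = (R·pa + pb)/(R + 1)`,
  `SF = (R·pa·Ma + pb·Mb)/(Ma·R + Mb)`), a general multiplicity-mixture
  variant, bisection inversion of `SF` for `U`, minimization of `IF/SF`
  over `R`, and parameter sweeps.
- `synspread.common_input` — distance-binned correction for labeling caused
  by inputs shared between starters (per-neighbor increment
  `shared_fraction · IF · (1 − IF)`), combination with the multiplicity
  correction, and the resulting `IF`/`U` estimates.
- `synspread.circuit_sim` — per-contact stochastic spread simulator over
  explicit starter/input contact graphs; the brute-force counterpart used
  to validate the closed forms.
- `synspread.synthetic_data` — seeded generators for circuits (multiplicity
  mixes, pairwise distance-dependent sharing), per-segment puncta-count
  tables (Poisson/binomial with optional beta overdispersion) and paired
  pre/postsynaptic point sets with planted ground truth.
- `synspread.coloc_quant` — anisotropic-ellipsoid apposition detection,
  per-neuron colocalization fractions with group mean/SEM,
  background-corrected `SF`, and the Wilcoxon rank-sum test (exact for
  small tie-free samples, tie/continuity-corrected normal otherwise).
- `synspread.report` — recomputes the twelve desk-scale headline numbers
  with pass/fail flags.

## Command line

The `synspread` entry point exposes the pipeline; every command that writes
a file also writes a `<out>.manifest.json` with its parameters, seed and
package version. Examples:

```sh
synspread model eval --r 2 --ma 1 --mb 2 --u 0.28          # IF, SF, IF/SF
synspread model solve-u --sf 0.4 --r 10 --ma 1 --mb 2      # invert SF for U
synspread model min-ratio --u 0.22 --ma 1 --mb 3           # min IF/SF over R
synspread model sweep --u 0.22,0.28,0.35 --r-grid 0.5,1,2,5,10 \
    --ma 1 --mb 2 --out sweep.csv
synspread correct --if-value 0.3 --starter-fraction 0.5    # shared-input correction
synspread generate circuit --spec circuit.yaml --seed 7 \
    --out-contacts circuit.tsv --out-starters starters.csv
synspread simulate --circuit circuit.tsv --u 0.28 --seed 1 --n-reps 50
synspread generate puncta --spec puncta.yaml --seed 21 --out puncta.csv
synspread quantify --table puncta.csv --group-by group
synspread reproduce --out report.json                      # all headline numbers
```

A circuit YAML looks like:

```yaml
n_starters: 2
inputs_per_starter: 5000
multiplicity_mix: [[1, 0.92], [2, 0.067], [3, 0.013]]
starter_positions: [[0, 0, 0], [40, 0, 0]]
sharing_profile: [[0, 50, 0.05], [50, 100, 0.033], [100, 200, 0.01]]
```

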
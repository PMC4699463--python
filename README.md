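# displaceq

Quantitative analysis of fluorescent-probe displacement assays for
RNA-binding compound libraries: binding/protonation equilibria, titration
fitting, 96-well plate screening with Z'-factor QC, positional
amino-acid preference statistics, and seeded synthetic-data generators.

## What it does

- **equilibria** — tight-binding (ligand-depletion) quadratic
  fluorescence isotherm; numeric two-ligand/one-site-class competitive
  mass-balance solver; monoanion/dianion fluorophore ionization; pKa-shift
  to apparent electrostatic potential (kT/e and volts).
- **fitting** — dissociation-constant fits of probe titrations,
  binding-site multiplicity selection by residual comparison, pKa fits of
  pH titrations, four-parameter-logistic IC50 fits of displacement
  titrations (all `scipy.optimize` least squares, deterministic starts).
- **screening** — Z'-factor with the excellent/marginal/unacceptable
  verdict scale, per-plate percent-binding normalization against the
  on-plate neomycin control, duplicate summarization, hit calling
  (default threshold 110%).
- **preferences** — per-compound sigma deviations (library z-scores),
  positional class averages (`NeoRX`, `NeoXS`, `NeoX`, ...), and
  cross-target specificity deltas for conjugate names like `NeoRS`
  (beta-alanine written `βA`, ASCII alias `bA`).
- **synthetic_data** — seeded generators for probe/displacement/pH
  titrations, ground-truth conjugate libraries with additive positional
  effects on log10(kd), full multi-plate single-point screens, control
  plates, and a dot-bracket bulge/internal-loop counter.
- **io_cli** — long-format plate tables, two-column titration tables,
  screen reports, JSON/key-value fit reports, YAML run configuration and
  the `displaceq` command-line interface.

## Command line

```sh
displaceq simulate --preset mir504 --seed 7 --out plates.csv
displaceq zfactor --plates plates.csv
displaceq screen --plates plates.csv --threshold 110 --out screen.csv
displaceq prefs --screens screen.csv --ids mir504 --out classes.csv
displaceq fit-kd --input titration.csv --probe-total 100 --estimate-sites
displaceq fit-ic50 --input displacement.csv
displaceq fit-pka --input ph_titration.csv
displaceq phi 6.37 7.45
displaceq bulges "(((.(((....))).)))"
```

Presets `mir504`, `premir504`, `mir142`, `mir335` encode the four assay
conditions (probe 100 nM; RNA 50/16.7/100/100 nM; screen compound
concentration 300/300/500/500 nM; 2/6/1/1 binding sites per RNA).
Every subcommand exits non-zero on validation errors; `-v` increases
logging on stderr.

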
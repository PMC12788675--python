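# nanodosim

Event-by-event Monte Carlo track-structure simulation of low-energy
electrons (8 eV – 1 MeV tabulation range; 20 eV – 10 keV study energies) in
liquid water, driven by interchangeable **total interaction cross-section
datasets**, with:

- scoring of **ionization cluster size distributions** (ICSDs) in
  nanometric spheres (8 nm / 100 nm in the reference configuration);
- nanodosimetric summary quantities M1, F2, F3 with binomial / GUM
  uncertainty propagation;
- **inter-dataset variability** metrics: Wasserstein-1 (earth-mover)
  distances between ICSDs and MV/SD/RSD dispersion with propagated
  uncertainties;
- a **harmonization experiment** driver: run a family of datasets with
  their own cross sections ("initial" phase), then re-run every member
  with the channel-wise arithmetic-mean "common" dataset ("final" phase)
  and quantify how much of the inter-dataset variability the totals
  explain;
- a **synthetic-data module** that fabricates realistic dataset families
  (multiplicative log-normal spread, large at low energy and shrinking
  with energy) and ICSD families, so the full pipeline is testable without
  any proprietary datasets.

## Layout

| module | role |
| --- | --- |
| `nanodosim.xsec` | dataset model, TSV template I/O, interpolation, channel probabilities, averaging |
| `nanodosim.synthetic` | synthetic dataset/ICSD families |
| `nanodosim.transport` | electron cascade transport (pure-Python reference loop + numba fast path) |
| `nanodosim.scoring` | ICSD construction and I/O |
| `nanodosim.stats` | M_k, F_k and their uncertainties |
| `nanodosim.variability` | W1 machinery, dispersion, harmonization experiment |
| `nanodosim.config` / `nanodosim.pipeline` / `nanodosim.cli` | configuration, orchestration, CLI |
| `nanodosim.intercomparison` | published per-code benchmark values used by the validation layer |

Units throughout: eV (energy), nm (length), nm² (cross section).

## CLI

```bash
nanodosim synth --members 7 --seed 1 --out family/
nanodosim average family/*.tsv --out common.tsv
nanodosim simulate --xsec common.tsv --energy 100 --histories 1000 --seed 1 --out events.tsv
nanodosim score --tracks events.tsv --diameter 8 --out icsd.tsv
nanodosim analyze icsd*.tsv --out analysis/
nanodosim experiment --config config.yaml --out report/
```

`experiment` runs the full two-phase pipeline (synthetic or on-disk family
→ averaging → transport → scoring → statistics → variability) and writes a
deterministic report bundle (TSV tables + JSON manifest keyed by the
configuration hash). Re-running with the same master seed reproduces the
bundle byte-for-byte.

Configuration is YAML/JSON; defaults mirror the reference study
(energies 20 eV–10 keV, 8/100 nm spheres, 10⁵ histories, 10 eV cutoff).

## Cross-section template

Tab-separated, two header rows, comments with `#`:

```
E_eV   ion1 ... ion5   exc1 ... exc5   elastic
transition_eV  B1 ... B5   W1 ... W5   -
8.0    0 ... 1.14
...
```

Ionization columns must be zero below 10 eV and at or below each shell's
binding energy; grids are strictly increasing.

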
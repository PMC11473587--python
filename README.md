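# uvcbkit

A toolkit for predictive risk assessment of UVCB substances (mixtures of
Unknown or Variable composition, Complex reaction products, or Biological
materials), applied to metal naphthenates:

1. **design_registry** — declarative library designs (scaffolds with
   attachment positions, alkyl and carboxylic-acid R-group sets) in YAML,
   with a packaged naphthenic-acid design (8 cores, 26 alkyl chains, 15
   acid chains).
2. **enumerator** — two-step combinatorial enumeration (one alkyl + one
   acid per core over all declared positions), canonicalization, and
   deduplication on InChIKey connectivity blocks. The packaged design
   enumerates to **11,850 unique structures**.
3. **profiler** — molecular weight, cyclization degree (ring heavy atoms /
   total heavy atoms), skeleton keys, local registry-table matching, and
   molecular-weight distribution summaries.
4. **readacross** — Morgan-fingerprint, similarity-weighted read-across
   (k-nearest analogs, Tanimoto weighting) with four-color POD binning.
5. **predictions** — ingestion of external QSAR prediction tables (LD50,
   log10-POD endpoints), EPA/GHS acute oral hazard categorization, and
   dual log/antilog POD range summaries.
6. **salt_composition** — acid-number stoichiometry: mg KOH/g titration
   values to molar acid content, metal:acid stoichiometry, and
   metal/naphthenate weight-fraction ranges (packaged Cu/Zn/Co registry).
7. **risk_assessment** — HGV equivalents from PODs and uncertainty
   factors, dose partitioning into concurrent metal/organic exposures,
   driver-of-toxicity determination against MRLs, and provisional limit
   recommendations.
8. **workflow/cli** — single-config orchestration with a reproducible run
   manifest.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(weighted-mean boundedness, mass balance, hazard-category monotonicity,
similarity symmetry), an independent brute-force enumeration oracle, and
`tests/test_acceptance.py` with one test per acceptance criterion. The
full-library enumeration runs once per session (~30 s).

## CLI

```sh
uvcb run --config config.yaml          # full workflow
uvcb enumerate --design paper --out out/           # 11,850 structures
uvcb profile --library out/library.csv --out profiles.csv
uvcb readacross --targets t.csv --analogs a.csv --out ra.csv
uvcb predictions --table opera.csv \
     --endpoint rat_chronic_pod_log10:chronic:log10-mg/kg/day:log10 --out s.json
uvcb composition --metal Cu --acid-number 225:270
uvcb assess --metal Zn --study noael=118 --uf 10,10
```

A workflow config looks like:

```yaml
design: paper            # or a path to a design YAML
output_dir: run/
registry_table: dsstox_keys.csv     # optional: skeleton-key matching
analog_table: analogs.csv           # optional: read-across
prediction_tables:                  # optional: QSAR export ingestion
  - path: opera_export.csv
    endpoints:
      rat_chronic_pod_log10: {name: rat_chronic_pod, units: log10-mg/kg/day, scale: log10}
assessments:
  - {metal: Cu, study: {pod: 30}}
  - {metal: Zn, study: {pod: 118}}
  - {metal: Co, whole_dose: 1.2}
```

Stages without inputs are skipped (and logged); every run writes
`run_manifest.json` with artifact hashes, so unchanged configs are
byte-reproducible.
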
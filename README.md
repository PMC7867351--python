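# soilmatch

Enzyme-biosensor soil analysis. Given a test soil's eight measured
characteristics — three enzymatic endpoints (residual BChE activity RA,
two-enzyme and three-enzyme residual bioluminescence T2/T3) plus five
physicochemical properties (extract optical density at 250 nm, humus, pH in
KCl, physical clay, physical sand) — the package:

- finds the closest standard (reference) soil by Euclidean distance over the
  raw eight-feature vectors (optionally standardized per coordinate),
- classifies enzymatic impact from residual luminescence
  (&gt; 80 % no impact, 50–80 % impact, &lt; 50 % significant impact;
  boundaries go to the middle class),
- reports a normalized side-by-side comparison where each matched-reference
  characteristic is scaled to 100 %,
- generates seeded synthetic reference databases (default: 17 categories ×
  3 replicates = 51 records) whose features stay inside the observed ranges
  and follow the documented texture/humus gradients.

Reference databases are flat JSON arrays keyed by
`RA, T2, T3, D250, Humus, pH, Clay, Sand, Sample Name`; a `js-wrapped`
dialect (`var refs = [...];`) is read by textual stripping, never evaluated.

## CLI

```sh
# generate a synthetic reference database (51 records by default)
soilmatch generate --seed 1 -o refs.json

# summarize a database: per-feature extrema and category counts
soilmatch summarize refs.json

# match a test soil against the database
soilmatch match --db refs.json \
  --ra 108.79 --t2 90.78 --t3 78.55 --d250 0.25 \
  --humus 0.38 --ph 8 --clay 6.7 --sand 90.4 --format json

# classify residual endpoints
soilmatch classify --t2 90.78 --t3 78.55
```

Exit codes: 0 success, 1 data error, 2 usage error. Logs go to stderr, so
`--format json` output on stdout is machine-parseable. BChE kinetics can be
supplied inline to `classify` as `--kinetics-test 0:0.10,60:0.13,...`
together with `--kinetics-control`; the rate is the OLS slope of optical
density versus time.

## Library

```python
import soilmatch as sm

db = sm.load_reference_db("refs.json", dialect="auto")
query = sm.QuerySample(ra=109.0, t2=90.78, t3=78.55, d250=0.25,
                       humus=0.38, ph=8.0, clay=6.7, sand=90.4)
result = sm.find_reference(db, query)
print(result.index, result.reference.name, result.distance)
```

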
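# vegrisk

Measurement and evaluation of pesticide-residue risk in vegetables from
regulatory supervision and sampling data.

Provincial market-supervision bureaus publish batch-level inspection results
for vegetables in circulation: which pesticides were detected in a sampled
batch and at what concentration, against the national maximum residue limits
(MRLs, GB 2763). `vegrisk` turns those disclosures into a quantitative risk
picture for regulators and analysts:

1. **Cleaning & harmonization** — delimiter-separated inspection tables are
   validated row by row (synonym harmonization of vegetable / pesticide /
   province names, unit normalization to mg/kg, counted drops for missing or
   unmappable rows) with a fully reconciled cleaning report.
2. **Compliance screening** — a batch is non-compliant when any residue
   strictly exceeds its MRL or a banned pesticide is detected at all. Its
   hazard follows the worst-case principle: S_n = max_k C_k / MRL_k over the
   violating detections.
3. **Risk index** — risk is probability × severity. For each province *i* ×
   vegetable *j* stratum, P_ij = M_ij / N_ij (non-compliant over sampled
   batches), S_ij is the mean worst-case hazard of its non-compliant
   batches, and IR_ij = P_ij × S_ij. Direct weighting pools strata to
   vegetable level (P_j = ΣM_ij / ΣN_ij, S_j = Σ S_ij N_ij / Σ N_ij) and to
   province level. The threshold IR₀ = 0.02 (98% acceptable pass rate ×
   acceptable hazard 1) separates low from high risk: IR ≥ 0.02 is high.
4. **Spatial trajectory** — each year's risk centroid is the IR-weighted
   mean of provincial-capital coordinates; the year-over-year transfer is
   reported as degree-space displacement, great-circle kilometres
   (haversine, R = 6371 km) and a bearing/quadrant label such as
   "Northeast to Southwest".
5. **Synthetic surveillance data** — national supervision databases are not
   openly deposited, so a seeded generator emulates their structure (skewed
   stratum batch counts, Bernoulli exceedances, shifted-log-normal
   exceedance multiples with a heavy tail, banned-pesticide detections) and
   drives every test end to end.

## Worked example

`examples/screen_batches.py` screens four hand-written batches:

```
batch_id province vegetable  year  compliant  hazard trigger_pesticide     trigger_kind
   c-001  Jiangsu    celery  2021       True     0.0                               none
   c-002  Jiangsu    celery  2021      False     2.5      imidacloprid       over-limit
   c-003  Jiangsu    celery  2021      False     5.0      chlorpyrifos banned-detection
   l-001    Henan      leek  2022      False     2.6       procymidone       over-limit
```

Batch c-002 exceeds two limits (2.5× and 2.0×); the worst case, 2.5, is its
hazard. Batch c-003 carries a banned pesticide — non-compliant at any
level — scored against the 0.01 mg/kg policy reference (0.05/0.01 = 5).
Batch l-001's 520 µg/kg is normalized to 0.52 mg/kg, 2.6× its 0.2 mg/kg
limit.

`examples/rank_vegetables.py` runs the full pipeline on the packaged
synthetic scenario (15,984 batches, 168 strata, seed 7) and prints the
vegetable ranking; its top of table:

```
 rank       vegetable  group_count    n   m  p_pct     s    ir risk_class
    1            leek           12 1044 117  11.21 9.944 1.114       high
    2          cowpea           12 1080 108  10.00 8.924 0.892       high
    3          ginger           12  900  99  11.00 3.930 0.432       high
```

`p_pct` is the exceedance probability in percent, `s` the mean worst-case
hazard of non-compliant batches, `ir = p × s`, and `risk_class` compares ir
with IR₀ = 0.02. `examples/track_risk_centroid.py` shows the planted
northeast → southwest migration of the risk centroid, and
`examples/simulate_and_clean.py` the generator and its cleaning audit.

The same pipeline is scriptable from a shell:

```bash
vegrisk report --scenario --seed 7 --outdir out/          # full bundle
vegrisk simulate --seed 7 --outdir data/                  # staged…
vegrisk assess --records data/records.csv --mrl data/mrl.csv --outdir out/
vegrisk risk --assessments out/assessments.csv --outdir out/
vegrisk centroid --assessments out/assessments.csv --outdir out/
```

## Layout

- `src/vegrisk/ingest.py` — table reading, harmonization, unit
  normalization, MRL matching, cleaning report
- `src/vegrisk/compliance.py` — per-batch screening and worst-case hazard
- `src/vegrisk/risk.py` — stratum/vegetable/province risk indices,
  threshold classification, composition and descriptive tables
- `src/vegrisk/spatial.py` — risk centroid, haversine distance, bearing and
  transfer labels
- `src/vegrisk/synthetic.py` — seeded scenario generator
- `src/vegrisk/pipeline.py`, `src/vegrisk/cli.py` — orchestration and the
  `vegrisk` command
- `docs/methods.md` — model, conventions, calibration and limitations
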
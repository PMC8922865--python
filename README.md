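# rankcutoff

Cutoff-point identification for **descriptive** high-throughput biology —
datasets where many continuous variables (gene expression in a tissue,
protein abundance, chemical-sensitivity scores) are measured in a single
sample, with no treatment groups or phenotypes to regress against.

When such values are sorted ascending and plotted against their rank, the
curve is almost always biphasic: a long first phase of values growing slowly
with rank, then a short second phase growing rapidly. The variables in the
steep tail are the ones assumed to dominate the system's biology. This
package finds the boundary between the two phases and turns it into a
shortlist.

## The method

Let the ranked values be the curve *A* with points `(R, V_R)`, `R = 1..N`.

1. Draw the chord *B* from the first ranked point `(1, V_min)` to the last
   `(N, V_max)`:  `y = m_B x + b_B` with `m_B = (V_max − V_min)/(N − 1)` and
   `b_B = V_min − m_B`.
2. For every curve point, drop a perpendicular onto *B* and measure its
   length. The perpendicular through `(R, V)` has intercept
   `b_C = V + R/m_B`, meets the chord at
   `y_CB = (b_B + b_C m_B²)/(1 + m_B²)`, `x_CB = (y_CB − b_B)/m_B`, and the
   segment length follows from the Pythagorean theorem. This all collapses
   to the point-to-line distance

   ```
   D(R) = |V − m_B R − b_B| / sqrt(1 + m_B²)
   ```

3. The cutoff is the rank maximising `D` — the bending point of the curve.
   The **shortlist** is every variable ranked *strictly above* the cutoff
   (the cutoff record itself is excluded), so with `N` records and cutoff
   rank `k` the shortlist has `N − k` members.

The cutoff is invariant under positive affine transforms of the values and,
on noiseless two-segment convex profiles, lands exactly on the junction.
A truncation sweep (stepwise removal of the lowest values with full
recomputation) quantifies how robust the cutoff is to low-abundance
detection dropout, and a low-tail control list (the same number of
lowest-ranked *non-zero* variables) supports negative-control enrichment
analyses.

## Worked example

Generate a synthetic biphasic table (12,000 records, true knee at rank
11,300, mild additive noise) and run the pipeline:

```
$ rankcutoff simulate --n 12000 --knee-rank 11300 --s1 0.002 --s2 1.0 \
      --noise-sd 5 --seed 3 --out demo.tsv
wrote 12000 records to demo.tsv

$ rankcutoff find --input demo.tsv --out-shortlist shortlist.tsv \
      --out-summary summary.json
{"n": 12000, "m_B": 0.06030164469598472, "b_B": -0.06030164469598472,
 "cutoff_rank": 11275, "cutoff_id": "v11269", "cutoff_value": 31.94013910125392,
 "max_distance": 646.7258293857744, "shortlist_size": 725, "tie_count": 1,
 "reference_rank": 11275, "stringency_offset": 0.0, "version": "0.1.0",
 "input_sha256": "7d1c..."}
```

The chord has slope 0.0603 and intercept −0.0603 (the data's minimum is 0,
so the chord passes through `(1, 0)` and the intercept is `−m_B`). The
longest perpendicular segment (length 646.7) falls on rank 11,275 — 25 ranks
below the true knee, pulled by the noise — so the 725 records ranked
11,276–12,000 form the shortlist, written highest-value-first to
`shortlist.tsv`.

```
$ rankcutoff robustness --input demo.tsv --increment 1000
{"n": 12000, "increment": 1000, "steps": 12, "max_stable_fraction": 0.083...}
```

With this noise level the shortlist stays *identical as a set* only through
the first 1,000-record removal (8.3% of the data); the per-step table
(`--out-table`) additionally reports the cutoff identity and the shortlist
overlap with the full-data run at each step, which degrade far more
gracefully. On noiseless profiles the cutoff survives removal of everything
but two points of the first phase.

Other useful flags: `--stringency 0.05` shifts the cutoff rank by
`+0.05·N` (the unadjusted rank is kept as `reference_rank` in the summary),
`--control-list ctl.tsv` writes the equivalent-size low-tail control list,
and `--plot curve.png` draws the ranked curve with the chord and cutoff
marker.

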
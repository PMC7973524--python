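# hicloops

Chromatin-loop and significant-contact annotation for balanced Hi-C
contact matrices.

Loops — focal contact enrichments between two genomic anchors — are
called against a **per-diagonal Weibull background model**: for every
genomic separation *d* the balanced pixel intensities are fitted by
maximum likelihood with a two-parameter Weibull distribution
(shape *k_d*, scale *λ_d*), and each pixel receives the upper-tail
p-value

    p(x) = exp( −(x / λ_d)^k_d )

i.e. the probability of an equally or more intense pixel under that
distance's background. Benjamini–Hochberg correction within each diagonal
yields q-values, optionally rescaled by the chromosome's distance-decay
profile. Significant pixels are clustered with DBSCAN at neighbourhood
radius 1 (4-adjacency on the pixel lattice); each cluster of at least
`min_cluster` pixels becomes a loop at its brightest pixel. Called loops
can be filtered by APA and PA scores (centre vs. the 3×3 corner of an
11×11 window), centre intensity, neighbourhood zeros, radial signal decay
and enrichment over random same-distance pixels; loop sets called at two
resolutions are merged by 70 % reciprocal span overlap. The same
significance machinery, run without clustering or filters, yields
significant contacts whose promoter-overlapping anchors annotate
enhancer–promoter interactions (promoter = strand-aware 1 kb upstream of
the TSS).

Inputs are cooler-schema HDF5 containers (single-resolution `.cool`,
multi-resolution `.mcool` addressed as `path::/resolutions/<res>`) or a
plain-text sparse-triplet fallback; outputs are BEDPE (loops), TSV
(contacts / EP interactions) and JSON run summaries. A synthetic Hi-C
generator with planted-loop ground truth makes every stage testable
without external data. See `docs/methods.md` for the model details and
design decisions.

## Worked example

Simulate a 500×500-bin matrix (10 kb bins) with 20 planted loops, call
loops, and compare runs:

```sh
hicloops simulate --n-bins 500 --n-loops 20 --fold 8 --seed 1 \
    --out-prefix demo
hicloops call-loops --matrix demo.cool --chrom chrS \
    --preset default --out demo.bedpe
hicloops compare demo.bedpe demo.bedpe
```

The call step logs the calling statistics to standard error:

```
[INFO] loaded demo.cool: 500 bins at 10000 bp
[INFO] 1184 significant pixels -> 21 loops before filters
[INFO] filter APA        removed 0
...
[INFO] wrote 21 loops to demo.bedpe
```

1184 pixels pass the per-diagonal q ≤ 0.1 threshold (planted foci plus the
expected scatter of single-pixel false positives); they group into 21
clusters of ≥ 3 adjacent pixels — the 20 planted loops plus one chance
cluster — and the comparison of the run with itself reports full
reciprocal overlap:

```
set	n	n_overlap	frac_overlap
A	21	21	1.0000
B	21	21	1.0000
```

`demo.bedpe` holds one loop per line: the two 10 kb anchors, a
`-100·log10(q)` display score, then q-value, APA, PA, centre intensity and
resolution columns. The same library calls are available in Python:

```python
import hicloops as hl

cm = hl.load_matrix("demo.cool", chrom="chrS", resolution=10000)
loops = hl.call_loops(cm, hl.get_preset("default"))
print(len(loops), loops[0].anchor1, loops[0].q_adj)
```

For enhancer–promoter annotation on real-style inputs:

```sh
hicloops call-ep --matrix sample.mcool --resolution 25000 --chrom chr1 \
    --tss tss.tsv --max-distance 2000000 --out chr1_ep.tsv
```

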
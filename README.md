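# anoht — possibly gapped histograms and analysis of histogram

`anoht` builds **data-driven histograms whose bins are uniform parts,
possibly separated by true gaps**, and uses them as the backbone of a
two-phase comparison of treatment groups ("analysis of histogram", ANOHT).
It is aimed at biostatisticians and data analysts who need to find
mechanistically meaningful discontinuities in one-dimensional measurements —
morphometric features, pitch speeds, survival times — rather than smooth
density estimates that erase them.

## The model

A histogram is a serial composition of uniform parts `U_p[a_j, b_j]`, with
gaps allowed between consecutive parts.  The candidate set on `n` sorted
points is a two-layer Ising ensemble of size `3^(n-1)`: one spin per spacing
(same bin / boundary), plus a gap/no-gap spin per boundary.  Decoding a bin
by the expected uniform order statistics incurs the decoding error sum of
squares

    DESS = m (b-a)^2 / (6(m+1)) + Σ_k [x_(k) − (a + (b−a) k/(m+1))]²,

whose mean under uniformity is `(b−a)² m/(3(m+1)) ≈ (b−a)²/3` — independent
of sample size, which makes it a usable uniformity criterion.  The energy of
a candidate histogram balances decoding error against boundary coding cost,

    H = Σ_j DESS_j + L0 · (B − 1),

with `L0` (default `0.1 ×` tree height) the exchange rate between the two.
Minimising `H` exactly is exponential; the package instead walks a
hierarchical-clustering tree (complete linkage by default; single linkage is
excluded) top-down, stopping a branch when its segment's DESS drops below
`L0` or passes the uniformity band.  Gaps between consecutive bins are
confirmed when the theoretically extended boundaries
`a−r/(m+1), b+r/(m+1)` do not cross.

**Phase 1** colours each bin by treatment and scores its composition by the
entropy ratio `H_k / H_0` with permutation p-values (sampling without
replacement, one-sided toward segregation).  **Phase 2** turns the
treatment×bin counts into row frequencies, builds a treatment tree, and
scores each branch's *authenticity*: the fraction of trees built on
mimicked rows — each row perturbed by the exact Brownian-bridge increment
covariance `Σ* = diag(p) − p pᵀ` scaled by `1/n_j` — in which the branch
re-forms at a rank no higher than in the reference tree.  For
right-censored data the same machinery runs on Kaplan–Meier survival
decrements or Nelson–Aalen hazard increments, with the plug-in covariances
`Σ#` and `Σ**` built from `∫ dF_u/(1−H)² ≈ n Σ δ_(i)/((n−i)(n−i+1))`, and
histogram bin masses re-weighted by redistribution-to-the-right.

## Worked example

```python
import anoht

s = anoht.iris_fixture(standardize=True)["petal_length"]
h = anoht.build(s, l0_frac=0.1)
for k, b in enumerate(h.bins):
    print(f"bin {k}: m={b.m:3d} [a,b]=[{b.a:+.4f},{b.b:+.4f}] "
          f"[a^,b^]=[{b.a_hat:+.4f},{b.b_hat:+.4f}] DESS={b.dess:.4f}")
print(h.gap_flags)

rep = anoht.phase1_report(h, reps=2000, seed=7)
print(rep["overall"]["weighted_entropy"], rep["overall"]["p"])

tree = anoht.authenticity(anoht.treatment_bin_table(s, h), mimics=10_000, seed=7)
print(tree.to_newick())
```

prints

```
bin 0: m= 50 [a,b]=[-1.5623,-1.0525] [a^,b^]=[-1.5723,-1.0425] DESS=0.2463
bin 1: m= 11 [a,b]=[-0.4294,+0.0804] [a^,b^]=[-0.4719,+0.1229] DESS=0.1235
bin 2: m= 55 [a,b]=[+0.1371,+0.7602] [a^,b^]=[+0.1260,+0.7713] DESS=0.1729
bin 3: m= 28 [a,b]=[+0.8169,+1.3267] [a^,b^]=[+0.7993,+1.3443] DESS=0.0612
bin 4: m=  6 [a,b]=[+1.4400,+1.7799] [a^,b^]=[+1.3914,+1.8284] DESS=0.0248
[True, True, True, True]
0.2211 0.0
(setosa,(versicolor,virginica)1.0000)1.0000;
```

The first bin is exactly the 50 *setosa* flowers; its extended right
boundary (−1.0425) does not cross the next bin's extended left boundary
(−0.4719), so the *setosa* gap is an existential one.  The overall weighted
entropy 0.2211 has permutation p-value 0 (species segregate strongly across
bins), and the {*versicolor*, *virginica*} branch re-formed in 100% of
10 000 mimicked species trees.

The same pipeline is available from a shell:

```sh
hist build --input data.csv --l0-frac 0.1 --linkage complete --out report.json
anoht phase1 --input data.csv --reps 10000 --seed 7
anoht phase2 --input data.csv --mimics 10000 --seed 7
anoht censored --input surv.csv --basis na --mimics 10000 --seed 7
anoht synth --preset gapped2 --n 400 --seed 7 --out data.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch — gapped histograms, both ANOHT
phases with 10 000 mimics on the bundled Iris fixture, and a censored-data
run on a seeded synthetic three-treatment sample — and writes its JSON
report to `--out`.

See `docs/methods.md` for the statistical details, numerical conventions and
known limitations.
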
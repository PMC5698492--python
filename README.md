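# dsfdr — discrete FDR control for sparse microbiome tables

Differential-abundance testing in microbiome surveys runs one two-sample
test per taxon — often thousands of taxa, most of them rare — and then
corrects for multiple testing. Count tables from 16S/metagenomic
experiments are extremely sparse, so rank-based test statistics take few
distinct values and their permutation p-values are coarsely discrete:
many taxa cannot reach a small p-value at all. The Benjamini-Hochberg
(BH) procedure stays valid in this regime but becomes needlessly
conservative, and its power collapses as rare taxa pile up.

`dsfdr` implements a permutation plug-in procedure that works on the test
statistics directly. For each feature *j* compute a statistic *T_j* (the
difference of group mean ranks, or equivalently a centered Mann-Whitney
U), permute the sample labels *B* times to obtain null statistics
*T\*_jb*, and for a cut-point *C* estimate

    V̂(C) = Σ_j [ Σ_b 1(|T*_jb| ≥ C) + 1(|T_j| ≥ C) ] / (B+1)
    R̂(C) = Σ_j 1(|T_j| ≥ C),        FDR̂(C) = V̂(C) / R̂(C)

then reject all features with |T_j| ≥ Ĉ, where Ĉ is the smallest
cut-point with FDR̂(C) ≤ q (Ĉ = ∞, rejecting nothing, if none qualifies).
Taxa whose permutation null cannot reach *C* contribute nothing to V̂, so
rare, heavily discrete taxa stop taxing the correction. Two comparators
are included: plain BH on the permutation p-values, and filtered BH
(FBH), which first drops taxa whose *minimal achievable* p-value — the
exact p-value of the most extreme relabeling — cannot reach *q*, then
runs BH on the survivors.

The package also ships the simulators and harnesses used to validate the
procedures: a sparse multinomial community generator with known ground
truth (differential / null / rare taxon blocks), data-driven
resample-split null and signal-spiking protocols that preserve cross-taxon
dependence, and replicate-based FDR/power evaluation with filter-level and
sample-size sweeps.

## Worked example

```sh
python examples/differential_abundance_test.py
```

simulates a 220-taxon community (20 truly differential, 20 null, 180
rare; 15 samples per group) and tests it with all three procedures at
q = 0.1 on a shared set of 1000 label permutations:

```
220 taxa, 30 samples, q = 0.1

method  rejected  true  false    FDP
 dsfdr        22    20      2  0.091
   fbh        21    20      1  0.048
    bh        20    20      0  0.000
```

Each row reports how many taxa the procedure rejected and, using the
simulator's ground truth, how many of those were truly differential. All
three control the false-discovery proportion under the nominal 10%; the
discrete procedure rejects the most. The margins widen sharply at smaller
sample sizes and higher sparsity — `examples/sample_size_power_curve.py`
and `examples/filter_sensitivity.py` show the discrete procedure finding
signals at cohort sizes where BH finds none, and staying flat across
abundance-filter levels that BH depends on.

The same analysis runs from the shell on TSV/BIOM tables with a
QIIME-style mapping file:

```sh
dsfdr run --table table.tsv --metadata map.tsv --group-column Status \
      --method dsfdr --alpha 0.1 --permutations 1000 --seed 0 \
      --output results.tsv
dsfdr simulate --preset sim1 --n-per-group 20 --seed 0 --outdir sim/
dsfdr evaluate --preset sim1 --replicates 20 --seed 0 --output summary.tsv
```

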
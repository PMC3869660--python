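# aimpanel

Design and evaluation of ancestry-informative-marker (AIM) panels for
multi-way admixed populations.

## The problem

Admixture confounds genetic association studies: if cases and controls carry
different ancestry proportions, allele-frequency differences between source
populations masquerade as disease associations.  Genome-wide data lets one
estimate each individual's ancestry proportions and adjust for them, but
candidate-gene and follow-up studies often cannot afford genome-wide
genotyping.  A small panel of AIMs — SNPs chosen for large allele-frequency
differences between the source populations — is the cost-effective
alternative.  This package implements panel design for admixtures of any
number of source populations (its motivating case is a five-way admixture of
African San, African non-San, European, South Asian and East Asian
ancestry), together with the machinery to ask whether a panel is good
enough: how well do ancestry proportions estimated from the panel track
proportions estimated from genome-wide data?

## The method

**Ranking markers.** For a biallelic SNP with allele-1 frequency `p_i` in
each of `K` populations, Rosenberg's informativeness for assignment is

```
In = Σ_{j∈{1,2}} ( −p̄_j ln p̄_j + Σ_{i=1..K} (p_ij / K) ln p_ij ),
```

with `p̄_j` the unweighted mean frequency of allele `j` across populations
and `0·ln 0 := 0`.  `In` is the expected log-likelihood ratio for assigning
a random allele to its population of origin versus the "average" population;
it is 0 when all populations share a frequency and at most `ln 2` for a
biallelic marker.

**Balancing pairs.** Ranking by the K-population `In` alone over-serves the
most diverged populations.  The selector therefore keeps a running `In`
total for each of the `C(K,2)` population pairs (all starting at zero),
repeatedly finds the pair with the smallest total, and adds the best
remaining marker for that pair, crediting the marker's pairwise `In` to the
pair.  An optional first stage takes a configurable proportion of the panel
by multi-population `In` rank.  Before acceptance every candidate must be
new, not in linkage disequilibrium with any selected marker (genotypic
r² ≤ threshold, default 0.2), and more than a minimum distance (default
100 kb) from any selected marker on the same chromosome.  The result is a
panel roughly equally informative for every pair of sources, with markers
per pair inversely related to the pair's genetic distance.

**Estimating and evaluating.** Ancestry proportions are estimated per
individual by maximizing the supervised admixture likelihood — each allele
copy drawn from population `k` with probability `q_k` and then from that
population's fixed reference frequency — via EM (`SupervisedAdmixture` /
`SupervisedAdmixtureResults`).  Panels are judged by per-ancestry Pearson
correlation and RMSE between panel-based and genome-wide estimates,
including a permutation protocol over random sub-cohorts and a panel-size
sweep.  A Balding-Nichols + Dirichlet simulator provides cohorts with known
ancestry truth for end-to-end validation.

## Worked example

```python
import aimpanel as ap

study = ap.simulate_study(n_snps=4000, k=5, n_admixed=60, n_per_pop=30, seed=7)
sel = ap.select_aims(study.freq_table, study.snp_map, study.admixed,
                     ap.SelectionConfig(n_aims=24))
print(sel.panel.table[["rank", "snp_id", "chrom", "bp", "selected_for", "in_value"]].head(6))
```

```
 rank  snp_id chrom        bp selected_for  in_value
    1 snp1559     6  60044840      san:sas  0.487895
    2 snp3593    18   9378424      afr:san  0.484746
    3 snp3558    17  60283041      eas:san  0.471286
    4  snp169     1 114390098      afr:sas  0.449916
    5 snp2842    12  95869353      afr:eur  0.447606
    6 snp3699    19   6246006      afr:eas  0.436483
```

Every pair total starts at zero, so the first ten picks serve the ten pairs
in turn, each with its strongest marker (`in_value` is the pairwise
informativeness, near its `ln 2 ≈ 0.693` ceiling for well-differentiated
pairs).  Fitting the supervised model on the admixed cohort with the panel's
reference frequencies:

```python
f_panel = ap.SourceFreqs.from_freq_table(study.freq_table.restrict(sel.panel.snp_ids))
res = ap.SupervisedAdmixture(study.admixed, f_panel).fit()
print(res.summary())
```

```
Supervised admixture estimation
===============================================
Individuals: 60    Markers: 24    Populations: 5
EM iterations: 409    converged: True
Total log-likelihood: -1692.7162

ancestry            mean   median             IQR
-------------------------------------------------
san               0.2843   0.2680    0.121-0.452
afr               0.2401   0.2163    0.075-0.358
eur               0.1999   0.1759    0.015-0.324
sas               0.1519   0.1313    0.004-0.230
eas               0.1239   0.0620    0.000-0.214
```

`ap.evaluate_panel(res.ancestry, study.q_true)` then reports per-ancestry
correlation against the simulation's known truth — with only 24 markers the
major components reach r ≈ 0.5–0.7 here; ~100 markers push the major
components above 0.8 (see the sweep below).

The same pipeline is scriptable from the shell:

```
aimpanel simulate --n-snps 20000 --k 5 --n-admixed 200 --seed 1 --out-prefix sim
aimpanel select   --freqs sim.frq.strat --bim sim.bim --traw sim.traw \
                  --n-aims 96 --out-panel panel.tsv
aimpanel evaluate --traw sim.traw --panel panel.tsv --source-freqs sim.frq.strat \
                  --out-report report.tsv
aimpanel sweep    --freqs sim.frq.strat --bim sim.bim --traw sim.traw \
                  --sizes 25,50,75,100 --proportions 0 --out sweep.tsv
```

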
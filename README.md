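# coanpipe

Fine-scale population structure and admixture history from phased
haplotypes, via haplotype sharing (coancestry). `coanpipe` implements, as a
single tested pipeline, the chain of methods used to dissect the genetic
structure of a densely sampled region — the kind of analysis that resolves
clusters below the 10-km scale and dates admixture pulses to within a few
generations:

1. **Chromosome painting.** Each haplotype is modelled as an imperfect
   mosaic of the other sampled haplotypes (a Li & Stephens copying model).
   The forward–backward posterior yields the *coancestry matrix*: for each
   pair of individuals *i*, *j*, the total amount of genome (in cM) for
   which *i*'s closest relative in the sample is *j*.
2. **Coancestry clustering.** A Dirichlet-multinomial partition model over
   1/*c*-rescaled coancestry rows (the fineSTRUCTURE model family) is
   explored by MCMC; the number of clusters is inferred, a greedy merge
   tree summarizes cluster relationships, and per-individual assignment
   certainty is read off the MCMC samples.
3. **Clustering on external sharing.** To separate plain isolation-driven
   drift from differential ancestry, recipients can be re-clustered purely
   on their copying from external donor groups: the rectangular matrix *X*
   (recipients × donors) is embedded in a square block matrix
   `C = [[0, X], [0, Y]]` whose donor–donor block carries calibration
   constants g_k (the group-k block mean of *Y* equals the group-k mean of
   *X*), with donor groups held fixed during the MCMC.
4. **Drift/admixture bootstrap test.** Clusters are repeatedly sub-sampled
   to equal size (13, without replacement), the matrix re-painted, and mean
   within-cluster coancestry compared with cross-cluster coancestry;
   p = (S+1)/(R+1) over R = 200 resamples. A cluster sharing *more* with
   another cluster than with itself can only arise through admixture from
   a highly drifted source.
5. **Ancestry profiles.** Each cluster's donor-group copying vector is fit
   as a non-negative, sum-to-one mixture of the donor groups' own copying
   vectors, with inner-95% intervals from a 1000-replicate
   pseudo-individual bootstrap (one random member's painting per
   chromosome).
6. **Spatial smoothing.** Individuals are placed at the centroid of their
   four grandparental birthplaces (80-km retention filter, ≤24-km display
   jitter), and copying vectors are smoothed on a 3-km grid with an
   adaptive-bandwidth Gaussian kernel; ancestry profiles are then fit per
   grid cell.
7. **Admixture dating.** Coancestry curves — the covariance of copying
   ancestry for pairs of donor groups as a function of genetic distance —
   decay as exp(−g·d) after a pulse g generations ago (d in Morgans).
   Joint exponential fits give the date, the rank-one amplitude structure
   α(1−α)·δδᵀ gives the proportion and source compositions, and a
   28-year generation time with a 1940 reference converts g to a calendar
   year: year = 1940 − 28·g.

Real cohort genotypes for such studies are access-restricted, so the
package ships a first-class synthetic-data generator (`coanpipe.simdata`)
producing phased panels with known demes, drift, geography, and dated
admixture pulses — every downstream stage is validated against that truth.

## Worked example

`examples/` contains one short script per capability. Dating a simulated
pulse (`python examples/07_admixture_dating.py`) prints:

```
admixture evidence p = 0.0099 (detected at 0.01)
date: 26.8 generations [95% bootstrap 22.0, 30.8]  (truth 30)
calendar: 1188 CE [1078, 1324]
minor-side proportion: 0.100 (truth 0.1)
minor-side composition: {'near': 0.01, 'far': 0.99}
```

A pulse of 10% ancestry from the diverged donor pool, placed 30
generations ago, is detected (p < 0.01 against an ancestry-LD-free
permutation null), dated with a bootstrap interval covering the truth,
converted to a calendar interval, and attributed to the correct source
group. `python examples/03_clustering.py` similarly recovers three
simulated demes exactly (ARI 1.0, mean assignment certainty 1.0) from the
coancestry matrix alone.

The full pipeline (simulate → paint → cluster → test-drift → profile →
smooth → date) runs from the shell and is byte-reproducible per seed:

```bash
coanpipe run --seed 0 --out runs/demo
```

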
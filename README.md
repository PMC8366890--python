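# hapassort

Tests of lineage–habitat assortment for a deeply diverged
mitochondrial pair, built around the *Halichoeres bivittatus*
(slippery dick wrasse) system: two cytochrome-*b* lineages —
a northern "subtropical" and a southern "tropical" haplotype group
separated by ~5% sequence divergence — co-occur in the Florida Keys,
and the question is whether they segregate by habitat (offshore reef
vs. inshore patch reef vs. grass bed), as an ecological-speciation
scenario would predict, or are randomly distributed.

The package is aimed at population geneticists who want the full
analysis chain as reusable, tested code:

- **seqio** — aligned FASTA, tab-separated sample metadata, Newick
  clock trees, and their validated join.
- **distances** — p, JC69, and TN93 distances with pairwise deletion;
  group divergence summaries.
- **lineages** — deterministic UPGMA clock trees, root-split lineage
  assignment, haplotype collapsing, minimum-spanning-tree haplotype
  networks.
- **popgen** — pairwise Nei Fst, `Fst = 1 − Hs/Ht` with
  `Hs = (h₁ + h₂)/2`, `Ht = 1 − Σ p̄ᵢ² + Hs/2ñ`, and the study's
  fixed-sample-size permutation null (exhaustive when
  `C(n₁+n₂, n₁) ≤ 10⁵`, add-one Monte-Carlo otherwise).
- **gmyc** — single-threshold generalized mixed Yule–coalescent
  delimitation: interval rates
  `bᵢ = λ₁nᵢ^p₁ + λ₂Σⱼ[nᵢⱼ(nᵢⱼ−1)]^p₂`, likelihood
  `Π bᵢ e^(−bᵢxᵢ)`, ML over all candidate thresholds, and an LRT
  against the one-species coalescent null (χ², df = 3).
- **simulate** — a structured-coalescent generator (two lineages
  diverged at time τ, within-lineage diversity θ, finite-sites JC69
  mutation, tunable habitat assortment α) plus a calibration harness.
- **pipeline / CLI** — end-to-end orchestration into a machine-
  readable report (`hapassort simulate|analyze|power|benchmark`).

See `docs/methods.md` for the models, parameter defaults, estimator
conventions, and measured operating characteristics.

## Worked example

The numbered scripts under `analysis/` run the study-shaped analysis
on a simulated dataset (written to `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_assign_lineages.py
python analysis/03_habitat_fst.py
python analysis/04_gmyc_delimitation.py
python analysis/05_error_rates.py
```

With the default design (78 samples, 8 Keys sites, α = 0, i.e. no
true assortment), `02` and `03` print:

```
lineage assignment agrees with simulated truth for 100.0% of samples
between-lineage TN93 divergence: mean 0.0544 (range 0.0501-0.0620)
19 haplotypes; network total weight 77 mutation steps

habitat-pooled pairwise Fst:
      group1        group2  n1  n2       fst  p_value
   grass_bed  inshore_reef  13  22 -0.006043   0.6166
   grass_bed offshore_reef  13  43 -0.006922   0.7108
inshore_reef offshore_reef  22  43 -0.006164   0.7753

site-level pairs significant at 0.05: 3 of 28
```

Reading this: the two lineages are recovered perfectly from the
sequences (the ~5% split dwarfs within-lineage diversity); all
habitat-pooled Fst values are ~0 with large permutation p-values, so
no habitat assortment is detected — correctly, since none was
simulated.  The three site-level "hits" all involve the n = 4 site,
illustrating how small-sample permutation tests can flag spurious
structure.  `05` estimates the family-wise type-I rate of the habitat
test at 0.14 (vs. 1 − 0.95³ = 0.143 expected for three raw pairwise
tests) and power 1.0 at complete segregation (α = 1).

## Benchmark mode

The study's deposited alignment is not redistributed here.  Given a
local copy, `hapassort benchmark ALIGNMENT --metadata META.tsv` runs
the same report against the real data; without it, the test suite and
acceptance script use the synthetic stand-in generated by
`hapassort.simulate.synthetic_benchmark_config`.
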
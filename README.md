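# mitogeo

A toolkit for single-locus mitochondrial phylogeography: given an aligned set
of mtDNA sequences (one per individual) and a sample table assigning
individuals to lineages and geographic groups, it infers where lineages sat
out the last glaciation and how they expanded afterwards. It was built around
the classic grass-snake (*Natrix helvetica* / *N. natrix*) study design — an
866 bp ND4+tRNAs alignment, blue/yellow/red mitochondrial lineages each split
into northern and southern groups — but every stage is generic.

The pipeline covers:

- **Haplotype networks** — minimum-spanning networks (union of all minimum
  spanning trees, ties retained as reticulations) with unit-step latent
  "missing" nodes, cluster-separation queries (minimum mutation steps between
  haplotype sets) and a star-likeness score.
- **Diversity and rarefaction** — segregating sites *S*, nucleotide diversity
  π, haplotype count *h*, private haplotypes *h*_P, and Nei's haplotype
  diversity *Hd* = n/(n−1)·(1 − Σ(f_i/n)²), with the draw-N-without-replacement
  rarefaction scheme (5 repetitions by default) to remove sample-size bias.
- **Demography** — pairwise mismatch distributions with the sudden-expansion
  model F_i(τ, θ₀, θ₁) (population size jumps from θ₀ to θ₁ at τ mutational
  units before present), fitted by least squares (SSD) with a parametric
  bootstrap for SSD and Harpending's raggedness; Tajima's *D* and Fu's *F*_S
  with coalescent-simulation p-values.
- **Coalescent simulation** — seeded haploid single-locus simulation (msprime
  backend, Jukes–Cantor mutations) of constant-size, sudden-expansion, and
  three-population split scenarios.
- **ABC scenario choice** — DIYABC-style inference over three demographic
  scenarios (two gradual stepwise-diversification directions and a sudden
  trifurcation) with uniform priors, seven summary statistics per
  group/group-pair, weighted multinomial logistic regression on the closest
  simulations, and Beaumont-style regression-adjusted parameter posteriors
  converted to years with a 10-year generation time.
- **Synthetic data** — exact-by-construction fixtures emulating the three
  empirical lineage structures (star expansion; two-refuge disjunction with
  one shared haplotype; two star subclusters two steps apart), so the whole
  pipeline runs and is testable without any download.

## Worked example

```python
>>> import mitogeo as mg
>>> aln, table = mg.make_two_refuge(seed=5)       # yellow-lineage-like fixture
>>> ht = mg.collapse_haplotypes(aln, table)
>>> d = mg.pairwise_diff_matrix(ht)
>>> north = [h.label for h in ht.haplotypes if h.group_frequencies["South"] == 0]
>>> south = [h.label for h in ht.haplotypes if h.group_frequencies["North"] == 0]
>>> mg.min_steps_between(d, north, south)
4
>>> mg.profile_frame(mg.diversity_profile(aln, table))
   group   n   S  h  h_P     Hd  pi_e3
0  North  40   7  8    7  0.323   0.40
1  South  25  12  7    6  0.880   2.73
```

The two exclusive cluster cores sit 4 mutation steps apart, only one
haplotype is shared between the disjunct groups, and the southern group is
far more diverse (Hd 0.88 vs 0.32) — the diversity signature of a southern
refugium with a founder-effect expansion northwards.

Fitting the sudden-expansion model to a simulated expanding population
(true parameters τ = 4, θ₀ = 0.5, θ₁ = 50):

```python
>>> aln, _ = mg.sudden_expansion_demography(0.5, 50.0, 4.0, 50, 866, seed=7)
>>> res = mg.SuddenExpansionModel.from_alignment(aln).fit(n_boot=100, seed=2)
>>> print(res.summary())
Sudden-expansion mismatch fit
-----------------------------
n sequences          50
mean pairwise diffs  5.0155
modality             1
tau                  5.5325
theta0               0.0000
theta1               33.9543
SSD                  0.001155
p(SSD)               0.810   (100 bootstrap reps)
raggedness rg        0.0106
p(rg)                0.890
>>> ns = mg.neutrality_tests(aln, reps=10_000, seed=3)
>>> round(ns.D, 4), round(ns.p_D, 4), round(ns.Fs, 4)
(-2.3283, 0.0016, -22.5781)
```

A unimodal mismatch distribution, non-significant SSD and raggedness, and
significantly negative Tajima's D and Fu's F_S — the full signature of
demographic expansion, with τ̂ near its simulated value.

The same stages are available from the shell:

```sh
mitogeo diversity  --input-fasta y.fasta --samples y.tsv --seed 1 --out out/
mitogeo network    --input-fasta y.fasta --samples y.tsv --out out/
mitogeo demography --input-fasta y.fasta --samples y.tsv --seed 1 --out out/
mitogeo abc        --input-fasta sim.fasta --samples sim.tsv --n-sims 5000 \
                   --seed 1 --out out/
```

Each run writes TSV/JSON/GraphML artifacts plus a `manifest.json` with the
seeds and input digests needed to reproduce it.

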
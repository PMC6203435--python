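# rh1coev

Detecting intramolecular coevolution with a focal residue of rhodopsin —
and testing whether selection entrenched it.

Vertebrate rod opsins (RH1) almost universally carry E122, a residue that
stabilizes the light-activated metarhodopsin-II conformation at the cost
of rod photosensitivity, while several fish lineages fixed alternatives
(e.g. I122 inside an F119/I122/N123/S124 motif). Asking whether nearby
sites coevolve with site 122 — and whether their variants became
entrenched by purifying selection — requires intersecting several
independent statistical signals. This package implements that full
analysis as a tested, reusable pipeline for codon alignments and trees of
any focal site, plus the two spectroscopy readouts used to characterize
candidate sites in vitro.

**For**: molecular evolution researchers analyzing coevolving residue
networks in protein-coding genes, and vision scientists fitting pigment
spectra and retinal-release kinetics.

## What it computes

* **Codon site-class models** (M0, M1a, M2a, M3, M7, M8, M8a, M2a_rel) and
  **Clade Model C** under a GY94-type model: rate i→j ∝ π_j · κ^[ts] ·
  ω^[nonsyn], with ω a finite mixture over sites. CmC adds a divergent
  class whose ω_d differs between named clades/branches and the
  background; the LRT against M2a_rel (df = number of extra ω_d) tests for
  long-term shifts in selection. AIC = 2k − 2lnL, ΔAIC against the best
  model, and naive-empirical-Bayes site posteriors (posterior-mean dN/dS
  per site).
* **Ancestral reconstruction**: marginal codon posteriors at internal
  nodes under the fitted mixture, with MAP codons and 4-site motif
  reports (e.g. LEIA/FINS at 119-122-123-124).
* **Covariation**: sequence-weighted mutual information with
  average-product correction, z-scores against within-column-shuffle
  nulls, and a randomization cutoff z* (max |z| over shuffled datasets).
* **Correlated evolution**: Pagel's 4-rate (independent) vs 8-rate
  (dependent) model of two binary traits on the tree, with Monte-Carlo
  (parametric bootstrap) p-values and Bonferroni correction.
* **Structure**: minimum heavy-atom inter-residue distances from a PDB
  file and the focal-site neighborhood (6 Å default).
* **Photochemistry**: λmax by least-squares A1 visual-pigment template
  fitting, and retinal-release kinetics y = y0 + a(1 − e^(−bt)) with
  t½ = ln2/b, an r² > 0.95 quality gate, and Welch's t tests between
  replicate groups.
* **Synthetic data** with known ground truth for every stage, so the whole
  pipeline is testable without downloads.

## Worked example

Simulate a 30-taxon, 500-codon alignment under Clade Model C with a
divergent class at ω_d = 0.24 (background) vs 0.13 (foreground clade) —
the kind of contrast reported for tetrapod vs teleost rhodopsin — then
refit and test:

```python
import numpy as np
from rh1coev.trees import two_clade_tree
from rh1coev.simulate import simulate_codon_alignment, cmc_spec
from rh1coev.codon_models import fit_clade_model_C, fit_site_model, lrt, lrt_df
from rh1coev.genetic_code import N_CODONS

pi = np.full(N_CODONS, 1 / N_CODONS)
tree = two_clade_tree(30, 1.0)
tree.partitions = tree.partitions[:1]          # one foreground clade
truth = cmc_spec(0.67, 0.03, 0.02, {"background": 0.24, "cladeA": 0.13})
aln, _ = simulate_codon_alignment(tree, truth, 500, seed=7, pi=pi)

null = fit_site_model(aln, tree, "M2a_rel", n_starts=2, seed=0, pi=pi)
alt = fit_clade_model_C(aln, tree, n_starts=2, seed=0, pi=pi)
df = lrt_df(alt, null)
stat, p = lrt(alt, null, df)
print(f"M2a_rel lnL = {null.lnL:.2f}")
print(f"CmC     lnL = {alt.lnL:.2f}")
print(f"LRT = {stat:.2f}, df = {df}, p = {p:.3g}")
print({k: round(float(v), 3) for k, v in alt.spec.divergent_omegas.items()})
```

prints

```
M2a_rel lnL = -19829.80
CmC     lnL = -19803.73
LRT = 52.15, df = 1, p = 5.15e-13
{'background': 0.241, 'cladeA': 0.124}
```

— the clade model is strongly preferred (the data really do contain a
foreground shift), and both divergent-class dN/dS values are recovered
close to their true 0.24/0.13. The photochemistry side is one call each:
a noisy template spectrum generated at λmax 492.6 nm refits to
`lambda_max = 492.6 nm`, and a noisy release trace generated at a
13.3-minute half-life refits to `t_half = 13.5 min (r2 = 0.999)`.

## Command line

Every stage is a subcommand of `rh1coev`:

```sh
rh1coev simulate --seed 1 --n-taxa 30 --n-sites 300 --out study/
rh1coev fit-sites  --alignment study/alignment.fasta --tree study/tree.nwk --out fits/
rh1coev fit-cmc    --alignment study/alignment.fasta --tree study/tree.nwk \
                   --partitions study/partitions.yaml --out fits/
rh1coev mi-scan    --alignment study/alignment.fasta --focal-site 122 --out mi.csv
rh1coev pagel      --alignment study/alignment.fasta --tree study/tree.nwk --site 119
rh1coev distances  --structure data/3PQR.pdb --focal 122 --out distances.csv
rh1coev scan       --config scan.yaml --out results/     # full evidence join
```

`scan` executes structure → M8 → CmC/M2a_rel → MI → Pagel and joins
everything into a per-site evidence table (distance, posterior-mean dN/dS,
divergent-class posterior, MI z vs cutoff, Monte-Carlo p with Bonferroni
call), with a JSON manifest of seeds and intermediates.

Structure-based stages need a structure file; the metarhodopsin-II crystal
structure used for site-122 work can be fetched once with

```sh
mkdir -p data && curl -o data/3PQR.pdb https://files.rcsb.org/download/3PQR.pdb
```

(two structure tests in `tests/test_acceptance.py` require this file and
fail with a pointer here when it is absent).

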
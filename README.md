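# wgdretain

Models of duplicate-gene retention for lineages that experienced **two
consecutive whole-genome duplications** (WGDs) — teleost fish, salmonids,
many plants.  After a WGD every gene pair is at risk of losing one copy;
whether both copies survive depends on the retention mechanism available to
the gene: **alternative functionalization** (`alt_func`, a merged sub- and
neofunctionalization category), **dosage balance** (`dos`, transient
stoichiometric constraint), or **chance** alone (`non`, constant hazard).
The package is for molecular evolutionists who want to explore — and
eventually fit — the sorting signal those mechanisms leave in genomes with
two WGDs.

## The model

Each category has a time-heterogeneous hazard for pair loss

> h(t) = d + f·exp(−b·t^c)

whose survival function, by term-wise integration, is

> S(t) = exp( −d·t − f·Σₙ (−b)ⁿ·t^(c·n+1) / (n!·(c·n+1)) )

truncated at `n_max = 100` with explicit convergence control.  For a genome
that is a mixture over categories with proportions α, the sorting statistic
is the **probability ratio**

> p_ratio(t1, t2) = P(pair survives t2 | parent pair survived t1) /
>                   P(pair survives t2 | parent pair lost in t1)

where `t1` is the time between the WGDs and `t2` the time since the second.
Three nested hypotheses are supported:

* **independence** — one category genome-wide; p_ratio ≡ 1;
* **gene duplicability** — a fixed α mixture; conditioning on the t1 fate
  re-weights the mixture and p_ratio deviates from 1;
* **mutational opportunity** — additionally, a fraction `β_switch_mo` of
  alt_func genes whose pair survived t1 lose the ability to alternatively
  functionalize again and follow the `non` curve during t2.

The package evaluates p_ratio surfaces over a (t1, t2) grid, simulates
per-gene fates through both WGDs (the Monte-Carlo oracle and synthetic-data
generator), and recovers α (and optionally β) from 2×2 retention-count
tables by maximum likelihood.

## Worked example

```python
from wgdretain import (GenomeComposition, HypothesisSpec, SimulationConfig,
                       evaluate_surface, summarize_surface, p_ratio,
                       simulate_retention, fit_composition)

comp = GenomeComposition(0.45, 0.30, 0.25)     # alt_func, dos, non
gd = HypothesisSpec("gene_duplicability")

print(p_ratio(comp, 0.1, 0.2, gd))             # 3.7490823148303862
print(p_ratio(comp, 0.1, 1e-4, gd))            # 1.0012542273755711

s = summarize_surface(evaluate_surface(comp, gd))
print(s.max_value, s.argmax_t1, s.argmax_t2)   # 4.341909104447141 0.01 0.25

counts = simulate_retention(SimulationConfig(10**6, 7, 0.1, 0.2, comp, gd))
fit = fit_composition(counts, "gene_duplicability", 0.1, 0.2, seed=3)
print(fit.composition.as_dict())
# {'alt_func': 0.44919..., 'dos': 0.30068..., 'non': 0.25012...}
```

A gene whose pair survived t1 is a much better prospect after the second
WGD than one whose pair was lost (ratio ≈ 3.75 at t1=0.1, t2=0.2): the
first round has sorted genes by retention propensity.  Right after the
second WGD (t2 → 0) the pattern is still unsorted (ratio ≈ 1).  The surface
peak sits at short t1 and intermediate t2.  The maximum-likelihood fit
recovers the generating composition to three decimals from a million-gene
synthetic table.

The same workflow is available from the shell:

```sh
wgdretain fixtures -o configs/            # the 15 study compositions
wgdretain surface  --config configs/composition_alt45_dos30_non25.json -o surf.tsv
wgdretain simulate --config configs/composition_alt45_dos30_non25.json \
                   --t1 0.1 --t2 0.2 --n-genes 1000000 --seed 7 -o counts.json
wgdretain fit      --counts counts.json -o fit.json
wgdretain survival --category dos --t-stop 0.5
```

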
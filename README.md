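# codiverge

Co-diversification scans, selection/drift contrasts, and competition
reanalysis for host-associated bacterial genomes.

## The scientific problem

Gut bacterial strains can diversify in parallel with their host species,
so that within a symbiont clade the phylogeny of metagenome-assembled
genomes (MAGs) mirrors the host phylogeny. Detecting such
*co-diversifying* clades identifies ancestral symbioses; comparing
laboratory- and wild-mouse strains inside them asks how captivity reshaped
these symbionts — by positive selection (gene-specific elevation of dN/dS)
or by genetic drift (genome-wide elevation of dN/dS under reduced
effective population size); and co-housing experiments in germ-free mice
measure the fitness consequences. `codiverge` implements this pipeline for
anyone with a rooted symbiont phylogeny plus tip-to-host metadata, a host
tree, per-gene codon alignments, or an ASV count table — and ships
generators that synthesize all of these with known ground truth.

The statistical core:

* **Hommola permutation test** — Mantel-style correlation r between host
  patristic distances and symbiont patristic distances over all pairs of
  (symbiont, host) links; null by independently permuting host and
  symbiont assignments; p = (1 + c)/(1 + B). A clade is co-diversifying
  when r > 0.75 and p < 0.01 at 999 permutations.
* **PACo** (Procrustes m² of the symbiont ordination superimposed on the
  host ordination) and **ParaFit** (trace(D′D), D = C′AB) as corroborating
  tests on clades dereplicated to one genome per same-host monophyletic
  group. The ParaFit statistic reproduces `ape::parafit` exactly.
* **Host-label permutation null** for the *number* of significant clades
  (nested clades make per-node FDR invalid).
* **NG86 branch dN/dS** — Fitch-parsimony ancestral sequences, pathway-
  averaged synonymous/nonsynonymous counts, Jukes–Cantor correction —
  feeding quadrant classification, an exact binomial asymmetry test, and
  paired t-tests on per-gene log(ω_lab) − log(ω_wild).
* **Competition pipeline** — rarefaction, diagnostic-ASV selection, Dice
  dissimilarity, PCoA, mouse-averaged permutation t-tests, and day-7–17
  trajectory tests.

See `docs/methods.md` for assumptions, conventions, and limitations.

## Worked example

Simulate a symbiont tree with 3 planted co-diversifying clades among 6
random clades, scan it at the standard thresholds, and check the scan
against the host-label null:

```python
from codiverge.simulate import SimConfig, simulate_scan_dataset
from codiverge.scan import ScanConfig, scan_tree, null_label_scan, records_to_frame

ds = simulate_scan_dataset(SimConfig(n_codiv_clades=3, n_random_clades=6, rng_seed=42))
records = scan_tree(ds.tree, ds.host_tree, ds.meta, ScanConfig(n_perm=999, rng_seed=0))
print(records_to_frame(records).query("significant").to_string(index=False))
```

```
node_id  n_hosts  n_symbionts        r     p  significant
     N1       10           20 0.999356 0.001         True
     N7        7           14 0.999732 0.001         True
    N11        5           10 0.996609 0.001         True
    N20        7           14 0.998719 0.001         True
    N24        5           10 0.998197 0.001         True
    N33       10           20 0.999507 0.001         True
    N39        7           14 0.999441 0.001         True
    N43        5           10 0.995744 0.001         True
```

Fourteen nodes pass the size/host/span filters; the eight significant
ones are the three planted clade roots (N1, N20, N33 — 20 genomes from 10
hosts each) and their large nested subclades, each with r ≈ 1 and p at
the 0.001 floor of 999 permutations. No random clade is flagged. The
host-label null confirms the count is not an artifact of tree shape:

```python
null = null_label_scan(ds.tree, ds.host_tree, ds.meta,
                       ScanConfig(n_perm=199, rng_seed=0), n_label_perms=19)
print(null.observed_count, max(null.null_counts), null.p_value)
# 8 0 0.05
```

The real labels yield 8 significant clades; all 19 label permutations
yield 0, so p = 1/20 — the floor attainable with 19 permutations.

Two deterministic statistics from the retention and selection stages:

```python
from codiverge.history import retention_contingency
from codiverge.dnds import binomial_asymmetry
chi2, p, table = retention_contingency(tbl)   # 2x2 over ancestral clades
# chi2 = 4.9428, p = 0.0262  for table [[7, 33], [16, 24]]
binomial_asymmetry(76, 126)                   # 0.0255
```

The first says ancestral clades are missing from laboratory mice
significantly more often than from wild mice; the second says
significantly more genes show positive selection in the laboratory but
purifying selection in the wild than the reverse.

The same stages are available from the shell:

```sh
codiverge simulate --seed 5 --out data/
codiverge scan --tree data/mags.nwk --host-tree data/hosts.nwk \
    --meta data/tips.tsv --seed 0 --out records.tsv
codiverge null-scan ... ; codiverge collapse-scan ... ; codiverge sensitivity ...
codiverge compete --table t.tsv --meta m.tsv --tax x.tsv \
    --codiv-taxa genera.txt --depth 40000 --seed 7 --out results/
```

All subcommands are byte-reproducible given the same seed and config.

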
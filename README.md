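# mtprov — mitochondrial DNA provenance analysis

`mtprov` infers and audits the geographic origin of wildlife samples —
the motivating case is African elephants and confiscated ivory — from
mitochondrial DNA.  Because female elephants are matrilocal, mtDNA
haplotypes barely disperse: most are found at a single sampling
locality or within one country, while male-mediated gene flow makes
nuclear markers tell a different, nearly independent, geographic story.
`mtprov` exploits both facts: it quantifies how locality-specific
haplotypes are, and it *triangulates* — combines a nuclear assignment
with mtDNA evidence to confirm or rule it out.

The pipeline covers:

- **alignment I/O** — aligned FASTA + metadata TSV, reference-coordinate
  bookkeeping, region windows (e.g. a short control-region fragment);
- **haplotype collapsing** — unique haplotypes and variable sites with an
  explicit missing-data policy;
- **diagnostic-site keys** — derive and apply a hierarchical flowchart
  that assigns a sequence to a deep clade (F or S) and then to one of
  the regionally restricted subclades;
- **geographic specificity** — what fraction of haplotypes (and of the
  individuals carrying them) occur in exactly k localities/countries;
- **haplotype F_ST** — frequency-based F_ST per locality pair,
  `F_ST = (d_b − (d_w(A)+d_w(B))/2) / d_b` over haplotype-identity
  distances, with a pooled-permutation significance test;
- **median-joining networks** — a clean-room implementation of the
  Bandelt–Forster–Röhl algorithm with ε-relaxed minimum spanning
  networks, median vectors and obsolete-node pruning;
- **triangulation** — per-sample categories combining nuclear
  assignments with haplotype sharing and F_ST significance, plus a
  batch (seizure-level) frequency score;
- **synthetic data** — a seeded generator of matrilocal datasets with
  planted diagnostic sites, controlled private-haplotype fraction and a
  subclade-independent nuclear mis-assignment process, with full ground
  truth.

## Worked example

```python
from mtprov import (SimConfig, simulate_mtdna, simulate_nuclear_assignments,
                    collapse_haplotypes, specificity, sharing_matrix,
                    fst_matrix, triangulate)

cfg = SimConfig(seed=1, n_localities=16, samples_per_locality=20, L=1500)
dataset, truth = simulate_mtdna(cfg)

table = collapse_haplotypes(dataset)
print(f"{len(table)} haplotypes from {table.n_samples_collapsed} individuals, "
      f"{len(table.variable_sites)} variable sites")

report = specificity(table, level="locality")
print(f"{report.hap_fraction_by_spread[1]:.0%} of haplotypes are locality-specific; "
      f"{report.individual_fraction_by_spread[1]:.0%} of individuals carry one")

fst = fst_matrix(table, n_permutations=999, seed=1)
records = simulate_nuclear_assignments(cfg, truth)
result = triangulate(records, sharing_matrix(table), fst, alpha=0.05)
print(f"{result.n_misassigned} nuclear mis-assignments: "
      f"{result.counts['mtdna_precludes']} precluded by haplotype sharing, "
      f"{result.counts['mtdna_distinguishes']} distinguished by F_ST "
      f"({result.improvement_fraction:.0%} improved)")
```

prints

```
61 haplotypes from 320 individuals, 274 variable sites
87% of haplotypes are locality-specific; 80% of individuals carry one
136 nuclear mis-assignments: 129 precluded by haplotype sharing, 7 distinguished by F_ST (100% improved)
```

Reading the output: the 320 simulated individuals collapse to 61
distinct haplotypes; 87% of those haplotypes were observed at a single
locality, and 80% of individuals carry such a locality-specific
haplotype — the matrilocal signature.  Of the nuclear mis-assignments,
every one is caught by mtDNA: for 129 the true and wrongly assigned
localities share no haplotype at all (sequencing would have precluded
the error), and for the remaining 7 the locality pair shows a
significant haplotype F_ST, so haplotype frequencies could still
separate them.

The same pipeline runs from the shell:

```bash
mtprov simulate --seed 1 --out-prefix sim
mtprov collapse --fasta sim.fasta --meta sim.meta.tsv --out haps.tsv
mtprov fst --fasta sim.fasta --meta sim.meta.tsv --permutations 10000 --seed 17 --out-prefix fst
mtprov triangulate --fasta sim.fasta --meta sim.meta.tsv --records sim.records.tsv
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.

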
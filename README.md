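# dpgwas

Differentially private release of the top-K most disease-associated SNPs
from case–control GWAS contingency data.

Publishing which SNPs are most associated with a phenotype leaks
information about study participants: membership in the case group can be
inferred from aggregate statistics. `dpgwas` is for analysts who must
release a top-K SNP list from a case–control panel while giving each case
participant an ε-differential-privacy guarantee — the released list's
distribution changes by at most a factor e^ε when any one case individual's
genotype changes.

## The model

Each SNP is a 2×3 genotype table: case counts (r₀, r₁, r₂) and control
counts (s₀, s₁, s₂) by number of minor alleles, with totals R, S, N = R+S.
Association is measured by the allelic test (Cochran–Armitage trend test,
additive model), the Pearson χ² on the collapsed 2×2 allele-count table:

    Y_A = 2N[(2r₀+r₁)S − (2s₀+s₁)R]² / (R·S·(2n₀+n₁)(n₁+2n₂)),   nᵢ = rᵢ + sᵢ

Controls are assumed public (given either as genotype counts or as allele
frequencies expanded under Hardy–Weinberg equilibrium); privacy protects the
case group. Two release mechanisms are provided, both calibrated by the
score's sensitivity s:

* **Laplace top-K** — add Laplace(0, 2Ks/ε) noise to every SNP's score and
  release the K largest.
* **Exponential top-K** — K sequential draws without replacement, each
  selecting SNP i with probability ∝ exp(ε·qᵢ/(2Ks)).

The scores are either the χ² statistic itself (sensitivity supplied by the
user; an empirical auditor is included) or the **Hamming distance score**:
with controls fixed, re-genotyping one case moves the table to one of six
lattice neighbours, and h(D) is the signed minimum number of such moves to
cross the significance boundary Y_A = c (the χ²(1) critical value of a
threshold p-value p*), with h = −d for insignificant and h = d−1 for
significant tables. Because Y_A depends on the case row only through
x = 2r₀+r₁ and is unimodal in x, the shortest distance has an exact
closed form; a breadth-first-search oracle verifies it exhaustively, and the
score's sensitivity is exactly 1 — no noise-inflating bound needed.

## Worked example

```
dpgwas simulate -M 200 -R 201 -S 174 --n-assoc 5 --effect 0.25 --seed 42 \
    -o panel.tsv --truth truth.json
dpgwas score --panel panel.tsv --score hamming --p-star 0.0005 -o scored.tsv
dpgwas release --panel scored.tsv --mechanism exponential --score hamming \
    --epsilon 1 -K 5 --p-star 0.0005 --seed 7 -o release
cat release.tsv
```

produces

```
rank	snp_id
1	snp00003
2	snp00123
3	snp00043
4	snp00002
5	snp00004
```

The synthetic panel planted 5 associated SNPs (snp00000–snp00004), which are
exactly the true top-5 by χ². At the stringent budget ε = 1 the released
list recovers three of them (utility u = |S₀∩S|/|S₀| = 0.6) and pays for
privacy with two false entries — rerun with `--epsilon 10` and the list
matches the true top-5. `dpgwas evaluate` sweeps mechanisms × budgets × K ×
thresholds and tabulates mean ± sd utility (`--plot` renders risk–utility
curves); `dpgwas audit-sensitivity` enumerates a table space and reports a
score's worst one-record change:

```
$ dpgwas audit-sensitivity --score hamming -R 10 --control-row 40,40,20 --p-star 0.05
{"score": "hamming", "p_star": 0.05, "sensitivity": 1, "R": 10,
 "control_row": [40.0, 40.0, 20.0], "n_tables": 66}
```

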
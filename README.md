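# orfunc

Ortholog-based inference of olfactory receptor function.

Insect odorant receptors such as *Drosophila* Or22a diverge across species,
and a handful of amino-acid positions carry most of the change in what the
receptor responds to. Given (a) a multiple sequence alignment of orthologous
receptor proteins, (b) a receptor × odorant response matrix from
single-sensillum recordings (spike counts), and (c) a structural model of the
reference receptor, `orfunc`:

1. **ranks response-determining positions** — for each alignment column `c`,
   over all receptor pairs with residues at `c`, the score is

   `S(c) = mean{ D(i,j) : residues differ at c } − mean{ D(i,j) : residues match at c }`

   where `D(i,j)` is the mean absolute response difference (spikes) over
   odorants measured in both receptors. Columns where residue identity
   predicts response similarity score high; the top *K* (default 20) form the
   candidate response-determining set;
2. **predicts a held-out receptor's responses from sequence alone** — a
   leave-one-species-out evaluation re-ranks positions without the held-out
   receptor, then predicts each odorant response as a similarity-weighted mean
   of the training receptors' responses, with weights
   `w_j = sim(held-out, j)^α` computed at the top-*K* columns (each column
   weighted by its score). Errors `D_pred = |predicted − actual|` are compared
   against a shuffled control (`D_ctrl`) in which training response rows are
   randomly reassigned to training sequences;
3. **quantifies robustness by jackknife** — the top-*K* set is recomputed with
   each species removed; reported are per-exclusion retention of the original
   set and the concordance of the frequency-ranked positions with it;
4. **tests structural clustering** — whether the top positions are
   over-represented within a 15 Å neighborhood of a seed residue
   (e.g. the pore entrance near R166 or the putative binding pocket near
   F265), by an upper-tail hypergeometric test: population `N` = protein
   length, `K` top positions, `n` neighborhood residues, overlap `k`,
   `p = P(X ≥ k)`.

A first-class synthetic-data generator (`orfunc.simulate`) produces all three
inputs with planted response-determining positions and known noise, so every
stage is testable end to end without any external data.

## Worked example

```python
import orfunc as o
from orfunc.simulate import GeneratorConfig, generate_dataset

# 14 receptors x 397 residues x 21 odorants, 5 planted determinant positions
ds = generate_dataset(GeneratorConfig(seed=1), cluster_planted=True,
                      cluster_seed_ref_index=198)
print(ds.truth.planted_positions)        # (13, 224, 245, 285, 290)

table = o.rank_positions(ds.alignment, ds.responses, k=20)
print(table.top_k[:5])                   # (290, 13, 285, 224, 26)

rep = o.loo_evaluate(ds.alignment, ds.responses, k=20, n_shuffles=1000, seed=1)
print(rep.mean_d_pred, rep.mean_d_ctrl, rep.improvement_percent)
# 29.46  45.20  34.8

jk = o.jackknife_top_positions(ds.alignment, ds.responses, k=20)
print(jk.mean_retention, o.frequency_concordance(jk))   # 17.93 (19, 20)

top_ref = [r for r in table.top_k_ref if r is not None]
e = o.enrichment_test(ds.structure, top_ref, seed_ref_index=198, radius=15.0, N=397)
print(e.n, e.k_overlap, round(e.expected, 2), e.p_value)
# 12 5 0.60 1.2e-04
```

Reading: four of the five planted positions top the ranking (the fifth sits
just below); sequence-informed prediction cuts the mean absolute error from
45.2 to 29.5 spikes, a 34.8 % improvement over the shuffled control; the
top-20 set is largely stable under leave-one-species-out (mean retention
17.9/20, 19 of the 20 most frequent positions concordant); and because the
planted residues were clustered around residue 198 in the synthetic
structure, the 12-residue neighborhood holds 5 top positions where 0.6 were
expected by chance (p ≈ 1.2 × 10⁻⁴).

Enrichment can also be computed from printed counts alone, without a
structure file:

```python
e = o.enrichment_from_counts(N=397, K=20, n=41, k=6)
print(round(e.expected, 2), round(e.p_value, 3))   # 2.07 0.011
```

## Command line

```sh
orfunc simulate --outdir sim --seed 5
orfunc all --alignment sim/alignment.fasta --responses sim/responses.csv \
           --structure sim/structure.pdb --reference-id sp01 --outdir run
orfunc enrich --protein-length 397 --n-top 20 --n-neighborhood 41 \
              --k-overlap 6 --outdir enrich   # parameters-only mode
```

Every run writes TSV/JSON outputs plus a manifest with the effective
configuration and its hash.

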
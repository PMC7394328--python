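# mddsite

Substrate-motif discovery and site prediction for lysine acylation
(glutarylation and related acyl marks) from protein sequence alone.

Lysine acyl modifications are written by acyltransferases that recognise
short sequence contexts around the target lysine. Given proteins and
annotated modified/unmodified lysines, `mddsite`:

1. extracts `2n+1`-mer peptide windows centred on each lysine (positions
   `-n..+n`, `X`-padded at protein termini; default 21-mers),
2. reduces redundancy (greedy identity clustering of the pre-aligned
   windows, cross-class exact deduplication, seeded class rebalancing),
3. encodes windows as composition features — AAC (21 letter frequencies),
   AAPC (441 adjacent-pair frequencies) and CKSAAP (441 k-spaced pair
   frequencies per spacing k),
4. measures the interdependence of flanking positions with chi-square
   statistics on residue-level (21×21) and biochemical-group (5×5)
   contingency tables,

   χ²(X_i, X_j) = Σ_mn (Y_mn − E_mn)² / E_mn,  E_mn = Y_mc · Y_rn / Y,

5. partitions the positive windows into motif subgroups by **maximal
   dependence decomposition** (MDD): recursively split on the position with
   the most significant total dependence, testing "residue at position p in
   group g" (polar / acidic / basic / hydrophobic / aromatic), until no
   grouped χ² exceeds the threshold (default 34.3 for the 5×5 table's 16
   degrees of freedom) or size limits bind,
6. trains one RBF-kernel SVM per subgroup, k(S_i,S_j) = exp(−γ‖S_i−S_j‖²),
   with (C, γ) chosen by exhaustive log₂ grid search under stratified
   cross-validation, and stacks the subgroup probability outputs into an
   integrated meta-SVM,
7. evaluates with pooled k-fold cross-validation: Sn, Sp, Acc, MCC and ROC
   AUC.

A synthetic-data module generates peptide sets with planted
position-specific residue-group motifs (configurable background
composition, subpopulation sizes, penetrance, class ratio), so the whole
pipeline is testable without any database download.

## Worked example

```sh
# synthesise proteins whose positive lysines carry two planted motif
# families (upstream basic, downstream acidic)
mddsite simulate --preset stacked-benchmark --seed 1 --out run/sim
# -> wrote 1290 proteins, 430+860 sites to run/sim
mddsite extract --fasta run/sim/proteins.fasta --sites run/sim/sites.tsv \
    --n 10 --negatives annotated --out run/frags
# -> extracted 430 positives, 860 negatives
mddsite mdd --positives run/frags/positives.fasta --out run/mdd
```

The `mdd` step prints the discovered subgroups and their split rules; on
the simulation above (seed 1) it reports:

```
Glutar1: 175 sequences
Glutar2: 149 sequences
Glutar3: 106 sequences
split: acidic at +4
split: basic at -8
```

The planted downstream acidic family is peeled off first (Glutar1: windows
with an acidic residue at +4), then the upstream basic family (Glutar2:
basic at −8), leaving the unstructured remainder in Glutar3. Training and
applying the stacked model:

```sh
mddsite train --positives run/frags/positives.fasta \
    --negatives run/frags/negatives.fasta --grid small --seed 1 --out run/model
# -> trained 3 subgroup models + meta model -> run/model
mddsite predict --model run/model --fasta run/sim/proteins.fasta \
    --out run/predictions.tsv
# -> scored 3505 lysines; 271 predicted positive
```

`predict` scores **every** lysine in the input proteins, one row per site:

```
protein_id           position  window                 probability  label          motif
prot_synthP0_00000   2         XXXXXXXXXTKYDWHKTKMAK  0.593        glutarylated   Glutar3
prot_synthP0_00000   7         XXXXTKYDWHKTKMAKMHSHL  0.528        glutarylated   Glutar3
```

where `motif` names the subgroup whose split rules the window satisfies.

## Library use

```python
from mddsite import (generate_fragments, stacked_benchmark_config,
                     mdd_partition, train_integrated)

pos, neg = generate_fragments(stacked_benchmark_config(seed=1))
tree = mdd_partition(pos)                  # motif subgroups
model = train_integrated(pos, neg, seed=1) # subgroup SVMs + meta-SVM
print(tree.splits, model.predict(pos[:3]))
```

## Layout

- `src/mddsite/seqio.py` — FASTA/TSV IO, window extraction, dataset assembly
- `src/mddsite/redundancy.py` — identity clustering, dedup, subsampling
- `src/mddsite/encoding.py` — AAC / AAPC / CKSAAP encoders
- `src/mddsite/dependence.py` — positional chi-square + two-sample enrichment
- `src/mddsite/mdd.py` — maximal dependence decomposition
- `src/mddsite/model.py` — subgroup SVMs, stacking, grid search
- `src/mddsite/evaluate.py` — metrics, pooled CV, ROC, sweeps
- `src/mddsite/synth.py` — synthetic data with planted motifs
- `src/mddsite/cli.py` — `mddsite` subcommands
- `docs/methods.md` — models, statistics and design choices in detail
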
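# crossdti

Cross-domain and few-shot **drug–target interaction (DTI) prediction** for
unseen proteins: a multi-level sequence/graph encoder with bilinear
attention, category-aware domain-adversarial pre-training, and
dynamic-prototype episodic meta-learning — packaged with a planted-rule
synthetic benchmark so every mechanism is testable on one CPU in minutes.

## Who this is for

Computational chemists and method developers who need a DTI pipeline that
(a) transfers binding patterns to protein families absent from training and
(b) exploits a handful of weakly related labelled pairs (homologous
proteins) at inference time, and who want each mechanism verifiable at desk
scale before committing to GPU-scale data.

## The method in brief

**Encoder.** A protein sequence (tokens A=1..Z=26) passes through three
convolution + max-pool stages; a molecular graph (RDKit heavy atoms) passes
through three graph-convolution stages.  At each level *i* a low-rank
bilinear attention forms a nonnegative residue × atom map and pools an
interaction vector `I_i`; sigmoid gates fuse the levels into one vector
`O = f_s(Σ_i g_i ⊙ I_i)`.  Heads on `O` give the binding probability
`y_c = σ(MLP(O))` and affinity `y_r = w·O + b`; the virtual-screening rank
score is `y_c² · y_r`.

**Stage one (inductive).** Supervised BCE on labelled source-domain pairs
plus category-aware domain-adversarial alignment against unlabelled
target-domain pairs: a gradient-reversal layer feeds two per-class domain
discriminators, each seeing the reversed features scaled by the model's own
class probability, with objective `L = L_s + λ·L_d` and the standard
λ-ramp `2/(1+e^(−10p))−1`.

**Stage two (associative).** 2-way k-shot episodes from one protein cluster.
With support features `O_s` and query features `O_q`, affine attention
(`Q = σ(O_c W_I)∘γ₁+β₁`, `K = σ(O_c W_I)∘γ₂+β₂`, scores `ReLU(QKᵀ)⊙²`)
builds per-query class prototypes `P[n,q,c]` as attention-softmax averages
of same-class supports; queries are classified by softmaxed cosine
similarity to the prototypes under a focal loss `−α(1−p)^γ log p`.

The differentiable core is a compact numpy reverse-mode autodiff engine
(`crossdti.autodiff`) — the gradient-reversal layer requires explicit
backward control — with every operation checked against finite differences.

## Worked example

```python
from crossdti.pipeline import prepare_benchmark, run_stage_one, run_stage_two

data = prepare_benchmark(seed=11)          # 180 proteins, 60 drugs, 1200 pairs
stage1, rep1 = run_stage_one(data, seed=11, adversarial=True)
print(rep1)
meta, rep2 = run_stage_two(data, stage1, seed=13, k=5)
print(rep2)
```

prints (one CPU, a few minutes; exact values for these seeds):

```
{'source_val_auroc': 0.8498, 'source_val_acc': 0.7654, 'target_zeroshot_auroc': 0.6889}
{'fewshot_auroc': 0.8222, 'fewshot_auroc_sd': 0.2188, 'fewshot_acc': 0.7333,
 'fewshot_auprc': 0.8754, 'n_eval_episodes': 50, 'train_query_acc': 0.8625}
```

Reading: after adversarial pre-training on 400 labelled source pairs the
encoder transfers to the shifted families at only 0.69 zero-shot AUROC
(plain supervised training scores higher in-domain — 0.92 on held-out
source pairs — but lower on the target); five labelled support pairs per
class from the same protein category lift held-out, unseen-protein query
AUROC to 0.82 — the gain the associative stage exists for.

The same pipeline is scriptable from the shell:

```bash
crossdti synth --out data/ --seed 7
crossdti cluster --proteins data/proteins.fasta --n-clusters 6 --out clusters.tsv
crossdti train-inductive --config config.yaml --seed 11 --out stage1.npz
crossdti train-meta --config config.yaml --checkpoint stage1.npz --out meta.npz
crossdti eval-fewshot --config config.yaml --model meta.npz
crossdti screen --config config.yaml --checkpoint stage1.npz --out ranking.tsv
crossdti explain --checkpoint stage1.npz --protein-seq MKT... --smiles CCO... --out att.tsv
```

## The synthetic benchmark

Six protein families carry planted sequence motifs; drugs are concatenated
SMILES fragments; a fixed motif × fragment compatibility matrix defines
binding (threshold calibrated to a 0.5 positive rate, 5 % label noise); two
held-out families use motifs disjoint from training.  Built-in oracles
bound the problem: the generative rule scores ~0.95 AUROC (noise ceiling),
and a protein-memorization baseline is chance-level on shifted families —
so the benchmark separates rule learning from memorization.  See
`docs/methods.md` for assumptions and limitations.

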
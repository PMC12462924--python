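"""Desk-scale experiment protocol on the planted-rule benchmark.

This module fixes the study conditions used by the test-suite and the
reproduction script, so every consumer runs the identical protocol:

1. **Data** — the default synthetic benchmark (6 families, 60 drugs, 5%
   label noise) split into 4 source and 2 target families with disjoint
   motifs.
2. **Stage one** — the encoder trains on 400 labelled source pairs for 30
   epochs, optionally with category-aware adversarial alignment against the
   unlabelled target pairs.
3. **Stage two** — each target family is subdivided into two balanced
   protein groups; 5-shot unseen-protein episodes from one group per family
   train the episodic model for 40 epochs, and episodes from the held-out
   groups measure few-shot transfer to proteins never seen in any training
   stage (their broad category is known only through the support set's
   weakly related annotations).

The encoder is deliberately small (embedding 32, three 64-channel levels,
fusion width 128) so a full two-stage run takes a couple of minutes on one
CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig
from .inductive import (AdversarialConfig, InductiveResult, PairFeaturizer,
                        predict_proba, train_inductive)
from .io_featurize import (ClusterAssignment, cluster_proteins,
                           refine_clusters)
from .meta import (MetaModel, MetaTrainConfig, build_episodes,
                   evaluate_fewshot, train_meta)
from .metrics import compute_metrics
from .synthetic import SyntheticConfig, generate_dataset, make_shifted_split


def experiment_encoder_config() -> EncoderConfig:
    """The scaled-down encoder used for all benchmark experiments."""
    return EncoderConfig(embed_dim=32, protein_channels=[64, 64, 64],
                         protein_kernel_sizes=[3, 6, 9],
                         drug_hidden_dims=[64, 64, 64], fusion_dim=128,
                         attention_rank=16, cls_hidden=32, dropout=0.2,
                         l_max=128)


@dataclass
class BenchmarkData:
    proteins: list
    drugs: list
    interactions: list
    ground_truth: object
    source: tuple      # (proteins, drugs, interactions)
    target: tuple
    target_families: list[int]
    featurizer: PairFeaturizer


def prepare_benchmark(seed: int = 11,
                      synth_config: SyntheticConfig | None = None,
                      n_target_families: int = 2,
                      l_max: int = 128) -> BenchmarkData:
    """Generate the benchmark and its shifted source/target family split."""
    proteins, drugs, inter, gt = generate_dataset(synth_config)
    source, target, fams = make_shifted_split(proteins, drugs, inter, gt,
                                              n_target_families, seed=seed)
    feat = PairFeaturizer(proteins, drugs, l_max)
    return BenchmarkData(proteins=proteins, drugs=drugs, interactions=inter,
                         ground_truth=gt, source=source, target=target,
                         target_families=fams, featurizer=feat)


def subsample_pairs(interactions, n: int, seed: int):
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(interactions), size=min(n, len(interactions)),
                     replace=False)
    return [interactions[i] for i in idx]


def run_stage_one(data: BenchmarkData, seed: int = 11, adversarial: bool = True,
                  n_source_pairs: int = 400, epochs: int = 30,
                  encoder_config: EncoderConfig | None = None
                  ) -> tuple[InductiveResult, dict]:
    """Train stage one and report source-validation and target zero-shot AUROC."""
    enc = encoder_config or experiment_encoder_config()
    sp, sd, si = data.source
    pairs = subsample_pairs(si, n_source_pairs, seed)
    # validate on the source pairs not used for training
    used = {(r.drug_id, r.protein_id) for r in pairs}
    val = [r for r in si if (r.drug_id, r.protein_id) not in used]
    adv = AdversarialConfig(lam=1.0 if adversarial else 0.0,
                            schedule="dann_ramp", epochs=epochs, lr=3e-3,
                            batch_size=16, val_fraction=0.0)
    result = train_inductive((sp, sd, pairs), data.target, enc, adv, seed=seed)
    tp, td, ti = data.target
    val_rep = compute_metrics(
        [r.label for r in val],
        predict_proba(result.model, data.featurizer, val)) if val else None
    scores = predict_proba(result.model, data.featurizer, ti)
    target_rep = compute_metrics([r.label for r in ti], scores)
    report = {"source_val_auroc": val_rep.auroc if val_rep else None,
              "source_val_acc": val_rep.acc if val_rep else None,
              "target_zeroshot_auroc": target_rep.auroc}
    return result, report


def target_episode_split(data: BenchmarkData, factor: int = 2,
                         seed: int = 0) -> tuple[ClusterAssignment,
                                                 ClusterAssignment]:
    """Split target families into train/held-out protein groups.

    Each target family is partitioned into ``factor`` balanced subclusters;
    the first subcluster of every family forms the meta-training pool and
    the rest are held out for evaluation.
    """
    tp = data.target[0]
    fam = cluster_proteins(tp, len(data.target_families), k=3, seed=seed)
    sub = refine_clusters(fam, factor=factor, seed=seed)
    train_ids = {c for c in range(sub.n_clusters) if c % factor == 0}
    tr = ClusterAssignment({p: c for p, c in sub.mapping.items()
                            if c in train_ids}, sub.n_clusters)
    ev = ClusterAssignment({p: c for p, c in sub.mapping.items()
                            if c not in train_ids}, sub.n_clusters)
    return tr, ev


def run_stage_two(data: BenchmarkData, stage_one: InductiveResult,
                  seed: int = 13, k: int = 5, k_q: int = 6,
                  n_train_tasks: int = 40, n_eval_tasks: int = 50,
                  epochs: int = 40) -> tuple[MetaModel, dict]:
    """Episodic training on target-domain tasks, evaluated on held-out
    protein groups (unseen-protein mode throughout)."""
    ti = data.target[2]
    tr_asg, ev_asg = target_episode_split(data, seed=0)
    train_eps = build_episodes(ti, tr_asg, k=k, k_q=k_q,
                               n_tasks=n_train_tasks, seed=seed)
    eval_eps = build_episodes(ti, ev_asg, k=k, k_q=k_q,
                              n_tasks=n_eval_tasks, seed=seed + 86)
    model, log = train_meta(train_eps, stage_one.model, data.featurizer,
                            MetaTrainConfig(epochs=epochs), seed=seed)
    _, agg = evaluate_fewshot(model, eval_eps, data.featurizer)
    report = {"fewshot_auroc": agg["auroc_mean"],
              "fewshot_auroc_sd": agg["auroc_sd"],
              "fewshot_acc": agg["acc_mean"],
              "fewshot_auprc": agg["auprc_mean"],
              "n_eval_episodes": agg["n_episodes"],
              "train_query_acc": log[-1]["query_acc"] if log else None}
    return model, report
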
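"""Stage-one training: supervised source learning with category-aware
domain-adversarial alignment.

The encoder is trained to classify labelled source-domain pairs while a
gradient-reversal layer (GRL) and a pair of per-class domain discriminators
push source and target interaction features toward a shared distribution.
The two discriminators handle the negative-interaction (k=0) and
positive-interaction (k=1) channels separately; each sees the reversed
feature vector scaled elementwise by the model's own predicted probability
for its class.  Aligning the two channels independently keeps positive and
negative binding patterns from blending during adaptation.

The adversarial game is the usual single-backward formulation: the
discriminators descend their binary cross-entropy on domain labels
(source=0, target=1) while the GRL hands the encoder the same gradient
scaled by -lambda, so one optimizer step serves both sides.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import (Adam, Tensor, concatenate, default_dtype,
                       grad_reversal, relu, sigmoid)
from .encoder import DTIEncoder, EncoderConfig, batch_drugs, batch_proteins
from .io_featurize import (DrugRecord, InteractionRecord, ProteinRecord,
                           smiles_to_graph, tokenize_protein)
from .metrics import compute_metrics


@dataclass
class AdversarialConfig:
    lam: float = 1.0                 # ceiling of the adversarial weight
    schedule: str = "dann_ramp"      # "dann_ramp" or "constant"
    conditioning: str = "category"   # "category" (dual channel) or "cdan"
    disc_hidden: int = 64
    lr: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" decay to 0
    weight_decay: float = 0.0
    batch_size: int = 64
    epochs: int = 30
    val_fraction: float = 0.15
    dtype: str = "float32"       # training precision; "float64" for checks


class DomainDiscriminators:
    """Two independent 2-layer MLP discriminators (negative / positive)."""

    def __init__(self, feature_dim: int, hidden: int, seed: int = 0,
                 n_channels: int = 2):
        rng = np.random.default_rng(seed)
        s1 = math.sqrt(6.0 / (feature_dim + hidden))
        s2 = math.sqrt(6.0 / (hidden + 1))
        self.params: dict[str, Tensor] = {}
        for k in range(n_channels):
            self.params[f"w1_{k}"] = Tensor(
                rng.uniform(-s1, s1, (feature_dim, hidden)), True)
            self.params[f"b1_{k}"] = Tensor(np.zeros(hidden), True)
            self.params[f"w2_{k}"] = Tensor(
                rng.uniform(-s2, s2, (hidden, 1)), True)
            self.params[f"b2_{k}"] = Tensor(np.zeros(1), True)
        self.n_channels = n_channels

    def logit(self, x: Tensor, k: int) -> Tensor:
        h = relu(x @ self.params[f"w1_{k}"] + self.params[f"b1_{k}"])
        return (h @ self.params[f"w2_{k}"] + self.params[f"b2_{k}"])[:, 0]

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]


def bce_from_probs(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from probabilities, clipped for stability."""
    t = Tensor(np.asarray(targets, dtype=np.float64))
    p = probs * (1.0 - 2e-7) + 1e-7
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def category_adversarial_loss(source_features: Tensor, target_features: Tensor,
                              class_probs: np.ndarray,
                              discs: DomainDiscriminators,
                              lam: float) -> Tensor:
    """Dual-channel domain-confusion loss (mean over 2*(n_s+n_t) terms).

    ``class_probs`` rows are [P(y=0), P(y=1)] for source rows then target
    rows, treated as constants (the classifier is not trained through the
    conditioning).  Features pass through the GRL, so minimizing the returned
    loss trains the discriminators while the encoder receives the reversed,
    -lam-scaled gradient.
    """
    n_s, n_t = source_features.shape[0], target_features.shape[0]
    if n_s == 0 or n_t == 0:
        raise ValueError("both domains must contribute at least one row")
    feats = concatenate([source_features, target_features], axis=0)
    rev = grad_reversal(feats, lam)
    domain = np.concatenate([np.zeros(n_s), np.ones(n_t)])
    probs = np.asarray(class_probs, dtype=np.float64)
    if probs.shape != (n_s + n_t, 2):
        raise ValueError("class_probs must be ((n_s+n_t) x 2)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("class probability rows must sum to 1")
    total = None
    for k in range(2):
        scaled = rev * Tensor(probs[:, k:k + 1])
        p = sigmoid(discs.logit(scaled, k))
        term = bce_from_probs(p, domain)
        total = term if total is None else total + term
    return total / 2.0


def cdan_adversarial_loss(source_features: Tensor, target_features: Tensor,
                          class_probs: np.ndarray,
                          discs: DomainDiscriminators, lam: float) -> Tensor:
    """CDAN-style multilinear conditioning: one discriminator over the
    flattened outer product feature x class-probability (ablation alternative
    to the dual-channel loss)."""
    n_s, n_t = source_features.shape[0], target_features.shape[0]
    feats = concatenate([source_features, target_features], axis=0)
    rev = grad_reversal(feats, lam)
    probs = np.asarray(class_probs, dtype=np.float64)
    d = feats.shape[1]
    # outer product rows: (B, d*2)
    outer = concatenate([rev * Tensor(probs[:, k:k + 1]) for k in range(2)],
                        axis=1)
    domain = np.concatenate([np.zeros(n_s), np.ones(n_t)])
    p = sigmoid(discs.logit(outer, 0))
    return bce_from_probs(p, domain)


def combined_objective(loss_sup: Tensor, loss_dom: Tensor, lam: float) -> Tensor:
    """Total stage-one objective L = L_s + lam * L_d."""
    return loss_sup + lam * loss_dom


def dann_ramp(progress: float) -> float:
    """Standard adversarial warm-up 2/(1+exp(-10 p)) - 1 over progress p."""
    return 2.0 / (1.0 + math.exp(-10.0 * progress)) - 1.0


# ---------------------------------------------------------------------------
# featurization cache

class PairFeaturizer:
    """Caches tokenized proteins and molecular graphs for repeated batching."""

    def __init__(self, proteins: list[ProteinRecord], drugs: list[DrugRecord],
                 l_max: int):
        self.tokens = {p.id: tokenize_protein(p.sequence, l_max)
                       for p in proteins}
        self.graphs = {d.id: smiles_to_graph(d.smiles) for d in drugs}

    def batch(self, pairs: list[InteractionRecord]):
        prot = batch_proteins([self.tokens[r.protein_id] for r in pairs])
        drug = batch_drugs([self.graphs[r.drug_id] for r in pairs])
        return prot, drug


def predict_proba(model: DTIEncoder, feat: PairFeaturizer,
                  pairs: list[InteractionRecord],
                  batch_size: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        _, yc = model.forward(*feat.batch(chunk))
        out.append(yc.data)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# training loop

@dataclass
class InductiveResult:
    model: DTIEncoder
    discriminators: DomainDiscriminators
    log: list[dict]
    seed: int


def train_inductive(source: tuple, target: tuple | None,
                    enc_config: EncoderConfig,
                    adv_config: AdversarialConfig | None = None,
                    seed: int = 0,
                    log_fn=None) -> InductiveResult:
    """Stage-one optimization.

    ``source`` is (proteins, drugs, interactions) with labels; ``target`` is
    the same for the unlabeled target domain (labels ignored) or None for
    plain supervised training.  Source and target protein id sets must be
    disjoint.  Deterministic for fixed inputs and seed.
    """
    adv = adv_config or AdversarialConfig()
    if adv.epochs < 0:
        raise ValueError("epochs must be >= 0")
    with default_dtype(np.float32 if adv.dtype == "float32" else np.float64):
        return _train_inductive(source, target, enc_config, adv, seed, log_fn)


def _train_inductive(source, target, enc_config, adv, seed, log_fn):
    src_p, src_d, src_i = source
    use_adv = target is not None and adv.lam > 0
    if target is not None:
        tgt_p, tgt_d, tgt_i = target
        overlap = {p.id for p in src_p} & {p.id for p in tgt_p}
        if overlap:
            raise ValueError(f"proteins appear in both domains: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)

    model = DTIEncoder(enc_config, seed=seed)
    discs = DomainDiscriminators(
        enc_config.fusion_dim * (1 if adv.conditioning == "category" else 2),
        adv.disc_hidden, seed=seed + 1,
        n_channels=2 if adv.conditioning == "category" else 1)
    all_p = list(src_p) + (list(tgt_p) if target is not None else [])
    drug_map = {d.id: d for d in src_d}
    if target is not None:
        drug_map.update({d.id: d for d in tgt_d})
    feat = PairFeaturizer(all_p, list(drug_map.values()), enc_config.l_max)

    # source train/validation split
    idx = rng.permutation(len(src_i))
    n_val = max(1, int(round(adv.val_fraction * len(src_i)))) \
        if adv.val_fraction > 0 and len(src_i) > 3 else 0
    val = [src_i[i] for i in idx[:n_val]]
    train = [src_i[i] for i in idx[n_val:]]

    params = model.parameters() + (discs.parameters() if use_adv else [])
    opt = Adam(params, lr=adv.lr, weight_decay=adv.weight_decay)
    loss_fn = (category_adversarial_loss if adv.conditioning == "category"
               else cdan_adversarial_loss)

    n_batches = max(1, math.ceil(len(train) / adv.batch_size))
    total_steps = max(1, adv.epochs * n_batches)
    step = 0
    log: list[dict] = []
    for epoch in range(adv.epochs):
        order = rng.permutation(len(train))
        ep_ls, ep_ld, lam_t = [], [], 0.0
        for b in range(n_batches):
            batch = [train[i] for i in order[b * adv.batch_size:(b + 1) * adv.batch_size]]
            if not batch:
                continue
            labels = np.array([r.label for r in batch], dtype=np.float64)
            model.training = True
            fused_s, yc_s = model.forward(*feat.batch(batch))
            loss_sup = bce_from_probs(yc_s, labels)
            progress = step / total_steps
            if adv.lr_schedule == "cosine":
                opt.lr = adv.lr * 0.5 * (1.0 + math.cos(math.pi * progress))
            lam_t = (adv.lam * dann_ramp(progress)
                     if adv.schedule == "dann_ramp" else adv.lam)
            if use_adv:
                t_idx = rng.choice(len(tgt_i), size=min(len(batch), len(tgt_i)),
                                   replace=False)
                t_batch = [tgt_i[i] for i in t_idx]
                fused_t, yc_t = model.forward(*feat.batch(t_batch))
                yc_all = np.concatenate([yc_s.data, yc_t.data])
                probs = np.stack([1.0 - yc_all, yc_all], axis=1)
                loss_dom = loss_fn(fused_s.vector, fused_t.vector, probs,
                                   discs, lam=1.0)
                total = combined_objective(loss_sup, loss_dom, lam_t)
                ep_ld.append(float(loss_dom.data))
            else:
                total = loss_sup
            opt.zero_grad()
            total.backward()
            opt.step()
            model.training = False
            ep_ls.append(float(loss_sup.data))
            step += 1
        rec = {"epoch": epoch, "loss_sup": float(np.mean(ep_ls)),
               "loss_dom": float(np.mean(ep_ld)) if ep_ld else None,
               "lambda": lam_t}
        if val:
            scores = predict_proba(model, feat, val)
            rep = compute_metrics([r.label for r in val], scores)
            rec.update(val_auroc=rep.auroc, val_acc=rep.acc)
        log.append(rec)
        if log_fn is not None:
            log_fn(rec)
    return InductiveResult(model=model, discriminators=discs, log=log,
                           seed=seed)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, result: InductiveResult) -> None:
    arrays = {f"enc:{k}": v.data for k, v in result.model.params.items()}
    arrays.update({f"disc:{k}": v.data
                   for k, v in result.discriminators.params.items()})
    meta = {"config": asdict(result.model.config), "seed": result.seed,
            "n_disc_channels": result.discriminators.n_channels}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> InductiveResult:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        cfg = EncoderConfig(**meta["config"])
        model = DTIEncoder(cfg, seed=0)
        for k in model.params:
            model.params[k] = Tensor(npz[f"enc:{k}"].copy(), True)
        disc_keys = [k for k in npz.files if k.startswith("disc:")]
        dim = npz["disc:w1_0"].shape[0]
        hidden = npz["disc:w1_0"].shape[1]
        discs = DomainDiscriminators(dim, hidden, seed=0,
                                     n_channels=meta["n_disc_channels"])
        for k in disc_keys:
            discs.params[k[5:]] = Tensor(npz[k].copy(), True)
    return InductiveResult(model=model, discriminators=discs, log=[],
                           seed=meta["seed"])
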
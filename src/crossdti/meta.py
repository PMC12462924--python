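"""Stage-two associative learning: episodes, dynamic prototypes, focal loss.

Few-shot prediction is organized in 2-way k-shot episodes drawn from one
protein cluster: a support set with k positive and k negative interactions
and a query set from the same cluster.  In ``unseen_protein`` mode the
support and query sets share no protein, which is the realistic cold-start
setting; ``same_protein`` mode relaxes that.

For each query the support features are aggregated into one prototype per
class by an affine attention unit: support and query features are projected
through a shared linear map with SiLU activation, modulated by two learned
affine (scale, shift) branches, and scored by the squared-ReLU inner product
between the query row and every support row.  A per-class softmax over those
scores weighs the supports into dynamic, query-specific prototypes.  The
query is classified by the softmax over cosine similarities to the two
prototypes, and training minimizes a focal loss that down-weights easy
queries.

The episodic model is metric-based: there is no inner-loop gradient
adaptation, and the encoder is initialized from the final stage-one
parameters so the transferable binding features carry over.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import (Adam, Tensor, concatenate, default_dtype, relu, silu,
                       softmax)
from .encoder import DTIEncoder, EncoderConfig
from .inductive import PairFeaturizer
from .io_featurize import ClusterAssignment, InteractionRecord
from .metrics import MetricReport, compute_metrics


@dataclass
class Episode:
    support: list[InteractionRecord]      # 2k records, k per class
    support_labels: np.ndarray            # (2k,) ints
    query: list[InteractionRecord]
    query_labels: np.ndarray              # (k_q,) ints
    cluster_id: int
    mode: str

    @property
    def k(self) -> int:
        return len(self.support) // 2


@dataclass
class FocalParams:
    alpha: float = 1.0   # positive-class weight
    gamma: float = 2.0   # modulation exponent

    def __post_init__(self):
        if self.alpha <= 0 or self.gamma < 0:
            raise ValueError("alpha must be > 0 and gamma >= 0")


@dataclass
class AffineAttentionParams:
    W_I: Tensor
    gamma1: Tensor
    beta1: Tensor
    gamma2: Tensor
    beta2: Tensor

    @classmethod
    def init(cls, d: int, seed: int = 0) -> "AffineAttentionParams":
        rng = np.random.default_rng(seed)
        s = math.sqrt(6.0 / (2 * d))
        return cls(W_I=Tensor(rng.uniform(-s, s, (d, d)), True),
                   gamma1=Tensor(np.ones(d), True),
                   beta1=Tensor(np.zeros(d), True),
                   gamma2=Tensor(np.ones(d), True),
                   beta2=Tensor(np.zeros(d), True))

    def parameters(self) -> list[Tensor]:
        return [self.W_I, self.gamma1, self.beta1, self.gamma2, self.beta2]


# ---------------------------------------------------------------------------
# episode construction

def build_episodes(interactions: list[InteractionRecord],
                   assignment: ClusterAssignment, k: int, k_q: int,
                   n_tasks: int, mode: str = "unseen_protein",
                   seed: int = 0) -> list[Episode]:
    """Sample 2-way k-shot episodes cluster by cluster.

    Supports hold exactly k positives and k negatives; queries are drawn as
    balanced as the cluster allows.  In ``unseen_protein`` mode the cluster's
    proteins are first split into disjoint support-side and query-side sets.
    Clusters that cannot satisfy the constraints are skipped with a warning;
    an error is raised only if no cluster qualifies.  Deterministic per seed.
    """
    if mode not in ("unseen_protein", "same_protein"):
        raise ValueError(f"unknown episode mode {mode!r}")
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[InteractionRecord]] = {}
    for r in interactions:
        cid = assignment.mapping.get(r.protein_id)
        if cid is not None:
            by_cluster.setdefault(cid, []).append(r)

    episodes: list[Episode] = []
    skipped: set[int] = set()
    cluster_ids = sorted(by_cluster)
    attempts = 0
    while len(episodes) < n_tasks and attempts < 20 * n_tasks:
        attempts += 1
        cid = cluster_ids[int(rng.integers(len(cluster_ids)))]
        if cid in skipped:
            continue
        ep = _sample_episode(by_cluster[cid], cid, k, k_q, mode, rng)
        if ep is None:
            pool = by_cluster[cid]
            n_prot = len({r.protein_id for r in pool})
            if (sum(r.label for r in pool) < k
                    or sum(1 - r.label for r in pool) < k
                    or (mode == "unseen_protein" and n_prot < 2)):
                warnings.warn(f"cluster {cid} cannot supply {k}-shot "
                              f"episodes in {mode} mode; skipping")
                skipped.add(cid)
                if len(skipped) == len(cluster_ids):
                    raise ValueError("no cluster can supply episodes")
            continue
        episodes.append(ep)
    return episodes


def _sample_episode(pool, cid, k, k_q, mode, rng) -> Episode | None:
    for _ in range(20):
        if mode == "unseen_protein":
            prots = sorted({r.protein_id for r in pool})
            if len(prots) < 2:
                return None
            prots = [prots[i] for i in rng.permutation(len(prots))]
            n_sup = max(1, len(prots) // 2)
            sup_ids = set(prots[:n_sup])
            sup_pool = [r for r in pool if r.protein_id in sup_ids]
            qry_pool = [r for r in pool if r.protein_id not in sup_ids]
        else:
            sup_pool = qry_pool = pool
        sup = _draw_balanced(sup_pool, k, k, rng)
        if sup is None:
            continue
        # fixed label layout (negatives first) lets episodes batch together;
        # prototypes are order-invariant within a class
        sup = sorted(sup, key=lambda r: (r.label, r.drug_id, r.protein_id))
        if mode == "same_protein":
            used = {(r.drug_id, r.protein_id) for r in sup}
            qry_pool = [r for r in pool if (r.drug_id, r.protein_id) not in used]
        n_pos = k_q // 2
        qry = _draw_balanced(qry_pool, n_pos, k_q - n_pos, rng)
        if qry is None:
            continue
        return Episode(support=sup,
                       support_labels=np.array([r.label for r in sup]),
                       query=qry,
                       query_labels=np.array([r.label for r in qry]),
                       cluster_id=cid, mode=mode)
    return None


def _draw_balanced(pool, n_pos, n_neg, rng):
    pos = [r for r in pool if r.label == 1]
    neg = [r for r in pool if r.label == 0]
    if len(pos) < n_pos or len(neg) < n_neg:
        return None
    pi = rng.choice(len(pos), size=n_pos, replace=False)
    ni = rng.choice(len(neg), size=n_neg, replace=False)
    out = [pos[i] for i in pi] + [neg[i] for i in ni]
    return [out[i] for i in rng.permutation(len(out))]


# ---------------------------------------------------------------------------
# the episodic core (tensor expansion -> attention -> prototypes -> loss)

def expand_concat(O_s: Tensor, O_q: Tensor) -> Tensor:
    """Replicate supports across queries and prepend the query row.

    O_s: (N, 2k, d), O_q: (N, k_q, d) -> O_c: (N, k_q, 2k+1, d) with
    O_c[n, q, 0] = O_q[n, q] and O_c[n, q, 1+i] = O_s[n, i].
    """
    N, two_k, d = O_s.shape
    _, k_q, d2 = O_q.shape
    if O_q.shape[0] != N or d2 != d:
        raise ValueError("support/query shape mismatch")
    ones = Tensor(np.ones((N, k_q, 1, 1)))
    sup = O_s.reshape(N, 1, two_k, d) * ones       # broadcast replication
    qry = O_q.reshape(N, k_q, 1, d)
    return concatenate([qry, sup], axis=2)


def affine_attention(O_c: Tensor, params: AffineAttentionParams) -> Tensor:
    """Squared-ReLU attention scores of the query row against each support.

    Both branches share the SiLU-activated projection O_c W_I and differ only
    in their affine modulation (gamma, beta).  Returns (N, k_q, 2k) with
    entry i the score between the query and support i; nonnegative by
    construction.
    """
    H = silu(O_c @ params.W_I)
    Q = H * params.gamma1 + params.beta1
    K = H * params.gamma2 + params.beta2
    raw = relu(Q @ K.swapaxes(2, 3)) ** 2          # (N, k_q, 2k+1, 2k+1)
    return raw[:, :, 0, 1:]


def dynamic_prototypes(O_s_exp: Tensor, support_labels: np.ndarray,
                       A: Tensor, cardinality_prefactor: bool = False
                       ) -> Tensor:
    """Attention-softmax prototypes per class.

    ``O_s_exp``: (N, k_q, 2k, d) replicated supports; ``A``: (N, k_q, 2k)
    scores.  For each class c the softmax runs over the class-c support
    indices only, so the two prototypes aggregate disjoint support subsets.
    Returns P: (N, k_q, 2, d).

    ``cardinality_prefactor`` rescales each prototype by 1/(2k+1).  Cosine
    classification is scale-invariant, so this cannot change predictions;
    the flag exists for bit-faithfulness comparisons only.
    """
    labels = np.asarray(support_labels)
    protos = []
    for c in (0, 1):
        idx = np.where(labels == c)[0]
        if idx.size == 0:
            raise ValueError(f"no supports with label {c}")
        w = softmax(A[:, :, idx], axis=-1)          # (N, k_q, |c|)
        sub = O_s_exp[:, :, idx, :]                 # (N, k_q, |c|, d)
        N, k_q, nc = w.shape
        p = w.reshape(N, k_q, 1, nc) @ sub          # (N, k_q, 1, d)
        protos.append(p)
    P = concatenate(protos, axis=2)
    if cardinality_prefactor:
        P = P * (1.0 / (labels.size + 1))
    return P


def classify_and_loss(P: Tensor, O_q: Tensor, query_labels: np.ndarray,
                      focal: FocalParams, eps: float = 1e-8
                      ) -> tuple[Tensor, Tensor, Tensor]:
    """Cosine scores, true-class probabilities, and the focal loss.

    Scores are cos(P[n,q,c], O_q[n,q]); class probabilities are the softmax
    over the two scores; the loss is the mean over queries of
    -alpha_c (1 - p)^gamma log p with alpha_c = alpha for positive-label
    queries and 1 otherwise.  Zero-norm vectors are epsilon-guarded.
    """
    N, k_q, _, d = P.shape
    q = O_q.reshape(N, k_q, 1, d)
    dot = (P * q).sum(axis=-1)                          # (N, k_q, 2)
    pn = ((P ** 2).sum(axis=-1)) ** 0.5
    qn = ((q ** 2).sum(axis=-1)) ** 0.5
    scores = dot / (pn * qn + eps)
    probs2 = softmax(scores, axis=-1)                   # (N, k_q, 2)
    y = np.asarray(query_labels)
    if y.ndim == 1:
        y = np.broadcast_to(y, (N, k_q))
    n_idx, q_idx = np.meshgrid(np.arange(N), np.arange(k_q), indexing="ij")
    p_true = probs2[n_idx, q_idx, y]                    # (N, k_q)
    p_safe = p_true * (1.0 - 2e-12) + 1e-12
    alpha_eff = Tensor(np.where(y == 1, focal.alpha, 1.0))
    loss = -(alpha_eff * (1.0 - p_safe) ** focal.gamma * p_safe.log()).mean()
    return scores, p_true, loss


# ---------------------------------------------------------------------------
# episode serialization (ids only; features are recomputed on load)

def episodes_to_jsonl(episodes: list[Episode], path) -> None:
    with open(path, "w") as fh:
        for ep in episodes:
            fh.write(json.dumps({
                "support": [[r.drug_id, r.protein_id, r.label]
                            for r in ep.support],
                "query": [[r.drug_id, r.protein_id, r.label]
                          for r in ep.query],
                "cluster_id": ep.cluster_id, "mode": ep.mode}) + "\n")


def episodes_from_jsonl(path) -> list[Episode]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            sup = [InteractionRecord(d, p, l) for d, p, l in rec["support"]]
            qry = [InteractionRecord(d, p, l) for d, p, l in rec["query"]]
            out.append(Episode(
                support=sup,
                support_labels=np.array([r.label for r in sup]),
                query=qry, query_labels=np.array([r.label for r in qry]),
                cluster_id=rec["cluster_id"], mode=rec["mode"]))
    return out


# ---------------------------------------------------------------------------
# episodic model

class MetaModel:
    """Encoder plus affine-attention parameters for episodic inference."""

    def __init__(self, encoder: DTIEncoder, seed: int = 0,
                 attention: AffineAttentionParams | None = None):
        self.encoder = encoder
        self.attention = attention or AffineAttentionParams.init(
            encoder.config.fusion_dim, seed=seed)

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.attention.parameters()

    def episode_features(self, episodes: list[Episode],
                         feat: PairFeaturizer) -> tuple[Tensor, Tensor]:
        """Encode all pairs of a homogeneous episode batch.

        Returns O_s (N, 2k, d) and O_q (N, k_q, d).
        """
        two_k = len(episodes[0].support)
        k_q = len(episodes[0].query)
        pairs = [r for ep in episodes for r in ep.support + ep.query]
        fused, _ = self.encoder.fuse_batch(*feat.batch(pairs))
        d = fused.vector.shape[1]
        per = two_k + k_q
        O = fused.vector.reshape(len(episodes), per, d)
        return O[:, :two_k, :], O[:, two_k:, :]

    def episode_forward(self, episodes: list[Episode], feat: PairFeaturizer,
                        focal: FocalParams):
        O_s, O_q = self.episode_features(episodes, feat)
        O_c = expand_concat(O_s, O_q)
        A = affine_attention(O_c, self.attention)
        labels = np.stack([ep.support_labels for ep in episodes])
        if not (labels == labels[0]).all():
            raise ValueError("episodes in a meta-batch must share the "
                             "support label layout")
        P = dynamic_prototypes(O_c[:, :, 1:, :], labels[0], A)
        y_q = np.stack([ep.query_labels for ep in episodes])
        return classify_and_loss(P, O_q, y_q, focal)

    def save(self, path) -> None:
        arrays = {f"enc:{k}": v.data for k, v in self.encoder.params.items()}
        att = self.attention
        for name in ("W_I", "gamma1", "beta1", "gamma2", "beta2"):
            arrays[f"att:{name}"] = getattr(att, name).data
        from dataclasses import asdict
        arrays["__meta__"] = np.frombuffer(
            json.dumps({"config": asdict(self.encoder.config)}).encode(),
            dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MetaModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
            enc = DTIEncoder(EncoderConfig(**meta["config"]), seed=0)
            for k in enc.params:
                enc.params[k] = Tensor(npz[f"enc:{k}"].copy(), True)
            att = AffineAttentionParams(
                **{n if n == "W_I" else n: Tensor(npz[f"att:{n}"].copy(), True)
                   for n in ("W_I", "gamma1", "beta1", "gamma2", "beta2")})
        return cls(enc, attention=att)

    def zero_parameters(self) -> None:
        """Zero all weights (used to verify chance-level behaviour)."""
        for t in self.parameters():
            t.data[...] = 0.0


# ---------------------------------------------------------------------------
# training and evaluation

@dataclass
class MetaTrainConfig:
    meta_batch: int = 4
    epochs: int = 40
    lr: float = 1e-3
    weight_decay: float = 0.0
    focal: FocalParams = field(default_factory=FocalParams)
    dtype: str = "float32"   # training precision; "float64" for checks


def train_meta(episodes: list[Episode], encoder_init: DTIEncoder,
               feat: PairFeaturizer,
               config: MetaTrainConfig | None = None,
               seed: int = 0, log_fn=None) -> tuple[MetaModel, list[dict]]:
    """Episodic training from a stage-one encoder.

    The encoder starts from a copy of ``encoder_init``'s parameters (the
    stage-one final epoch).  Meta-batches of N episodes with identical
    (k, k_q) are optimized jointly on the focal loss; purely metric-based,
    with no per-episode gradient adaptation.
    """
    cfg = config or MetaTrainConfig()
    with default_dtype(np.float32 if cfg.dtype == "float32" else np.float64):
        return _train_meta(episodes, encoder_init, feat, cfg, seed, log_fn)


def _train_meta(episodes, encoder_init, feat, cfg, seed, log_fn):
    enc = DTIEncoder(encoder_init.config, seed=seed)
    enc.load_state(encoder_init.state_copy())
    model = MetaModel(enc, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(episodes))
        losses, accs = [], []
        for b0 in range(0, len(order), cfg.meta_batch):
            batch = [episodes[i] for i in order[b0:b0 + cfg.meta_batch]]
            # encoder stays in eval mode: prototypes compare samples, so
            # feature noise (dropout) directly corrupts the metric
            scores, p_true, loss = model.episode_forward(batch, feat, cfg.focal)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(float((p_true.data > 0.5).mean()))
        rec = {"epoch": epoch, "loss_focal": float(np.mean(losses)),
               "query_acc": float(np.mean(accs))}
        log.append(rec)
        if log_fn is not None:
            log_fn(rec)
    return model, log


def predict_episode(model: MetaModel, episode: Episode,
                    feat: PairFeaturizer) -> np.ndarray:
    """Positive-class probability for each query of one episode."""
    scores, _, _ = model.episode_forward([episode], feat,
                                         FocalParams(gamma=0.0))
    probs2 = softmax(scores, axis=-1).data[0]        # (k_q, 2)
    return probs2[:, 1]


def evaluate_fewshot(model: MetaModel, episodes: list[Episode],
                     feat: PairFeaturizer
                     ) -> tuple[list[MetricReport], dict]:
    """Per-episode metrics over pooled query predictions, plus mean +/- sd."""
    reports = []
    for ep in episodes:
        scores = predict_episode(model, ep, feat)
        rep = compute_metrics(ep.query_labels, scores)
        if rep.auroc is None:
            warnings.warn(f"episode on cluster {ep.cluster_id} has "
                          "single-class queries; excluded from AUROC")
        reports.append(rep)
    agg = {}
    for name in ("auroc", "auprc", "acc"):
        vals = [getattr(r, name) for r in reports
                if getattr(r, name) is not None]
        agg[f"{name}_mean"] = float(np.mean(vals)) if vals else None
        agg[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    agg["n_episodes"] = len(reports)
    return reports, agg
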
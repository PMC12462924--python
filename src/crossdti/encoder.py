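"""Multi-level interaction encoder with bilinear attention and gated fusion.

The encoder reads a tokenized protein and a molecular graph and produces one
interaction vector O per pair.  Both inputs pass through ``n_levels`` staged
blocks — 1-D convolutions with max-pooling on the sequence side, graph
convolutions on the molecule side — giving per-level representations
(P_i, D_i).  At every level a low-rank bilinear attention couples residue
positions to atoms, yielding a nonnegative residue x atom attention map and a
pooled interaction vector I_i.  A gating unit weighs the levels and a final
linear+ReLU selection layer produces O.  Two heads sit on top of O: a small
MLP giving the binding probability y_c and a single linear layer giving the
pK-scale affinity y_r.

Shallow levels see raw residue/atom neighbourhoods, deeper levels see pooled,
wider contexts; keeping every level in the fused representation is what makes
the learned binding patterns transfer across protein families.

All computation runs on the package's autodiff tensors so the same forward
code serves supervised, adversarial, and episodic training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import (Tensor, concatenate, conv1d_same, maximum, relu,
                       sigmoid)
from .io_featurize import (ATOM_FEATURE_DIM, MolecularGraph, TokenizedProtein)

VOCAB_SIZE = 27  # pad + A..Z
_NEG_SENTINEL = -1e9  # placed in masked slots so they never win a pooling max


@dataclass
class EncoderConfig:
    n_levels: int = 3
    embed_dim: int = 128
    protein_channels: list[int] = field(default_factory=lambda: [128, 128, 128])
    protein_kernel_sizes: list[int] = field(default_factory=lambda: [3, 6, 9])
    drug_hidden_dims: list[int] = field(default_factory=lambda: [128, 128, 128])
    fusion_dim: int = 256
    attention_rank: int = 8
    dropout: float = 0.0
    l_max: int = 1200
    pool_stride: int = 2
    cls_hidden: int = 64
    use_stem: bool = True        # embedding + first conv block (ablation switch)
    use_gated: bool = True       # gated level fusion vs plain sum (ablation switch)

    def __post_init__(self):
        for name in ("protein_channels", "protein_kernel_sizes", "drug_hidden_dims"):
            if len(getattr(self, name)) != self.n_levels:
                raise ValueError(f"{name} must list {self.n_levels} entries")
        if self.attention_rank <= 0:
            raise ValueError("attention_rank must be positive")
        if min(self.protein_channels + self.drug_hidden_dims +
               [self.embed_dim, self.fusion_dim]) <= 0:
            raise ValueError("all dimensions must be positive")


@dataclass
class LevelInteraction:
    vector: Tensor            # (B, fusion_dim)
    attention_map: Tensor     # (B, positions_i, atoms)
    level: int


@dataclass
class FusedInteraction:
    vector: Tensor            # (B, fusion_dim)
    gates: Tensor | None      # (B, n_levels)


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[-1], shape[-1]
    s = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class DTIEncoder:
    """Parameter container plus the staged forward pass."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, Tensor] = {}
        p["embed"] = Tensor(_glorot(rng, VOCAB_SIZE, c.embed_dim), True)
        in_ch = c.embed_dim
        for i in range(c.n_levels):
            k, out_ch = c.protein_kernel_sizes[i], c.protein_channels[i]
            if i == 0 and not c.use_stem:
                out_ch = c.embed_dim
            else:
                p[f"p_conv{i}"] = Tensor(
                    _glorot(rng, in_ch, out_ch)[None].repeat(k, 0) / math.sqrt(k),
                    True)
                p[f"p_bias{i}"] = Tensor(np.zeros(out_ch), True)
            in_ch = out_ch
        d_in = ATOM_FEATURE_DIM
        for i in range(c.n_levels):
            p[f"d_w{i}"] = Tensor(_glorot(rng, d_in, c.drug_hidden_dims[i]), True)
            p[f"d_b{i}"] = Tensor(np.zeros(c.drug_hidden_dims[i]), True)
            d_in = c.drug_hidden_dims[i]
        for i in range(c.n_levels):
            cp = self._protein_dim(i)
            cd = c.drug_hidden_dims[i]
            p[f"att_u{i}"] = Tensor(_glorot(rng, cp, c.attention_rank), True)
            p[f"att_v{i}"] = Tensor(_glorot(rng, cd, c.attention_rank), True)
            p[f"pool_u{i}"] = Tensor(_glorot(rng, cp, c.fusion_dim), True)
            p[f"pool_v{i}"] = Tensor(_glorot(rng, cd, c.fusion_dim), True)
            p[f"gate_w{i}"] = Tensor(_glorot(rng, c.fusion_dim, 1), True)
            p[f"gate_b{i}"] = Tensor(np.zeros(1), True)
        p["sel_w"] = Tensor(_glorot(rng, c.fusion_dim, c.fusion_dim), True)
        p["sel_b"] = Tensor(np.zeros(c.fusion_dim), True)
        p["cls_w1"] = Tensor(_glorot(rng, c.fusion_dim, c.cls_hidden), True)
        p["cls_b1"] = Tensor(np.zeros(c.cls_hidden), True)
        p["cls_w2"] = Tensor(_glorot(rng, c.cls_hidden, 1), True)
        p["cls_b2"] = Tensor(np.zeros(1), True)
        p["aff_w"] = Tensor(_glorot(rng, c.fusion_dim, 1), True)
        p["aff_b"] = Tensor(np.zeros(1), True)
        self.params = p
        self.training = False
        self._drop_rng = np.random.default_rng(seed + 977)

    def _dropout(self, x: Tensor) -> Tensor:
        """Inverted dropout, active only while ``self.training`` is set."""
        rate = self.config.dropout
        if not self.training or rate <= 0:
            return x
        keep = (self._drop_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(keep)

    def _protein_dim(self, level: int) -> int:
        if level == 0 and not self.config.use_stem:
            return self.config.embed_dim
        return self.config.protein_channels[level]

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DTIEncoder":
        with np.load(path) as npz:
            cfg = json.loads(bytes(npz["__config__"].tobytes()).decode())
            model = cls(EncoderConfig(**cfg), seed=0)
            for k in model.params:
                model.params[k] = Tensor(npz[k].copy(), True)
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = Tensor(v.copy(), True)

    # -- protein branch ------------------------------------------------------
    def encode_protein(self, tokens: np.ndarray, mask: np.ndarray
                       ) -> tuple[list[Tensor], list[np.ndarray]]:
        """Per-level protein features for a batch of token rows.

        ``tokens``: (B, L) ints, 0 = pad; ``mask``: (B, L) float 0/1.
        Returns n_levels feature tensors (B, L_i, C_i) and their masks.
        Padding positions carry zero features at every level, and pooling
        windows never let a pad position win, so appending pad columns leaves
        the valid features untouched.
        """
        if mask.sum() == 0:
            raise ValueError("all-pad protein input")
        c = self.config
        x = self.params["embed"][tokens]              # (B, L, E)
        m = Tensor(mask[:, :, None])
        x = x * m                                     # zero pad embeddings
        feats, masks = [], []
        cur_mask = mask
        for i in range(c.n_levels):
            if i == 0 and not c.use_stem:
                h = x
            else:
                h = self._conv1d(x, i) * Tensor(cur_mask[:, :, None])
                h = self._dropout(relu(h))
            x, cur_mask = self._maxpool(h, cur_mask)
            feats.append(x)
            masks.append(cur_mask)
        return feats, masks

    def _conv1d(self, x: Tensor, level: int) -> Tensor:
        return conv1d_same(x, self.params[f"p_conv{level}"]) + \
            self.params[f"p_bias{level}"]

    def _maxpool(self, x: Tensor, mask: np.ndarray
                 ) -> tuple[Tensor, np.ndarray]:
        s = self.config.pool_stride
        B, L, C = x.shape
        pad = (-L) % s
        if pad:
            x = concatenate(
                [x, Tensor(np.full((B, pad, C), _NEG_SENTINEL))], axis=1)
            mask = np.concatenate([mask, np.zeros((B, pad))], axis=1)
        # masked slots must not win the max: post-ReLU features are >= 0
        x = x * Tensor(mask[:, :, None]) + Tensor(
            (1.0 - mask[:, :, None]) * _NEG_SENTINEL)
        pooled = x[:, 0::s, :]
        for j in range(1, s):
            pooled = maximum(pooled, x[:, j::s, :])
        new_mask = mask.reshape(B, -1, s).max(axis=2)
        pooled = pooled * Tensor(new_mask[:, :, None])
        return pooled, new_mask

    # -- drug branch ---------------------------------------------------------
    def encode_drug(self, feats: np.ndarray, adj_norm: np.ndarray,
                    mask: np.ndarray) -> list[Tensor]:
        """Per-level node features for a padded batch of molecular graphs.

        ``feats``: (B, A, F) node features; ``adj_norm``: (B, A, A)
        symmetric-normalized adjacency with self-connections (zero rows for
        padded nodes); ``mask``: (B, A).  Message passing keeps all atoms at
        every level.
        """
        if mask.sum() == 0:
            raise ValueError("empty molecular graph")
        A = Tensor(adj_norm)
        m = Tensor(mask[:, :, None])
        h = Tensor(feats)
        out = []
        for i in range(self.config.n_levels):
            h = self._dropout(relu(A @ (h @ self.params[f"d_w{i}"]) +
                                   self.params[f"d_b{i}"])) * m
            out.append(h)
        return out

    # -- fusion --------------------------------------------------------------
    def bilinear_fuse(self, P_i: Tensor, D_i: Tensor, p_mask: np.ndarray,
                      d_mask: np.ndarray, level: int) -> LevelInteraction:
        """Low-rank bilinear attention between residue positions and atoms.

        The attention map is ReLU(P U)(ReLU(D V))^T — nonnegative by
        construction — with masked cells zeroed.  The interaction vector is
        the attention-weighted bilinear pooling over all valid
        (position, atom) pairs, normalized by the total attention mass so the
        vector is a weighted average of per-pair bilinear products (and
        reduces to that product exactly when one pair remains).
        """
        hu = relu(P_i @ self.params[f"att_u{level}"])      # (B, L, r)
        hv = relu(D_i @ self.params[f"att_v{level}"])      # (B, A, r)
        att = hu @ hv.swapaxes(1, 2)                       # (B, L, A)
        pm = Tensor(p_mask[:, :, None])
        dm = Tensor(d_mask[:, None, :])
        att = att * pm * dm
        m1 = P_i @ self.params[f"pool_u{level}"]           # (B, L, F)
        m2 = D_i @ self.params[f"pool_v{level}"]           # (B, A, F)
        pooled = (m1 * (att @ m2)).sum(axis=1)             # (B, F)
        mass = att.sum(axis=2).sum(axis=1).reshape(-1, 1) + 1e-8  # (B, 1)
        vector = pooled / mass
        return LevelInteraction(vector=vector, attention_map=att, level=level + 1)

    def gated_fuse(self, interactions: list[LevelInteraction]) -> FusedInteraction:
        """Sigmoid-gated sum of the per-level vectors, then linear+ReLU."""
        c = self.config
        if len(interactions) != c.n_levels:
            raise ValueError("expected one interaction per level")
        dims = {tuple(i.vector.shape[1:]) for i in interactions}
        if len(dims) != 1:
            raise ValueError("fusion_dim mismatch across levels")
        if c.use_gated:
            gates = []
            total = None
            for i, li in enumerate(interactions):
                g = sigmoid(li.vector @ self.params[f"gate_w{i}"] +
                            self.params[f"gate_b{i}"])      # (B, 1)
                gates.append(g)
                term = li.vector * g
                total = term if total is None else total + term
            gate_t = concatenate(gates, axis=1)
        else:
            total = interactions[0].vector
            for li in interactions[1:]:
                total = total + li.vector
            gate_t = None
        O = self._dropout(relu(total @ self.params["sel_w"] +
                               self.params["sel_b"]))
        return FusedInteraction(vector=O, gates=gate_t)

    # -- full passes ---------------------------------------------------------
    def fuse_batch(self, prot_batch, drug_batch) -> tuple[FusedInteraction,
                                                          list[LevelInteraction]]:
        tokens, p_mask = prot_batch
        feats, adj, d_mask = drug_batch
        P, p_masks = self.encode_protein(tokens, p_mask)
        D = self.encode_drug(feats, adj, d_mask)
        inter = [self.bilinear_fuse(P[i], D[i], p_masks[i], d_mask, i)
                 for i in range(self.config.n_levels)]
        return self.gated_fuse(inter), inter

    def classify(self, O: Tensor) -> Tensor:
        h = relu(O @ self.params["cls_w1"] + self.params["cls_b1"])
        logit = h @ self.params["cls_w2"] + self.params["cls_b2"]
        return sigmoid(logit)[:, 0]

    def forward(self, prot_batch, drug_batch) -> tuple[FusedInteraction, Tensor]:
        """Binding probability y_c in (0,1) for each pair in the batch."""
        fused, _ = self.fuse_batch(prot_batch, drug_batch)
        return fused, self.classify(fused.vector)

    def predict_affinity(self, O: Tensor) -> Tensor:
        """pK-scale affinity from a single linear decoding layer."""
        return (O @ self.params["aff_w"] + self.params["aff_b"])[:, 0]


# ---------------------------------------------------------------------------
# batching helpers (pure numpy; no gradients needed)

def batch_proteins(tokenized: list[TokenizedProtein],
                   trim: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack token rows, optionally trimming shared padding to the batch max."""
    L = max(t.length for t in tokenized) if trim else len(tokenized[0].tokens)
    tokens = np.stack([t.tokens[:L] for t in tokenized])
    mask = (tokens != 0).astype(np.float64)
    return tokens, mask


def normalized_adjacency(graph: MolecularGraph, size: int) -> np.ndarray:
    """D^-1/2 (A + I) D^-1/2 on a zero-padded (size x size) canvas."""
    n = graph.num_atoms
    a = np.zeros((size, size))
    a[np.arange(n), np.arange(n)] = 1.0
    for i, j in graph.edges:
        a[i, j] = a[j, i] = 1.0
    deg = a.sum(axis=1)
    inv = np.zeros(size)
    inv[deg > 0] = deg[deg > 0] ** -0.5
    return a * inv[:, None] * inv[None, :]


def batch_drugs(graphs: list[MolecularGraph]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A = max(g.num_atoms for g in graphs)
    feats = np.zeros((len(graphs), A, ATOM_FEATURE_DIM))
    adj = np.zeros((len(graphs), A, A))
    mask = np.zeros((len(graphs), A))
    for b, g in enumerate(graphs):
        feats[b, :g.num_atoms] = g.node_features
        adj[b] = normalized_adjacency(g, A)
        mask[b, :g.num_atoms] = 1.0
    return feats, adj, mask


# ---------------------------------------------------------------------------
# attention read-out

def top_indices(scores: np.ndarray, top_fraction: float) -> list[int]:
    """Indices of the top ceil(f*n) scores; ties resolved to lower index."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = len(scores)
    k = math.ceil(top_fraction * n)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    return sorted(order[:k])


def extract_attention(model: DTIEncoder, tokenized: TokenizedProtein,
                      graph: MolecularGraph, top_fraction: float = 0.2
                      ) -> list[dict]:
    """Per-level highlighted atoms and residue positions.

    Each atom (residue position) is ranked by its summed attention mass over
    the other axis; the top ``top_fraction`` indices per level are returned.
    Residue indices refer to the pooled positions of that level.
    """
    prot = batch_proteins([tokenized])
    drug = batch_drugs([graph])
    _, inter = model.fuse_batch(prot, drug)
    out = []
    for li in inter:
        att = li.attention_map.data[0]          # (L_i, A)
        out.append({
            "level": li.level,
            "atoms": top_indices(att.sum(axis=0), top_fraction),
            "residues": top_indices(att.sum(axis=1), top_fraction),
            "atom_scores": att.sum(axis=0),
            "residue_scores": att.sum(axis=1),
        })
    return out
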
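"""The cell-set transformer: tokenization, dual-attention blocks, NB decoder,
query position embedding, confidence classifier, and attention-mask logic.

Forward-pass contract
---------------------
Input counts are library-normalized to the within-set median library size and
log1p-transformed; masked genes are zeroed after normalization. Each cell is
projected by a single linear layer into ``n_tokens`` tokens of width
``token_dim`` and a shared gene-token embedding ``P`` is added; query-role
cells additionally receive the query position embedding. ``n_layers``
tabular blocks then alternate attention across tokens (within each cell)
and across cells (with flattened tokens, honoring the causal mask), each
sub-layer using residual-then-layernorm. The decoder maps each cell's
flattened embedding independently to a normalized NB rate vector (softmax)
and positive dispersions (softplus + 1e-4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autograd import Tensor, concatenate
from .nn import MLP, LayerNorm, Linear, Module, MultiheadAttention, Parameter

__all__ = [
    "ModelConfig",
    "MODEL_PRESETS",
    "TokenState",
    "CellEmbedding",
    "NBParams",
    "AttentionMaskSpec",
    "ROLE_PROMPT_CONDITION",
    "ROLE_PROMPT_CONTEXT",
    "ROLE_QUERY",
    "build_causal_mask",
    "full_attention_mask",
    "StackModel",
    "save_checkpoint",
    "load_checkpoint",
]

ROLE_PROMPT_CONDITION = "prompt_condition"
ROLE_PROMPT_CONTEXT = "prompt_context"
ROLE_QUERY = "query"
_ROLES = (ROLE_PROMPT_CONDITION, ROLE_PROMPT_CONTEXT, ROLE_QUERY)

CHECKPOINT_VERSION = 1
_NEG_INF = -1e30


@dataclass(frozen=True)
class ModelConfig:
    n_genes: int
    n_layers: int = 6
    n_tokens: int = 100
    token_dim: int = 8
    heads_intra: int = 8
    heads_inter: int = 8
    ffn_expansion: int = 4
    decoder_hidden: int | None = None  # defaults to nd
    inter_cell_attention: bool = True

    @property
    def nd(self) -> int:
        return self.n_tokens * self.token_dim

    def __post_init__(self):
        if self.token_dim % self.heads_intra != 0:
            raise ValueError("heads_intra must divide token_dim")
        if self.nd % self.heads_inter != 0:
            raise ValueError("heads_inter must divide n_tokens*token_dim")


#: Named model-size presets (layers, tokens, token width, heads).
MODEL_PRESETS = {
    "base-": dict(n_layers=3, n_tokens=100, token_dim=8, heads_intra=8, heads_inter=8),
    "base": dict(n_layers=6, n_tokens=100, token_dim=8, heads_intra=8, heads_inter=8),
    "base+": dict(n_layers=9, n_tokens=100, token_dim=8, heads_intra=8, heads_inter=8),
    "medium": dict(n_layers=6, n_tokens=100, token_dim=16, heads_intra=8, heads_inter=8),
    "large": dict(n_layers=9, n_tokens=100, token_dim=16, heads_intra=8, heads_inter=8),
    "xlarge": dict(n_layers=6, n_tokens=100, token_dim=32, heads_intra=8, heads_inter=20),
    "huge": dict(n_layers=9, n_tokens=100, token_dim=32, heads_intra=8, heads_inter=20),
}


@dataclass
class TokenState:
    values: Tensor  # (K, n, d)
    roles: np.ndarray | None = None


@dataclass
class CellEmbedding:
    tokens: Tensor  # (K, n, d)
    flat: Tensor    # (K, nd), row-major flattening of tokens


@dataclass
class NBParams:
    rho: Tensor    # (K, G), rows sum to 1
    theta: Tensor  # (K, G), strictly positive

    def mu(self, library) -> Tensor:
        lib = np.asarray(library, dtype=np.float64).reshape(-1, 1)
        if np.any(lib <= 0):
            raise ValueError("library sizes must be positive")
        return self.rho * Tensor(lib)


@dataclass(frozen=True)
class AttentionMaskSpec:
    allowed: np.ndarray  # (K, K) booleans

    def __post_init__(self):
        a = np.asarray(self.allowed, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("attention mask must be square")
        if not np.all(np.diag(a)):
            raise ValueError("every cell must attend to itself")
        object.__setattr__(self, "allowed", a)

    def bias(self) -> np.ndarray:
        return np.where(self.allowed, 0.0, _NEG_INF)


def _check_roles(roles) -> np.ndarray:
    roles = np.asarray(roles, dtype=object)
    bad = set(roles) - set(_ROLES)
    if bad:
        raise ValueError(f"unknown roles: {sorted(map(str, bad))}")
    return roles


def build_causal_mask(roles) -> AttentionMaskSpec:
    """Prompt-condition cells attend only to prompt-condition cells; prompt
    context and query cells attend everywhere. Information therefore flows
    strictly from the conditioning block to the rest of the set."""
    roles = _check_roles(roles)
    k = len(roles)
    is_pc = roles == ROLE_PROMPT_CONDITION
    allowed = np.ones((k, k), dtype=bool)
    allowed[np.ix_(is_pc, ~is_pc)] = False
    return AttentionMaskSpec(allowed=allowed)


def full_attention_mask(k: int) -> AttentionMaskSpec:
    return AttentionMaskSpec(allowed=np.ones((k, k), dtype=bool))


class TabularBlock(Module):
    """One dual-attention layer: intra-cell MHA over tokens, inter-cell MHA
    over flattened cells (mask-aware), token-wise FFN; post-norm residuals."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, nd = cfg.token_dim, cfg.nd
        self.intra = MultiheadAttention(d, cfg.heads_intra, rng)
        self.ln_intra = LayerNorm(d)
        self.inter = (MultiheadAttention(nd, cfg.heads_inter, rng)
                      if cfg.inter_cell_attention else None)
        self.ln_inter = LayerNorm(nd) if cfg.inter_cell_attention else None
        self.ffn = MLP([d, cfg.ffn_expansion * d, d], rng)
        self.ln_ffn = LayerNorm(d)
        self._cfg = cfg

    def __call__(self, z: Tensor, mask_bias: np.ndarray | None = None) -> Tensor:
        k, n, d = z.shape
        z = self.ln_intra(z + self.intra(z))
        if self.inter is not None:
            if mask_bias is not None and mask_bias.shape != (k, k):
                raise ValueError("inter-cell mask must be K x K")
            flat = z.reshape(1, k, n * d)
            flat = self.ln_inter(flat + self.inter(flat, mask_bias=mask_bias))
            z = flat.reshape(k, n, d)
        return self.ln_ffn(z + self.ffn(z))


class StackModel(Module):
    """Cell-set transformer with NB decoder and confidence classifier."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(0) if rng is None else rng
        g, nd = config.n_genes, config.nd
        hidden = config.decoder_hidden or nd
        self.config = config
        self.tokenizer = Linear(g, nd, rng)
        self.gene_token_embedding = Parameter(
            rng.normal(0.0, 0.02, size=(config.n_tokens, config.token_dim)))
        self.query_embedding = Parameter(np.zeros(nd))
        self.blocks = [TabularBlock(config, rng) for _ in range(config.n_layers)]
        self.decoder = MLP([nd, hidden, 2 * g], rng)
        self.classifier = MLP([2 * nd, nd, 1], rng)

    # -- input preparation ---------------------------------------------------
    @staticmethod
    def normalize_counts(counts: np.ndarray, library: np.ndarray) -> np.ndarray:
        """log1p of counts scaled per cell to the within-set median library."""
        lib = np.asarray(library, dtype=np.float64)
        target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
        scale = np.where(lib > 0, target / np.maximum(lib, 1.0), 1.0)
        return np.log1p(np.asarray(counts, dtype=np.float64) * scale[:, None])

    def tokenize(self, x_norm) -> TokenState:
        x = x_norm if isinstance(x_norm, Tensor) else Tensor(np.asarray(x_norm, float))
        k, g = x.shape
        if g != self.config.n_genes:
            raise ValueError(f"expected {self.config.n_genes} genes, got {g}")
        z = self.tokenizer(x).reshape(k, self.config.n_tokens, self.config.token_dim)
        return TokenState(values=z + self.gene_token_embedding)

    # -- forward passes ------------------------------------------------------
    def encode(self, counts, library, masked_genes=None, roles=None,
               mask: AttentionMaskSpec | None = None,
               add_query_embedding: bool = True) -> CellEmbedding:
        counts = np.asarray(counts, dtype=np.float64)
        k = counts.shape[0]
        if roles is not None:
            roles = _check_roles(roles)
            if len(roles) != k:
                raise ValueError("role vector length must equal number of cells")
        x = self.normalize_counts(counts, library)
        if masked_genes is not None and len(list(masked_genes)):
            x = x.copy()
            x[:, np.asarray(sorted(int(g) for g in masked_genes))] = 0.0
        state = self.tokenize(x)
        z = state.values
        if roles is not None and add_query_embedding:
            is_query = (roles == ROLE_QUERY).astype(np.float64)[:, None, None]
            pq = self.query_embedding.reshape(self.config.n_tokens, self.config.token_dim)
            z = z + pq * Tensor(is_query)
        bias = mask.bias() if mask is not None else None
        for block in self.blocks:
            z = block(z, mask_bias=bias)
        return CellEmbedding(tokens=z, flat=z.reshape(k, self.config.nd))

    def decode(self, embedding: CellEmbedding | Tensor, library=None) -> NBParams:
        flat = embedding.flat if isinstance(embedding, CellEmbedding) else embedding
        if library is not None and np.any(np.asarray(library) <= 0):
            raise ValueError("library sizes must be positive")
        h = self.decoder(flat)
        g = self.config.n_genes
        rho = h[:, :g].softmax(axis=-1)
        theta = h[:, g:].softplus() + 1e-4
        return NBParams(rho=rho, theta=theta)

    def classifier_score(self, prompt_mean, cell_flat) -> Tensor:
        """Confidence logit(s) from [mean prompt-condition embedding ; cell
        embedding]. Positive means "more like a query cell". Inputs are
        treated as constants by the backbone (pass detached embeddings)."""
        pm = prompt_mean if isinstance(prompt_mean, Tensor) else Tensor(prompt_mean)
        cf = cell_flat if isinstance(cell_flat, Tensor) else Tensor(cell_flat)
        if pm.ndim == 1:
            pm = pm.reshape(1, -1)
        if cf.ndim == 1:
            cf = cf.reshape(1, -1)
        if pm.shape[-1] != self.config.nd or cf.shape[-1] != self.config.nd:
            raise ValueError("embedding dimension mismatch")
        if pm.shape[0] == 1 and cf.shape[0] > 1:
            pm = pm * Tensor(np.ones((cf.shape[0], 1)))  # tile rows, grad-aware
        out = self.classifier(concatenate([pm, cf], axis=1))
        return out.reshape(-1)

    def forward_params(self, counts, library, masked_genes=None, roles=None,
                       mask: AttentionMaskSpec | None = None) -> tuple[CellEmbedding, NBParams]:
        emb = self.encode(counts, library, masked_genes=masked_genes, roles=roles, mask=mask)
        return emb, self.decode(emb, library)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: StackModel, path, gene_index=None, extra: dict | None = None):
    """Self-describing archive: version, config, weights, optional gene index."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "genes": list(gene_index.genes) if gene_index is not None else None,
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)
    return path


def load_checkpoint(path) -> tuple[StackModel, dict]:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = StackModel(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta
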
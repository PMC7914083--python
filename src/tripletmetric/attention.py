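"""Multi-round cross-modal attention memory encoder and its two decoders.

A class-identification query is first encoded by a recurrent (LSTM) encoder
into a state vector u.  For each of r rounds the state is projected into two
memory banks in turn:

* category memory M^H (one learned row per class): scores s_i = u . m_i^H,
  attention alpha = softmax(s), update u <- u + sum_i alpha_i m_i^H;
* visual memory M^I (one row per spatial region of a conv feature map, 196
  rows at full scale): h_i = tanh(W_fh m_i^I + W_u u + b_h), region score
  w_p . h_i + b_p, attention p^I = softmax(scores), update
  u <- u + sum_i p_i^I m_i^I.

After r rounds the encoder output is e_c = tanh(W_e u_r + b_e).  Two
decoders consume e_c: a generative LSTM decoder emitting a category-token
distribution per step, and a discriminative decoder that encodes each
candidate category with a shared LSTM and ranks candidates by the softmax of
dot-product similarities with e_c.

All weights are uniform [-0.1, 0.1] initialized under an explicit seed; the
cells are standard LSTMs (input/forget/output gates, tanh candidate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import softmax

__all__ = [
    "LSTMCell",
    "MemoryBanks",
    "AttentionParams",
    "EncoderState",
    "DecoderOutput",
    "encode_input",
    "attend_category",
    "attend_visual",
    "multi_round_encode",
    "generative_decode",
    "discriminative_decode",
]


class LSTMCell:
    """Standard LSTM cell in numpy (gates ordered i, f, o, g)."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        k = hidden_dim
        self.W_x = rng.uniform(-0.1, 0.1, size=(4 * k, input_dim))
        self.W_h = rng.uniform(-0.1, 0.1, size=(4 * k, k))
        self.b = rng.uniform(-0.1, 0.1, size=4 * k)

    def step(self, x, state=None):
        k = self.hidden_dim
        if state is None:
            h = np.zeros(k)
            c = np.zeros(k)
        else:
            h, c = state
        z = self.W_x @ np.asarray(x, float) + self.W_h @ h + self.b
        i = _sigmoid(z[:k])
        f = _sigmoid(z[k : 2 * k])
        o = _sigmoid(z[2 * k : 3 * k])
        g = np.tanh(z[3 * k :])
        c = f * c + i * g
        h = o * np.tanh(c)
        return h, c

    def run(self, xs) -> np.ndarray:
        state = None
        for x in xs:
            state = self.step(x, state)
        return state[0]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class MemoryBanks:
    """Category fact memory (c x d) and visual fact memory (R x d)."""

    category_memory: np.ndarray
    visual_memory: np.ndarray

    def __post_init__(self):
        self.category_memory = np.atleast_2d(np.asarray(self.category_memory, float))
        self.visual_memory = np.atleast_2d(np.asarray(self.visual_memory, float))
        if not (
            np.isfinite(self.category_memory).all()
            and np.isfinite(self.visual_memory).all()
        ):
            raise ValueError("memory banks must be finite")

    @classmethod
    def init(cls, n_classes: int, d: int, regions: int = 196, seed: int = 0):
        if n_classes < 1 or regions < 1:
            raise ValueError("need at least one category row and one region")
        rng = np.random.default_rng(seed)
        return cls(
            category_memory=rng.uniform(-0.1, 0.1, size=(n_classes, d)),
            visual_memory=rng.uniform(-0.1, 0.1, size=(regions, d)),
        )

    @classmethod
    def from_conv_map(cls, conv_map, category_memory) -> "MemoryBanks":
        """Visual memory rows = spatial positions of a C x H x W conv map
        (each row the C-vector at one position, row-major)."""
        fm = np.asarray(conv_map, float)
        if fm.ndim != 3:
            raise ValueError("conv_map must be C x H x W")
        C, H, W = fm.shape
        return cls(
            category_memory=category_memory,
            visual_memory=fm.reshape(C, H * W).T,
        )


@dataclass
class AttentionParams:
    """All encoder/decoder weights; see module docstring for roles.

    The region-score projection is a k-vector ``w_p`` with scalar bias
    ``b_p`` applied per region, which is the only shape under which the
    softmax over regions yields one probability per region.
    """

    d: int
    k: int
    vocab_size: int
    W_fh: np.ndarray
    W_u: np.ndarray
    b_h: np.ndarray
    w_p: np.ndarray
    b_p: float
    W_e: np.ndarray
    b_e: np.ndarray
    lstm_f: LSTMCell
    lstm_g: LSTMCell
    lstm_d: LSTMCell
    W_g: np.ndarray
    b_g: np.ndarray
    token_embeddings: np.ndarray  # (vocab_size, d)

    @classmethod
    def init(cls, d: int, k: int, vocab_size: int, seed: int = 0) -> "AttentionParams":
        if d < 1 or k < 1 or vocab_size < 1:
            raise ValueError("dimensions must be positive")
        rng = np.random.default_rng(seed)
        u = lambda *shape: rng.uniform(-0.1, 0.1, size=shape)
        return cls(
            d=d,
            k=k,
            vocab_size=vocab_size,
            W_fh=u(k, d),
            W_u=u(k, d),
            b_h=u(k),
            w_p=u(k),
            b_p=float(u(1)[0]),
            W_e=u(d, d),
            b_e=u(d),
            lstm_f=LSTMCell(d, d, rng),
            lstm_g=LSTMCell(d, d, rng),
            lstm_d=LSTMCell(d, d, rng),
            W_g=u(vocab_size, d),
            b_g=u(vocab_size),
            token_embeddings=u(vocab_size, d),
        )


@dataclass
class EncoderState:
    u: np.ndarray
    round: int
    rounds_total: int
    last_category_weights: Optional[np.ndarray] = None
    last_visual_weights: Optional[np.ndarray] = None
    encoded: Optional[np.ndarray] = None


@dataclass
class DecoderOutput:
    token_probs: Optional[List[np.ndarray]] = None
    tokens: Optional[List[int]] = None
    candidate_scores: Optional[np.ndarray] = None
    posterior: Optional[np.ndarray] = None


def encode_input(sequence, params: AttentionParams) -> np.ndarray:
    """Run the shared recurrent encoder over an ordered list of d-vectors
    and return its final hidden state V_fc."""
    seq = [np.asarray(x, float) for x in sequence]
    if not seq:
        raise ValueError("sequence is empty")
    return params.lstm_f.run(seq)


def attend_category(u, memory: MemoryBanks) -> Tuple[np.ndarray, np.ndarray]:
    """Project the state into the category memory: dot-product scores,
    softmax weights, additive convex-combination update."""
    u = np.asarray(u, float)
    MH = memory.category_memory
    if MH.shape[0] < 1 or MH.size == 0:
        raise ValueError("category memory is empty")
    if MH.shape[1] != u.size:
        raise ValueError("state and category memory dimensions differ")
    scores = MH @ u
    alpha = softmax(scores)
    return u + alpha @ MH, alpha


def attend_visual(
    u, memory: MemoryBanks, params: AttentionParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Project the state into the visual memory through the one-layer tanh
    scoring network."""
    u = np.asarray(u, float)
    MI = memory.visual_memory
    if MI.shape[1] != u.size or params.W_fh.shape != (params.k, u.size):
        raise ValueError("shape mismatch between state, memory and weights")
    # h has one k-column per region: W_fh m_i + (W_u u + b_h)
    H = np.tanh(params.W_fh @ MI.T + (params.W_u @ u + params.b_h)[:, None])
    scores = params.w_p @ H + params.b_p
    p = softmax(scores)
    return u + p @ MI, p


def multi_round_encode(
    V_fc, memory: MemoryBanks, params: AttentionParams, rounds: int
) -> EncoderState:
    """Alternate category and visual projections for ``rounds`` rounds, then
    finalize with e_c = tanh(W_e u_r + b_e)."""
    if rounds < 0:
        raise ValueError("rounds must be nonnegative")
    u = np.asarray(V_fc, float)
    state = EncoderState(u=u, round=0, rounds_total=rounds)
    for j in range(rounds):
        u, alpha = attend_category(u, memory)
        u, p = attend_visual(u, memory, params)
        state = EncoderState(
            u=u,
            round=j + 1,
            rounds_total=rounds,
            last_category_weights=alpha,
            last_visual_weights=p,
        )
    state.encoded = np.tanh(params.W_e @ state.u + params.b_e)
    return state


def generative_decode(e_c, params: AttentionParams, max_len: int) -> DecoderOutput:
    """Greedy generative decoding: h_0 = e_c, then per step
    h_i = LSTM^g(h_{i-1}, x_{i-1}) and p_i = softmax(W_g h_i + b_g); the
    emitted token's embedding feeds the next step."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    h = np.asarray(e_c, float)
    c = np.zeros_like(h)
    x_prev = np.zeros(params.d)
    probs, tokens = [], []
    for _ in range(max_len):
        h, c = params.lstm_g.step(x_prev, (h, c))
        p = softmax(params.W_g @ h + params.b_g)
        tok = int(np.argmax(p))
        probs.append(p)
        tokens.append(tok)
        x_prev = params.token_embeddings[tok]
    return DecoderOutput(token_probs=probs, tokens=tokens)


def discriminative_decode(
    e_c, candidates: Sequence[Sequence[int]], params: AttentionParams
) -> DecoderOutput:
    """Encode every candidate token sequence with the shared candidate LSTM,
    score by dot product with e_c, and return the softmax posterior over
    candidates (sortable from large to small)."""
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    e_c = np.asarray(e_c, float)
    encodings = []
    for cand in candidates:
        toks = list(cand)
        if not toks:
            raise ValueError("candidate token sequences must be nonempty")
        xs = [params.token_embeddings[int(t)] for t in toks]
        encodings.append(params.lstm_d.run(xs))
    scores = np.array([e_c @ h for h in encodings])
    return DecoderOutput(candidate_scores=scores, posterior=softmax(scores))
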
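"""Keyword-conditioned recurrent encoder-decoder over subword ids.

Architecture: a shared embedding table feeds a bidirectional 2-layer LSTM
encoder; its per-position outputs (forward and backward states concatenated)
are the *latent features*.  An autoregressive 2-layer LSTM decoder, seeded
from the encoder's final states through a tanh bridge, generates the target
sentence token by token; at every step a single-head content-based attention
(learned projections of decoder state and latent features, dot-product energy,
softmax) forms a context vector that is concatenated with the decoder state
before the output projection.  The decoder is unidirectional: a bidirectional
autoregressive decoder is incoherent, so bidirectionality applies to the
encoder only.

The model input for one training pattern is a single concatenated sequence:

    <kw> kw1 <kwsep> kw2 ... <sep> initial-sentence <eos>

i.e. the dictated keywords of the target sentence followed by the previous
report sentence (or the report-start placeholder).

Everything is plain numpy (float64) with hand-derived gradients; the
forward/backward pair is verified against finite differences in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, model_validator

from .corpus_io import Report, Sentence
from .tokenizer import SubwordVocabulary, decode as sp_decode, encode as sp_encode

EMPTY_SENTENCE = "<EMPTY>"  # surface form when generation yields no content


class ModelConfigError(ValueError):
    pass


class ModelConfig(BaseModel):
    vocab_size: int
    embedding_size: int = 512
    hidden_size: int = 256  # per direction
    encoder_layers: int = 2
    encoder_bidirectional: bool = True
    decoder_layers: int = 2
    max_decode_length: int = 60
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.vocab_size < 8:
            raise ModelConfigError("vocab_size implausibly small")
        if self.hidden_size <= 0 or self.embedding_size <= 0:
            raise ModelConfigError("hidden_size and embedding_size must be positive")
        if self.max_decode_length < 1:
            raise ModelConfigError("max_decode_length must be >= 1")
        if not self.encoder_bidirectional:
            raise ModelConfigError("only the bidirectional encoder is supported")
        return self


@dataclass
class ModelParams:
    """All weights plus their configuration.  Arrays are keyed by role:
    ``emb``, ``enc_l{l}_{f|b}_{Wx|Wh|b}``, ``bridge_l{l}_{Wh|bh|Wc|bc}``,
    ``dec_l{l}_{Wx|Wh|b}``, ``att_Wq``, ``att_Wk``, ``out_W``, ``out_b``."""

    config: ModelConfig
    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelParams":
        return ModelParams(self.config, {k: v.copy() for k, v in self.arrays.items()})

    @property
    def embedding_table(self) -> np.ndarray:
        return self.arrays["emb"]

    def check_finite(self) -> bool:
        return all(np.all(np.isfinite(v)) for v in self.arrays.values())

    def save(self, path: str | Path) -> None:
        """Checkpoint: one .npz holding the flat weight arrays plus the
        config as a JSON string entry."""
        np.savez(
            Path(path),
            __config__=np.array(self.config.model_dump_json()),
            **self.arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(Path(path), allow_pickle=False) as data:
            config = ModelConfig.model_validate_json(str(data["__config__"]))
            arrays = {k: data[k] for k in data.files if k != "__config__"}
        return cls(config, arrays)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def init_model(config: ModelConfig, seed: int | None = None,
               dtype=np.float32) -> ModelParams:
    """Seeded random initialization.  This untrained state is the
    "before training" arm of the before/after comparison.

    float32 is the working precision; pass ``dtype=np.float64`` for
    numerical verification (finite-difference gradient checks)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    E, H, V = config.embedding_size, config.hidden_size, config.vocab_size
    A = H  # attention projection width

    def u(*shape: int, r: float = 0.08) -> np.ndarray:
        return rng.uniform(-r, r, size=shape).astype(dtype)

    arrays: dict[str, np.ndarray] = {
        "emb": rng.uniform(-0.1, 0.1, size=(V, E)).astype(dtype)
    }
    for l in range(config.encoder_layers):
        d_in = E if l == 0 else 2 * H
        for d in ("f", "b"):
            arrays[f"enc_l{l}_{d}_Wx"] = u(d_in, 4 * H)
            arrays[f"enc_l{l}_{d}_Wh"] = u(H, 4 * H)
            b = np.zeros(4 * H, dtype=dtype)
            b[H: 2 * H] = 1.0  # forget-gate bias
            arrays[f"enc_l{l}_{d}_b"] = b
    for l in range(config.decoder_layers):
        d_in = E if l == 0 else H
        arrays[f"dec_l{l}_Wx"] = u(d_in, 4 * H)
        arrays[f"dec_l{l}_Wh"] = u(H, 4 * H)
        b = np.zeros(4 * H, dtype=dtype)
        b[H: 2 * H] = 1.0
        arrays[f"dec_l{l}_b"] = b
        arrays[f"bridge_l{l}_Wh"] = u(2 * H, H)
        arrays[f"bridge_l{l}_bh"] = np.zeros(H, dtype=dtype)
        arrays[f"bridge_l{l}_Wc"] = u(2 * H, H)
        arrays[f"bridge_l{l}_bc"] = np.zeros(H, dtype=dtype)
    arrays["att_Wq"] = u(H, A)
    arrays["att_Wk"] = u(2 * H, A)
    arrays["out_W"] = u(H + 2 * H, V)
    arrays["out_b"] = np.zeros(V, dtype=dtype)
    return ModelParams(config, arrays)


def check_vocab_compatible(config: ModelConfig, vocab: SubwordVocabulary) -> None:
    if config.vocab_size != vocab.size:
        raise ModelConfigError(
            f"model vocab_size {config.vocab_size} != tokenizer vocabulary size {vocab.size}"
        )


def assemble_pattern_input(vocab: SubwordVocabulary, keywords: list[str],
                           initial_sentence: str) -> list[int]:
    """Build the concatenated model input for one pattern:
    keyword block (marker + <kwsep>-delimited keywords), block separator,
    initial sentence, end-of-sentence."""
    from .tokenizer import BLOCK_SEP, KW_MARK, KW_SEP

    ids = [vocab.piece_id(KW_MARK)]
    for i, kw in enumerate(keywords):
        if i:
            ids.append(vocab.piece_id(KW_SEP))
        ids.extend(sp_encode(vocab, kw))
    ids.append(vocab.piece_id(BLOCK_SEP))
    ids.extend(sp_encode(vocab, initial_sentence))
    ids.append(vocab.eos_id)
    return ids


# ---------------------------------------------------------------------------
# LSTM primitives (batched over (B, T, d), binary mask for padding)
# ---------------------------------------------------------------------------

def _lstm_forward(x: np.ndarray, mask: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                  b: np.ndarray, reverse: bool = False):
    """Run one LSTM direction over a padded batch.  Masked steps carry the
    state through unchanged, so the final state is the state at each
    sequence's last valid position.  Returns (outputs, caches, (hT, cT))."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    outputs = np.zeros((B, T, H), dtype=x.dtype)
    xp = x @ Wx + b
    caches = []
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        a = xp[:, t] + h @ Wh
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H: 2 * H])
        g = np.tanh(a[:, 2 * H: 3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        m = mask[:, t: t + 1]
        caches.append((t, h, c, i, f, g, o, c_new))
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        outputs[:, t] = h * m
    return outputs, caches, (h, c)


def _lstm_backward(d_out: np.ndarray, dhT: np.ndarray, dcT: np.ndarray,
                   x: np.ndarray, mask: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                   caches) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gradient of :func:`_lstm_forward` w.r.t. inputs and weights."""
    dx = np.zeros_like(x)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dh = dhT.copy()
    dc = dcT.copy()
    for (t, h_prev, c_prev, i, f, g, o, c_new) in reversed(caches):
        m = mask[:, t: t + 1]
        G = dh + m * d_out[:, t]
        dh_new = m * G
        dh_prev_dir = (1.0 - m) * G
        tc = np.tanh(c_new)
        dc_new = m * dc + dh_new * o * (1.0 - tc * tc)
        dc_prev_dir = (1.0 - m) * dc
        do = dh_new * tc
        di = dc_new * g
        dg = dc_new * i
        df = dc_new * c_prev
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dx[:, t] = da @ Wx.T
        dWx += x[:, t].T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dh = dh_prev_dir + da @ Wh.T
        dc = dc_prev_dir + dc_new * f
    return dx, dWx, dWh, db


def _encoder_forward(params: ModelParams, X: np.ndarray, mask: np.ndarray):
    """All encoder layers/directions.  Returns (latents (B,Tx,2H), layer
    inputs, per-layer caches and finals)."""
    p = params.arrays
    x = p["emb"][X]
    layer_inputs = [x]
    layer_caches = []
    finals = []
    for l in range(params.config.encoder_layers):
        Hf, cf, finf = _lstm_forward(
            x, mask, p[f"enc_l{l}_f_Wx"], p[f"enc_l{l}_f_Wh"], p[f"enc_l{l}_f_b"])
        Hb, cb, finb = _lstm_forward(
            x, mask, p[f"enc_l{l}_b_Wx"], p[f"enc_l{l}_b_Wh"], p[f"enc_l{l}_b_b"],
            reverse=True)
        x = np.concatenate([Hf, Hb], axis=2)
        layer_inputs.append(x)
        layer_caches.append((cf, cb))
        finals.append((finf, finb))
    return x, layer_inputs, layer_caches, finals


def _bridge_forward(params: ModelParams, finals):
    """Map the encoder's final states to the decoder's initial states."""
    p = params.arrays
    state = []
    caches = []
    for l in range(params.config.decoder_layers):
        (hf, _cf), (hb, _cb) = finals[min(l, len(finals) - 1)]
        ef = np.concatenate([hf, hb], axis=1)
        h0 = np.tanh(ef @ p[f"bridge_l{l}_Wh"] + p[f"bridge_l{l}_bh"])
        c0 = np.tanh(ef @ p[f"bridge_l{l}_Wc"] + p[f"bridge_l{l}_bc"])
        state.append((h0, c0))
        caches.append((ef, h0, c0))
    return state, caches


def _dec_lstm_step(x, h_prev, c_prev, Wx, Wh, b):
    H = Wh.shape[0]
    a = x @ Wx + h_prev @ Wh + b
    i = _sigmoid(a[:, :H])
    f = _sigmoid(a[:, H: 2 * H])
    g = np.tanh(a[:, 2 * H: 3 * H])
    o = _sigmoid(a[:, 3 * H:])
    c_new = f * c_prev + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new, (x, h_prev, c_prev, i, f, g, o, c_new)


def _dec_step_back(cache, dh, dc, Wx, Wh):
    x, h_prev, c_prev, i, f, g, o, c_new = cache
    tc = np.tanh(c_new)
    dc_tot = dc + dh * o * (1.0 - tc * tc)
    do = dh * tc
    di = dc_tot * g
    dg = dc_tot * i
    df = dc_tot * c_prev
    da = np.concatenate(
        [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
        axis=1,
    )
    dx = da @ Wx.T
    dh_prev = da @ Wh.T
    dc_prev = dc_tot * f
    return dx, dh_prev, dc_prev, da, x, h_prev


def _attend(params: ModelParams, s: np.ndarray, latents: np.ndarray,
            K: np.ndarray, mask: np.ndarray):
    """Content-based attention: energies between the projected decoder state
    and projected latent features; softmax over valid source positions."""
    A = K.shape[2]
    q = s @ params.arrays["att_Wq"]
    e = np.einsum("bta,ba->bt", K, q) / np.sqrt(A)
    e = np.where(mask > 0, e, -1e30)
    alpha = _softmax(e, axis=1)
    ctx = np.einsum("bt,btj->bj", alpha, latents)
    return q, alpha, ctx


# ---------------------------------------------------------------------------
# Teacher-forced loss and gradients
# ---------------------------------------------------------------------------

def loss_and_grads(params: ModelParams, X: np.ndarray, Mx: np.ndarray,
                   Yin: np.ndarray, Yout: np.ndarray, My: np.ndarray,
                   want_grads: bool = True):
    """Token-level negative log-likelihood of the target sentences under
    teacher forcing, averaged over valid target tokens, and its gradients.

    X/Yin/Yout: int id matrices (B,Tx)/(B,Ty); Mx/My: binary masks.
    """
    p = params.arrays
    cfg = params.config
    H = cfg.hidden_size
    B, Ty = Yin.shape
    dtype = p["emb"].dtype
    Mx = np.asarray(Mx, dtype=dtype)
    My = np.asarray(My, dtype=dtype)

    latents, enc_inputs, enc_caches, enc_finals = _encoder_forward(params, X, Mx)
    state, bridge_caches = _bridge_forward(params, enc_finals)
    K = latents @ p["att_Wk"]

    emb_y = p["emb"][Yin]
    step_caches = []
    n_valid = My.sum()
    loss = 0.0
    dlogits_steps = [] if want_grads else None
    L = cfg.decoder_layers
    for t in range(Ty):
        x = emb_y[:, t]
        layer_caches = []
        new_state = []
        for l in range(L):
            h_prev, c_prev = state[l]
            h_new, c_new, cache = _dec_lstm_step(
                x, h_prev, c_prev, p[f"dec_l{l}_Wx"], p[f"dec_l{l}_Wh"], p[f"dec_l{l}_b"])
            layer_caches.append(cache)
            new_state.append((h_new, c_new))
            x = h_new
        s = x
        q, alpha, ctx = _attend(params, s, latents, K, Mx)
        feat = np.concatenate([s, ctx], axis=1)
        logits = feat @ p["out_W"] + p["out_b"]
        logp = logits - np.log(np.exp(logits - logits.max(1, keepdims=True)).sum(1, keepdims=True)) - logits.max(1, keepdims=True)
        tgt = Yout[:, t]
        loss -= (logp[np.arange(B), tgt] * My[:, t]).sum()
        if want_grads:
            soft = np.exp(logp)
            dlog = soft
            dlog[np.arange(B), tgt] -= 1.0
            dlog *= (My[:, t] / n_valid)[:, None]
            dlogits_steps.append(dlog)
        step_caches.append((layer_caches, q, alpha, ctx, feat))
        state = new_state
    loss = float(loss / n_valid)
    if not want_grads:
        return loss, None

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    A = K.shape[2]
    dlatents = np.zeros_like(latents)
    dK = np.zeros_like(K)
    dh_l = [np.zeros((B, H), dtype=dtype) for _ in range(L)]
    dc_l = [np.zeros((B, H), dtype=dtype) for _ in range(L)]
    demb_y = np.zeros_like(emb_y)
    Wq = p["att_Wq"]
    for t in range(Ty - 1, -1, -1):
        layer_caches, q, alpha, ctx, feat = step_caches[t]
        dlog = dlogits_steps[t]
        grads["out_W"] += feat.T @ dlog
        grads["out_b"] += dlog.sum(axis=0)
        dfeat = dlog @ p["out_W"].T
        ds = dfeat[:, :H].copy()
        dctx = dfeat[:, H:]
        # attention backward
        dalpha = np.einsum("bj,btj->bt", dctx, latents)
        dlatents += alpha[:, :, None] * dctx[:, None, :]
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dq = np.einsum("bt,bta->ba", de, K) / np.sqrt(A)
        dK += de[:, :, None] * q[:, None, :] / np.sqrt(A)
        s_vec = feat[:, :H]
        grads["att_Wq"] += s_vec.T @ dq
        ds += dq @ Wq.T
        # decoder layers, top to bottom
        dx_up = ds
        for l in range(L - 1, -1, -1):
            dh = dh_l[l] + dx_up
            dx, dh_prev, dc_prev, da, x_in, h_prev = _dec_step_back(
                layer_caches[l], dh, dc_l[l], p[f"dec_l{l}_Wx"], p[f"dec_l{l}_Wh"])
            grads[f"dec_l{l}_Wx"] += x_in.T @ da
            grads[f"dec_l{l}_Wh"] += h_prev.T @ da
            grads[f"dec_l{l}_b"] += da.sum(axis=0)
            dh_l[l] = dh_prev
            dc_l[l] = dc_prev
            dx_up = dx
        demb_y[:, t] = dx_up

    # bridge backward: dh_l/dc_l now hold grads w.r.t. the decoder init states
    denc_final_h = [[np.zeros((B, H), dtype=dtype), np.zeros((B, H), dtype=dtype)]
                    for _ in range(cfg.encoder_layers)]
    for l in range(L):
        ef, h0, c0 = bridge_caches[l]
        dh0 = dh_l[l] * (1.0 - h0 * h0)
        dc0 = dc_l[l] * (1.0 - c0 * c0)
        grads[f"bridge_l{l}_Wh"] += ef.T @ dh0
        grads[f"bridge_l{l}_bh"] += dh0.sum(axis=0)
        grads[f"bridge_l{l}_Wc"] += ef.T @ dc0
        grads[f"bridge_l{l}_bc"] += dc0.sum(axis=0)
        def_ = dh0 @ p[f"bridge_l{l}_Wh"].T + dc0 @ p[f"bridge_l{l}_Wc"].T
        src = min(l, cfg.encoder_layers - 1)
        denc_final_h[src][0] += def_[:, :H]
        denc_final_h[src][1] += def_[:, H:]

    # encoder backward
    grads["att_Wk"] += np.einsum("btj,bta->ja", latents, dK)
    dlatents += dK @ p["att_Wk"].T
    d_out = dlatents
    zero = np.zeros((B, H), dtype=dtype)
    for l in range(cfg.encoder_layers - 1, -1, -1):
        cf, cb = enc_caches[l]
        x_in = enc_inputs[l]
        dhTf, dhTb = denc_final_h[l]
        dxf, dWxf, dWhf, dbf = _lstm_backward(
            d_out[:, :, :H], dhTf, zero, x_in, Mx,
            p[f"enc_l{l}_f_Wx"], p[f"enc_l{l}_f_Wh"], cf)
        dxb, dWxb, dWhb, dbb = _lstm_backward(
            d_out[:, :, H:], dhTb, zero, x_in, Mx,
            p[f"enc_l{l}_b_Wx"], p[f"enc_l{l}_b_Wh"], cb)
        grads[f"enc_l{l}_f_Wx"] += dWxf
        grads[f"enc_l{l}_f_Wh"] += dWhf
        grads[f"enc_l{l}_f_b"] += dbf
        grads[f"enc_l{l}_b_Wx"] += dWxb
        grads[f"enc_l{l}_b_Wh"] += dWhb
        grads[f"enc_l{l}_b_b"] += dbb
        d_out = dxf + dxb

    np.add.at(grads["emb"], X, d_out)
    np.add.at(grads["emb"], Yin, demb_y)
    return loss, grads


# ---------------------------------------------------------------------------
# Public encoding / decoding operations
# ---------------------------------------------------------------------------

@dataclass
class DecoderState:
    layers: list[tuple[np.ndarray, np.ndarray]]


def encode_sequence(params: ModelParams, ids: list[int] | np.ndarray) -> np.ndarray:
    """Latent features for one input sequence: one (2*hidden) vector per
    position.  Errors on empty input."""
    ids = np.asarray(ids, dtype=np.int64)
    if ids.ndim != 1 or ids.size == 0:
        raise ValueError("encode_sequence requires a non-empty 1-D id sequence")
    if ids.min() < 0 or ids.max() >= params.config.vocab_size:
        raise ValueError("token id out of range for model vocabulary")
    X = ids[None, :]
    mask = np.ones(X.shape, dtype=params.arrays["emb"].dtype)
    latents, _, _, _ = _encoder_forward(params, X, mask)
    return latents[0]


def init_decoder_state(params: ModelParams, ids: list[int] | np.ndarray):
    """Encode the input and bridge to the decoder's initial state.
    Returns (state, latents)."""
    ids = np.asarray(ids, dtype=np.int64)
    if ids.size == 0:
        raise ValueError("empty input")
    X = ids[None, :]
    mask = np.ones(X.shape, dtype=params.arrays["emb"].dtype)
    latents, _, _, finals = _encoder_forward(params, X, mask)
    state, _ = _bridge_forward(params, finals)
    return DecoderState(layers=state), latents[0]


def decode_step(params: ModelParams, state: DecoderState, prev_id: int,
                latents: np.ndarray):
    """One autoregressive step: consume the previously generated token,
    attend over the latent features, and return (probability distribution
    over the vocabulary, next state, attention weights)."""
    p = params.arrays
    lat = latents[None, :, :]
    K = lat @ p["att_Wk"]
    mask = np.ones((1, lat.shape[1]), dtype=lat.dtype)
    x = p["emb"][np.array([prev_id])]
    new_layers = []
    for l, (h_prev, c_prev) in enumerate(state.layers):
        h_new, c_new, _ = _dec_lstm_step(
            x, h_prev, c_prev, p[f"dec_l{l}_Wx"], p[f"dec_l{l}_Wh"], p[f"dec_l{l}_b"])
        new_layers.append((h_new, c_new))
        x = h_new
    s = x
    _, alpha, ctx = _attend(params, s, lat, K, mask)
    feat = np.concatenate([s, ctx], axis=1)
    logits = feat @ p["out_W"] + p["out_b"]
    probs = _softmax(logits, axis=1)[0]
    return probs, DecoderState(layers=new_layers), alpha[0]


def generate_sentence(params: ModelParams, input_ids: list[int],
                      mode: str = "greedy", beam_width: int = 4) -> list[int]:
    """Autoregressive generation from begin-of-sentence, terminating at
    end-of-sentence or ``max_decode_length`` tokens.  Returns the generated
    ids without the begin/end markers.  Greedy decoding is deterministic;
    ``mode="beam"`` runs a small beam search scored by mean log-probability.
    """
    cfg = params.config
    bos, eos = 2, 3  # special-token layout is fixed by the tokenizer config
    state, latents = init_decoder_state(params, input_ids)
    if mode == "greedy":
        out: list[int] = []
        prev = bos
        for _ in range(cfg.max_decode_length):
            probs, state, _ = decode_step(params, state, prev, latents)
            nxt = int(np.argmax(probs))
            if nxt == eos:
                break
            out.append(nxt)
            prev = nxt
        return out
    if mode != "beam":
        raise ValueError(f"unknown decoding mode {mode!r}")
    beams = [([], 0.0, state, False)]
    for _ in range(cfg.max_decode_length):
        if all(done for _, _, _, done in beams):
            break
        expanded = []
        for ids, score, st, done in beams:
            if done:
                expanded.append((ids, score, st, True))
                continue
            prev = ids[-1] if ids else bos
            probs, new_st, _ = decode_step(params, st, prev, latents)
            logp = np.log(probs + 1e-300)
            for tok in np.argsort(-logp)[:beam_width]:
                tok = int(tok)
                if tok == eos:
                    expanded.append((ids, score + logp[tok], new_st, True))
                else:
                    expanded.append((ids + [tok], score + logp[tok], new_st, False))
        expanded.sort(key=lambda b: -(b[1] / max(1, len(b[0]) + 1)))
        beams = expanded[:beam_width]
    best = max(beams, key=lambda b: b[1] / max(1, len(b[0]) + 1))
    return best[0]


def generate_report(params: ModelParams, vocab: SubwordVocabulary,
                    keyword_groups: list[list[str]], mode: str = "greedy",
                    beam_width: int = 4) -> Report:
    """Generate a report from dictated keyword groups: sentence i is generated
    from group i with the previously *generated* sentence as context (the
    report-start placeholder for the first)."""
    from .corpus_io import REPORT_START

    check_vocab_compatible(params.config, vocab)
    if not keyword_groups:
        raise ValueError("no keyword groups")
    for i, group in enumerate(keyword_groups):
        if not group:
            raise ValueError(f"keyword group {i} is empty")
    sentences: list[Sentence] = []
    prev = REPORT_START
    for group in keyword_groups:
        ids = assemble_pattern_input(vocab, group, prev)
        out = generate_sentence(params, ids, mode=mode, beam_width=beam_width)
        text = sp_decode(vocab, out) or EMPTY_SENTENCE
        sentences.append(Sentence(text=text, keywords=list(group)))
        prev = text
    return Report(report_id="generated", sentences=sentences)
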
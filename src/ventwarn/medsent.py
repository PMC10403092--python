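"""Medication-history sentences, GloVe embeddings, and the CNN extractor.

The second medication-feature strategy treats a patient's medication record
as natural language: the ordered stream of (medication, action) events in a
window becomes a "sentence" ("med_a given med_b given med_a rate_changed
..."), word vectors are learned from within-sentence co-occurrence with the
GloVe weighted least-squares objective, and a small 1-D convolutional
sentence classifier (Kim-style: parallel filters of a few token lengths,
ReLU, global max-pooling, dropout, softmax) is trained to predict the MV
outcome.  The pooled penultimate layer — 5 filters x 3 lengths = 15 numbers
by default — is then frozen and used as ``medhist1..medhist15`` features by
the downstream risk model.

Both the embedding trainer and the CNN (forward and backward passes) are
implemented in numpy: the vocabularies are tiny, sentences are short, and a
deterministic, dependency-free implementation keeps the extractor exactly
reproducible for a given seed.

Training corpus vs feature extraction (an intentional asymmetry): the
classifier trains on one sentence per encounter covering the full history
(up to the MV-preparation time for cases, the whole stay for controls),
while at scoring time each grid point uses only the trailing 6-hour window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SENTINEL = "<no_meds>"
PAD = "<pad>"
ACTION_TOKENS = {"given": "given", "rate changed": "rate_changed", "stopped": "stopped"}
MED_WINDOW_MINUTES = 360


def normalize_name(name: str) -> str:
    return str(name).strip().lower().replace(" ", "_")


# ---------------------------------------------------------------------------
# sentences
# ---------------------------------------------------------------------------

def _sentence_from_events(med_frame: pd.DataFrame) -> list:
    """Tokenize an event frame (already windowed) into ``med action`` pairs."""
    if len(med_frame) == 0:
        return [SENTINEL]
    frame = med_frame.sort_values(["time", "sequence_no"], kind="mergesort")
    tokens = []
    for med, act in zip(frame["medication"], frame["action"]):
        if act not in ACTION_TOKENS:
            raise ValueError(f"unknown medication action {act!r}")
        tokens.append(normalize_name(med))
        tokens.append(ACTION_TOKENS[act])
    return tokens


def build_sentence(
    medications: pd.DataFrame,
    encounter_id,
    t: float,
    window_minutes: float = MED_WINDOW_MINUTES,
) -> list:
    """Sentence for the half-open trailing window ``(t - w, t]``.

    Events are ordered by (time, sequence_no); an empty window yields the
    single sentinel token.
    """
    sub = medications[
        (medications["encounter_id"] == encounter_id)
        & (medications["time"] > t - window_minutes)
        & (medications["time"] <= t)
    ]
    return _sentence_from_events(sub)


def build_training_corpus(medications: pd.DataFrame, encounters: pd.DataFrame):
    """One full-history sentence per encounter, labeled with the MV outcome.

    MV cases contribute their history up to the MV-preparation time (onset
    minus 30 min); controls contribute the entire stay.  Call with the
    training split only.
    """
    sentences, labels = [], []
    meds_by_enc = {k: v for k, v in medications.groupby("encounter_id")}
    for row in encounters.itertuples(index=False):
        if bool(row.mv_flag):
            cutoff = float(row.mv_onset_time) - 30.0
        else:
            cutoff = float(row.discharge_time)
        sub = meds_by_enc.get(row.encounter_id)
        if sub is None:
            sentences.append([SENTINEL])
        else:
            sentences.append(_sentence_from_events(sub[sub["time"] <= cutoff]))
        labels.append(int(bool(row.mv_flag)))
    return sentences, np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# GloVe embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingModel:
    vocab: list
    vectors: np.ndarray  # (V, dim)
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {tok: i for i, tok in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def token_index(self, token: str) -> int:
        """Index for a token; out-of-vocabulary maps to the sentinel."""
        return self.index.get(token, self.index[SENTINEL])

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.token_index(token)]


def cooccurrence_counts(sentences, vocab_index, window: int = 25):
    """Symmetric within-sentence co-occurrence, weighted 1/distance.

    Returns a dict ``(i, j) -> x_ij`` over ordered index pairs (both
    directions present by symmetry of the window).
    """
    counts: dict = {}
    for sent in sentences:
        idx = [vocab_index[t] for t in sent if t in vocab_index]
        n = len(idx)
        for a in range(n):
            for b in range(a + 1, min(a + window + 1, n)):
                w = 1.0 / (b - a)
                i, j = idx[a], idx[b]
                counts[(i, j)] = counts.get((i, j), 0.0) + w
                counts[(j, i)] = counts.get((j, i), 0.0) + w
    return counts


def fit_embeddings(
    corpus,
    window: int = 25,
    dim: int = 10,
    epochs: int = 30,
    seed: int = 0,
    x_max: float = 10.0,
    alpha: float = 0.75,
    learning_rate: float = 0.05,
) -> EmbeddingModel:
    """Train GloVe vectors on the corpus with AdaGrad.

    Minimizes sum f(x_ij) (w_i . u_j + b_i + c_j - log x_ij)^2 with the
    standard saturating weight f(x) = min(1, (x / x_max)^alpha).  The final
    vector for each token is w + u; sentinel and pad tokens are part of the
    vocabulary.
    """
    if not corpus:
        raise ValueError("empty corpus")
    tokens = sorted({t for s in corpus for t in s} | {SENTINEL, PAD})
    if len(tokens) < 2:
        raise ValueError("vocabulary must contain at least 2 tokens")
    index = {t: i for i, t in enumerate(tokens)}
    counts = cooccurrence_counts(corpus, index, window)
    V = len(tokens)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-0.5, 0.5, (V, dim)) / dim
    U = rng.uniform(-0.5, 0.5, (V, dim)) / dim
    b = np.zeros(V)
    c = np.zeros(V)
    gW = np.ones_like(W)
    gU = np.ones_like(U)
    gb = np.ones(V)
    gc = np.ones(V)

    if counts:
        ii = np.fromiter((k[0] for k in counts), int, len(counts))
        jj = np.fromiter((k[1] for k in counts), int, len(counts))
        xx = np.fromiter(counts.values(), float, len(counts))
        fw = np.minimum(1.0, (xx / x_max) ** alpha)
        logx = np.log(xx)
        order = np.arange(len(xx))
        for _ in range(epochs):
            rng.shuffle(order)
            for k in order:
                i, j = ii[k], jj[k]
                diff = W[i] @ U[j] + b[i] + c[j] - logx[k]
                g = fw[k] * diff
                dw, du = g * U[j], g * W[i]
                gW[i] += dw * dw
                gU[j] += du * du
                W[i] -= learning_rate * dw / np.sqrt(gW[i])
                U[j] -= learning_rate * du / np.sqrt(gU[j])
                gb[i] += g * g
                gc[j] += g * g
                b[i] -= learning_rate * g / np.sqrt(gb[i])
                c[j] -= learning_rate * g / np.sqrt(gc[j])

    return EmbeddingModel(vocab=tokens, vectors=W + U)


# ---------------------------------------------------------------------------
# convolutional extractor
# ---------------------------------------------------------------------------

@dataclass
class ConvExtractorConfig:
    filter_lengths: tuple = (4, 5, 6)
    filters_per_length: int = 5
    dropout_rate: float = 0.5
    max_sentence_tokens: int = 512
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 5e-3
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.filters_per_length < 1 or not self.filter_lengths:
            raise ValueError("need at least one filter")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def feature_dim(self) -> int:
        return self.filters_per_length * len(self.filter_lengths)


class ConvExtractor:
    """Kim-style 1-D convolutional sentence classifier over frozen embeddings.

    Architecture: frozen embedding lookup -> parallel 1-D convolutions of
    token lengths ``filter_lengths`` (``filters_per_length`` each, filter
    width = embedding dim) -> ReLU -> global max-pool -> dropout -> dense
    softmax over {no-MV, MV}.  ``features()`` returns the pooled penultimate
    activations with dropout disabled.
    """

    def __init__(self, config: ConvExtractorConfig, embeddings: EmbeddingModel):
        self.config = config
        self.embeddings = embeddings
        d = embeddings.dim
        rng = np.random.default_rng(config.seed)
        self.filters = {}
        self.biases = {}
        for L in config.filter_lengths:
            scale = math.sqrt(2.0 / (L * d))
            self.filters[L] = rng.normal(0.0, scale, (config.filters_per_length, L, d))
            self.biases[L] = np.zeros(config.filters_per_length)
        F = config.feature_dim
        self.W_out = rng.normal(0.0, math.sqrt(2.0 / F), (F, 2))
        self.b_out = np.zeros(2)
        self.cv_scores_: list = []

    # -- encoding -----------------------------------------------------------

    def encode(self, sentences) -> np.ndarray:
        """Token-index matrix (B, T): head-truncated to the most recent
        ``max_sentence_tokens`` tokens, right-padded, min length = longest
        filter."""
        cap = self.config.max_sentence_tokens
        idxs = [
            [self.embeddings.token_index(t) for t in s[-cap:]] for s in sentences
        ]
        T = max(max((len(s) for s in idxs), default=1), max(self.config.filter_lengths))
        pad = self.embeddings.index[PAD]
        out = np.full((len(idxs), T), pad, dtype=np.int32)
        for r, s in enumerate(idxs):
            out[r, : len(s)] = s
        return out

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train_mask=None):
        E = self.embeddings.vectors[X]  # (B, T, d)
        pad_idx = self.embeddings.index[PAD]
        lengths = (X != pad_idx).sum(axis=1)  # true token counts
        pooled, caches = [], []
        for L in self.config.filter_lengths:
            sw = np.lib.stride_tricks.sliding_window_view(E, L, axis=1)  # (B,P,d,L)
            conv = np.einsum("bpdl,fld->bpf", sw, self.filters[L]) + self.biases[L]
            # global max-pool over windows that start inside the real
            # sentence (window 0 always valid so short sentences still pool
            # something); the pooled max is itself the nonlinearity, which
            # keeps gradients alive for every filter
            n_valid = np.maximum(lengths - L + 1, 1)  # (B,)
            pos = np.arange(conv.shape[1])
            invalid = pos[None, :] >= n_valid[:, None]
            act = np.where(invalid[:, :, None], -np.inf, conv)
            arg = act.argmax(axis=1)  # (B, F)
            mx = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
            pooled.append(mx)
            caches.append((sw, conv, arg))
        h = np.concatenate(pooled, axis=1)  # (B, F_total)
        h_used = h * train_mask if train_mask is not None else h
        logits = h_used @ self.W_out + self.b_out
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return h, h_used, p, caches

    def _step(self, X, y, rng, lr, adam_state, t_step):
        B = X.shape[0]
        keep = 1.0 - self.config.dropout_rate
        mask = (rng.random((B, self.config.feature_dim)) < keep) / keep
        h, h_used, p, caches = self._forward(X, train_mask=mask)
        dlogits = p.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {
            "W_out": h_used.T @ dlogits,
            "b_out": dlogits.sum(axis=0),
        }
        dh = (dlogits @ self.W_out.T) * mask
        off = 0
        F = self.config.filters_per_length
        for (L, (sw, conv, arg)) in zip(self.config.filter_lengths, caches):
            dpool = dh[:, off : off + F]  # (B, F)
            off += F
            picked = sw[np.arange(B)[:, None], arg, :, :]  # (B, F, d, L)
            grads[f"W_{L}"] = np.einsum("bf,bfdl->fld", dpool, picked)
            grads[f"b_{L}"] = dpool.sum(axis=0)
        self._adam_update(grads, adam_state, lr, t_step)
        loss = -np.log(p[np.arange(B), y] + 1e-12).mean()
        return loss

    def _params(self):
        out = {"W_out": self.W_out, "b_out": self.b_out}
        for L in self.config.filter_lengths:
            out[f"W_{L}"] = self.filters[L]
            out[f"b_{L}"] = self.biases[L]
        return out

    def _adam_update(self, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self._params()
        for k, g in grads.items():
            m, v = state[k]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            params[k] -= lr * mh / (np.sqrt(vh) + eps)

    # -- training -----------------------------------------------------------

    def fit(self, sentences, labels, rng=None):
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        rng = rng or np.random.default_rng(self.config.seed)
        X = self.encode(sentences)
        n = X.shape[0]
        state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self._params().items()}
        t_step = 0
        for _ in range(self.config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                t_step += 1
                self._step(X[idx], y[idx], rng, self.config.learning_rate, state, t_step)
        return self

    def predict_proba(self, sentences) -> np.ndarray:
        X = self.encode(sentences)
        out = np.empty((X.shape[0], 2))
        for start in range(0, X.shape[0], 512):
            _, _, p, _ = self._forward(X[start : start + 512])
            out[start : start + 512] = p
        return out

    def features(self, sentences) -> np.ndarray:
        """Penultimate-layer (pooled) activations; dropout disabled."""
        X = self.encode(sentences)
        out = np.empty((X.shape[0], self.config.feature_dim))
        for start in range(0, X.shape[0], 512):
            h, _, _, _ = self._forward(X[start : start + 512])
            out[start : start + 512] = h
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": dataclass_dict(self.config),
            "vocab": self.embeddings.vocab,
        }
        arrays = {
            "vectors": self.embeddings.vectors,
            "W_out": self.W_out,
            "b_out": self.b_out,
        }
        for L in self.config.filter_lengths:
            arrays[f"W_{L}"] = self.filters[L]
            arrays[f"b_{L}"] = self.biases[L]
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ConvExtractor":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = ConvExtractorConfig(**{
            **meta["config"],
            "filter_lengths": tuple(meta["config"]["filter_lengths"]),
        })
        emb = EmbeddingModel(vocab=list(meta["vocab"]), vectors=data["vectors"])
        obj = cls(cfg, emb)
        obj.W_out = data["W_out"]
        obj.b_out = data["b_out"]
        for L in cfg.filter_lengths:
            obj.filters[L] = data[f"W_{L}"]
            obj.biases[L] = data[f"b_{L}"]
        return obj


def dataclass_dict(cfg) -> dict:
    import dataclasses

    d = dataclasses.asdict(cfg)
    d["filter_lengths"] = list(d["filter_lengths"])
    return d


def _auroc(y, score) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, score))


def train_extractor(
    sentences,
    labels,
    config: ConvExtractorConfig,
    embeddings: EmbeddingModel,
    run_cv: bool = True,
) -> ConvExtractor:
    """Cross-validate the sentence classifier, then refit on all sentences.

    Stratified ``config.folds``-fold CV records held-out AUROC per fold
    (``cv_scores_`` on the returned extractor) as a sanity check on the
    architecture; the deployed extractor is refit on the full training
    corpus with frozen embeddings and its pooled penultimate layer is the
    ``medhist`` feature map.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    cv_scores = []
    if run_cv and config.folds >= 2:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            model = ConvExtractor(config, embeddings)
            model.fit(
                [sentences[i] for i in tr], y[tr],
                rng=np.random.default_rng(config.seed * 1000 + f),
            )
            p = model.predict_proba([sentences[i] for i in te])[:, 1]
            cv_scores.append(_auroc(y[te], p))
    final = ConvExtractor(config, embeddings)
    final.fit(sentences, y, rng=np.random.default_rng(config.seed))
    final.cv_scores_ = cv_scores
    return final


def extract_medhist(extractor: ConvExtractor, sentences) -> pd.DataFrame:
    """``medhist1..medhistF`` features for a list of sentences."""
    feats = extractor.features(sentences)
    cols = [f"medhist{i + 1}" for i in range(feats.shape[1])]
    return pd.DataFrame(feats, columns=cols)


def medhist_grid_features(
    extractor: ConvExtractor,
    medications: pd.DataFrame,
    grid: pd.DataFrame,
    window_minutes: float = MED_WINDOW_MINUTES,
) -> pd.DataFrame:
    """medhist features for every (encounter, time) grid row.

    The trailing-window sentence only changes when an event enters or leaves
    the window, so sentences are computed once per distinct window per
    encounter and broadcast to the grid rows that share it.
    """
    meds_by_enc = {k: v.sort_values(["time", "sequence_no"], kind="mergesort")
                   for k, v in medications.groupby("encounter_id")}
    enc_ids = grid["encounter_id"].to_numpy()
    gtimes = grid["time"].to_numpy(float)

    sentences = []
    row_to_sentence = np.zeros(len(grid), dtype=np.int64)
    from .features import _group_bounds

    bounds = _group_bounds(enc_ids)
    for eid, (a, b) in bounds.items():
        sub = meds_by_enc.get(eid)
        t_slice = gtimes[a:b]
        if sub is None or len(sub) == 0:
            sentences.append([SENTINEL])
            row_to_sentence[a:b] = len(sentences) - 1
            continue
        ev_times = sub["time"].to_numpy(float)
        # window content changes at event times and event times + window
        breaks = np.unique(np.concatenate([ev_times, ev_times + window_minutes]))
        seg = np.searchsorted(breaks, t_slice, side="left")
        # distinct segments present on this encounter's grid
        seg_ids, seg_inverse = np.unique(seg, return_inverse=True)
        base = len(sentences)
        for s in seg_ids:
            t_rep = t_slice[seg == s][0]
            lo = np.searchsorted(ev_times, t_rep - window_minutes, side="right")
            hi = np.searchsorted(ev_times, t_rep, side="right")
            sentences.append(_sentence_from_events(sub.iloc[lo:hi]))
        row_to_sentence[a:b] = base + seg_inverse

    feats = extractor.features(sentences)
    cols = [f"medhist{i + 1}" for i in range(feats.shape[1])]
    return pd.DataFrame(
        feats[row_to_sentence].astype(np.float32), columns=cols, index=grid.index
    )
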
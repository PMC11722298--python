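"""Two-head sequence network, training loop, and call decision logic.

The pileup network runs the 33-position feature sequence through two
bidirectional LSTM layers and three fully connected stages, ending in
two probabilistic heads: a 21-class genotype head (unordered allele
pairs over {A,C,G,T,Ins,Del}) and a 3-class zygosity head (hom-ref /
het / hom-var). Training uses focal loss, a Rectified Adam optimizer
with a short learning-rate warm-up, an exponentially decaying learning
rate, a 90/10 train/validation split, and early stopping on validation
loss (at most 30 epochs, patience 5); the best-validation epoch's
weights are kept.

Implemented directly in NumPy (forward and backward passes are written
out), which keeps the package dependency-light and the training
fully deterministic under a seed on one CPU.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .candidates import CandidateSite, SitePileup, scan_candidates
from .formats import AlignedRead, VariantCall
from .labels import (
    GENOTYPE21_PAIRS,
    N_GENOTYPE_CLASSES,
    N_ZYGOSITY_CLASSES,
    TrainingExample,
)
from .tensors import (
    CoverageCap,
    build_pileup_tensor,
    normalize_tensor,
)

log = logging.getLogger("rnacall")

#: platform-specific LowQual thresholds
QUAL_THRESHOLDS = {"pacbio": 2.0, "ont": 8.0}
MAX_QUAL = 60.0


@dataclass
class NetworkConfig:
    input_features: int = 18  # 30 with phasing
    hidden_size: int = 64
    dense_sizes: tuple[int, int] = (128, 64)
    focal_gamma: float = 2.0
    learning_rate: float = 2e-2
    lr_decay: float = 0.95  # per epoch, exponential
    warmup_epochs: int = 1
    batch_size: int = 32
    max_epochs: int = 30
    early_stop_patience: int = 5
    window: int = 33

    n_genotype: int = N_GENOTYPE_CLASSES
    n_zygosity: int = N_ZYGOSITY_CLASSES


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# LSTM primitives
# ---------------------------------------------------------------------------

def _lstm_forward(x, Wx, Wh, b):
    """Single-direction LSTM over (B, T, D) input; returns (B, T, H)."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        cache.append((x[:, t], h, c, i, f, g, o, tc))
        h = o * tc
        c = c_new
        hs[:, t] = h
    return hs, cache


def _lstm_backward(dhs, cache, Wx, Wh):
    B, T, H = dhs.shape
    D = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dx, dWx, dWh, db


def _bilstm_forward(x, params, prefix):
    hs_f, cache_f = _lstm_forward(
        x, params[prefix + "Wx_f"], params[prefix + "Wh_f"], params[prefix + "b_f"]
    )
    hs_b, cache_b = _lstm_forward(
        x[:, ::-1],
        params[prefix + "Wx_b"], params[prefix + "Wh_b"], params[prefix + "b_b"],
    )
    out = np.concatenate([hs_f, hs_b[:, ::-1]], axis=2)
    return out, (cache_f, cache_b)


def _bilstm_backward(dout, caches, params, prefix, grads):
    H = params[prefix + "Wh_f"].shape[0]
    cache_f, cache_b = caches
    dx_f, dWx, dWh, db = _lstm_backward(
        dout[:, :, :H], cache_f, params[prefix + "Wx_f"], params[prefix + "Wh_f"]
    )
    grads[prefix + "Wx_f"] = dWx
    grads[prefix + "Wh_f"] = dWh
    grads[prefix + "b_f"] = db
    dx_b, dWx, dWh, db = _lstm_backward(
        dout[:, ::-1, H:], cache_b,
        params[prefix + "Wx_b"], params[prefix + "Wh_b"],
    )
    grads[prefix + "Wx_b"] = dWx
    grads[prefix + "Wh_b"] = dWh
    grads[prefix + "b_b"] = db
    return dx_f + dx_b[:, ::-1]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class PileupNetwork:
    """Bi-LSTM x2 -> flatten -> dense x2 (ReLU) -> two softmax heads."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        H = config.hidden_size
        F = config.input_features
        T = config.window

        def glorot(shape):
            limit = math.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-limit, limit, size=shape)

        for layer, d_in in (("l1_", F), ("l2_", 2 * H)):
            for d in ("f", "b"):
                self.params[layer + "Wx_" + d] = glorot((d_in, 4 * H))
                self.params[layer + "Wh_" + d] = glorot((H, 4 * H))
                bias = np.zeros(4 * H)
                bias[H : 2 * H] = 1.0  # forget-gate bias
                self.params[layer + "b_" + d] = bias
        d1, d2 = config.dense_sizes
        flat = T * 2 * H
        self.params["d1_W"] = glorot((flat, d1))
        self.params["d1_b"] = np.zeros(d1)
        self.params["d2_W"] = glorot((d1, d2))
        self.params["d2_b"] = np.zeros(d2)
        self.params["hg_W"] = glorot((d2, config.n_genotype))
        self.params["hg_b"] = np.zeros(config.n_genotype)
        self.params["hz_W"] = glorot((d2, config.n_zygosity))
        self.params["hz_b"] = np.zeros(config.n_zygosity)

    # -- forward / backward -------------------------------------------------

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """Compress counts with log1p; keeps allele ratios visible while
        taming the heavy-tailed coverage scale."""
        if x.shape[-1] != self.config.input_features:
            raise ValueError(
                f"expected input (*, {self.config.window}, "
                f"{self.config.input_features}), got {x.shape}"
            )
        return np.log1p(x)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        if x.ndim != 3 or x.shape[2] != self.config.input_features:
            raise ValueError(
                f"expected input (*, {self.config.window}, "
                f"{self.config.input_features}), got {x.shape}"
            )
        p = self.params
        h1, cache1 = _bilstm_forward(x, p, "l1_")
        h2, cache2 = _bilstm_forward(h1, p, "l2_")
        B = x.shape[0]
        flat = h2.reshape(B, -1)
        a1 = flat @ p["d1_W"] + p["d1_b"]
        r1 = np.maximum(a1, 0)
        a2 = r1 @ p["d2_W"] + p["d2_b"]
        r2 = np.maximum(a2, 0)
        zg = r2 @ p["hg_W"] + p["hg_b"]
        zz = r2 @ p["hz_W"] + p["hz_b"]
        pg = _softmax(zg)
        pz = _softmax(zz)
        if not want_cache:
            return pg, pz
        cache = (cache1, cache2, h2.shape, flat, a1, r1, a2, r2)
        return pg, pz, cache

    def backward(self, dzg, dzz, cache) -> dict[str, np.ndarray]:
        p = self.params
        cache1, cache2, h2_shape, flat, a1, r1, a2, r2 = cache
        grads: dict[str, np.ndarray] = {}
        grads["hg_W"] = r2.T @ dzg
        grads["hg_b"] = dzg.sum(axis=0)
        grads["hz_W"] = r2.T @ dzz
        grads["hz_b"] = dzz.sum(axis=0)
        dr2 = dzg @ p["hg_W"].T + dzz @ p["hz_W"].T
        da2 = dr2 * (a2 > 0)
        grads["d2_W"] = r1.T @ da2
        grads["d2_b"] = da2.sum(axis=0)
        dr1 = da2 @ p["d2_W"].T
        da1 = dr1 * (a1 > 0)
        grads["d1_W"] = flat.T @ da1
        grads["d1_b"] = da1.sum(axis=0)
        dflat = da1 @ p["d1_W"].T
        dh2 = dflat.reshape(h2_shape)
        dh1 = _bilstm_backward(dh2, cache2, p, "l2_", grads)
        _bilstm_backward(dh1, cache1, p, "l1_", grads)
        return grads


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

_P_FLOOR = 1e-12


def focal_loss(
    probabilities: np.ndarray,
    one_hot_label: np.ndarray,
    gamma: float = 2.0,
    class_weights: Optional[np.ndarray] = None,
) -> float:
    """Focal loss -sum_c w_c (1 - p_c)^gamma y_c log p_c.

    At gamma = 0 with uniform weights this is ordinary cross-entropy.
    Down-weights well-classified examples, which matters here because
    hom-ref artifacts vastly outnumber true variants.
    """
    p = np.clip(np.asarray(probabilities, dtype=float), _P_FLOOR, 1.0)
    y = np.asarray(one_hot_label, dtype=float)
    w = np.ones(p.shape[-1]) if class_weights is None else np.asarray(class_weights)
    terms = -w * (1 - p) ** gamma * y * np.log(p)
    return float(terms.sum(axis=-1).mean()) if p.ndim > 1 else float(terms.sum())


def _focal_dlogits(p, labels, gamma, weights=None):
    """Gradient of mean focal loss w.r.t. softmax logits.

    With p_t the true-class probability, dL/dp_t = -w[gamma (1-p_t)^{g-1}
    (-log p_t) + (1-p_t)^g / p_t] and dL/dz = dL/dp_t * p_t (onehot - p).
    """
    B, C = p.shape
    pt = np.clip(p[np.arange(B), labels], _P_FLOOR, 1.0)
    w = 1.0 if weights is None else weights[labels]
    one_minus = 1.0 - pt
    dl_dpt = -w * (
        -gamma * np.where(one_minus > 0, one_minus ** (gamma - 1), 0.0)
        * np.log(pt)
        + one_minus ** gamma / pt
    )
    onehot = np.zeros_like(p)
    onehot[np.arange(B), labels] = 1.0
    dz = (dl_dpt * pt)[:, None] * (onehot - p)
    return dz / B


def _focal_batch_loss(p, labels, gamma, weights=None):
    B = p.shape[0]
    pt = np.clip(p[np.arange(B), labels], _P_FLOOR, 1.0)
    w = 1.0 if weights is None else weights[labels]
    return float(np.mean(-w * (1 - pt) ** gamma * np.log(pt)))


# ---------------------------------------------------------------------------
# Rectified Adam
# ---------------------------------------------------------------------------

class RAdam:
    """Rectified Adam: Adam with a variance-rectification term that
    behaves like un-adapted SGD-with-momentum during the first steps."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, params, grads, lr_scale=1.0, clip_norm=5.0):
        if clip_norm is not None:
            total = math.sqrt(
                sum(float((g * g).sum()) for g in grads.values())
            )
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        rho = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        if rho > 4.0:
            r = math.sqrt(
                ((rho - 4) * (rho - 2) * self.rho_inf)
                / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho)
            )
        else:
            r = None
        lr = self.lr * lr_scale
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = m / (1 - b1**t)
            if r is not None:
                v_hat = np.sqrt(v / (1 - b2**t)) + self.eps
                params[k] -= lr * r * m_hat / v_hat
            else:
                params[k] -= lr * m_hat


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingLog:
    epochs_run: int = 0
    best_epoch: int = -1
    best_val_loss: float = math.inf
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)


def _stack_examples(examples: Sequence[TrainingExample]):
    x = np.stack([np.asarray(ex.features, dtype=np.float64) for ex in examples])
    yg = np.array([ex.genotype21 for ex in examples], dtype=np.int64)
    yz = np.array([ex.zygosity for ex in examples], dtype=np.int64)
    return x, yg, yz



def train(
    examples: Sequence[TrainingExample],
    config: Optional[NetworkConfig] = None,
    seed: int = 0,
) -> tuple[PileupNetwork, TrainingLog]:
    """Train the two-head network; deterministic under seed.

    90% of the examples train, 10% validate; training stops after
    max_epochs or when validation loss has not improved for
    early_stop_patience consecutive epochs, and the best-validation
    epoch's weights are restored.
    """
    if len(examples) == 0:
        raise ValueError("empty example set")
    if config is None:
        config = NetworkConfig(
            input_features=np.asarray(examples[0].features).shape[1]
        )
    rng = np.random.default_rng(seed)
    x, yg, yz = _stack_examples(examples)
    n = len(x)
    perm = rng.permutation(n)
    n_val = max(1, n // 10) if n > 1 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm
    wg = wz = None  # focal loss itself handles the class imbalance

    net = PileupNetwork(config, seed=seed + 1)
    x = net.standardize(x)
    opt = RAdam(net.params, lr=config.learning_rate)
    tlog = TrainingLog()
    best_params: Optional[dict[str, np.ndarray]] = None
    stale = 0
    steps_per_epoch = max(1, math.ceil(len(train_idx) / config.batch_size))
    gamma = config.focal_gamma

    def epoch_lr_scale(epoch: int, step: int) -> float:
        decay = config.lr_decay**epoch
        if epoch < config.warmup_epochs:
            total = config.warmup_epochs * steps_per_epoch
            frac = (epoch * steps_per_epoch + step + 1) / total
            return decay * frac
        return decay

    def evaluate(idx) -> float:
        if len(idx) == 0:
            return math.nan
        loss = 0.0
        for s in range(0, len(idx), 256):
            sl = idx[s : s + 256]
            pg, pz = net.forward(x[sl])
            loss += (
                _focal_batch_loss(pg, yg[sl], gamma, wg)
                + _focal_batch_loss(pz, yz[sl], gamma, wz)
            ) * len(sl)
        return loss / len(idx)

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        ep_loss = 0.0
        for step in range(steps_per_epoch):
            sl = order[step * config.batch_size : (step + 1) * config.batch_size]
            if len(sl) == 0:
                continue
            pg, pz, cache = net.forward(x[sl], want_cache=True)
            dzg = _focal_dlogits(pg, yg[sl], gamma, wg)
            dzz = _focal_dlogits(pz, yz[sl], gamma, wz)
            grads = net.backward(dzg, dzz, cache)
            opt.step(net.params, grads, lr_scale=epoch_lr_scale(epoch, step))
            ep_loss += (
                _focal_batch_loss(pg, yg[sl], gamma, wg)
                + _focal_batch_loss(pz, yz[sl], gamma, wz)
            ) * len(sl)
        tlog.train_losses.append(ep_loss / max(len(train_idx), 1))
        val_loss = evaluate(val_idx)
        if math.isnan(val_loss):
            val_loss = tlog.train_losses[-1]
        tlog.val_losses.append(val_loss)
        tlog.epochs_run = epoch + 1
        if val_loss < tlog.best_val_loss - 1e-9:
            tlog.best_val_loss = val_loss
            tlog.best_epoch = epoch
            best_params = {k: v.copy() for k, v in net.params.items()}
        # early stop when the loss fails to decrease epoch-over-epoch
        # for patience consecutive epochs
        if epoch > 0 and val_loss >= tlog.val_losses[-2] - 1e-9:
            stale += 1
            if stale >= config.early_stop_patience:
                break
        else:
            stale = 0
    if best_params is not None:
        net.params = best_params
    log.info(
        "training done: %d epochs, best epoch %d, best val loss %.4f",
        tlog.epochs_run, tlog.best_epoch, tlog.best_val_loss,
    )
    return net, tlog


def predict(
    model: PileupNetwork, tensors: Sequence[np.ndarray], batch_size: int = 256
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Batched inference; returns (genotype21, zygosity) probability
    pairs in input order."""
    if len(tensors) == 0:
        return []
    x = model.standardize(
        np.stack([np.asarray(t, dtype=np.float64) for t in tensors])
    )
    out = []
    for s in range(0, len(x), batch_size):
        pg, pz = model.forward(x[s : s + batch_size])
        out.extend(zip(pg, pz))
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: PileupNetwork, path: str) -> None:
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config)}
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.params,
    )


def load_checkpoint(path: str) -> PileupNetwork:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = meta["config"]
        cfg["dense_sizes"] = tuple(cfg["dense_sizes"])
        config = NetworkConfig(**cfg)
        net = PileupNetwork(config)
        net.params = {k: z[k] for k in z.files if k != "__meta__"}
    return net


# ---------------------------------------------------------------------------
# Call decision
# ---------------------------------------------------------------------------

def _pair_zygosity(pair: tuple[str, str], ref_sym: str) -> int:
    a, b = pair
    if a == b:
        return 0 if a == ref_sym else 2
    return 1


def decide_call(
    probs: tuple[np.ndarray, np.ndarray],
    candidate_pileup: SitePileup,
    platform: str = "ont",
    ref_seq: Optional[str] = None,
    qual_threshold: Optional[float] = None,
) -> Optional[VariantCall]:
    """Turn head probabilities into a VCF record (or no call).

    The joint score of genotype class g is s(g) = P21(g) x Pzyg(z(g)),
    with z(g) the zygosity consistent with g given the reference
    allele. A hom-ref argmax emits nothing. QUAL is the phred-scaled
    joint confidence, -10 log10(1 - s), capped at 60; records below the
    platform threshold (QUAL < 2 PacBio, < 8 ONT) are tagged LowQual.
    Indel allele sequences come from the supporting reads: the most
    frequent insertion/deletion at the site, ties broken to shortest.
    """
    pg, pz = probs
    pile = candidate_pileup
    ref_base = pile.ref_base
    if ref_base not in "ACGT":
        return None
    # The maximization is restricted to genotype classes whose alleles
    # are the reference or have read support at the site: allele
    # identity (like indel length) comes from the supporting read
    # evidence, and the heads' mass on unsupported alleles is
    # renormalized away.
    ad = pile.AD
    allowed = {ref_base} | {a for a, n in ad.items() if n > 0}
    if not pile.ins_seqs:
        allowed.discard("I")
    if not pile.del_lens:
        allowed.discard("D")
    scores = np.array(
        [
            pg[i] * pz[_pair_zygosity(pair, ref_base)]
            if pair[0] in allowed and pair[1] in allowed
            else 0.0
            for i, pair in enumerate(GENOTYPE21_PAIRS)
        ]
    )
    best = int(scores.argmax())
    pair = GENOTYPE21_PAIRS[best]
    if _pair_zygosity(pair, ref_base) == 0 and pair[0] == ref_base:
        return None  # hom-ref
    # QUAL follows VCF semantics: phred-scaled probability that the
    # site carries no variant, i.e. the normalized joint mass of the
    # hom-ref genotype.
    total = max(float(scores.sum()), _P_FLOOR)
    p_hom_ref = float(
        scores[GENOTYPE21_PAIRS.index((ref_base, ref_base))]
    ) / total
    qual = min(-10.0 * math.log10(max(p_hom_ref, 1e-6)), MAX_QUAL)

    ad = pile.AD
    pos0 = pile.pos

    def resolve(sym: str) -> Optional[tuple[int, int, str]]:
        """-> (vcf_pos, ref_end, alt_string) in VCF representation.

        SNPs and insertions anchor at the candidate position itself; a
        deletion (counted at its first deleted base) re-anchors one
        base left, VCF-style.
        """
        if sym in "ACGT":
            return (pos0, pos0 + 1, sym) if ad.get(sym, 0) > 0 else None
        if sym == "I":
            if not pile.ins_seqs:
                return None
            seq = sorted(
                pile.ins_seqs.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
            )[0][0]
            return (pos0, pos0 + 1, ref_base + seq)
        if not pile.del_lens or pos0 == 0:
            return None
        ln = sorted(pile.del_lens.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        anchor = (
            ref_seq[pos0 - 1]
            if ref_seq is not None and pos0 - 1 < len(ref_seq)
            else "N"
        )
        return (pos0 - 1, pos0 + ln, anchor)

    def ref_slice(lo: int, hi: int) -> str:
        if ref_seq is not None and hi <= len(ref_seq):
            return ref_seq[lo:hi]
        filler = ref_base if hi - lo == 1 and lo == pos0 else None
        return filler if filler is not None else "N" * (hi - lo)

    alt_syms = [s_ for s_ in pair if s_ != ref_base]
    if not alt_syms:  # hom-ref handled above; defensive
        return None
    resolved = []
    for sym in dict.fromkeys(alt_syms):
        r = resolve(sym)
        if r is None:
            log.info(
                "no read support for called %s allele at %s:%d; no call",
                sym, pile.contig, pile.pos + 1,
            )
            return None
        resolved.append((sym, r))

    # merge alleles onto one shared reference span
    rec_start = min(p for _, (p, _, _) in resolved)
    rec_end = max(e for _, (_, e, _) in resolved)
    ref_allele = ref_slice(rec_start, rec_end)
    alts = []
    for _, (p, e, alt) in resolved:
        alts.append(ref_slice(rec_start, p) + alt + ref_slice(e, rec_end))
    if len(resolved) == 2:
        genotype = "1/2"
    elif pair[0] == pair[1]:
        genotype = "1/1"
    else:
        genotype = "0/1"

    if qual_threshold is None:
        qual_threshold = QUAL_THRESHOLDS[platform]
    filt = "LowQual" if qual < qual_threshold else "PASS"
    alt_depths = tuple(ad.get(sym, 0) for sym, _ in resolved)
    return VariantCall(
        contig=pile.contig,
        pos=rec_start,
        ref=ref_allele,
        alts=tuple(alts),
        genotype=genotype,
        qual=qual,
        filter=filt,
        ref_depth=ad.get(ref_base, 0),
        alt_depths=alt_depths,
    )


# ---------------------------------------------------------------------------
# Calling pipeline
# ---------------------------------------------------------------------------

def call_variants(
    alignments: Sequence[AlignedRead],
    ref: dict[str, str],
    model: PileupNetwork,
    platform: str = "ont",
    af_threshold: float = 0.08,
    min_dp: int = 4,
    min_ad: int = 2,
    cap: Optional[CoverageCap] = None,
    enable_phasing: bool = False,
    qual_threshold: Optional[float] = None,
) -> list[VariantCall]:
    """Scan candidates, build tensors, run the network, decide calls."""
    from .formats import GenomicInterval
    from .phasing import extract_haplotype_counts
    from .tensors import WINDOW_FLANK, attach_phasing_features

    cands = scan_candidates(
        alignments, ref, af_threshold=af_threshold,
        min_dp=min_dp, min_ad=min_ad,
    )
    if not cands:
        return []
    by_contig: dict[str, list[AlignedRead]] = {}
    for r in alignments:
        by_contig.setdefault(r.contig, []).append(r)
    feats = []
    for cand in cands:
        reads = [
            r for r in by_contig.get(cand.contig, [])
            if r.pos < cand.pos + WINDOW_FLANK + 1
            and r.reference_end > cand.pos - WINDOW_FLANK
        ]
        tensor = build_pileup_tensor(cand, reads)
        if enable_phasing:
            win = GenomicInterval(
                cand.contig,
                max(cand.pos - WINDOW_FLANK, 0),
                cand.pos + WINDOW_FLANK + 1,
            )
            hap = extract_haplotype_counts(reads, win)
            full = np.zeros((2 * WINDOW_FLANK + 1, hap.shape[1]), dtype=np.int64)
            off = win.start - (cand.pos - WINDOW_FLANK)
            full[off : off + hap.shape[0]] = hap
            tensor = attach_phasing_features(tensor, full)
        if cap is not None:
            tensor = normalize_tensor(tensor, cap)
        feats.append(tensor.features)
    probs = predict(model, feats)
    calls = []
    for cand, pr in zip(cands, probs):
        call = decide_call(
            pr, cand.pileup, platform=platform,
            ref_seq=ref.get(cand.contig), qual_threshold=qual_threshold,
        )
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.pos))
    return calls
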
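"""Bidirectional GRU murmur-grading network.

The network ingests a log-spectrogram (frames x frequency bins), runs it
through one or more bidirectional gated-recurrent-unit layers, mean-pools
the hidden states over time and maps them through a linear head to class
logits.  Training minimizes softmax cross-entropy with the Adam optimizer;
grades are treated as unordered classes.

The transfer-learning workflow mirrors clinical practice for porting a
human murmur detector to dogs: a base model with a binary head is
pretrained (here on synthetic data), its final layer is then cleared and
replaced by a zero-initialized 5-class head covering {none, soft, moderate,
loud, thrilling}, and the whole network is fine-tuned on graded dog
recordings with patient-level 5-fold cross-validation and early stopping.
Test-time predictions average the softmax outputs of the five fold models.

Everything is implemented in NumPy: forward pass, backpropagation through
time, and Adam, so the package trains on a single CPU with no deep-learning
framework.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .features import MODEL_SPECTROGRAM, SpectrogramConfig, compute_log_spectrogram
from .grades import GRADES, N_GRADES, grade_index
from .synth import Recording


@dataclass(frozen=True)
class ModelConfig:
    recurrent_cell: str = "gru"
    bidirectional: bool = True
    hidden_size: int = 48
    num_layers: int = 1
    num_output_classes: int = N_GRADES
    learning_rate: float = 5e-3
    batch_size: int = 64
    max_epochs: int = 40
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.recurrent_cell != "gru":
            raise ValueError("only GRU cells are supported")
        if not self.bidirectional:
            raise ValueError("the grading network is bidirectional")
        if self.hidden_size <= 0 or self.num_layers <= 0:
            raise ValueError("hidden_size and num_layers must be positive")
        if self.num_output_classes < 2:
            raise ValueError("need at least two output classes")


@dataclass
class GradeDistribution:
    """Probability vector over the five reduced murmur grades."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (N_GRADES,):
            raise ValueError(f"expected {N_GRADES} probabilities, got shape {p.shape}")
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
        self.probabilities = p

    @property
    def argmax_grade(self) -> str:
        return GRADES[int(np.argmax(self.probabilities))]

    def p(self, grade: str | int) -> float:
        return float(self.probabilities[grade_index(grade)])


@dataclass
class PatientPrediction:
    """Per-site grading results aggregated to one dog."""

    site_distributions: dict        # site -> GradeDistribution
    site_grades: dict               # site -> predicted grade name
    murmur_flag: bool
    sites_of_maximal_predicted_grade: set


def binary_murmur_probability(dist: GradeDistribution) -> float:
    """Probability of a murmur of any intensity: 1 - P(none)."""
    return 1.0 - dist.p("none")


def loud_or_greater_probability(dist: GradeDistribution) -> float:
    """P(loud) + P(thrilling): the continuous score used for staging."""
    return dist.p("loud") + dist.p("thrilling")


def aggregate_patient(site_distributions: dict) -> PatientPrediction:
    """Combine per-site grade distributions into a patient-level call.

    A murmur is predicted for the patient if any site's argmax grade is not
    "none"; the maximal-grade site set contains every site attaining the
    highest predicted grade (shared maxima are all reported).
    """
    if not site_distributions:
        raise ValueError("need at least one site distribution")
    site_grades = {s: d.argmax_grade for s, d in site_distributions.items()}
    murmur_sites = {s: g for s, g in site_grades.items() if g != "none"}
    flag = bool(murmur_sites)
    if flag:
        top = max(grade_index(g) for g in murmur_sites.values())
        maximal = {s for s, g in murmur_sites.items() if grade_index(g) == top}
    else:
        maximal = set()
    return PatientPrediction(site_distributions=dict(site_distributions),
                             site_grades=site_grades, murmur_flag=flag,
                             sites_of_maximal_predicted_grade=maximal)


# --------------------------------------------------------------------------
# network internals


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class GRUModel:
    """Bidirectional GRU sequence classifier with a mean-pool linear head.

    Parameters live in ``params``: per layer ``l`` and direction ``d`` in
    {"f", "b"}, ``gru{l}{d}_Wi`` (input x 3H), ``_Wh`` (H x 3H), ``_bi``,
    ``_bh`` (3H) with gate order (reset, update, candidate), plus ``head_W``
    (2H x classes) and ``head_b``.
    """

    def __init__(self, config: ModelConfig, input_dim: int,
                 spectrogram: SpectrogramConfig = MODEL_SPECTROGRAM):
        self.config = config
        self.input_dim = int(input_dim)
        self.spectrogram = spectrogram
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- construction -----------------------------------------------------

    def _init_params(self):
        rng = np.random.default_rng(self.config.seed)
        H = self.config.hidden_size
        bound = 1.0 / math.sqrt(H)
        in_dim = self.input_dim
        for layer in range(self.config.num_layers):
            for d in ("f", "b"):
                k = f"gru{layer}{d}"
                self.params[f"{k}_Wi"] = rng.uniform(-bound, bound, (in_dim, 3 * H))
                self.params[f"{k}_Wh"] = rng.uniform(-bound, bound, (H, 3 * H))
                self.params[f"{k}_bi"] = rng.uniform(-bound, bound, 3 * H)
                self.params[f"{k}_bh"] = rng.uniform(-bound, bound, 3 * H)
            in_dim = 2 * H
        C = self.config.num_output_classes
        self.params["head_W"] = rng.uniform(-bound, bound, (2 * H, C))
        self.params["head_b"] = rng.uniform(-bound, bound, C)

    def clone(self) -> "GRUModel":
        m = object.__new__(GRUModel)
        m.config = self.config
        m.input_dim = self.input_dim
        m.spectrogram = self.spectrogram
        m.params = {k: v.copy() for k, v in self.params.items()}
        return m

    # -- forward / backward ----------------------------------------------

    def _direction_forward(self, X, key, reverse, cache=None):
        # X: (B, T, in_dim) -> hidden states (B, T, H)
        p = self.params
        H = self.config.hidden_size
        B, T, _ = X.shape
        xp = X @ p[f"{key}_Wi"] + p[f"{key}_bi"]      # (B, T, 3H)
        Wh = p[f"{key}_Wh"]
        bh = p[f"{key}_bh"]
        hs = np.empty((B, T, H))
        h = np.zeros((B, H))
        order = range(T - 1, -1, -1) if reverse else range(T)
        steps = []
        for t in order:
            hg = h @ Wh + bh
            g = xp[:, t, :]
            r = _sigmoid(g[:, :H] + hg[:, :H])
            z = _sigmoid(g[:, H:2 * H] + hg[:, H:2 * H])
            hn = hg[:, 2 * H:]
            n = np.tanh(g[:, 2 * H:] + r * hn)
            h_new = (1.0 - z) * n + z * h
            if cache is not None:
                steps.append((t, h, r, z, n, hn))
            hs[:, t, :] = h_new
            h = h_new
        if cache is not None:
            cache[key] = steps
        return hs

    def _forward(self, X, cache=None):
        """X: (B, T, F) -> logits (B, C); optionally fill a backprop cache."""
        layer_in = X
        layer_inputs = []
        for layer in range(self.config.num_layers):
            layer_inputs.append(layer_in)
            hf = self._direction_forward(layer_in, f"gru{layer}f", False, cache)
            hb = self._direction_forward(layer_in, f"gru{layer}b", True, cache)
            layer_in = np.concatenate([hf, hb], axis=2)
        pooled = layer_in.mean(axis=1)                     # (B, 2H)
        logits = pooled @ self.params["head_W"] + self.params["head_b"]
        if cache is not None:
            cache["layer_inputs"] = layer_inputs
            cache["pooled"] = pooled
        return logits

    def _direction_backward(self, key, dh_seq, cache, grads, layer_input):
        """Backprop one direction; returns gradient w.r.t. the layer input."""
        p = self.params
        H = self.config.hidden_size
        Wh = p[f"{key}_Wh"]
        B, T, _ = dh_seq.shape
        dG = np.empty((B, T, 3 * H))
        dWh = np.zeros_like(Wh)
        dbh = np.zeros(3 * H)
        dh = np.zeros((B, H))
        for (t, h_prev, r, z, n, hn) in reversed(cache[key]):
            dh = dh + dh_seq[:, t, :]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh = dh * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * hn
            dhn = dn_pre * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dg = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dG[:, t, :] = dg
            dhg = np.concatenate([dr_pre, dz_pre, dhn], axis=1)
            dWh += h_prev.T @ dhg
            dbh += dhg.sum(axis=0)
            dh = dh + dhg @ Wh.T
        grads[f"{key}_Wh"] = dWh
        grads[f"{key}_bh"] = dbh
        Wi = p[f"{key}_Wi"]
        flat = dG.reshape(B * T, 3 * H)
        grads[f"{key}_Wi"] = layer_input.reshape(B * T, -1).T @ flat
        grads[f"{key}_bi"] = flat.sum(axis=0)
        return (flat @ Wi.T).reshape(B, T, -1)

    def loss_and_grads(self, X, y):
        """Mean softmax cross-entropy and parameter gradients on a batch."""
        cache: dict = {}
        logits = self._forward(X, cache)
        B, T, _ = X.shape
        probs = _softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads: dict[str, np.ndarray] = {}
        pooled = cache["pooled"]
        grads["head_W"] = pooled.T @ dlogits
        grads["head_b"] = dlogits.sum(axis=0)
        dpooled = dlogits @ self.params["head_W"].T    # (B, 2H)

        H = self.config.hidden_size
        dlayer = np.repeat(dpooled[:, None, :] / T, T, axis=1)   # (B, T, 2H)
        for layer in range(self.config.num_layers - 1, -1, -1):
            layer_input = cache["layer_inputs"][layer]
            dxf = self._direction_backward(f"gru{layer}f", dlayer[:, :, :H],
                                           cache, grads, layer_input)
            dxb = self._direction_backward(f"gru{layer}b", dlayer[:, :, H:],
                                           cache, grads, layer_input)
            dlayer = dxf + dxb
        return loss, grads

    # -- inference --------------------------------------------------------

    def predict_logits(self, X) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.predict_logits(X))

    def loss(self, X, y) -> float:
        probs = self.predict_proba(X)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


def build_base_model(config: ModelConfig, input_dim: int | None = None,
                     spectrogram: SpectrogramConfig = MODEL_SPECTROGRAM,
                     ) -> GRUModel:
    """Construct the sequence classifier with seed-deterministic weights."""
    if input_dim is None:
        input_dim = _spectrogram_input_dim(spectrogram)
    return GRUModel(config, input_dim, spectrogram)


def _spectrogram_input_dim(cfg: SpectrogramConfig, sample_rate: int = 4000) -> int:
    freqs = np.fft.rfftfreq(cfg.fft_size, d=1.0 / sample_rate)
    lo, hi = cfg.frequency_range
    return int(np.sum((freqs >= lo) & (freqs <= hi)))


def spectrogram_batch(recordings: list[Recording],
                      cfg: SpectrogramConfig = MODEL_SPECTROGRAM) -> np.ndarray:
    """Stack per-recording spectrograms into an (N, T, F) array."""
    mats = [compute_log_spectrogram(r, cfg).values for r in recordings]
    T = min(m.shape[0] for m in mats)
    return np.stack([m[:T] for m in mats])


# --------------------------------------------------------------------------
# training


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    converged: bool = True


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t)
                                                        + self.eps)


def train_model(model: GRUModel, X, y, X_val=None, y_val=None,
                seed: int | None = None) -> TrainHistory:
    """Adam + cross-entropy training with optional early stopping.

    When a validation set is given, training monitors its cross-entropy and
    restores the best parameters after ``early_stopping_patience`` epochs
    without improvement.
    """
    cfg = model.config
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    opt = _Adam(model.params, cfg.learning_rate)
    hist = TrainHistory()
    best_val = math.inf
    best_params = None
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X[idx], y[idx])
            opt.step(model.params, grads)
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        if X_val is not None and len(X_val):
            vl = model.loss(X_val, y_val)
            hist.val_loss.append(vl)
            if vl < best_val - 1e-6:
                best_val = vl
                best_params = {k: v.copy() for k, v in model.params.items()}
                hist.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stopping_patience:
                    break
    if best_params is not None:
        model.params = best_params
    if hist.train_loss and hist.train_loss[-1] > hist.train_loss[0]:
        hist.converged = False
        warnings.warn("training loss did not decrease within max_epochs")
    return hist


def surrogate_pretrain(model: GRUModel, X, y_binary, val_fraction: float = 0.25,
                       seed: int | None = None) -> TrainHistory:
    """Pretrain the base (binary-head) model on murmur-present labels.

    Stands in for large-scale pretraining on human heart-sound corpora: the
    interface downstream (head surgery, fine-tuning) is identical.  Holds
    out a random fraction for early stopping.
    """
    if model.config.num_output_classes != 2:
        raise ValueError("surrogate pretraining expects a binary head")
    y = np.asarray(y_binary, dtype=np.int64)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(val_fraction * len(X))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    X = np.asarray(X, dtype=np.float64)
    return train_model(model, X[tr_idx], y[tr_idx], X[val_idx], y[val_idx],
                       seed=seed)


def transfer_head_surgery(pretrained: GRUModel,
                          num_output_classes: int = N_GRADES) -> GRUModel:
    """Replace the final layer with a zero-initialized multi-class head.

    Every non-final parameter is copied verbatim; the new head outputs
    all-zero logits, i.e. a uniform distribution over the grades, until
    fine-tuning moves it.
    """
    if num_output_classes < 2:
        raise ValueError("num_output_classes must be at least 2")
    m = pretrained.clone()
    m.config = replace(pretrained.config, num_output_classes=num_output_classes)
    H2 = pretrained.params["head_W"].shape[0]
    m.params["head_W"] = np.zeros((H2, num_output_classes))
    m.params["head_b"] = np.zeros(num_output_classes)
    return m


@dataclass
class Ensemble:
    """The k fold models produced by cross-validated fine-tuning."""

    members: list
    histories: list = field(default_factory=list)
    fold_assignment: dict = field(default_factory=dict)   # patient_id -> fold

    def predict_proba(self, X) -> np.ndarray:
        if not self.members:
            raise ValueError("ensemble has no trained members")
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)


def stratified_patient_folds(patient_ids, labels_by_patient, k, seed=0):
    """Partition patients into k folds, stratified by maximum patient grade."""
    patients = list(dict.fromkeys(patient_ids))
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for p in patients:
        by_label.setdefault(labels_by_patient[p], []).append(p)
    folds: dict[str, int] = {}
    counter = 0
    for lab in sorted(by_label):
        group = by_label[lab]
        rng.shuffle(group)
        for p in group:
            folds[p] = counter % k
            counter += 1
    return folds


def finetune_crossval(model: GRUModel, X, y, patient_ids, k: int = 5,
                      seed: int | None = None) -> Ensemble:
    """Fine-tune k fold models with patient-level folds and early stopping.

    Folds partition patients (never recordings of one dog across folds),
    stratified by each patient's maximum grade so no fold misses a class
    entirely.  Each member trains on k-1 folds and early-stops on its
    held-out fold; the ensemble predicts by averaging member softmaxes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    patient_ids = list(patient_ids)
    base_seed = model.config.seed if seed is None else seed
    max_grade = {}
    for pid, lab in zip(patient_ids, y):
        max_grade[pid] = max(max_grade.get(pid, 0), int(lab))
    folds = stratified_patient_folds(patient_ids, max_grade, k, seed=base_seed)
    fold_of_rec = np.array([folds[p] for p in patient_ids])
    members, histories = [], []
    for fold in range(k):
        member = model.clone()
        tr = fold_of_rec != fold
        va = ~tr
        hist = train_model(member, X[tr], y[tr], X[va], y[va],
                           seed=base_seed + 1000 * (fold + 1))
        members.append(member)
        histories.append(hist)
    return Ensemble(members=members, histories=histories, fold_assignment=folds)


def predict_grade(ensemble: Ensemble, recording: Recording,
                  cfg: SpectrogramConfig | None = None) -> GradeDistribution:
    """Ensemble-averaged grade distribution for one recording."""
    cfg = cfg or ensemble.members[0].spectrogram
    X = spectrogram_batch([recording], cfg)
    probs = ensemble.predict_proba(X)[0]
    return GradeDistribution(probs / probs.sum())
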
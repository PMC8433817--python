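"""Per-phase recurrent sequence models (LSTM_FO, LSTM_MidS, LSTM_FC).

One binary classifier per gait phase maps a 251-frame window of the three
magnitude features to the probability that the phase occurs at the
window's center frame.  The reference architecture stacks five LSTM
layers with units [30, 60, 60, 60, 30] — all but the last returning
per-step sequences — each followed by batch normalization (momentum 0.99,
epsilon 0.001) and dropout (rate 0.2), ending in a 1-unit sigmoid output;
training uses Adam (learning rate 1e-4) on binary cross-entropy for up to
100 epochs.  A ``desk_scale`` preset with units [8, 16, 16, 16, 8],
fewer epochs and a larger learning rate makes single-CPU training on
balanced synthetic windows practical; the full profile remains available.

Sliding a trained model across a recording yields a probability trace,
one value per possible center frame; the event caller turns traces into
discrete timepoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from gaitphase._nn import Adam, SequenceClassifier
from gaitphase.features import FeatureSet
from gaitphase.gait_labeler import LabeledSeries
from gaitphase.windowing import WindowTensor, WINDOW_LENGTH, CENTER_OFFSET


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of one per-phase model."""

    units: tuple[int, ...] = (30, 60, 60, 60, 30)
    dropout_rate: float = 0.2
    batch_norm_momentum: float = 0.99
    batch_norm_epsilon: float = 0.001
    seq_len: int = WINDOW_LENGTH
    n_features: int = 3
    #: Feed windows to the recurrent stack in reverse time order.  A
    #: unidirectional final-state readout is most sensitive to the end of
    #: the sequence, so each phase model should read the window in the
    #: direction that places that phase's discriminative flanking peaks
    #: last: forward for FO (its MidS/FC follow the event), reversed for
    #: FC (its FO/MidS precede it).
    reverse_input: bool = False

    def __post_init__(self) -> None:
        if not self.units or any(u <= 0 for u in self.units):
            raise ValueError("units must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.seq_len % 2 != 1:
            raise ValueError("seq_len must be odd (center-frame target)")

    @classmethod
    def desk_scale(cls) -> "ModelSpec":
        # dropout off: at this size and epoch budget the models underfit,
        # and dropout noise on 8-16 unit layers stops the boundary cases
        # (terminal steps, gait initiation) from ever being fit
        return cls(units=(8, 16, 16, 16, 8), dropout_rate=0.0)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (reference profile: Adam 1e-4, 100 epochs)."""

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    shuffle: bool = True
    #: multiplicative per-epoch learning-rate decay (1.0 = constant)
    lr_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 10) -> "TrainConfig":
        return cls(learning_rate=3e-3, epochs=epochs, batch_size=64, seed=seed)


@dataclass(frozen=True)
class PredictionTrace:
    """Per-center-frame phase probabilities for one recording.

    ``probabilities[i]`` belongs to frame ``first_center_frame + i``;
    a length-n recording yields n − (seq_len − 1) values.
    """

    phase: str
    probabilities: np.ndarray
    first_center_frame: int = CENTER_OFFSET

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_values(self) -> int:
        return self.probabilities.shape[0]

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_center_frame, self.first_center_frame + self.n_values)


#: Reading direction(s) per phase (False = forward, True = reversed).
#: FO's discriminative flanking peaks follow the event, so a forward
#: reader suffices; FC's precede it and its terminal-step peak is faint,
#: so FC uses a forward+reverse consensus; MidS is flanked on both sides.
PHASE_DIRECTIONS: dict[str, tuple[bool, ...]] = {
    "FO": (False,),
    "MidS": (False,),
    "FC": (False, True),
}


class PhaseModel:
    """A built (possibly trained) per-phase model with its metadata."""

    def __init__(self, spec: ModelSpec, phase: str = "FO", seed: int = 0) -> None:
        self.spec = spec
        self.phase = phase
        self.seed = seed
        self.net = SequenceClassifier(
            n_features=spec.n_features,
            units=list(spec.units),
            dropout_rate=spec.dropout_rate,
            bn_momentum=spec.batch_norm_momentum,
            bn_epsilon=spec.batch_norm_epsilon,
            seed=seed,
        )
        self.history: list[dict] = []

    def save(self, directory) -> None:
        """Persist weights (npz) plus spec/seed/history metadata (JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.net.state_arrays())
        meta = {
            "phase": self.phase,
            "seed": self.seed,
            "spec": asdict(self.spec),
            "history": self.history,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PhaseModel":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        spec_dict = dict(meta["spec"])
        spec_dict["units"] = tuple(spec_dict["units"])
        model = cls(ModelSpec(**spec_dict), phase=meta["phase"], seed=meta["seed"])
        with np.load(directory / "weights.npz") as arrays:
            model.net.load_state_arrays(arrays)
        model.history = meta["history"]
        return model


def build_model(spec: ModelSpec | None = None, phase: str = "FO", seed: int = 0) -> PhaseModel:
    """Construct an untrained per-phase model from its architecture spec."""
    return PhaseModel(spec or ModelSpec(), phase=phase, seed=seed)


def _epoch_metrics(net: SequenceClassifier, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    p = net.predict_proba(x)
    eps = 1e-7
    pc = np.clip(p, eps, 1 - eps)
    loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    acc = float(np.mean((p > 0.5) == (y == 1)))
    return loss, acc


def train(model: PhaseModel, windows: WindowTensor, val: WindowTensor | None = None,
          cfg: TrainConfig | None = None, verbose: bool = False) -> list[dict]:
    """Fit a model on center-labeled windows with Adam + binary cross-entropy.

    Returns (and stores on the model) the per-epoch history: training loss
    and accuracy averaged over the epoch's batches (training mode, the
    usual deep-learning convention), plus validation loss/accuracy in
    inference mode when a validation tensor is given.  After the final
    epoch the batch-norm moving statistics are replaced by exact
    training-set statistics — short runs leave the exponential moving
    averages far behind the trained weights, which would otherwise open a
    gap between training and inference behavior.  ``epochs = 0`` leaves
    the freshly initialized model untouched.
    """
    cfg = cfg or TrainConfig()
    x = windows.windows
    if model.spec.reverse_input:
        x = np.ascontiguousarray(x[:, ::-1, :])
    y = windows.targets.astype(float)
    if x.shape[1] != model.spec.seq_len or x.shape[2] != model.spec.n_features:
        raise ValueError(
            f"window shape {x.shape[1:]} does not match model spec "
            f"({model.spec.seq_len}, {model.spec.n_features})"
        )
    optimizer = Adam(model.net.layers, learning_rate=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        optimizer.lr = cfg.learning_rate * cfg.lr_decay ** epoch
        order = shuffle_rng.permutation(x.shape[0]) if cfg.shuffle else np.arange(x.shape[0])
        batch_stats = [
            model.net.train_batch(x[order[s:s + cfg.batch_size]],
                                  y[order[s:s + cfg.batch_size]], optimizer)
            for s in range(0, order.size, cfg.batch_size)
        ]
        row = {
            "epoch": epoch,
            "loss": float(np.mean([b[0] for b in batch_stats])),
            "accuracy": float(np.mean([b[1] for b in batch_stats])),
        }
        if val is not None:
            model.net.calibrate_batchnorm(x)
            vloss, vacc = _epoch_metrics(model.net, val.windows, val.targets.astype(float))
            row.update(val_loss=vloss, val_accuracy=vacc)
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: " + " ".join(f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
    if cfg.epochs > 0:
        model.net.calibrate_batchnorm(x)
    model.history = model.history + history
    return history


def predict_trace(model: PhaseModel, features: FeatureSet, batch_size: int = 256) -> PredictionTrace:
    """Phase probability for every possible center frame of a recording.

    The feature matrix is min–max scaled per recording exactly as during
    training; inference is deterministic (dropout off, batch-norm using
    moving statistics).
    """
    L = model.spec.seq_len
    matrix = features.as_matrix(scaled=True)
    if matrix.shape[0] < L:
        raise ValueError(f"recording has {matrix.shape[0]} frames; need at least {L}")
    windows = np.lib.stride_tricks.sliding_window_view(matrix, L, axis=0).transpose(0, 2, 1)
    if model.spec.reverse_input:
        windows = windows[:, ::-1, :]
    probs = model.net.predict_proba(np.ascontiguousarray(windows), batch_size=batch_size)
    return PredictionTrace(phase=model.phase, probabilities=probs,
                           first_center_frame=(L - 1) // 2)


def combine_traces(traces: list[PredictionTrace]) -> PredictionTrace:
    """Geometric-mean consensus of probability traces for the same phase.

    A unidirectional recurrent readout has a blind side: read forward it
    over-weights context *after* the center frame, read backward context
    *before* it.  Combining a forward and a reverse reader by geometric
    mean requires both to agree, which suppresses the one-sided phantom
    detections either reader produces alone.  Traces must be aligned
    (same phase, same length, same first center frame).
    """
    if not traces:
        raise ValueError("need at least one trace")
    first = traces[0]
    for t in traces[1:]:
        if (t.phase != first.phase or t.n_values != first.n_values
                or t.first_center_frame != first.first_center_frame):
            raise ValueError("traces are not aligned")
    stacked = np.stack([t.probabilities for t in traces])
    probs = np.exp(np.mean(np.log(np.clip(stacked, 1e-12, 1.0)), axis=0))
    return PredictionTrace(phase=first.phase, probabilities=probs,
                           first_center_frame=first.first_center_frame)


def frame_metrics(trace: PredictionTrace, labels: LabeledSeries, phase: str) -> dict:
    """Frame-level accuracy and BCE of a trace against the label channel.

    Labels are cropped to the trace's center-frame range.  Accuracy is the
    fraction of center frames where the thresholded probability (> 0.5
    counts as positive, the usual deep-learning convention) matches the
    label;
    BCE clamps probabilities 1e-7 away from 0/1.  The all-negative
    baseline accuracy (fraction of zero labels) is reported alongside
    because labeled frames are a sub-percent minority and raw accuracy
    alone is uninformative.
    """
    y = labels.channel(phase)[trace.frames]
    if y.shape[0] != trace.n_values:
        raise ValueError("label channel shorter than the prediction trace")
    p = np.clip(trace.probabilities, 1e-7, 1 - 1e-7)
    y = y.astype(float)
    bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    acc = float(np.mean((trace.probabilities > 0.5) == (y == 1)))
    return {
        "accuracy": acc,
        "bce_loss": bce,
        "all_negative_baseline": float(np.mean(y == 0)),
        "n_frames": int(trace.n_values),
    }
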
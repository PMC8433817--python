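"""Reusable end-to-end experiment recipe on synthetic gait data.

Bundles the full desk-scale study: a training set of simulated trials
spanning the three protocol speeds with a boundary-heavy mix of bout
lengths, per-phase detector training (one reading direction per phase,
two for FC), and event-level evaluation on a held-out trial.  The CLI's
``run-all`` command and the acceptance script are thin wrappers around
these functions.
"""

from __future__ import annotations

import dataclasses

from gaitphase.config import BalanceConfig, RunConfig
from gaitphase.event_caller import CallerConfig, call_events, evaluate_events, refine_on_signal
from gaitphase.features import FeatureSet
from gaitphase.gait_labeler import GaitEvent
from gaitphase.gait_synth import SynthConfig, synth_features, synth_training_set
from gaitphase.phase_model import (
    PHASE_DIRECTIONS,
    ModelSpec,
    PhaseModel,
    TrainConfig,
    build_model,
    combine_traces,
    predict_trace,
    train,
)

#: Protocol walking speeds (steps per second per leg): slow, convenient, fast.
PROTOCOL_CADENCES = (0.8, 1.0, 1.3)

#: Bout lengths cycled over training trials.  Short bouts oversample gait
#: initiation and termination, the step shapes that break naive detectors.
TRAINING_BOUT_STEPS = (8, 3, 5, 3)


def training_configs(seed: int, n_trials: int = 11,
                     base: SynthConfig | None = None) -> list[SynthConfig]:
    """Simulated training trials covering the three speeds and bout mixes."""
    base = base or SynthConfig()
    return [
        dataclasses.replace(
            base,
            seed=(seed * 1009 + i) % (2**31),
            cadence_steps_per_s=PROTOCOL_CADENCES[i % len(PROTOCOL_CADENCES)],
            n_steps_per_bout=TRAINING_BOUT_STEPS[i % len(TRAINING_BOUT_STEPS)],
        )
        for i in range(n_trials)
    ]


def train_phase_detector(phase: str, train_cfgs: list[SynthConfig],
                         model_spec: ModelSpec, train_cfg: TrainConfig,
                         balance: BalanceConfig | None = None,
                         seed: int = 0, verbose: bool = False) -> list[PhaseModel]:
    """Train the per-phase detector: one model per reading direction."""
    balance = balance or BalanceConfig()
    tensor = synth_training_set(
        train_cfgs, phase,
        balance_strategy=balance.strategy, ratio=balance.ratio,
        dilation_radius=balance.dilation_radius,
        hard_negative_radius=balance.hard_negative_radius,
        hard_fraction=balance.hard_fraction, seed=seed,
    )
    models = []
    for reverse in PHASE_DIRECTIONS[phase]:
        spec = dataclasses.replace(model_spec, reverse_input=reverse)
        model = build_model(spec, phase=phase, seed=seed)
        train(model, tensor, cfg=train_cfg, verbose=verbose)
        models.append(model)
    return models


def detect_events(models: list[PhaseModel], features: FeatureSet,
                  caller: CallerConfig | None = None) -> list[GaitEvent]:
    """Probability-trace consensus -> discrete events -> raw-signal refinement."""
    caller = caller or CallerConfig()
    trace = combine_traces([predict_trace(m, features) for m in models])
    events = call_events(trace, caller, side=features.side,
                         sampling_rate_hz=features.sampling_rate_hz)
    return refine_on_signal(events, features.raw_ang_vel_mag, caller,
                            features.sampling_rate_hz)


def evaluate_detector(models: list[PhaseModel], holdout: SynthConfig,
                      caller: CallerConfig | None = None,
                      tolerance_frames: int = 5) -> dict:
    """Event-level scores pooled over both legs of a held-out trial."""
    phase = models[0].phase
    features, truth, _ = synth_features(holdout)
    matched = predicted = n_truth = 0
    errors = []
    for side in ("left", "right"):
        events = detect_events(models, features[side], caller)
        truth_side = [e for e in truth if e.side == side and e.valid and e.phase == phase]
        stats = evaluate_events(events, truth_side, tolerance_frames)
        matched += stats["n_matched"]
        predicted += stats["n_predicted"]
        n_truth += stats["n_truth"]
        if stats["n_matched"]:
            errors.append(stats["mean_abs_timing_error_frames"] * stats["n_matched"])
    precision = matched / predicted if predicted else 0.0
    recall = matched / n_truth if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "phase": phase,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mean_abs_timing_error_frames": sum(errors) / matched if matched else float("nan"),
        "n_truth": n_truth,
        "n_predicted": predicted,
        "n_matched": matched,
    }


def run_desk_experiment(run_cfg: RunConfig, n_trials: int = 11,
                        phases=("FO", "MidS", "FC"), verbose: bool = False) -> dict:
    """Full train-and-evaluate pass; returns per-phase event-level scores."""
    train_cfgs = training_configs(run_cfg.seed, n_trials, base=run_cfg.synth)
    holdout = dataclasses.replace(run_cfg.synth,
                                  seed=(run_cfg.seed * 1009 + n_trials) % (2**31))
    report = {}
    for phase in phases:
        models = train_phase_detector(phase, train_cfgs, run_cfg.model,
                                      run_cfg.training, run_cfg.balance,
                                      seed=run_cfg.seed, verbose=verbose)
        report[phase] = evaluate_detector(models, holdout, run_cfg.caller)
        report[phase]["models"] = models
    return report
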
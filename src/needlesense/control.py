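"""Closed-loop insertion control: advance, measure, remap, classify, stop.

The needle advances one motor step per cycle.  Depth bookkeeping is in whole
steps (the motor counter: +1 forward, -1 backward); millimetres appear only
as ``step * step_mm`` at the reporting boundary.  A stop policy fires when
the target tissue has been predicted for a debounced run of consecutive
steps, after an optional arming rule (e.g. the epidural-injection policy arms
only once ligament has been seen, so subcutaneous fat cannot trigger a stop).

The comfortable travel distance (CTD) between the zero-position step count N1
and terminal step count N2 is

    H1 = N1 * Hs,   H2 = N2 * Hs,   delta = H2 - H1 = (N2 - N1) * Hs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import bnn as _bnn
from .bnn import BNNModel, Prediction
from .errors import ConfigError, ValidationError
from .phantom import PhantomStack, TissueTemplate, default_templates, spectrum_at_depth
from .remap import ConductivitySpectrum, ImpedanceSpectrum, RemapTable, remap_spectrum

__all__ = [
    "MotorConfig",
    "StopPolicy",
    "StepCounter",
    "CTDReport",
    "InsertionRecord",
    "InsertionTrace",
    "TraceMetrics",
    "OracleClassifier",
    "compute_ctd",
    "run_insertion",
    "evaluate_trace",
    "LP_POLICY",
    "ESI_POLICY",
]

_STEP_MM_MIN, _STEP_MM_MAX = 0.08, 0.22


@dataclass(frozen=True)
class MotorConfig:
    """Stepper-motor linear travel per step (mm); driver range 0.08-0.22."""

    step_mm: float = 0.08

    def __post_init__(self) -> None:
        if not (_STEP_MM_MIN - 1e-12 <= self.step_mm <= _STEP_MM_MAX + 1e-12):
            raise ConfigError(
                f"step_mm {self.step_mm} outside motor range "
                f"[{_STEP_MM_MIN}, {_STEP_MM_MAX}]"
            )


class StepCounter:
    """Motor impulse counter: +1 per forward impulse, -1 per backward."""

    def __init__(self, value: int = 0):
        self.value = int(value)

    def forward(self, steps: int = 1) -> int:
        self.value += int(steps)
        return self.value

    def backward(self, steps: int = 1) -> int:
        self.value -= int(steps)
        return self.value


@dataclass(frozen=True)
class StopPolicy:
    """When to halt the needle.

    target          tissue whose detection stops the motion
    consecutive_hits debounce: required run of consecutive target predictions
    min_depth_mm    detections shallower than this never count
    arm_after       if set, detections are ignored until this tissue has been
                    predicted at least once (the "skip subcutaneous fat" rule)
    max_spread      optional confidence gate on Prediction.spread_of_max
    """

    target: str
    consecutive_hits: int = 2
    min_depth_mm: float = 0.0
    arm_after: str | None = None
    max_spread: float | None = None

    def __post_init__(self) -> None:
        if self.consecutive_hits < 1:
            raise ConfigError("consecutive_hits must be >= 1")
        if self.min_depth_mm < 0:
            raise ConfigError("min_depth_mm must be >= 0")


#: Lumbar puncture: run until cerebrospinal fluid.
LP_POLICY = StopPolicy(target="csf", consecutive_hits=2)
#: Epidural steroid injection: stop in fat, but only after ligament was seen.
ESI_POLICY = StopPolicy(target="fat", consecutive_hits=2, arm_after="ligament")


@dataclass(frozen=True)
class CTDReport:
    """Comfortable-travel-distance bookkeeping per the step-count equations."""

    n1: float
    n2: float
    step_mm: float
    h1_mm: float
    h2_mm: float
    delta_mm: float


def compute_ctd(n1: float, n2: float, step_mm: float) -> CTDReport:
    """H1 = N1*Hs, H2 = N2*Hs, delta = (N2 - N1)*Hs.

    Step counts may be real-valued (e.g. means over repeated trials).
    """
    if n1 < 0 or n2 < n1:
        raise ValidationError(f"need N2 >= N1 >= 0, got N1={n1}, N2={n2}")
    motor = MotorConfig(step_mm=step_mm)  # validates the motor range
    h1 = n1 * motor.step_mm
    h2 = n2 * motor.step_mm
    return CTDReport(n1=n1, n2=n2, step_mm=motor.step_mm,
                     h1_mm=h1, h2_mm=h2, delta_mm=h2 - h1)


@dataclass(frozen=True)
class InsertionRecord:
    step: int
    depth_mm: float
    impedance: ImpedanceSpectrum
    conductivity: ConductivitySpectrum
    prediction: Prediction
    true_label: str


@dataclass(frozen=True)
class InsertionTrace:
    records: tuple[InsertionRecord, ...]
    stop_step: int | None
    stop_reason: str  # "target" or "not_found"
    policy: StopPolicy
    motor: MotorConfig

    @property
    def stop_depth_mm(self) -> float | None:
        if self.stop_step is None:
            return None
        return self.stop_step * self.motor.step_mm

    @property
    def stopped(self) -> bool:
        return self.stop_step is not None


class OracleClassifier:
    """Perfect classifier: predicts the phantom's true label with certainty."""

    def predict_true(self, true_label: str, classes=_bnn.CLASSES) -> Prediction:
        probs = np.zeros(len(classes))
        probs[classes.index(true_label)] = 1.0
        return Prediction(class_label=true_label, mean_probs=probs,
                          spread_of_max=0.0, n_posterior_samples=1)


def run_insertion(
    stack: PhantomStack,
    model: BNNModel | OracleClassifier,
    table: RemapTable,
    policy: StopPolicy,
    motor: MotorConfig,
    seed: int = 0,
    templates: Mapping[str, TissueTemplate] | None = None,
    n_predict_samples: int | None = None,
) -> InsertionTrace:
    """Simulate one closed-loop insertion from depth 0.

    Each cycle advances one motor step, measures the phantom spectrum at the
    new depth, remaps it and classifies it; the needle halts when the stop
    policy is satisfied.  Exhausting the stack depth is reported in the trace
    (stop_reason "not_found"), not raised.
    """
    if templates is None:
        templates = default_templates(table)
    missing = {layer.tissue for layer in stack.layers} - set(templates)
    if missing:
        raise ConfigError(f"no template for stack tissues {sorted(missing)}")
    stack.first_layer_of(policy.target)  # policy target must exist in the stack

    rng = np.random.default_rng(seed)
    counter = StepCounter(0)
    records: list[InsertionRecord] = []
    hits = 0
    armed = policy.arm_after is None
    stop_step: int | None = None
    max_steps = int(np.floor(stack.total_depth_mm / motor.step_mm))
    while counter.value < max_steps:
        n = counter.forward()
        depth = n * motor.step_mm
        z_spec, true_label = spectrum_at_depth(stack, depth, templates, rng)
        sigma = remap_spectrum(z_spec, table)
        if isinstance(model, OracleClassifier):
            pred = model.predict_true(true_label)
        else:
            pred = _bnn.predict(sigma, model, n_samples=n_predict_samples, seed=rng)
        records.append(InsertionRecord(step=n, depth_mm=depth, impedance=z_spec,
                                       conductivity=sigma, prediction=pred,
                                       true_label=true_label))
        if not armed and pred.class_label == policy.arm_after:
            armed = True
            continue  # arming observation itself never counts as a hit
        counted = (
            armed
            and depth >= policy.min_depth_mm
            and pred.class_label == policy.target
            and (policy.max_spread is None or pred.spread_of_max <= policy.max_spread)
        )
        hits = hits + 1 if counted else 0
        if hits >= policy.consecutive_hits:
            stop_step = n
            break
    return InsertionTrace(
        records=tuple(records),
        stop_step=stop_step,
        stop_reason="target" if stop_step is not None else "not_found",
        policy=policy,
        motor=motor,
    )


@dataclass(frozen=True)
class TraceMetrics:
    overshoot_mm: float | None
    per_step_accuracy: float
    false_stop: bool
    stopped: bool
    stop_layer_index: int | None
    target_entry_depth_mm: float


def evaluate_trace(trace: InsertionTrace, stack: PhantomStack) -> TraceMetrics:
    """Overshoot past the target-layer entry, step accuracy, false-stop flag.

    If the needle stopped inside a target-tissue layer, overshoot is measured
    from that layer's entry depth (the stack may contain the target tissue
    more than once, e.g. subcutaneous and epidural fat).  A stop in any other
    layer is a false stop, measured against the first target layer.  A trace
    that never stopped has undefined overshoot (None).
    """
    if not trace.records:
        raise ValidationError("empty trace")
    correct = sum(r.prediction.class_label == r.true_label for r in trace.records)
    accuracy = correct / len(trace.records)
    target = trace.policy.target
    first_target_entry = stack.entry_depth_mm(stack.first_layer_of(target))
    if not trace.stopped:
        return TraceMetrics(overshoot_mm=None, per_step_accuracy=accuracy,
                            false_stop=False, stopped=False, stop_layer_index=None,
                            target_entry_depth_mm=first_target_entry)
    stop_depth = trace.stop_depth_mm
    assert stop_depth is not None
    stop_layer = stack.layer_index_at(stop_depth)
    if stack.layers[stop_layer].tissue == target:
        entry = stack.entry_depth_mm(stop_layer)
        return TraceMetrics(overshoot_mm=stop_depth - entry, per_step_accuracy=accuracy,
                            false_stop=False, stopped=True, stop_layer_index=stop_layer,
                            target_entry_depth_mm=entry)
    return TraceMetrics(overshoot_mm=stop_depth - first_target_entry,
                        per_step_accuracy=accuracy, false_stop=True, stopped=True,
                        stop_layer_index=stop_layer,
                        target_entry_depth_mm=first_target_entry)
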
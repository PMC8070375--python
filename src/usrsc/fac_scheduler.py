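"""Discrete-event simulation of imaging + classification scheduling.

A portable scanner streams one frame of IQ data to the device every
``t_transfer`` ms; the GPU then runs the image-rendering pipeline (IRP,
``t_irp`` ms) and, when a classifier is attached, inference layers that are
non-preemptive once launched.  Three structures are simulated:

* plain imaging — no classifier; the frame period is ``max(t_transfer, t_irp)``
  and there is an idle window of ``t_transfer - t_irp`` per frame.
* frame-synchronous classification (FSC) — the whole classification pipeline
  (CP, the summed layer times) runs after every IRP, stretching the frame
  period to ``max(t_transfer, t_irp + t_cp)``.
* frame-asynchronous classification (FAC) — the CP is split into M
  sub-pipelines (sCPs), each fitting the idle window; one sCP runs per frame,
  so imaging proceeds at the transfer rate while one classification completes
  every M frames: ``f_image ~= M * f_cp``.

Splitting is greedy and order-preserving: layers accumulate into an sCP while
its total stays within the idle budget.  A single layer longer than the
budget forms its own overrunning sCP (tasks cannot be preempted), which
delays the next frame.  Greedy packing is optimal here — for contiguous
partitions, finishing each bin as late as possible never increases the bin
count.

Optional jitter adds a truncated-normal (non-negative) delay to every task,
seeded for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import USRSCError


@dataclass(frozen=True)
class TimingModel:
    """Per-frame timing in milliseconds.

    t_transfer: period of the IQ data transfer (one frame's worth).
    t_irp: image-rendering-pipeline time.
    layer_times: per-layer classification times; empty = imaging only.
    jitter_std: std of the truncated-normal additive task delay (0 = off).
    """

    t_transfer: float
    t_irp: float
    layer_times: tuple[float, ...] = field(default_factory=tuple)
    jitter_std: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_transfer <= 0 or self.t_irp <= 0:
            raise USRSCError("t_transfer and t_irp must be positive")
        if any(t <= 0 for t in self.layer_times):
            raise USRSCError("layer times must be positive")
        if self.jitter_std < 0:
            raise USRSCError("jitter_std must be >= 0")

    @property
    def t_cp(self) -> float:
        return float(sum(self.layer_times))


@dataclass
class ScheduleResult:
    """Measured outcome of a simulated run (times ms, rates per second)."""

    mode: str
    display_times: np.ndarray
    classification_times: np.ndarray
    f_image: float
    f_cp: float
    M: int
    overrun_count: int
    eq_residual: float | None = None  # |f_image - M * f_cp| / f_image

    def __post_init__(self) -> None:
        if np.any(np.diff(self.display_times) <= 0):
            raise USRSCError("display timestamps must be strictly increasing")


def split_pipeline(
    layer_times: "tuple[float, ...] | list[float]", idle_budget: float
) -> tuple[list[list[float]], bool]:
    """Greedily pack consecutive layers into sub-pipelines of total time
    <= ``idle_budget``.

    Returns ``(sCPs, overrun)`` where ``overrun`` flags any single layer
    exceeding the budget (it forms its own sCP — non-preemptive tasks cannot
    be cut).  Concatenating the sCPs reproduces the layer list.
    """
    if idle_budget <= 0:
        raise USRSCError("idle budget must be positive")
    layers = list(layer_times)
    if not layers:
        raise USRSCError("empty layer list")
    scps: list[list[float]] = [[]]
    total = 0.0
    overrun = False
    for t in layers:
        if t > idle_budget:
            overrun = True
        if scps[-1] and total + t > idle_budget:
            scps.append([])
            total = 0.0
        scps[-1].append(t)
        total += t
    return scps, overrun


def _mean_rate(times: np.ndarray) -> float:
    """Mean event rate in events/s from ms timestamps (0 if < 2 events)."""
    if len(times) < 2:
        return 0.0
    return 1000.0 * (len(times) - 1) / float(times[-1] - times[0])


def _task_time(nominal: float, rng: np.random.Generator | None, std: float) -> float:
    if rng is None or std == 0.0:
        return nominal
    return nominal + max(0.0, rng.normal(0.0, std))


def simulate_fsc(model: TimingModel, n_frames: int) -> ScheduleResult:
    """Frame-synchronous run: IRP then the whole CP, every frame.

    With no classifier layers this degenerates to plain imaging.  One
    classification completes per frame, so ``f_cp = f_image`` exactly.
    """
    if n_frames < 1:
        raise USRSCError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed) if model.jitter_std > 0 else None
    displays = np.empty(n_frames)
    completions = []
    gpu_free = 0.0
    for n in range(n_frames):
        start = max(n * model.t_transfer, gpu_free)
        displays[n] = start + _task_time(model.t_irp, rng, model.jitter_std)
        gpu_free = displays[n]
        if model.layer_times:
            for t in model.layer_times:
                gpu_free += _task_time(t, rng, model.jitter_std)
            completions.append(gpu_free)
    completions = np.asarray(completions)
    return ScheduleResult(
        mode="fsc",
        display_times=displays,
        classification_times=completions,
        f_image=_mean_rate(displays),
        f_cp=_mean_rate(completions),
        M=1,
        overrun_count=0,
    )


def simulate_fac(model: TimingModel, n_frames: int) -> ScheduleResult:
    """Frame-asynchronous run: one sCP per idle window.

    The CP is split against the idle budget ``t_transfer - t_irp``; each frame
    renders, then executes the next sCP in cyclic order.  With no overruns,
    imaging runs at the transfer rate and one classification completes every
    M frames.  The result reports the residual of ``f_image ~= M * f_cp``.
    """
    if n_frames < 1:
        raise USRSCError("n_frames must be >= 1")
    if not model.layer_times:
        raise USRSCError("FAC needs a classification pipeline (layer_times)")
    idle = model.t_transfer - model.t_irp
    if idle <= 0:
        raise USRSCError(
            "no idle window: t_irp >= t_transfer, FAC cannot interleave"
        )
    scps, _ = split_pipeline(model.layer_times, idle)
    M = len(scps)
    rng = np.random.default_rng(model.seed) if model.jitter_std > 0 else None
    displays = np.empty(n_frames)
    completions = []
    gpu_free = 0.0
    k = 0  # next sCP index
    overruns = 0
    for n in range(n_frames):
        start = max(n * model.t_transfer, gpu_free)
        displays[n] = start + _task_time(model.t_irp, rng, model.jitter_std)
        gpu_free = displays[n]
        for t in scps[k]:
            gpu_free += _task_time(t, rng, model.jitter_std)
        if gpu_free > (n + 1) * model.t_transfer:
            overruns += 1
        if k == M - 1:
            completions.append(gpu_free)
        k = (k + 1) % M
    completions = np.asarray(completions)
    f_image = _mean_rate(displays)
    f_cp = _mean_rate(completions)
    residual = abs(f_image - M * f_cp) / f_image if f_image > 0 and f_cp > 0 else None
    return ScheduleResult(
        mode="fac",
        display_times=displays,
        classification_times=completions,
        f_image=f_image,
        f_cp=f_cp,
        M=M,
        overrun_count=overruns,
        eq_residual=residual,
    )
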
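"""SPEN-SE-EPI sequence assembly and timing bookkeeping.

Three single-shot spin-echo EPI timelines are built from one configuration:

- ``chirp_spen``: a WURST chirped-RF excitation under a constant encoding
  gradient (imprinting the SPEN quadratic phase), a linear-term refocusing
  lobe, a slice-selective 180, and an EPI readout whose SPEN-axis blips sweep
  the stationary point across the FOV;
- ``quadgrad_spen``: a short slice-selective sinc excitation, a non-selective
  180, and a quadratic-gradient event (field C*y^2 for a duration tau) that
  imprints the same quadratic phase directly, placed in the TE delay either
  after ("post") or before ("pre") the 180 — the "pre" placement inverts the
  phase parabola, which reconstruction must account for;
- ``fourier``: a conventional SE-EPI reference with the identical readout
  train, phase-encode blips replacing the SPEN encoding.

TE is measured from the excitation center to the designated echo (the ADC
center of the middle readout line) and is met exactly or a TimingError is
raised.  Every SPEN build satisfies the gradient-area condition
``|G_exc * T_exc| = integral(G_acq) dt`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import (EncodingParams, KTrajectory, QuadGradientDesign,
                       beta_from_chirp, beta_from_quadratic_gradient,
                       check_spen_condition)
from .errors import InvalidDesignError, TimingError
from .rf import (ChirpDesign, RFPulse, SincDesign, design_sinc,
                 design_wurst_chirp)

GRAD_RASTER = 1e-5   # s; gradient events snap to this raster
RF_RASTER = 1e-6     # s


@dataclass(frozen=True)
class TrapGradient:
    """Trapezoidal gradient lobe; amplitude in Hz/m (gamma*G/2pi)."""

    channel: str        # {"x", "y", "z"}
    amplitude: float    # Hz/m
    ramp_up: float      # s
    flat: float         # s
    ramp_down: float    # s

    @property
    def duration(self) -> float:
        return self.ramp_up + self.flat + self.ramp_down

    @property
    def area(self) -> float:
        """Gradient area in Hz*s/m (trapezoid rule)."""
        return self.amplitude * (self.flat + (self.ramp_up + self.ramp_down) / 2)


@dataclass(frozen=True)
class QuadGradientEvent:
    """Quadratic-field event B(y) = coefficient * y**2 for ``duration``."""

    coefficient: float   # T/m^2
    duration: float      # s


@dataclass(frozen=True)
class AdcEvent:
    num_samples: int
    dwell: float         # s

    @property
    def duration(self) -> float:
        return self.num_samples * self.dwell


@dataclass(frozen=True)
class SequenceEvent:
    """A timed sequence event.

    ``kind`` is one of {"rf", "grad_trap", "grad_quad", "adc", "delay"};
    ``payload`` is the kind-specific object (RFPulse, TrapGradient,
    QuadGradientEvent, AdcEvent or None for delays).
    """

    kind: str
    start: float
    duration: float
    payload: object = None

    def __post_init__(self):
        if self.kind == "delay":
            if self.duration < 0:
                raise InvalidDesignError("delay duration must be >= 0")
        elif self.duration <= 0:
            raise InvalidDesignError(f"{self.kind} duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


def _overlaps(a: SequenceEvent, b: SequenceEvent) -> bool:
    return a.start < b.end - 1e-12 and b.start < a.end - 1e-12


@dataclass
class EventTimeline:
    """Ordered sequence events with TE bookkeeping.

    ``mode`` is one of {"chirp_spen", "quadgrad_spen", "fourier"};
    ``trajectory`` holds the SPEN/phase-encode k-trajectory used for signal
    synthesis and ``exc_area`` the excitation-side gradient area entering the
    SPEN condition.  ``meta`` carries the derived encoding numbers.
    """

    events: list
    te: float
    mode: str
    trajectory: KTrajectory | None = None
    exc_area: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.events = sorted(
            self.events,
            key=lambda e: (e.start, e.kind,
                           getattr(e.payload, "channel", "")))
        rf = [e for e in self.events if e.kind == "rf"]
        for a, b in zip(rf, rf[1:]):
            if _overlaps(a, b):
                raise InvalidDesignError("RF events overlap")
        adc = [e for e in self.events if e.kind == "adc"]
        for a, b in zip(adc, adc[1:]):
            if _overlaps(a, b):
                raise InvalidDesignError("ADC events overlap")
        for e in self.events:
            raster = RF_RASTER if e.kind == "rf" else GRAD_RASTER
            for v in (e.start, e.duration):
                if abs(v / raster - round(v / raster)) > 1e-6:
                    raise InvalidDesignError(
                        f"{e.kind} timing {v} is not on the "
                        f"{raster * 1e6:.0f} us raster")

    @property
    def total_duration(self) -> float:
        return total_duration(self)


def total_duration(t: EventTimeline) -> float:
    """End of the last event minus the start of the first (0 when empty)."""
    if not t.events:
        return 0.0
    return max(e.end for e in t.events) - min(e.start for e in t.events)


@dataclass(frozen=True)
class SequenceConfig:
    """Shared configuration for the three sequence builders.

    Defaults give a 64x64 single-shot readout at TE = 60 ms over a 220 mm
    FOV, a 50 kHz / 4 ms WURST-40 chirp (the excitation gradient is derived
    as bandwidth/FOV unless given), and a 313 mT/m^2 / 5 ms quadratic
    gradient event.  ``matched_beta=True`` designs the quadratic-gradient
    acquisition for the same beta as the chirp variant so the two forward
    operators are directly comparable; the quadratic event itself always
    carries the configured coefficient and duration.
    """

    matrix: int = 64
    fov: float = 0.22                 # m
    te: float = 60e-3                 # s
    esp: float = 500e-6               # s, echo spacing
    dwell: float = 5e-6               # s per readout sample
    bandwidth: float = 50e3           # Hz chirp sweep
    chirp_duration: float = 4e-3      # s
    wurst_order: float = 40.0
    excitation_gradient: float | None = None   # Hz/m; None -> bandwidth/fov
    quad_coefficient: float = 0.313   # T/m^2
    quad_duration: float = 5e-3       # s
    placement: str = "post"           # quad event: {"post", "pre"}
    matched_beta: bool = True
    sinc_duration: float = 3e-3       # s
    sinc_tbw: float = 4.0
    slice_thickness: float = 5e-3     # m
    refocus_duration: float = 2.5e-3  # s, selective 180
    hard_refocus_duration: float = 1e-3  # s, non-selective 180
    calibration: str = "analytic"

    @property
    def g_exc(self) -> float:
        if self.excitation_gradient is not None:
            return self.excitation_gradient
        return self.bandwidth / self.fov

    @property
    def beta_chirp(self) -> float:
        return beta_from_chirp(self.g_exc, self.bandwidth,
                               self.chirp_duration)


_RAMP = 1e-4          # s, default gradient ramp
_RO_RAMP = 5e-5       # s, readout-lobe ramp
_BLIP = 8e-5          # s, blip duration (20/40/20 us)
_PREPHASE = 1e-3      # s, prephaser duration
_ADC_OFFSET = None    # computed per layout


def _trap_for_area(channel: str, area: float, ramp: float,
                   flat: float) -> TrapGradient:
    amp = area / (flat + ramp)
    return TrapGradient(channel=channel, amplitude=amp, ramp_up=ramp,
                        flat=flat, ramp_down=ramp)


def _readout_train(cfg: SequenceConfig, t0: float, blip_areas: np.ndarray
                   ) -> tuple[list, np.ndarray]:
    """EPI readout train: alternating readout lobes, ADCs, encode blips.

    ``blip_areas`` (Hz*s/m, length n-1) are played between lines on the y
    channel.  Returns the events and the ADC center times.
    """
    n = cfg.matrix
    adc_dur = n * cfg.dwell
    flat = adc_dur
    if 2 * _RO_RAMP + flat > cfg.esp - _BLIP + 1e-12:
        raise TimingError("echo spacing too short for the readout lobe")
    area_x = n / cfg.fov                      # full kx coverage, Hz*s/m
    amp_x = area_x / flat
    events = []
    centers = np.empty(n)
    for i in range(n):
        ls = t0 + i * cfg.esp
        sign = 1 if i % 2 == 0 else -1
        events.append(SequenceEvent(
            "grad_trap", ls, 2 * _RO_RAMP + flat,
            TrapGradient("x", sign * amp_x, _RO_RAMP, flat, _RO_RAMP)))
        events.append(SequenceEvent(
            "adc", ls + _RO_RAMP, adc_dur, AdcEvent(n, cfg.dwell)))
        centers[i] = ls + _RO_RAMP + adc_dur / 2
        if i < n - 1:
            blip = _trap_for_area("y", blip_areas[i], 2e-5, 4e-5)
            events.append(SequenceEvent(
                "grad_trap", ls + cfg.esp - _BLIP, _BLIP, blip))
    return events, centers


def _common_timing(cfg: SequenceConfig, t_exc: float) -> tuple[float, float]:
    """(180 center, train start) honoring the TE definition."""
    n = cfg.matrix
    adc_center_off = _RO_RAMP + n * cfg.dwell / 2
    t180 = t_exc + cfg.te / 2
    t_train = t_exc + cfg.te - (n // 2) * cfg.esp - adc_center_off
    return t180, t_train


def _spen_areas(beta: float, fov: float, n: int) -> tuple[float, np.ndarray]:
    """Prephase area and per-blip areas (Hz*s/m) for a SPEN sweep.

    Prephase sets k0 = +beta*fov; n-1 equal blips sweep k down to -beta*fov,
    so the stationary point crosses the FOV edge-to-edge.
    """
    k0 = beta * fov
    dk = 2 * k0 / (n - 1)
    return k0 / (2 * np.pi), np.full(n - 1, -dk / (2 * np.pi))


def _spen_trajectory(beta: float, fov: float, n: int, esp: float,
                     times: np.ndarray) -> KTrajectory:
    k0 = beta * fov
    k = np.linspace(k0, -k0, n)
    return KTrajectory(samples=k, sample_times=times, prephase=k0,
                       acq_gradient_area=2 * abs(k0) / (2 * np.pi))


def build_chirp_spen_se_epi(config: SequenceConfig | None = None
                            ) -> EventTimeline:
    """Chirped-RF SPEN-SE-EPI timeline (swept excitation under a gradient)."""
    cfg = config or SequenceConfig()
    n = cfg.matrix
    chirp = design_wurst_chirp(
        ChirpDesign(bandwidth=cfg.bandwidth, duration=cfg.chirp_duration,
                    wurst_order=cfg.wurst_order),
        calibration=cfg.calibration)
    beta = cfg.beta_chirp
    events = []
    # excitation gradient flat during the chirp
    events.append(SequenceEvent(
        "grad_trap", 0.0, 2 * _RAMP + cfg.chirp_duration,
        TrapGradient("y", cfg.g_exc, _RAMP, cfg.chirp_duration, _RAMP)))
    events.append(SequenceEvent("rf", _RAMP, cfg.chirp_duration, chirp))
    t_exc = _RAMP + cfg.chirp_duration / 2
    exc_end = 2 * _RAMP + cfg.chirp_duration
    # linear-term refocusing lobe: cancels the beta*fov*y ramp of the
    # encoded phase so the parabola vertex starts at one FOV edge
    refocus = _trap_for_area("y", -beta * cfg.fov / (2 * np.pi), _RAMP,
                             _PREPHASE - 2 * _RAMP)
    events.append(SequenceEvent("grad_trap", exc_end, _PREPHASE, refocus))
    t180, t_train = _common_timing(cfg, t_exc)
    rf180 = design_sinc(SincDesign(duration=cfg.refocus_duration,
                                   time_bandwidth=4.0, flip=np.pi))
    t180_start = t180 - cfg.refocus_duration / 2
    if t180_start < exc_end + _PREPHASE:
        raise TimingError(
            f"TE {cfg.te * 1e3:.1f} ms infeasible: minimum TE is "
            f"{2 * (exc_end + _PREPHASE + cfg.refocus_duration / 2 - t_exc) * 1e3:.1f} ms")
    g_slice = cfg.sinc_tbw / (cfg.slice_thickness * cfg.refocus_duration)
    events.append(SequenceEvent(
        "grad_trap", t180_start - _RAMP, 2 * _RAMP + cfg.refocus_duration,
        TrapGradient("z", g_slice, _RAMP, cfg.refocus_duration, _RAMP)))
    events.append(SequenceEvent("rf", t180_start, cfg.refocus_duration, rf180))
    pre_area, blip_areas = _spen_areas(beta, cfg.fov, n)
    t_pre = t_train - _PREPHASE
    if t_pre < t180_start + cfg.refocus_duration + _RAMP:
        raise TimingError("TE infeasible: readout train overlaps the 180")
    events.append(SequenceEvent(
        "grad_trap", t_pre, _PREPHASE,
        _trap_for_area("y", pre_area, _RAMP, _PREPHASE - 2 * _RAMP)))
    events.append(SequenceEvent(
        "grad_trap", t_pre, _PREPHASE,
        _trap_for_area("x", -n / (2 * cfg.fov), _RAMP, _PREPHASE - 2 * _RAMP)))
    train, centers = _readout_train(cfg, t_train, blip_areas)
    events += train
    traj = _spen_trajectory(beta, cfg.fov, n, cfg.esp, centers - centers[0]
                            + cfg.esp / 2)
    exc_area = cfg.g_exc * cfg.chirp_duration
    return EventTimeline(events=events, te=cfg.te, mode="chirp_spen",
                         trajectory=traj, exc_area=exc_area,
                         meta={"beta": beta, "fov": cfg.fov,
                               "esp": cfg.esp, "dwell": cfg.dwell,
                               "t_exc": t_exc})


def build_quadgrad_spen_se_epi(config: SequenceConfig | None = None
                               ) -> EventTimeline:
    """Quadratic-gradient SPEN-SE-EPI timeline.

    The quadratic event is placed in the TE delay after the 180
    (``placement="post"``) or before it (``"pre"``, inverting the phase
    parabola: reconstruction must use the inverted kernel).
    """
    cfg = config or SequenceConfig()
    n = cfg.matrix
    if cfg.placement not in ("post", "pre"):
        raise InvalidDesignError("placement must be 'post' or 'pre'")
    quad = QuadGradientDesign(coefficient=cfg.quad_coefficient,
                              duration=cfg.quad_duration)
    beta = cfg.beta_chirp if cfg.matched_beta \
        else beta_from_quadratic_gradient(quad)
    events = []
    sinc = design_sinc(SincDesign(duration=cfg.sinc_duration,
                                  time_bandwidth=cfg.sinc_tbw))
    g_slice = cfg.sinc_tbw / (cfg.slice_thickness * cfg.sinc_duration)
    events.append(SequenceEvent(
        "grad_trap", 0.0, 2 * _RAMP + cfg.sinc_duration,
        TrapGradient("z", g_slice, _RAMP, cfg.sinc_duration, _RAMP)))
    events.append(SequenceEvent("rf", _RAMP, cfg.sinc_duration, sinc))
    t_exc = _RAMP + cfg.sinc_duration / 2
    exc_end = 2 * _RAMP + cfg.sinc_duration
    rephase = _trap_for_area("z", -g_slice * (cfg.sinc_duration + _RAMP) / 2,
                             _RAMP, 4e-4)
    events.append(SequenceEvent("grad_trap", exc_end, rephase.duration,
                                rephase))
    t180, t_train = _common_timing(cfg, t_exc)
    t180_start = t180 - cfg.hard_refocus_duration / 2
    rf180 = RFPulse(samples=np.full(
        int(round(cfg.hard_refocus_duration / RF_RASTER)),
        0.5 / cfg.hard_refocus_duration, dtype=complex), raster=RF_RASTER)
    events.append(SequenceEvent("rf", t180_start, cfg.hard_refocus_duration,
                                rf180))
    quad_ev = QuadGradientEvent(coefficient=cfg.quad_coefficient,
                                duration=cfg.quad_duration)
    t180_end = t180_start + cfg.hard_refocus_duration
    pre_start = t_train - _PREPHASE
    if cfg.placement == "post":
        q_start = t180_end
        if q_start + cfg.quad_duration > pre_start:
            raise TimingError(
                "quadratic gradient event does not fit between the 180 and "
                "the readout; increase TE")
    else:
        q_start = t180_start - cfg.quad_duration
        if q_start < exc_end + rephase.duration:
            raise TimingError(
                "quadratic gradient event does not fit before the 180; "
                "increase TE")
    events.append(SequenceEvent("grad_quad", q_start, cfg.quad_duration,
                                quad_ev))
    if t180_start < exc_end + rephase.duration:
        raise TimingError("TE infeasible for the sinc excitation block")
    pre_area, blip_areas = _spen_areas(beta, cfg.fov, n)
    events.append(SequenceEvent(
        "grad_trap", pre_start, _PREPHASE,
        _trap_for_area("y", pre_area, _RAMP, _PREPHASE - 2 * _RAMP)))
    events.append(SequenceEvent(
        "grad_trap", pre_start, _PREPHASE,
        _trap_for_area("x", -n / (2 * cfg.fov), _RAMP, _PREPHASE - 2 * _RAMP)))
    train, centers = _readout_train(cfg, t_train, blip_areas)
    events += train
    traj = _spen_trajectory(beta, cfg.fov, n, cfg.esp,
                            centers - centers[0] + cfg.esp / 2)
    # quadratic-gradient equivalent of the excitation-side area:
    # the full k coverage 2*beta*fov over 2*pi, in Hz*s/m
    exc_area = beta * cfg.fov / np.pi
    return EventTimeline(events=events, te=cfg.te, mode="quadgrad_spen",
                         trajectory=traj, exc_area=exc_area,
                         meta={"beta": beta, "fov": cfg.fov,
                               "esp": cfg.esp, "dwell": cfg.dwell,
                               "t_exc": t_exc,
                               "placement": cfg.placement,
                               "inverted_kernel": cfg.placement == "pre"})


def build_fourier_se_epi(config: SequenceConfig | None = None
                         ) -> EventTimeline:
    """Conventional Fourier SE-EPI reference with the identical readout."""
    cfg = config or SequenceConfig()
    n = cfg.matrix
    events = []
    sinc = design_sinc(SincDesign(duration=cfg.sinc_duration,
                                  time_bandwidth=cfg.sinc_tbw))
    g_slice = cfg.sinc_tbw / (cfg.slice_thickness * cfg.sinc_duration)
    events.append(SequenceEvent(
        "grad_trap", 0.0, 2 * _RAMP + cfg.sinc_duration,
        TrapGradient("z", g_slice, _RAMP, cfg.sinc_duration, _RAMP)))
    events.append(SequenceEvent("rf", _RAMP, cfg.sinc_duration, sinc))
    t_exc = _RAMP + cfg.sinc_duration / 2
    exc_end = 2 * _RAMP + cfg.sinc_duration
    rephase = _trap_for_area("z", -g_slice * (cfg.sinc_duration + _RAMP) / 2,
                             _RAMP, 4e-4)
    events.append(SequenceEvent("grad_trap", exc_end, rephase.duration,
                                rephase))
    t180, t_train = _common_timing(cfg, t_exc)
    t180_start = t180 - cfg.hard_refocus_duration / 2
    if t180_start < exc_end + rephase.duration:
        raise TimingError("TE infeasible for the sinc excitation block")
    rf180 = RFPulse(samples=np.full(
        int(round(cfg.hard_refocus_duration / RF_RASTER)),
        0.5 / cfg.hard_refocus_duration, dtype=complex), raster=RF_RASTER)
    events.append(SequenceEvent("rf", t180_start, cfg.hard_refocus_duration,
                                rf180))
    # phase-encode: prephase to -N/(2*FOV), blips of 1/FOV each
    pre_start = t_train - _PREPHASE
    events.append(SequenceEvent(
        "grad_trap", pre_start, _PREPHASE,
        _trap_for_area("y", -n / (2 * cfg.fov), _RAMP, _PREPHASE - 2 * _RAMP)))
    events.append(SequenceEvent(
        "grad_trap", pre_start, _PREPHASE,
        _trap_for_area("x", -n / (2 * cfg.fov), _RAMP, _PREPHASE - 2 * _RAMP)))
    blip_areas = np.full(n - 1, 1 / cfg.fov)
    train, centers = _readout_train(cfg, t_train, blip_areas)
    events += train
    k = 2 * np.pi * (np.arange(n) - n // 2) / cfg.fov
    traj = KTrajectory(samples=k, sample_times=centers - centers[0]
                       + cfg.esp / 2, prephase=k[0],
                       acq_gradient_area=(n - 1) / cfg.fov)
    return EventTimeline(events=events, te=cfg.te, mode="fourier",
                         trajectory=traj, exc_area=None,
                         meta={"beta": 0.0, "fov": cfg.fov,
                               "esp": cfg.esp, "dwell": cfg.dwell,
                               "t_exc": t_exc})


def extract_spen_trajectory(timeline: EventTimeline) -> KTrajectory:
    """Recompute the acquisition k-trajectory from the gradient events.

    Integrates the y-channel gradient areas played after the refocusing
    pulse (prephaser and blips; the excitation-side events set up the
    encoded phase and are not part of the acquisition sweep) and evaluates
    k at each ADC center.
    """
    rf = [e for e in timeline.events if e.kind == "rf"]
    if len(rf) < 2:
        raise InvalidDesignError("timeline has no refocusing pulse")
    t_ref_end = rf[-1].end
    traps = [e for e in timeline.events
             if e.kind == "grad_trap" and e.payload.channel == "y"
             and e.start >= t_ref_end - 1e-9]
    adcs = [e for e in timeline.events if e.kind == "adc"]
    if not adcs:
        raise InvalidDesignError("timeline has no ADC events")
    centers = np.array([e.start + e.duration / 2 for e in adcs])
    k = np.zeros(centers.size)
    for e in traps:
        done = centers >= e.end - 1e-12
        k[done] += 2 * np.pi * e.payload.area
    k0 = 2 * np.pi * traps[0].payload.area if traps else 0.0
    area = sum(abs(e.payload.area) for e in traps[1:])
    return KTrajectory(samples=k, sample_times=centers - centers[0]
                       + (timeline.meta.get("esp", 1e-3)) / 2,
                       prephase=k0, acq_gradient_area=area)


def verify_spen_condition(timeline: EventTimeline,
                          tolerance: float = 1e-6):
    """Run the excitation/acquisition area check on a built SPEN timeline."""
    if timeline.exc_area is None or timeline.trajectory is None:
        raise InvalidDesignError("timeline is not a SPEN build")
    return check_spen_condition(timeline.exc_area, timeline.trajectory,
                                tolerance)
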
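"""Event staging: colonization / control / damage calls from three channels.

The three normalized-variance series — CV current, EIS impedance magnitude,
EIS phase — each yield a changepoint, a cost-improvement and a raw-variance
change ratio.  A channel shows a "sudden change" (step) when the split
improves the no-split cost by at least ``log(4) * n`` (the improvement an
artifact-free linear drift can reach, so trends do not flag) *and* its
change ratio leaves a band around 1.  A colonization event steps all three
channels concurrently with a faradaic signature: current variance up
(R >> 1), impedance variance down, phase variance down.  Electrode damage
after colonization adds a later current-variance decrement with a
phase-variance increment; early electrode damage steps exactly two channels
(current down, phase up) with no faradaic signature; a control run steps
none.

The per-channel ratio bands differ because the phase-variance ratio of a
real colonization event is modest (≈0.7–0.8) while current and impedance
ratios move by close to an order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .changestats import ChangepointResult, single_changepoint, change_ratio
from .cvpeaks import CVSession, cv_variance_pipeline
from .eisfit import EISSession, eis_variance_series
from .imaging import GrowthCurve

__all__ = ["MonitorConfig", "ChannelEvidence", "EventClassification",
           "classify_event", "stage_experiment", "image_echem_concordance"]


@dataclass
class MonitorConfig:
    """Thresholds of the staging rules (all configurable)."""

    theta_current: float = 2.0        # ratio band for the CV current channel
    theta_impedance: float = 2.0      # ratio band for |Z| variance
    theta_phase: float = 1.1          # ratio band for phase variance
    improvement_margin_scale: float = float(np.log(4.0))   # x n samples
    concurrence_intervals: float = 2.0
    measurement_interval_s: float = 1800.0
    concordance_limit_s: float = 2.5 * 3600.0


@dataclass
class ChannelEvidence:
    change_ratio: float
    step: bool
    event_time_s: Optional[float]
    improvement: float


@dataclass
class EventClassification:
    label: str
    event_time_s: Optional[float]
    evidence: dict[str, ChannelEvidence] = field(default_factory=dict)
    image_concordance_s: Optional[float] = None
    discordant: bool = False


def _channel_evidence(result: ChangepointResult, theta: float,
                      n: int, cfg: MonitorConfig) -> ChannelEvidence:
    if result.degenerate:
        return ChannelEvidence(change_ratio=1.0, step=False,
                               event_time_s=None, improvement=0.0)
    margin = cfg.improvement_margin_scale * n
    r = result.change_ratio
    outside = r > theta or r < 1.0 / theta
    step = bool(outside and result.improvement >= margin)
    return ChannelEvidence(change_ratio=float(r), step=step,
                           event_time_s=result.time_s,
                           improvement=float(result.improvement))


def _post_step(sigma2: np.ndarray, normalized: np.ndarray, k: int,
               n_total: int, cfg: MonitorConfig,
               timestamps: np.ndarray) -> Optional[ChannelEvidence]:
    """Secondary changepoint scan on the post-event tail of a channel."""
    tail = normalized[k - 1:]
    if tail.size < 4:
        return None
    cp = single_changepoint(tail, timestamps=timestamps[k - 1:])
    r = change_ratio(sigma2[k - 1:], cp.k)
    margin = cfg.improvement_margin_scale * tail.size
    return ChannelEvidence(change_ratio=float(r),
                           step=bool(cp.improvement >= margin),
                           event_time_s=cp.time_s,
                           improvement=float(cp.improvement))


def classify_event(
    cv_result: ChangepointResult,
    z_result: ChangepointResult,
    phase_result: ChangepointResult,
    config: Optional[MonitorConfig] = None,
    cv_sigma2: Optional[np.ndarray] = None,
    cv_normalized: Optional[np.ndarray] = None,
    cv_timestamps: Optional[np.ndarray] = None,
    phase_sigma2: Optional[np.ndarray] = None,
    phase_normalized: Optional[np.ndarray] = None,
    phase_timestamps: Optional[np.ndarray] = None,
) -> EventClassification:
    """Combine the three channel changepoints into one staging call.

    The optional raw series enable the post-colonization damage check
    (current decrement + phase increment after the primary event).
    """
    cfg = config or MonitorConfig()
    n_cv = (cv_sigma2.size if cv_sigma2 is not None
            else cv_result.objective.size + 3)
    n_z = z_result.objective.size + 3
    ev = {
        "current": _channel_evidence(cv_result, cfg.theta_current, n_cv, cfg),
        "impedance": _channel_evidence(z_result, cfg.theta_impedance, n_z, cfg),
        "phase": _channel_evidence(phase_result, cfg.theta_phase, n_z, cfg),
    }
    steps = [name for name, e in ev.items() if e.step]
    faradaic = ev["current"].step and \
        ev["current"].change_ratio > cfg.theta_current

    window = cfg.concurrence_intervals * cfg.measurement_interval_s
    times = [e.event_time_s for e in ev.values() if e.step]
    concurrent = (len(times) >= 2 and
                  max(times) - min(times) <= window) if times else False

    label = "control"
    event_time: Optional[float] = None
    if len(steps) == 3 and faradaic and \
            ev["impedance"].change_ratio < 1 and \
            ev["phase"].change_ratio < 1 and concurrent:
        label = "colonization"
        event_time = ev["current"].event_time_s
    elif len(steps) >= 2 and not faradaic:
        label = "early_damage"
        event_time = min(times)
    elif faradaic and ev["impedance"].step and \
            ev["impedance"].change_ratio < 1:
        # faradaic signature with an impedance drop: colonization even if
        # the phase channel stepped elsewhere (e.g. at a later failure)
        label = "colonization"
        event_time = ev["current"].event_time_s
    elif len(steps) >= 2:
        label = "early_damage"
        event_time = min(times)
    if label == "colonization" and cv_sigma2 is not None and \
            phase_sigma2 is not None:
        # damage after colonization: later current decrement + phase increment
        cv_post = _post_step(cv_sigma2, cv_normalized, cv_result.k,
                             n_cv, cfg, cv_timestamps)
        k_ph = _nearest_index(phase_timestamps, event_time)
        ph_post = _post_step(phase_sigma2, phase_normalized, k_ph,
                             n_z, cfg, phase_timestamps)
        if cv_post is not None and ph_post is not None and \
                cv_post.step and cv_post.change_ratio < 1 and \
                ph_post.step and ph_post.change_ratio > 1:
            label = "damage_after_colonization"
            ev["current_post"] = cv_post
            ev["phase_post"] = ph_post
    return EventClassification(label=label, event_time_s=event_time,
                               evidence=ev)


def _nearest_index(timestamps: np.ndarray, t: float) -> int:
    """1-based index of the sample closest to time t."""
    return int(np.argmin(np.abs(np.asarray(timestamps) - t))) + 1


def stage_experiment(
    cv_session: CVSession,
    eis_session: EISSession,
    config: Optional[MonitorConfig] = None,
) -> EventClassification:
    """Run all three variance pipelines on paired sessions and classify."""
    cv_vs, cv_cp = cv_variance_pipeline(cv_session)
    (z_vs, z_cp), (ph_vs, ph_cp) = eis_variance_series(eis_session)
    return classify_event(
        cv_cp, z_cp, ph_cp, config,
        cv_sigma2=cv_vs.sigma2, cv_normalized=cv_vs.normalized,
        cv_timestamps=cv_vs.timestamps,
        phase_sigma2=ph_vs.sigma2, phase_normalized=ph_vs.normalized,
        phase_timestamps=ph_vs.timestamps,
    )


def image_echem_concordance(
    image_curve: Optional[GrowthCurve],
    event: EventClassification,
    config: Optional[MonitorConfig] = None,
) -> EventClassification:
    """Signed offset between the electrochemical event and image colonization.

    Positive when the electrochemical event trails the image-derived
    stationary onset at the active-area segment; flags discordance beyond
    the configured limit (2.5 h by default).  Missing detections mark the
    comparison as incomparable (offset None).
    """
    cfg = config or MonitorConfig()
    if image_curve is None or image_curve.stationary_start_s is None or \
            event.event_time_s is None:
        event.image_concordance_s = None
        event.discordant = False
        return event
    offset = float(event.event_time_s - image_curve.stationary_start_s)
    event.image_concordance_s = offset
    event.discordant = abs(offset) > cfg.concordance_limit_s
    return event
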
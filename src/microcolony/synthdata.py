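"""Seeded generators for image stacks, CV sessions, and EIS sessions.

The generators emulate the raw records of a confined-growth microsystem
experiment: a bacterial front advancing along a 60-µm microchannel imaged
every 10 min, triangular-sweep voltammograms acquired three at a time every
30 min, and 25-point impedance spectra acquired every 30 min.  Each
generator is a pure function of its scenario (including the seed): repeated
calls are bit-identical, and every dataset is returned together with its
ground truth (event times, per-frame colonized fractions, injected peak
amplitudes, parameter trajectories) so recovery tests never reach into the
generator's internals.

The electrochemical waveform models are deliberately minimal.  A
voltammogram is a capacitive box (sign following the sweep direction) plus
an ohmic slope plus stray Gaussian noise; at the colonization event a
Gaussian-shaped anodic peak appears at E_pa on the forward sweep and a
cathodic peak at E_pc on the reverse sweep — abruptly, as the bacteria
establish electrical contact — and their amplitudes stabilize over the
following hours to a steady state fixed by the requested change ratios.
Impedance spectra are evaluated from the simplified equivalent circuit with
complex Gaussian noise proportional to |Z|.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation

from .cvpeaks import CVSession, VoltammogramSample
from .eisfit import (
    CircuitParams,
    EISSession,
    ImpedanceSample,
    scale_impedance,
    simplified_circuit_impedance,
)
from .imaging import FrameStack

__all__ = [
    "ImagingScenario",
    "CVScenario",
    "EISScenario",
    "ImagingGroundTruth",
    "BEFORE_COLONIZATION",
    "AFTER_COLONIZATION",
    "default_frequencies",
    "colonization_after_params",
    "generate_image_stack",
    "generate_cv_session",
    "generate_eis_session",
    "generate_paired_sessions",
]

# Circuit-parameter regimes of the microsystem before and after bacterial
# colonization (simplified equivalent circuit element means).
BEFORE_COLONIZATION = CircuitParams(R_elec=15.96e3, C_belec=0.919e-9,
                                    R_b=5.71e6, Q_i=31.37848e-9, n_i=0.77428)
AFTER_COLONIZATION = CircuitParams(R_elec=3.904e3, C_belec=6.72e-9,
                                   R_b=0.107e6, Q_i=69.78041e-9, n_i=0.865045)


def default_frequencies(n: int = 25, f_min: float = 200.0,
                        f_max: float = 50e3) -> np.ndarray:
    """The instrument's 25 log-spaced frequencies, 200 Hz to 50 kHz."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def colonization_after_params(
    variance_ratio: float = 0.15,
    params_before: CircuitParams = BEFORE_COLONIZATION,
    shape: CircuitParams = AFTER_COLONIZATION,
    frequencies: Optional[np.ndarray] = None,
) -> CircuitParams:
    """After-colonization parameters with a prescribed |Z|-variance drop.

    The after state keeps the post-colonization spectral *shape* (so phase
    behaviour matches the colonized regime) and is impedance-scaled so that
    the across-frequency variance of |Z| equals ``variance_ratio`` times
    the before-state variance, in closed form: scaling every impedance by c
    scales that variance by c^2.
    """
    f = default_frequencies() if frequencies is None else frequencies
    w = 2 * np.pi * f
    s_b = np.var(np.abs(simplified_circuit_impedance(params_before, w)), ddof=1)
    s_a = np.var(np.abs(simplified_circuit_impedance(shape, w)), ddof=1)
    c = float(np.sqrt(variance_ratio * s_b / s_a))
    return scale_impedance(shape, c)


# --- imaging ---------------------------------------------------------------


@dataclass
class ImagingScenario:
    """Conditions of one microchannel-segment time-lapse.

    Geometry is expressed in pixels at the instrument's 4 px/µm scale: a
    60-µm channel is 240 px wide, a 300-µm segment 1200 px long.  The
    colonization front enters at ``front_arrival_time_s`` and traverses the
    segment in ``colonization_duration_s`` (nominal 3900 s = 65 min).
    ``border_offset_fraction`` is the fraction of the analysed crop that the
    channel borders and static image artifacts contribute to the segmented
    area even without bacteria (nominal 0.30).
    """

    channel_width_px: int = 240
    segment_length_px: int = 1200
    frame_interval_s: float = 600.0
    pixel_scale: float = 4.0
    segment_offset_mm: float = 1.5
    front_arrival_time_s: float = 1800.0
    colonization_duration_s: float = 3900.0
    border_offset_fraction: float = 0.30
    scouting_colony_rate: float = 0.5
    noise_sd: float = 2.0
    crop_margin_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_width_px <= 0 or self.segment_length_px <= 0:
            raise ValueError("dimensions must be positive")
        if self.frame_interval_s <= 0 or self.colonization_duration_s <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.border_offset_fraction < 1:
            raise ValueError("border_offset_fraction must lie in [0, 1)")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


@dataclass
class ImagingGroundTruth:
    """Truth emitted with a generated stack."""

    colonized_fraction: np.ndarray     # per frame, over the analysis crop
    front_position_px: np.ndarray      # per frame
    arrival_time_s: float
    colonization_duration_s: float
    border_rows: tuple[int, int]       # first row of each 2-px border line
    crop_rows: tuple[int, int]         # analysis crop row range (inclusive)


_BG_LEVEL = 200.0
_BORDER_LEVEL = 60.0
_TEXTURE_AMP = 45.0
_LINE_PX = 2                     # border line thickness
_HALO = 2                        # reach of the 5x5 texture window around a
                                 # textured region (its dilation radius)
_STRUCT = np.ones((2 * _HALO + 1, 2 * _HALO + 1), dtype=bool)


def _disk_mask(shape, centers, radii) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for (r, c), rad in zip(centers, radii):
        r0, r1 = max(0, int(r - rad)), min(shape[0], int(r + rad) + 1)
        c0, c1 = max(0, int(c - rad)), min(shape[1], int(c + rad) + 1)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.ogrid[r0:r1, c0:c1]
        m[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2
    return m


def generate_image_stack(
    scenario: ImagingScenario, n_frames: int
) -> tuple[FrameStack, ImagingGroundTruth]:
    """Render a seeded time-lapse of one microchannel segment.

    Frames hold two dark border lines delimiting the channel, a static
    artifact field, a colonization front advancing left to right, and
    Poisson-seeded scouting colonies ahead of the front; bacteria are
    rendered as clipped-Gaussian granular texture.  Ground truth (and the
    artifact calibration towards ``border_offset_fraction``) counts the
    texture-visible area: each textured region plus the halo that a local
    5x5-window statistic responds in.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    H = sc.channel_width_px + 2 * 30          # 30-px outside margin per side
    W = sc.segment_length_px
    r0 = 30                                    # first row of top border line
    r1 = r0 + _LINE_PX + sc.channel_width_px   # first row of bottom line
    crop_lo = r0 - sc.crop_margin_px
    crop_hi = r1 + _LINE_PX - 1 + sc.crop_margin_px
    crop = np.s_[crop_lo: crop_hi + 1, :]
    crop_area = (crop_hi - crop_lo + 1) * W

    border_mask = np.zeros((H, W), dtype=bool)
    border_mask[r0: r0 + _LINE_PX] = True
    border_mask[r1: r1 + _LINE_PX] = True
    # the local-variance texture statistic responds in a halo around lines
    textured_border = np.zeros((H, W), dtype=bool)
    textured_border[r0 - _HALO: r0 + _LINE_PX + _HALO] = True
    textured_border[r1 - _HALO: r1 + _LINE_PX + _HALO] = True

    # static artifact field: add textured disks until the empty-frame
    # texture-visible coverage (disk + window halo) of the crop reaches
    # the requested offset fraction
    interior = np.s_[r0 + _LINE_PX: r1, :]
    truth_empty = textured_border.copy()
    target = sc.border_offset_fraction * crop_area
    artifact_mask = np.zeros((H, W), dtype=bool)
    max_disks = 100_000
    for _ in range(max_disks):
        if truth_empty[crop].sum() >= target:
            break
        rr = rng.uniform(r0 + _LINE_PX + 3, r1 - 3)
        cc = rng.uniform(0, W)
        rad = rng.uniform(2.0, 5.0)
        m = _disk_mask((H, W), [(rr, cc)], [rad])
        artifact_mask |= m
        truth_empty |= _disk_mask((H, W), [(rr, cc)], [rad + _HALO])

    # scouting colonies: Poisson count per frame, seeded ahead of the front
    times = np.arange(n_frames) * sc.frame_interval_s
    front = np.clip(
        (times - sc.front_arrival_time_s) / sc.colonization_duration_s,
        0.0, 1.0,
    ) * W

    frames: list[np.ndarray] = []
    fractions = np.empty(n_frames)
    scout_mask = np.zeros((H, W), dtype=bool)
    for idx in range(n_frames):
        x = front[idx]
        n_scouts = rng.poisson(sc.scouting_colony_rate)
        for _ in range(n_scouts):
            if x >= W - 5:
                break
            cc = rng.uniform(x + 5, min(x + 200, W))
            rr = rng.uniform(r0 + _LINE_PX + 4, r1 - 4)
            scout_mask |= _disk_mask((H, W), [(rr, cc)], [rng.uniform(3, 6)])
        bact_mask = np.zeros((H, W), dtype=bool)
        bact_mask[interior] = np.arange(W)[None, :] < x
        bact_mask |= scout_mask
        bact_mask &= ~border_mask

        img = np.full((H, W), _BG_LEVEL)
        img[border_mask] = _BORDER_LEVEL
        texture = np.abs(rng.normal(0.0, _TEXTURE_AMP, size=(H, W)))
        textured = artifact_mask | bact_mask
        img[textured] -= texture[textured]
        img += rng.normal(0.0, sc.noise_sd, size=(H, W))
        frames.append(np.clip(img, 0, 255).astype(np.uint8))

        truth = truth_empty | binary_dilation(bact_mask, structure=_STRUCT)
        fractions[idx] = truth[crop].sum() / crop_area

    stack = FrameStack(frames=frames, timestamps=times,
                       pixel_scale=sc.pixel_scale,
                       segment_offset_mm=sc.segment_offset_mm)
    gt = ImagingGroundTruth(
        colonized_fraction=fractions, front_position_px=front,
        arrival_time_s=sc.front_arrival_time_s,
        colonization_duration_s=sc.colonization_duration_s,
        border_rows=(r0, r1), crop_rows=(crop_lo, crop_hi),
    )
    return stack, gt


# --- cyclic voltammetry ----------------------------------------------------


@dataclass
class CVScenario:
    """Conditions of one CV monitoring session.

    Baseline currents follow a capacitive box (+/- the capacitive current
    by sweep direction) plus an ohmic slope.  At ``colonization_time_s``
    faradaic peaks appear at ``E_pa``/``E_pc``: the electrical contact is
    abrupt (``contact_fraction`` of the steady state immediately) and the
    signal then stabilizes over ``ramp_duration_s``.  Steady-state peak
    currents are the requested change ratios times the pre-event current
    magnitude at those potentials.
    """

    potential_range: tuple[float, float] = (-0.5, 0.5)
    points_per_sweep: int = 201
    scan_rate: float = 0.05
    sweeps_per_timepoint: int = 3
    measurement_interval_s: float = 1800.0
    baseline_capacitive_current: float = 2e-9
    baseline_resistive_slope: float = 2e-8
    stray_noise_sd: float = 1e-10
    colonization_time_s: float = float("inf")
    anodic_change_ratio: float = 8.29
    cathodic_change_ratio: float = 6.07
    E_pa: float = 0.1398
    E_pc: float = -0.20455
    peak_width: float = 0.045
    ramp_duration_s: float = 7200.0
    contact_fraction: float = 0.8
    amp_noise_sd: float = 0.10        # per-sweep faradaic amplitude scatter
    damage_mode: str = "none"             # 'none' | 'electrode_damage'
    damage_time_s: Optional[float] = None
    damage_floor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_pc >= self.E_pa:
            raise ValueError("require E_pc < E_pa")
        if self.anodic_change_ratio <= 1 or self.cathodic_change_ratio <= 1:
            raise ValueError("change ratios must exceed 1")
        if self.points_per_sweep < 3:
            raise ValueError("points_per_sweep must be >= 3")
        if self.damage_mode not in ("none", "electrode_damage"):
            raise ValueError(f"unknown damage_mode {self.damage_mode!r}")


def triangular_grid(lo: float, hi: float, n_points: int) -> np.ndarray:
    """Triangular potential grid lo -> hi -> lo over ``n_points`` samples."""
    n_fwd = n_points // 2 + 1
    fwd = np.linspace(lo, hi, n_fwd)
    step = (hi - lo) / (n_fwd - 1)
    rev = hi - step * np.arange(1, n_points - n_fwd + 1)
    return np.concatenate([fwd, rev])


def _rise(t: np.ndarray | float, t0: float, ramp: float,
          contact: float = 0.8) -> np.ndarray:
    # abrupt jump to partial contact at the event, then a saturating
    # stabilization tail: ~95% of the residual gap closes within the ramp
    t = np.asarray(t, dtype=float)
    tail = 1.0 - np.exp(-np.clip(t - t0, 0.0, None) / (ramp / 3.0))
    return np.where(t < t0, 0.0, contact + (1.0 - contact) * tail)


def generate_cv_session(
    scenario: CVScenario, total_duration_s: float
) -> tuple[CVSession, dict]:
    """Simulate a CV monitoring session; returns (session, ground truth)."""
    sc = scenario
    if total_duration_s < sc.measurement_interval_s:
        raise ValueError("session shorter than one measurement interval")
    rng = np.random.default_rng(sc.seed)
    lo, hi = sc.potential_range
    pot = triangular_grid(lo, hi, sc.points_per_sweep)
    fwd = np.diff(pot, prepend=pot[0] - 1) > 0

    base = np.where(fwd, sc.baseline_capacitive_current,
                    -sc.baseline_capacitive_current)
    base = base + sc.baseline_resistive_slope * pot

    j_pa = int(np.argmin(np.where(fwd, np.abs(pot - sc.E_pa), np.inf)))
    j_pc = int(np.argmin(np.where(~fwd, np.abs(pot - sc.E_pc), np.inf)))
    b_pa, b_pc = base[j_pa], base[j_pc]
    amp_a = sc.anodic_change_ratio * abs(b_pa) - b_pa       # > 0
    amp_c = -sc.cathodic_change_ratio * abs(b_pc) - b_pc    # < 0
    shape_a = np.where(fwd, np.exp(-0.5 * ((pot - pot[j_pa]) / sc.peak_width) ** 2), 0.0)
    shape_c = np.where(~fwd, np.exp(-0.5 * ((pot - pot[j_pc]) / sc.peak_width) ** 2), 0.0)

    sweep_cycle_s = 2 * (hi - lo) / sc.scan_rate
    sweep_gap = max(sweep_cycle_s * 1.5, 60.0)
    n_timepoints = int(total_duration_s // sc.measurement_interval_s) + 1
    sweeps: list[VoltammogramSample] = []
    amps: list[tuple[float, float, float]] = []
    for m in range(n_timepoints):
        t_block = m * sc.measurement_interval_s
        for s in range(sc.sweeps_per_timepoint):
            t = t_block + s * sweep_gap
            if np.isfinite(sc.colonization_time_s):
                g = float(_rise(t, sc.colonization_time_s,
                                sc.ramp_duration_s, sc.contact_fraction))
            else:
                g = 0.0
            jit = 1.0 + rng.normal(0.0, sc.amp_noise_sd) if g > 0 else 1.0
            i = base + g * jit * (amp_a * shape_a + amp_c * shape_c)
            if sc.damage_mode == "electrode_damage" and sc.damage_time_s is not None \
                    and t >= sc.damage_time_s:
                decay = sc.damage_floor + (1 - sc.damage_floor) * np.exp(
                    -(t - sc.damage_time_s) / 3600.0)
                i = i * decay
            i = i + rng.normal(0.0, sc.stray_noise_sd, size=pot.size)
            sweeps.append(VoltammogramSample(pot.copy(), i, t))
            amps.append((t, g * amp_a, g * amp_c))
    truth = {
        "event_time_s": sc.colonization_time_s,
        "E_pa_grid": float(pot[j_pa]),
        "E_pc_grid": float(pot[j_pc]),
        "steady_anodic_ratio": sc.anodic_change_ratio,
        "steady_cathodic_ratio": sc.cathodic_change_ratio,
        "peak_amplitudes": amps,
        "damage_time_s": sc.damage_time_s,
    }
    return CVSession(sweeps), truth


# --- impedance spectroscopy ------------------------------------------------


@dataclass
class EISScenario:
    """Conditions of one EIS monitoring session.

    Circuit parameters interpolate (log-linearly) from ``params_before`` to
    ``params_after`` across ``transition_duration_s`` centred at
    ``colonization_time_s``.  Damage modes: ``post_colonization_damage``
    degrades the established electrical contact after ``damage_time_s``
    (series resistance up by ``damage_r_factor``, bacterial
    charge-transfer resistance up by ``damage_rb_factor``, raising the
    phase variance); ``early_damage`` applies a bare series-resistance
    step with no faradaic branch change and no colonization transition.
    """

    frequencies: np.ndarray = field(default_factory=default_frequencies)
    params_before: CircuitParams = field(default_factory=lambda: BEFORE_COLONIZATION)
    params_after: Optional[CircuitParams] = None
    colonization_time_s: float = float("inf")
    transition_duration_s: float = 1800.0
    rel_noise_sd: float = 0.01
    measurement_interval_s: float = 1800.0
    damage_mode: str = "none"   # 'none' | 'post_colonization_damage' | 'early_damage'
    damage_time_s: Optional[float] = None
    damage_r_factor: float = 5.0
    damage_rb_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.frequencies[0] < 200 - 1e-9 or self.frequencies[-1] > 50e3 + 1e-9:
            raise ValueError("frequencies must lie within [200, 50000] Hz")
        if self.rel_noise_sd < 0:
            raise ValueError("rel_noise_sd must be >= 0")
        if self.damage_mode not in ("none", "post_colonization_damage",
                                    "early_damage"):
            raise ValueError(f"unknown damage_mode {self.damage_mode!r}")
        if self.params_after is None:
            self.params_after = colonization_after_params(
                frequencies=self.frequencies,
                params_before=self.params_before)


def _interp_params(a: CircuitParams, b: CircuitParams, frac: float) -> CircuitParams:
    if frac <= 0:
        return a
    if frac >= 1:
        return b
    def geo(x, y):
        return float(np.exp((1 - frac) * np.log(x) + frac * np.log(y)))
    return CircuitParams(
        R_elec=geo(a.R_elec, b.R_elec), C_belec=geo(a.C_belec, b.C_belec),
        R_b=geo(a.R_b, b.R_b), Q_i=geo(a.Q_i, b.Q_i),
        n_i=(1 - frac) * a.n_i + frac * b.n_i,
    )


def generate_eis_session(
    scenario: EISScenario, total_duration_s: float
) -> tuple[EISSession, dict]:
    """Simulate an EIS monitoring session; returns (session, ground truth)."""
    sc = scenario
    if total_duration_s < sc.measurement_interval_s:
        raise ValueError("session shorter than one measurement interval")
    rng = np.random.default_rng(sc.seed)
    w = 2 * np.pi * sc.frequencies
    n_spectra = int(total_duration_s // sc.measurement_interval_s) + 1
    spectra: list[ImpedanceSample] = []
    trajectory: list[CircuitParams] = []
    for m in range(n_spectra):
        t = m * sc.measurement_interval_s
        if sc.damage_mode == "early_damage":
            p = sc.params_before
        else:
            if np.isfinite(sc.colonization_time_s):
                if sc.transition_duration_s > 0:
                    frac = (t - sc.colonization_time_s
                            + sc.transition_duration_s / 2) / sc.transition_duration_s
                else:
                    frac = 1.0 if t >= sc.colonization_time_s else 0.0
                p = _interp_params(sc.params_before, sc.params_after,
                                   float(np.clip(frac, 0, 1)))
            else:
                p = sc.params_before
        if sc.damage_time_s is not None and t >= sc.damage_time_s:
            if sc.damage_mode == "post_colonization_damage":
                p = replace(p, R_elec=p.R_elec * sc.damage_r_factor,
                            R_b=p.R_b * sc.damage_rb_factor)
            elif sc.damage_mode == "early_damage":
                p = replace(p, R_elec=p.R_elec * sc.damage_r_factor)
        z = simplified_circuit_impedance(p, w)
        noise = rng.normal(0, sc.rel_noise_sd, size=(2, w.size))
        z = z + np.abs(z) * (noise[0] + 1j * noise[1])
        spectra.append(ImpedanceSample(sc.frequencies.copy(), z, float(t)))
        trajectory.append(p)
    truth = {
        "event_time_s": sc.colonization_time_s,
        "damage_time_s": sc.damage_time_s,
        "params_trajectory": trajectory,
        "params_before": sc.params_before,
        "params_after": sc.params_after,
    }
    return EISSession(spectra), truth


# --- paired panels ---------------------------------------------------------


def generate_paired_sessions(
    kind: str,
    seed: int,
    total_duration_s: float = 30 * 3600.0,
    event_time_s: float = 6 * 3600.0,
    damage_time_s: float = 20 * 3600.0,
) -> tuple[CVSession, EISSession, dict]:
    """CV + EIS sessions for one experiment class, on a shared timeline.

    ``kind`` is one of ``colonization``, ``control``,
    ``damage_after_colonization``, ``early_damage``.
    """
    if kind == "colonization":
        cv_sc = CVScenario(colonization_time_s=event_time_s, seed=seed)
        eis_sc = EISScenario(colonization_time_s=event_time_s, seed=seed + 1)
    elif kind == "control":
        cv_sc = CVScenario(seed=seed)
        eis_sc = EISScenario(seed=seed + 1)
    elif kind == "damage_after_colonization":
        cv_sc = CVScenario(colonization_time_s=event_time_s,
                           damage_mode="electrode_damage",
                           damage_time_s=damage_time_s, seed=seed)
        eis_sc = EISScenario(colonization_time_s=event_time_s,
                             damage_mode="post_colonization_damage",
                             damage_time_s=damage_time_s, seed=seed + 1)
    elif kind == "early_damage":
        cv_sc = CVScenario(damage_mode="electrode_damage",
                           damage_time_s=damage_time_s, seed=seed)
        eis_sc = EISScenario(damage_mode="early_damage",
                             damage_time_s=damage_time_s, seed=seed + 1)
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")
    cv, cv_truth = generate_cv_session(cv_sc, total_duration_s)
    eis, eis_truth = generate_eis_session(eis_sc, total_duration_s)
    truth = {"kind": kind, "cv": cv_truth, "eis": eis_truth,
             "event_time_s": event_time_s if kind.startswith(("colonization",
                                                              "damage")) else None,
             "damage_time_s": damage_time_s if "damage" in kind else None}
    return cv, eis, truth
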
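"""Cyclic-voltammetry analytics: redox peak identification and change ratios.

Each acquisition records three triangular sweeps (-0.5 V -> 0.5 V -> -0.5 V,
201 potential points).  The per-potential variance of the current across
sweeps highlights the potentials at which the response changes between
acquisitions; local extrema of that variance curve ("primary peaks"), plus
extrema of derivative ratios ("secondary peaks"), are clustered on the
potential axis to identify the anodic/cathodic redox pair.  Peak currents
before and after the colonization event give the anodic and cathodic change
ratios.

Sign convention: anodic (oxidation) currents positive, the forward sweep is
the increasing-potential half of the triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changestats import SampleSeries, sample_variance, variance_pipeline

__all__ = [
    "VoltammogramSample",
    "CVSession",
    "Peak",
    "PeakSet",
    "PotentialReference",
    "split_by_changepoint",
    "per_potential_variance",
    "find_primary_peaks",
    "find_secondary_peaks",
    "cluster_peaks",
    "peak_change_ratio",
    "formal_potential",
    "agcl_correction",
    "mean_cv_peak_stats",
    "cv_variance_pipeline",
]

#: floor for derivative denominators in secondary peak detection
DERIVATIVE_FLOOR = 1e-15


@dataclass
class VoltammogramSample:
    """One CV sweep: potential grid (V), currents (A), timestamp (s)."""

    potentials: np.ndarray
    currents: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape:
            raise ValueError("potential and current grids differ in shape")
        if self.potentials.size < 3:
            raise ValueError("a sweep needs at least 3 points")

    @property
    def forward(self) -> np.ndarray:
        """Boolean mask of the increasing-potential (forward) half."""
        d = np.diff(self.potentials, prepend=self.potentials[0] - 1e-12)
        return d > 0


@dataclass
class CVSession:
    """Ordered sweeps sharing a single potential grid."""

    sweeps: list[VoltammogramSample]

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("empty session")
        g0 = self.sweeps[0].potentials
        for s in self.sweeps[1:]:
            if not np.allclose(s.potentials, g0):
                raise ValueError("sweeps use different potential grids")
        ts = self.timestamps
        if np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be non-decreasing")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.sweeps])

    @property
    def potentials(self) -> np.ndarray:
        return self.sweeps[0].potentials

    def current_matrix(self) -> np.ndarray:
        return np.stack([s.currents for s in self.sweeps])

    def mean_currents(self) -> np.ndarray:
        return self.current_matrix().mean(axis=0)


@dataclass
class Peak:
    E: float                 # potential, V
    i: float                 # current of the mean voltammogram, A
    polarity: str            # 'anodic' | 'cathodic'
    tier: str                # 'primary' | 'secondary'
    epoch: str = ""          # 'before' | 'after' (optional context)
    index: int = -1          # grid index of the peak


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def by_polarity(self, polarity: str) -> list[Peak]:
        return [p for p in self.peaks if p.polarity == polarity]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PotentialReference:
    """Internal-standard referencing of potentials to Ag/AgCl."""

    measured_formal_potential: float
    standard_vs_agcl: float = 0.241
    correction: float = 0.0

    def __post_init__(self) -> None:
        self.correction = self.standard_vs_agcl - self.measured_formal_potential


def split_by_changepoint(
    session: CVSession, event_time_s: float
) -> tuple[CVSession, CVSession]:
    """Partition sweeps strictly before vs. at-or-after the event time."""
    before = [s for s in session.sweeps if s.timestamp < event_time_s]
    after = [s for s in session.sweeps if s.timestamp >= event_time_s]
    if not before or not after:
        raise ValueError("event time leaves an empty partition")
    return CVSession(before), CVSession(after)


def per_potential_variance(group: CVSession) -> np.ndarray:
    """Unbiased variance of the current across sweeps at each potential."""
    mat = group.current_matrix()
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 sweeps")
    return np.array([sample_variance(mat[:, j]) for j in range(mat.shape[1])])


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    idx = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
    return idx


def _peaks_from_indices(
    idx: np.ndarray, group: CVSession, tier: str, epoch: str
) -> PeakSet:
    pot = group.potentials
    mean_i = group.mean_currents()
    fwd = group.sweeps[0].forward
    peaks = [
        Peak(E=float(pot[j]), i=float(mean_i[j]),
             polarity="anodic" if fwd[j] else "cathodic",
             tier=tier, epoch=epoch, index=int(j))
        for j in idx
    ]
    return PeakSet(peaks)


def find_primary_peaks(
    variance_curve: np.ndarray, group: CVSession, epoch: str = ""
) -> PeakSet:
    """Strict local maxima of the per-potential variance curve.

    Each extremum is mapped back to the (E, i) of the group's mean
    voltammogram; polarity follows the sweep direction at that index.
    """
    v = np.asarray(variance_curve, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 potential points")
    return _peaks_from_indices(_local_maxima(v), group, "primary", epoch)


def find_secondary_peaks(
    variance_curve: np.ndarray, group: CVSession, epoch: str = ""
) -> PeakSet:
    """Extrema of variance/derivative ratios, for peaks the primary survey
    misses.

    Uses |s2/s2'| and |s2'/s2''| with central-difference derivatives on the
    potential grid; denominators are floored to avoid division blow-ups on
    flat curves.
    """
    v = np.asarray(variance_curve, dtype=float)
    if v.size < 7:
        raise ValueError("need at least 7 potential points")
    # index-based central differences; the grid is uniform per half sweep
    d1 = np.gradient(v)
    d2 = np.gradient(d1)
    r1 = np.abs(v) / np.maximum(np.abs(d1), DERIVATIVE_FLOOR)
    r2 = np.abs(d1) / np.maximum(np.abs(d2), DERIVATIVE_FLOOR)
    # a point whose denominator sat at the floor has no meaningful ratio
    # (flat or linear stretch): it cannot be a candidate
    cand1 = np.array([j for j in _local_maxima(r1)
                      if np.abs(d1[j]) > DERIVATIVE_FLOOR], dtype=int)
    cand2 = np.array([j for j in _local_maxima(r2)
                      if np.abs(d2[j]) > DERIVATIVE_FLOOR], dtype=int)
    idx = np.union1d(cand1, cand2)
    return _peaks_from_indices(idx.astype(int), group, "secondary", epoch)


def cluster_peaks(candidates: PeakSet, gap_V: float = 0.05) -> PeakSet:
    """Single-linkage 1-D clustering of peak candidates on potential.

    Clusters are formed per polarity with the given linkage gap; the
    representative of each cluster is its highest-|i| member.  The
    highest-|i| anodic and cathodic representatives are flagged as the
    redox pair by being listed first.
    """
    survivors: list[Peak] = []
    for polarity in ("anodic", "cathodic"):
        cand = sorted(candidates.by_polarity(polarity), key=lambda p: p.E)
        if not cand:
            continue
        clusters: list[list[Peak]] = [[cand[0]]]
        for p in cand[1:]:
            if p.E - clusters[-1][-1].E <= gap_V:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        reps = [max(c, key=lambda p: abs(p.i)) for c in clusters]
        reps.sort(key=lambda p: abs(p.i), reverse=True)
        survivors.extend(reps)
    survivors.sort(key=lambda p: abs(p.i), reverse=True)
    return PeakSet(survivors)


def peak_change_ratio(
    before: CVSession, after: CVSession, peaks: PeakSet
) -> dict[str, float | None]:
    """Anodic and cathodic peak-current change ratios.

    For each polarity the clustered after-event peak fixes the potential
    index; the ratio is the mean |current| across after-event sweeps at
    that index divided by the mean |current| across before-event sweeps at
    the same index (the change-ratio construction applied at the peak
    potential).  A missing polarity maps to None.
    """
    out: dict[str, float | None] = {"anodic": None, "cathodic": None}
    for polarity in ("anodic", "cathodic"):
        cand = peaks.by_polarity(polarity)
        if not cand:
            continue
        j = cand[0].index
        i_before = np.abs(before.current_matrix()[:, j]).mean()
        i_after = np.abs(after.current_matrix()[:, j]).mean()
        if i_before == 0:
            continue
        out[polarity] = float(i_after / i_before)
    return out


def formal_potential(E_pa: float, E_pc: float) -> float:
    """Midpoint of the anodic and cathodic peak potentials."""
    if E_pc >= E_pa:
        raise ValueError("expected E_pc < E_pa")
    return 0.5 * (E_pa + E_pc)


def agcl_correction(
    measured_formal: float, standard_vs_agcl: float = 0.241
) -> PotentialReference:
    """Correction shifting measured potentials onto the Ag/AgCl scale."""
    return PotentialReference(measured_formal_potential=measured_formal,
                              standard_vs_agcl=standard_vs_agcl)


def mean_cv_peak_stats(group: CVSession) -> dict:
    """Peak currents and separation of the group's mean voltammogram.

    Anodic peak = maximum current on the forward half, cathodic = minimum on
    the reverse half.  Returns None fields when no signed extremum exists
    (flat or single-signed voltammogram).
    """
    if len(group.sweeps) < 2:
        raise ValueError("need at least 2 sweeps")
    mean_i = group.mean_currents()
    pot = group.potentials
    fwd = group.sweeps[0].forward
    out: dict = {"i_pa": None, "i_pc": None, "E_pa": None, "E_pc": None,
                 "delta_Ep": None}
    if fwd.any() and np.ptp(mean_i[fwd]) > 0:
        ja = np.nonzero(fwd)[0][int(np.argmax(mean_i[fwd]))]
        if mean_i[ja] > 0:
            out["i_pa"], out["E_pa"] = float(mean_i[ja]), float(pot[ja])
    rev = ~fwd
    if rev.any() and np.ptp(mean_i[rev]) > 0:
        jc = np.nonzero(rev)[0][int(np.argmin(mean_i[rev]))]
        if mean_i[jc] < 0:
            out["i_pc"], out["E_pc"] = float(mean_i[jc]), float(pot[jc])
    if out["E_pa"] is not None and out["E_pc"] is not None:
        out["delta_Ep"] = abs(out["E_pa"] - out["E_pc"])
    return out


def cv_variance_pipeline(session: CVSession, *, ratio_on: str = "raw"):
    """Per-sweep current variance series and its changepoint analysis."""
    series = SampleSeries([s.currents for s in session.sweeps],
                          session.timestamps)
    return variance_pipeline(series, ratio_on=ratio_on)
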
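"""Idealization of single-channel sweeps and conductance estimation.

The workflow mirrors standard outside-out patch analysis: subtract a
leak-only control sweep recorded close in time, discard points within the
noise (|I| < 3 pA), treat the surviving runs as channel openings, histogram
event amplitudes at a fixed holding potential to resolve the two open
levels, and average open-channel current across ramp sweeps to build the
single-channel I-V relation, whose inward and outward limbs are fit by
straight lines for the branch slope conductances.  The 3 pA cut leaves a
gap in the I-V relation around the reversal potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.mixture import GaussianMixture

from .synthgen import Sweep

#: noise rejection threshold in pA: points with |I| >= 3 pA are kept
DEFAULT_THRESHOLD_PA = 3.0
#: minimum event duration, about one filter rise time at 5 kHz
DEFAULT_MIN_DURATION_S = 0.5e-3


@dataclass(frozen=True)
class AmplitudeFit:
    """Gaussian-mixture description of event amplitudes at one voltage."""

    means_pA: tuple[float, ...]
    widths_pA: tuple[float, ...]
    weights: tuple[float, ...]
    conductances_pS: tuple[float, ...]
    n_components: int
    bic: tuple[float, float]

    @property
    def ratio_small_large(self) -> float | None:
        """Sub-level conductance as a fraction of the main level."""
        if self.n_components < 2:
            return None
        return self.conductances_pS[1] / self.conductances_pS[0]


@dataclass(frozen=True)
class BranchSlope:
    slope_pS: float
    stderr_pS: float
    voltage_range_mV: tuple[float, float]
    n_bins: int


@dataclass(frozen=True)
class ConductanceEstimate:
    """Branch-wise slope conductances from an averaged I-V relation."""

    negative: BranchSlope | None
    positive: BranchSlope | None


def subtract_leak(sweep: Sweep, control: Sweep) -> np.ndarray:
    """Pointwise difference between an active sweep and its leak control."""
    if sweep.protocol != control.protocol:
        raise ValueError("sweep and control must share the same protocol")
    if len(sweep.current_pA) != len(control.current_pA):
        raise ValueError("sweep and control length mismatch")
    return sweep.current_pA - control.current_pA


def detect_events(
    trace: np.ndarray,
    sample_rate_Hz: float,
    threshold_pA: float = DEFAULT_THRESHOLD_PA,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    voltage_mV: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Threshold-run event detection on a leak-subtracted trace.

    Events are maximal runs of consecutive samples with |I| >= threshold
    lasting at least ``min_duration_s``; the event amplitude is the mean
    current over the run.  Returns a table with columns ``start``, ``stop``
    (half-open sample indices), ``amplitude_pA``, ``duration_s`` and
    ``voltage_mV`` (mean command voltage over the run, when supplied).
    """
    if threshold_pA <= 0:
        raise ValueError("threshold must be positive")
    trace = np.asarray(trace, dtype=float)
    min_len = max(1, int(round(min_duration_s * sample_rate_Hz)))

    above = np.abs(trace) >= threshold_pA
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(trace)]))
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not above[a] or (b - a) < min_len:
            continue
        row = {
            "start": int(a),
            "stop": int(b),
            "amplitude_pA": float(trace[a:b].mean()),
            "duration_s": (b - a) / sample_rate_Hz,
        }
        if voltage_mV is not None:
            v = np.asarray(voltage_mV, dtype=float)
            row["voltage_mV"] = float(v[a:b].mean()) if v.ndim else float(v)
        rows.append(row)
    cols = ["start", "stop", "amplitude_pA", "duration_s"]
    if voltage_mV is not None:
        cols.append("voltage_mV")
    return pd.DataFrame(rows, columns=cols)


def fit_amplitude_states(
    events: pd.DataFrame,
    at_voltage_mV: float,
    reversal_potential_mV: float = 0.0,
    min_events: int = 50,
    random_state: int = 0,
) -> AmplitudeFit:
    """Resolve one or two open levels from event amplitudes at one voltage.

    Fits 1- and 2-component Gaussian mixtures to the event amplitudes and
    keeps the model preferred by BIC.  A second component is only accepted
    as a distinct open level when its peak is resolved - component means
    separated by more than twice the pooled component width - since
    event-mean noise scales with event duration and produces same-mean
    scale mixtures that BIC would otherwise split.  Component means are
    converted to conductances via ``|mean| / |V - V_rev| * 1e3``
    (pA/mV -> pS) and sorted so the main (larger) level comes first.
    """
    if len(events) < min_events:
        raise ValueError(f"need at least {min_events} events, got {len(events)}")
    if at_voltage_mV == reversal_potential_mV:
        raise ValueError("cannot estimate conductance at the reversal potential")
    amps = np.asarray(events["amplitude_pA"], dtype=float).reshape(-1, 1)

    fits = {}
    bics = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k, n_init=5, reg_covar=1e-6, random_state=random_state
        ).fit(amps)
        fits[k] = gm
        bics[k] = gm.bic(amps)
    k_best = 1 if bics[1] <= bics[2] else 2
    if k_best == 2:
        m = fits[2].means_.ravel()
        w = np.sqrt(fits[2].covariances_.ravel())
        if abs(m[0] - m[1]) < 2.0 * np.sqrt(w[0] ** 2 + w[1] ** 2):
            k_best = 1  # unresolved peaks: same level, heteroscedastic events
    gm = fits[k_best]

    means = gm.means_.ravel()
    widths = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(-np.abs(means))  # main level (largest |mean|) first
    means, widths, weights = means[order], widths[order], weights[order]
    drive = abs(at_voltage_mV - reversal_potential_mV)
    conductances = np.abs(means) / drive * 1e3
    return AmplitudeFit(
        means_pA=tuple(map(float, means)),
        widths_pA=tuple(map(float, widths)),
        weights=tuple(map(float, weights)),
        conductances_pS=tuple(map(float, conductances)),
        n_components=k_best,
        bic=(float(bics[1]), float(bics[2])),
    )


def _main_level_mask(
    chords_pS: np.ndarray,
    drive_mV: np.ndarray,
    min_drive_mV: float = 20.0,
    random_state: int = 0,
    min_events: int = 50,
) -> np.ndarray:
    """Keep events belonging to the main (larger) conductance level.

    Chord conductances are clustered separately on the inward and outward
    limbs (a rectifying channel has different conductances on each) with
    1- vs 2-component Gaussian mixtures selected by BIC; when two levels
    are resolved on a limb, only events assigned to the larger one are
    retained there.  Near-gap events (mean drive below ``min_drive_mV``)
    have unstable chords and are left untouched, as are limbs with few
    events or a single resolved level.
    """
    keep = np.ones(len(chords_pS), dtype=bool)
    for sign in (-1, 1):
        sel = (np.sign(drive_mV) == sign) & (np.abs(drive_mV) >= min_drive_mV)
        if sel.sum() < min_events:
            continue
        x = chords_pS[sel].reshape(-1, 1)
        fits = {
            k: GaussianMixture(
                n_components=k, n_init=5, reg_covar=1e-6, random_state=random_state
            ).fit(x)
            for k in (1, 2)
        }
        if fits[1].bic(x) <= fits[2].bic(x):
            continue
        gm = fits[2]
        main = int(np.argmax(np.abs(gm.means_.ravel())))
        keep[sel] = gm.predict(x) == main
    return keep


def average_open_iv(
    sweeps: Sequence[Sweep],
    controls: Sequence[Sweep],
    threshold_pA: float = DEFAULT_THRESHOLD_PA,
    bin_mV: float = 5.0,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    reversal_potential_mV: float = 0.0,
    keep_main_level: bool = True,
) -> pd.DataFrame:
    """Averaged open-channel I-V relation from an ensemble of ramp sweeps.

    Each sweep is leak-subtracted against its paired control; samples
    belonging to detected openings are binned by command voltage and
    averaged.  Bins where the expected current falls below the threshold
    stay empty - the characteristic gap around the reversal potential.
    With ``keep_main_level`` (the default) openings to the smaller
    sub-conductance level are excluded, so the relation describes the main
    open state only: events are classified by their chord conductance with
    a BIC-selected Gaussian mixture.  Returns a table with ``voltage_mV``
    (bin centers), ``mean_pA``, ``sd_pA`` and ``n``.
    """
    ramp = [s for s in sweeps if s.protocol.kind == "ramp"]
    if not ramp:
        raise ValueError("average_open_iv requires ramp sweeps")
    if len(sweeps) != len(controls):
        raise ValueError("each sweep needs a paired control")

    proto = ramp[0].protocol
    lo = min(proto.ramp_start_mV, proto.ramp_end_mV)
    hi = max(proto.ramp_start_mV, proto.ramp_end_mV)
    edges = np.arange(lo, hi + bin_mV / 2, bin_mV)
    centers = (edges[:-1] + edges[1:]) / 2

    ev_volts, ev_amps, ev_chords, ev_drive = [], [], [], []
    for sweep, control in zip(sweeps, controls):
        if sweep.protocol.kind != "ramp":
            continue
        corrected = subtract_leak(sweep, control)
        voltage = sweep.protocol.voltage()
        table = detect_events(
            corrected, sweep.protocol.sample_rate_Hz, threshold_pA,
            min_duration_s, voltage_mV=voltage,
        )
        for _, ev in table.iterrows():
            sl = slice(int(ev["start"]), int(ev["stop"]))
            v = voltage[sl]
            i = corrected[sl]
            drive = v - reversal_potential_mV
            ev_volts.append(v)
            ev_amps.append(i)
            ev_chords.append(1e3 * np.mean(i / drive))
            ev_drive.append(float(drive.mean()))

    if ev_volts:
        keep = (
            _main_level_mask(np.asarray(ev_chords), np.asarray(ev_drive))
            if keep_main_level
            else np.ones(len(ev_volts), dtype=bool)
        )
        volts = np.concatenate([v for v, k in zip(ev_volts, keep) if k])
        amps = np.concatenate([a for a, k in zip(ev_amps, keep) if k])
    else:
        volts = np.array([])
        amps = np.array([])

    idx = np.digitize(volts, edges) - 1
    rows = []
    for b, center in enumerate(centers):
        sel = amps[idx == b]
        rows.append(
            {
                "voltage_mV": float(center),
                "mean_pA": float(sel.mean()) if len(sel) else np.nan,
                "sd_pA": float(sel.std(ddof=1)) if len(sel) > 1 else np.nan,
                "n": int(len(sel)),
            }
        )
    return pd.DataFrame(rows)


def slope_conductance(
    iv: pd.DataFrame,
    negative_window_mV: tuple[float, float] = (-100.0, -20.0),
    positive_window_mV: tuple[float, float] = (20.0, 100.0),
    min_bins: int = 5,
    min_mean_pA: float = DEFAULT_THRESHOLD_PA + 2.0,
) -> ConductanceEstimate:
    """Branch-wise slope conductances by ordinary least squares.

    Fits I = g V + b separately on the inward (V < -20 mV) and outward
    (V > +20 mV) limbs of the averaged I-V relation.  Bins whose mean
    current magnitude is below ``min_mean_pA`` are excluded: where the
    expected current sits within ~2 pA of the detection threshold, the
    per-point cut truncates the noise distribution and biases the bin mean,
    so such bins belong to the gap rather than to the linear limb.  A
    branch with fewer than ``min_bins`` usable bins is reported absent
    (None).
    """

    def _branch(window: tuple[float, float]) -> BranchSlope | None:
        lo, hi = window
        sel = iv[(iv["voltage_mV"] >= lo) & (iv["voltage_mV"] <= hi) & (iv["n"] > 0)]
        sel = sel.dropna(subset=["mean_pA"])
        sel = sel[sel["mean_pA"].abs() >= min_mean_pA]
        if len(sel) < min_bins:
            return None
        res = scipy.stats.linregress(sel["voltage_mV"], sel["mean_pA"])
        return BranchSlope(
            slope_pS=float(res.slope * 1e3),  # pA/mV -> pS
            stderr_pS=float(res.stderr * 1e3),
            voltage_range_mV=(float(sel["voltage_mV"].min()), float(sel["voltage_mV"].max())),
            n_bins=len(sel),
        )

    return ConductanceEstimate(
        negative=_branch(negative_window_mV), positive=_branch(positive_window_mV)
    )
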
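"""Synthetic single-channel and whole-cell patch-clamp data generator.

The generator reproduces the statistical structure the downstream analyses
assume: a two-state (closed/open) Markov gating scheme where each opening
lands on one of two conductance levels (a main level and a ~60% sub-level),
ohmic open-channel current around a 0 mV reversal in symmetrical solutions,
a linear leak, and Gaussian recording noise shaped by a 4-pole low-pass
Bessel filter (5 kHz at a 10 kHz sampling rate, mimicking an Axopatch-style
chain).  Rectifying pore mutants are modeled phenomenologically through
separate negative- and positive-branch conductances applied on voltage
ramps.

Whole-cell divalent-block families are generated directly from the
voltage-dependent Hill block model in :mod:`trpa1pore.blockfit`, so a
noiseless dataset is exactly invertible by the fitter.

``fixture_registry`` packages the recording conditions used throughout:
wild-type and mutant channels in symmetrical Cs+ at several concentrations,
with and without Ba2+.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import scipy.signal

from .blockfit import BlockModelParams, hill_block_fraction

CLOSED, OPEN_LARGE, OPEN_SMALL = 0, 1, 2

#: oversampling factor for noise synthesis, so the anti-alias/Bessel filter
#: is well-posed even when the cutoff sits at the output Nyquist frequency
_NOISE_OVERSAMPLE = 4


@dataclass(frozen=True)
class VoltageProtocol:
    """Command-voltage waveform of one episodic sweep."""

    kind: Literal["hold", "ramp"]
    hold_voltage_mV: float = 0.0
    ramp_start_mV: float = -100.0
    ramp_end_mV: float = 100.0
    duration_s: float = 0.2
    sample_rate_Hz: float = 10_000.0
    filter_cutoff_Hz: float = 5_000.0

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "ramp"):
            raise ValueError("protocol kind must be 'hold' or 'ramp'")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate_Hz < 2 * self.filter_cutoff_Hz:
            raise ValueError("sample rate must be at least twice the filter cutoff")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_Hz))

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_Hz

    def voltage(self) -> np.ndarray:
        """Per-sample command voltage in mV (linear ramp or constant hold)."""
        if self.kind == "hold":
            return np.full(self.n_samples, self.hold_voltage_mV)
        return np.linspace(self.ramp_start_mV, self.ramp_end_mV, self.n_samples)


#: ramp from -100 to +100 mV in 200 ms, sampled at 10 kHz / 5 kHz Bessel
RAMP_PROTOCOL = VoltageProtocol(kind="ramp")


def hold_protocol(voltage_mV: float, duration_s: float = 0.5) -> VoltageProtocol:
    """Constant-voltage protocol (e.g. -60 mV for amplitude histograms)."""
    return VoltageProtocol(kind="hold", hold_voltage_mV=voltage_mV, duration_s=duration_s)


@dataclass(frozen=True)
class BranchConductances:
    """Separate slope conductances for the inward and outward limbs.

    Applied only on ramp protocols; they encode empirically rectifying
    mutants for which the negative- and positive-branch slope conductances
    are reported separately.
    """

    negative_pS: float
    positive_pS: float

    def __post_init__(self) -> None:
        if self.negative_pS < 0 or self.positive_pS < 0:
            raise ValueError("branch conductances must be >= 0")


@dataclass(frozen=True)
class GatingFixture:
    """Generator truth for one recording condition."""

    name: str
    gamma_large_pS: float
    gamma_small_pS: float
    p_small: float = 0.3
    open_rate_per_s: float = 50.0
    close_rate_per_s: float = 50.0
    reversal_potential_mV: float = 0.0
    leak_conductance_pS: float = 20.0
    noise_rms_pA: float = 1.0
    branch_conductances: BranchConductances | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_small <= 1.0:
            raise ValueError("p_small must lie in [0, 1]")
        if self.gamma_small_pS >= self.gamma_large_pS:
            raise ValueError("gamma_small must be below gamma_large")
        if min(self.gamma_large_pS, self.gamma_small_pS, self.leak_conductance_pS) < 0:
            raise ValueError("conductances must be >= 0")
        if self.noise_rms_pA < 0:
            raise ValueError("noise_rms must be >= 0")
        if self.open_rate_per_s < 0 or self.close_rate_per_s <= 0:
            raise ValueError("rates must be positive (open_rate may be 0)")

    @property
    def sublevel_ratio(self) -> float:
        return self.gamma_small_pS / self.gamma_large_pS


@dataclass(frozen=True)
class Sweep:
    """One episodic recording: sampled current plus its protocol."""

    current_pA: np.ndarray
    protocol: VoltageProtocol
    condition: str
    blocker_concentration_mM: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.current_pA) != self.protocol.n_samples:
            raise ValueError("sample count must match protocol duration x rate")


@dataclass(frozen=True)
class BlockDataset:
    """Family of normalized I-V curves at increasing blocker concentrations.

    ``curves`` holds (concentration_mM, voltage_mV array, normalized current
    array) triples; every curve equals 1 at ``normalization_voltage_mV``.
    """

    curves: tuple[tuple[float, np.ndarray, np.ndarray], ...]
    normalization_voltage_mV: float
    reversal_potential_mV: float = 0.0

    def __post_init__(self) -> None:
        concs = [c for c, _, _ in self.curves]
        if any(c < 0 for c in concs):
            raise ValueError("blocker concentrations must be >= 0")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")


# --------------------------------------------------------------------------
# gating simulation

def simulate_gating(
    fixture: GatingFixture, protocol: VoltageProtocol, seed: int
) -> np.ndarray:
    """Sample a closed/open gating trajectory on the protocol grid.

    Continuous-time two-state Markov chain with exponential dwell times;
    each opening independently lands on the small level with probability
    ``p_small``.  Returns an int8 array of per-sample state codes
    (CLOSED / OPEN_LARGE / OPEN_SMALL).  Identical seeds give identical
    trajectories.
    """
    rng = np.random.default_rng(seed)
    n = protocol.n_samples
    states = np.zeros(n, dtype=np.int8)
    if fixture.open_rate_per_s == 0:
        return states  # closed state is absorbing

    p_open = fixture.open_rate_per_s / (
        fixture.open_rate_per_s + fixture.close_rate_per_s
    )
    is_open = bool(rng.random() < p_open)  # stationary initial state

    dt = 1.0 / protocol.sample_rate_Hz
    t = 0.0
    idx = 0
    while idx < n:
        rate = fixture.close_rate_per_s if is_open else fixture.open_rate_per_s
        t += rng.exponential(1.0 / rate)
        stop = min(int(t / dt), n)
        if is_open:
            level = OPEN_SMALL if rng.random() < fixture.p_small else OPEN_LARGE
            states[idx:stop] = level
        idx = stop
        is_open = not is_open
    return states


def _state_conductances(
    fixture: GatingFixture, protocol: VoltageProtocol, voltage: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (gamma_large, gamma_small) in pS, honoring ramp branches."""
    if protocol.kind == "ramp" and fixture.branch_conductances is not None:
        bc = fixture.branch_conductances
        g_large = np.where(voltage < 0, bc.negative_pS, bc.positive_pS)
    else:
        g_large = np.full_like(voltage, fixture.gamma_large_pS)
    return g_large, g_large * fixture.sublevel_ratio


def _filtered_noise(
    n: int, noise_rms_pA: float, protocol: VoltageProtocol, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with exact RMS after 4-pole Bessel low-pass shaping.

    White noise is synthesized on a 4x-oversampled grid, filtered, and
    decimated back to the protocol rate; the input is pre-scaled by the
    filter's noise gain so the output RMS equals ``noise_rms_pA`` exactly in
    expectation.
    """
    fs = protocol.sample_rate_Hz * _NOISE_OVERSAMPLE
    sos = scipy.signal.bessel(
        4, protocol.filter_cutoff_Hz, btype="low", fs=fs, output="sos"
    )
    impulse = np.zeros(8192)
    impulse[0] = 1.0
    gain = np.sqrt(np.sum(scipy.signal.sosfilt(sos, impulse) ** 2))
    white = rng.standard_normal(n * _NOISE_OVERSAMPLE) * (noise_rms_pA / gain)
    shaped = scipy.signal.sosfilt(sos, white)
    return shaped[::_NOISE_OVERSAMPLE][:n]


def render_sweep(
    trajectory: np.ndarray,
    fixture: GatingFixture,
    protocol: VoltageProtocol,
    seed: int,
) -> Sweep:
    """Turn a gating trajectory into a current sweep in pA.

    ``i = gamma(state) * (V - V_rev) * 1e-3 + g_leak * V * 1e-3 + noise``
    (pS * mV * 1e-3 = pA); inward current is negative.
    """
    trajectory = np.asarray(trajectory)
    if len(trajectory) != protocol.n_samples:
        raise ValueError("trajectory length must match the protocol grid")
    voltage = protocol.voltage()
    g_large, g_small = _state_conductances(fixture, protocol, voltage)
    gamma = np.select(
        [trajectory == OPEN_LARGE, trajectory == OPEN_SMALL], [g_large, g_small], 0.0
    )
    current = gamma * (voltage - fixture.reversal_potential_mV) * 1e-3
    current = current + fixture.leak_conductance_pS * voltage * 1e-3
    if fixture.noise_rms_pA > 0:
        rng = np.random.default_rng(seed)
        current = current + _filtered_noise(
            len(current), fixture.noise_rms_pA, protocol, rng
        )
    return Sweep(current_pA=current, protocol=protocol, condition=fixture.name, seed=seed)


def render_noiseless_open_trace(
    fixture: GatingFixture, protocol: VoltageProtocol
) -> np.ndarray:
    """Open-large-channel current without leak or noise (diagnostics)."""
    voltage = protocol.voltage()
    g_large, _ = _state_conductances(fixture, protocol, voltage)
    return g_large * (voltage - fixture.reversal_potential_mV) * 1e-3


def make_control_sweep(
    fixture: GatingFixture, protocol: VoltageProtocol, seed: int
) -> Sweep:
    """Leak-only sweep: the trajectory is forced closed, noise statistics kept."""
    closed = np.zeros(protocol.n_samples, dtype=np.int8)
    return render_sweep(closed, fixture, protocol, seed)


def simulate_sweep_pairs(
    fixture: GatingFixture,
    protocol: VoltageProtocol,
    n_sweeps: int,
    seed: int,
) -> tuple[list[Sweep], list[Sweep]]:
    """Simulate ``n_sweeps`` active sweeps, each paired with its own control."""
    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2**31 - 1, size=3 * n_sweeps)
    sweeps, controls = [], []
    for k in range(n_sweeps):
        traj = simulate_gating(fixture, protocol, int(child[3 * k]))
        sweeps.append(render_sweep(traj, fixture, protocol, int(child[3 * k + 1])))
        controls.append(make_control_sweep(fixture, protocol, int(child[3 * k + 2])))
    return sweeps, controls


# --------------------------------------------------------------------------
# whole-cell block families

def simulate_block_dataset(
    params: BlockModelParams,
    unblocked_conductance_pS: float,
    concentrations_mM: Sequence[float],
    protocol: VoltageProtocol = RAMP_PROTOCOL,
    noise_fraction: float = 0.0,
    seed: int = 0,
    voltage_step_mV: float = 5.0,
    reversal_potential_mV: float = 0.0,
) -> BlockDataset:
    """Whole-cell I-V family under increasing blocker concentrations.

    At each voltage ``I = g (V - V_rev) * f_unblocked(V, C)``, multiplied by
    lognormal noise with coefficient of variation ``noise_fraction``, then
    normalized to the current at the highest ramp voltage.  With
    ``noise_fraction = 0`` the dataset is an exact forward evaluation of the
    block model and is invertible by :func:`trpa1pore.blockfit.fit_block_model`.
    """
    if len(concentrations_mM) == 0:
        raise ValueError("need at least one blocker concentration")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if protocol.kind != "ramp":
        raise ValueError("block datasets are recorded on voltage ramps")
    rng = np.random.default_rng(seed)
    voltage = np.arange(
        protocol.ramp_start_mV, protocol.ramp_end_mV + voltage_step_mV / 2,
        voltage_step_mV,
    )
    v_norm = float(voltage[-1])
    curves = []
    for conc in sorted(concentrations_mM):
        current = (
            unblocked_conductance_pS
            * (voltage - reversal_potential_mV)
            * 1e-3
            * hill_block_fraction(conc, params, voltage)
        )
        if noise_fraction > 0:
            sigma = np.sqrt(np.log1p(noise_fraction**2))
            current = current * rng.lognormal(-0.5 * sigma**2, sigma, size=len(current))
        curves.append((float(conc), voltage.copy(), current / current[-1]))
    return BlockDataset(
        curves=tuple(curves),
        normalization_voltage_mV=v_norm,
        reversal_potential_mV=reversal_potential_mV,
    )


# --------------------------------------------------------------------------
# fixture registry

_WT_150_GAMMA = 251.0  # pS, wild type in 150 mM symmetrical Cs+
_WT_500_GAMMA = 345.0


def _gating_fixtures() -> dict[str, GatingFixture]:
    wt150 = GatingFixture("WT-150", gamma_large_pS=_WT_150_GAMMA, gamma_small_pS=170.0)
    wt500 = GatingFixture("WT-500", gamma_large_pS=_WT_500_GAMMA, gamma_small_pS=215.0)
    return {
        "WT-150": wt150,
        "WT-500": wt500,
        # 100 uM Ba2+ partially blocks both open levels
        "WT-150-Ba100": replace(
            wt150, name="WT-150-Ba100", gamma_large_pS=161.0, gamma_small_pS=89.0
        ),
        # E920A: histogram levels 172/99 pS at -60 mV; ramp slope conductance
        # 54% of wild type inward, slightly reduced outward
        "E920A-150": replace(
            wt150,
            name="E920A-150",
            gamma_large_pS=172.0,
            gamma_small_pS=99.0,
            branch_conductances=BranchConductances(
                negative_pS=0.54 * _WT_150_GAMMA, positive_pS=0.90 * _WT_150_GAMMA
            ),
        ),
        # in 500 mM Cs+ the surface charge is screened: E920A inward
        # conductance converges to wild type
        "E920A-500": replace(
            wt500,
            name="E920A-500",
            gamma_large_pS=0.97 * _WT_500_GAMMA,
            gamma_small_pS=0.60 * 0.97 * _WT_500_GAMMA,
            branch_conductances=BranchConductances(
                negative_pS=_WT_500_GAMMA, positive_pS=0.90 * _WT_500_GAMMA
            ),
        ),
        # D915E: conductance reduced to 63%/62% of WT on the two branches
        "D915E-150": replace(
            wt150,
            name="D915E-150",
            gamma_large_pS=0.63 * _WT_150_GAMMA,
            gamma_small_pS=0.60 * 0.63 * _WT_150_GAMMA,
            branch_conductances=BranchConductances(
                negative_pS=0.63 * _WT_150_GAMMA, positive_pS=0.62 * _WT_150_GAMMA
            ),
        ),
        # D915A rectifies strongly: 10% of WT inward, 50% outward (500 mM Cs+)
        "D915A-500": replace(
            wt500,
            name="D915A-500",
            gamma_large_pS=0.50 * _WT_500_GAMMA,
            gamma_small_pS=0.60 * 0.50 * _WT_500_GAMMA,
            branch_conductances=BranchConductances(
                negative_pS=0.10 * _WT_500_GAMMA, positive_pS=0.50 * _WT_500_GAMMA
            ),
        ),
    }


def _block_fixtures() -> dict[str, BlockModelParams]:
    # WT Ba2+ block: K_D(0) = 0.6 mM split evenly between the exit routes,
    # binding site halfway across the field
    wt = BlockModelParams(k_out_mM=0.3, k_through_mM=0.3, delta=0.5, z_blocker=2.0,
                          hill_n=0.5)
    return {
        "WT-Ba": wt,
        # three-fold lower affinity, Hill coefficient nearer 1
        "E920A-Ba": replace(wt, k_out_mM=0.9, k_through_mM=0.9, hill_n=0.63),
        # three-fold higher affinity
        "D915E-Ba": replace(wt, k_out_mM=0.1, k_through_mM=0.1),
        # an order of magnitude lower affinity
        "D915A-Ba": replace(wt, k_out_mM=3.0, k_through_mM=3.0, hill_n=0.63),
    }


#: printed amplitude-histogram conditions used for the conductance-ratio average
HISTOGRAM_CONDITIONS = ("WT-150", "WT-500", "WT-150-Ba100", "E920A-150")


def fixture_registry() -> dict[str, GatingFixture | BlockModelParams]:
    """All packaged condition fixtures, keyed by condition name."""
    reg: dict[str, GatingFixture | BlockModelParams] = {}
    reg.update(_gating_fixtures())
    reg.update(_block_fixtures())
    return reg


def get_fixture(name: str) -> GatingFixture | BlockModelParams:
    reg = fixture_registry()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(reg)}"
        ) from None
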
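"""Voltage-dependent block of a cation channel by a permeant blocker.

A permeant blocker such as Ba2+ enters the pore from the outside (rate k1),
can return to the outside (k-1) or pass through to the cytoplasm (k2).  With
the binding site a fraction ``delta`` across the membrane electric field and
the access barriers placed halfway to the site on each side, the apparent
dissociation constant is voltage dependent:

    K_D(V) = (k-1/k1) exp(delta z F V / RT)
           + (k2/k1)  exp((delta - 1/2) z F V / RT)

At V = 0 the two rate ratios add: K_D(0) = K_out + K_through.  With
delta = 1/2 the through-pore term is voltage independent, so K_D flattens
at negative potentials while rising steeply at positive ones - the signature
of a permeant blocker that produces outward rectification.

The fraction of unblocked current follows a Hill equation,
``1 / (1 + (C / K_D(V))^n)``; Hill coefficients below one are the signature
of surface charge concentrating the blocker at the pore mouth.

The module fits this model globally across multi-concentration families of
normalized I-V curves, and fits plain Hill dose-response curves for
impermeant blockers (Ruthenium Red, Gd3+).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence, TYPE_CHECKING

import lmfit
import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .synthgen import BlockDataset


class UnderDeterminedFitError(ValueError):
    """Raised when a dataset cannot constrain the block-model parameters."""


@dataclass(frozen=True)
class BlockModelParams:
    """Parameters of the voltage-dependent Hill block model.

    ``k_out_mM`` is the outward rate ratio k-1/k1 and ``k_through_mM`` the
    through-pore ratio k2/k1, both in mM; ``delta`` is the electrical
    distance of the binding site (0..1 from the outside); ``z_blocker`` the
    blocker valence; ``hill_n`` the Hill coefficient.
    """

    k_out_mM: float
    k_through_mM: float
    delta: float
    z_blocker: float = 2.0
    hill_n: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.k_out_mM <= 0 or self.k_through_mM <= 0:
            raise ValueError("rate ratios k_out and k_through must be > 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("electrical distance delta must lie in [0, 1]")
        if self.hill_n <= 0:
            raise ValueError("Hill coefficient must be > 0")

    @property
    def kd_zero_mM(self) -> float:
        """Dissociation constant at 0 mV: K_out + K_through."""
        return self.k_out_mM + self.k_through_mM

    @property
    def constants(self) -> PhysicalConstants:
        return replace(DEFAULT_CONSTANTS, temperature=self.temperature)


@dataclass(frozen=True)
class BlockFitResult:
    """Outcome of a global block-model fit."""

    params: BlockModelParams
    stderr: dict[str, float]
    kd_zero_mM: float
    kd_zero_stderr_mM: float
    residual_norm: float
    predicted: dict[float, np.ndarray] = field(repr=False)


@dataclass(frozen=True)
class DoseResponseFit:
    """Hill fit of fraction-unblocked vs blocker concentration."""

    kd: float
    hill_n: float
    kd_stderr: float
    hill_n_stderr: float
    well_determined: bool

    def fraction_unblocked(self, concentration: np.ndarray) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        return 1.0 / (1.0 + (c / self.kd) ** self.hill_n)


def kd_of_voltage(params: BlockModelParams, voltage_mV) -> np.ndarray | float:
    """Voltage-dependent dissociation constant K_D(V) in mM."""
    v = np.asarray(voltage_mV, dtype=float)
    rtf = params.constants.rt_over_f_mV
    zf = params.z_blocker / rtf
    kd = params.k_out_mM * np.exp(params.delta * zf * v) + params.k_through_mM * np.exp(
        (params.delta - 0.5) * zf * v
    )
    return kd if kd.ndim else float(kd)


def hill_block_fraction(
    concentration_mM, params: BlockModelParams, voltage_mV
) -> np.ndarray | float:
    """Fraction of current left unblocked at concentration C and voltage V."""
    c = np.asarray(concentration_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("blocker concentration must be >= 0")
    kd = kd_of_voltage(params, voltage_mV)
    frac = 1.0 / (1.0 + (c / kd) ** params.hill_n)
    return frac if np.ndim(frac) else float(frac)


def predict_normalized_iv(
    params: BlockModelParams,
    voltage_mV: np.ndarray,
    concentration_mM: float,
    normalization_voltage_mV: float,
    reversal_potential_mV: float = 0.0,
) -> np.ndarray:
    """Blocked I-V curve normalized to the current at the reference voltage.

    The unblocked open channel is taken ohmic, so the conductance cancels in
    the normalization and only the block model shapes the curve.
    """
    v = np.asarray(voltage_mV, dtype=float)
    num = (v - reversal_potential_mV) * hill_block_fraction(concentration_mM, params, v)
    den = (normalization_voltage_mV - reversal_potential_mV) * hill_block_fraction(
        concentration_mM, params, normalization_voltage_mV
    )
    return num / den


def _block_residuals(lm_params, dataset, z_blocker, temperature):
    p = BlockModelParams(
        k_out_mM=np.exp(lm_params["log_k_out"].value),
        k_through_mM=np.exp(lm_params["log_k_through"].value),
        delta=lm_params["delta"].value,
        z_blocker=z_blocker,
        hill_n=lm_params["hill_n"].value,
        temperature=temperature,
    )
    res = []
    for conc, voltage, current in dataset.curves:
        pred = predict_normalized_iv(
            p, voltage, conc, dataset.normalization_voltage_mV,
            dataset.reversal_potential_mV,
        )
        res.append(current - pred)
    return np.concatenate(res)


def fit_block_model(
    dataset: "BlockDataset",
    z_blocker: float = 2.0,
    temperature: float = 298.15,
) -> BlockFitResult:
    """Global least-squares fit of the block model across all concentrations.

    K_out and K_through are optimized in log space, delta is bounded to
    [0, 1], and one (K_out, K_through, delta, hill_n) set is shared by every
    concentration.  Raises :class:`UnderDeterminedFitError` when fewer than
    two nonzero concentrations are present.
    """
    concs = [c for c, _, _ in dataset.curves]
    if sum(c > 0 for c in concs) < 2:
        raise UnderDeterminedFitError(
            "global block fit needs at least two nonzero blocker concentrations"
        )
    n_voltages = min(len(v) for _, v, _ in dataset.curves)
    if n_voltages < 10:
        raise UnderDeterminedFitError("need at least 10 voltages per curve")

    # generic start: K_D(0) near the median nonzero concentration, split evenly
    c_scale = float(np.median([c for c in concs if c > 0]))
    lm = lmfit.Parameters()
    lm.add("log_k_out", value=np.log(c_scale / 2.0))
    lm.add("log_k_through", value=np.log(c_scale / 2.0))
    lm.add("delta", value=0.3, min=0.0, max=1.0)
    lm.add("hill_n", value=1.0, min=1e-3, max=10.0)

    minimizer = lmfit.Minimizer(
        _block_residuals, lm, fcn_args=(dataset, z_blocker, temperature)
    )
    out = minimizer.minimize(method="leastsq", xtol=1e-12, ftol=1e-12)
    if not out.success:
        raise RuntimeError(f"block-model fit did not converge: {out.message}")

    fitted = BlockModelParams(
        k_out_mM=float(np.exp(out.params["log_k_out"].value)),
        k_through_mM=float(np.exp(out.params["log_k_through"].value)),
        delta=float(out.params["delta"].value),
        z_blocker=z_blocker,
        hill_n=float(out.params["hill_n"].value),
        temperature=temperature,
    )

    def _se(name: str) -> float:
        err = out.params[name].stderr
        return float(err) if err is not None else np.nan

    # delta-method SEs for the log-parameterized rate ratios
    stderr = {
        "k_out_mM": fitted.k_out_mM * _se("log_k_out"),
        "k_through_mM": fitted.k_through_mM * _se("log_k_through"),
        "delta": _se("delta"),
        "hill_n": _se("hill_n"),
    }
    if out.covar is not None:
        names = list(out.var_names)
        i, j = names.index("log_k_out"), names.index("log_k_through")
        var = (
            fitted.k_out_mM**2 * out.covar[i, i]
            + fitted.k_through_mM**2 * out.covar[j, j]
            + 2 * fitted.k_out_mM * fitted.k_through_mM * out.covar[i, j]
        )
        kd_se = float(np.sqrt(max(var, 0.0)))
    else:
        kd_se = np.nan

    predicted = {
        conc: predict_normalized_iv(
            fitted, voltage, conc, dataset.normalization_voltage_mV,
            dataset.reversal_potential_mV,
        )
        for conc, voltage, _ in dataset.curves
    }
    return BlockFitResult(
        params=fitted,
        stderr=stderr,
        kd_zero_mM=fitted.kd_zero_mM,
        kd_zero_stderr_mM=kd_se,
        residual_norm=float(np.sqrt(np.sum(out.residual**2))),
        predicted=predicted,
    )


def fit_dose_response(
    points: Sequence[tuple[float, float]],
    noise_sd: float = 0.05,
) -> DoseResponseFit:
    """Fit ``1 / (1 + (C/K_D)^n)`` to (concentration, fraction unblocked) data.

    Warns when the data rise with concentration by more than ~2 noise SDs
    (block should be monotone), and flags the fit as not well determined
    when essentially no block is seen so K_D is unbounded above.
    """
    pts = sorted(points)
    if len(pts) < 3:
        raise ValueError("dose-response fit needs at least 3 concentrations")
    conc = np.array([c for c, _ in pts], dtype=float)
    frac = np.array([f for _, f in pts], dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")

    if np.any(np.diff(frac) > 2 * noise_sd):
        warnings.warn("fraction unblocked increases with concentration beyond noise")

    if frac.min() > 0.9:
        # no appreciable block anywhere: K_D unbounded above
        return DoseResponseFit(
            kd=np.inf, hill_n=np.nan, kd_stderr=np.nan, hill_n_stderr=np.nan,
            well_determined=False,
        )

    nz = conc[conc > 0]
    model = lmfit.Model(
        lambda c, log_kd, hill_n: 1.0 / (1.0 + (c / np.exp(log_kd)) ** hill_n)
    )
    out = model.fit(
        frac,
        c=conc,
        log_kd=np.log(float(np.median(nz))),
        hill_n=1.0,
        method="leastsq",
        fit_kws={"xtol": 1e-14, "ftol": 1e-14},
    )
    kd = float(np.exp(out.params["log_kd"].value))
    kd_se = out.params["log_kd"].stderr
    return DoseResponseFit(
        kd=kd,
        hill_n=float(out.params["hill_n"].value),
        kd_stderr=kd * float(kd_se) if kd_se is not None else np.nan,
        hill_n_stderr=(
            float(out.params["hill_n"].stderr)
            if out.params["hill_n"].stderr is not None
            else np.nan
        ),
        well_determined=True,
    )
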
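# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic recordings do and do not emulate, and
the numerical choices that matter.

## Synthetic recordings

The generator produces episodic sweeps with the statistical structure the
analyses assume: a two-state (closed ↔ open) continuous-time Markov chain
sampled on the protocol grid, where every opening independently lands on
the main conductance level or, with probability `p_small`, on a sub-level;
an ohmic open-channel current γ·(V − V_rev) around a 0 mV reversal
(symmetrical solutions); a linear leak g_leak·V; and Gaussian noise shaped
by a 4-pole low-pass Bessel filter, mimicking an amplifier chain filtering
at 5 kHz with 10 kHz sampling.  Noise is synthesized on a 4×-oversampled
grid and decimated, so the filter design is well-posed even with the
cutoff at the output Nyquist frequency, and the input is pre-scaled by the
filter's noise gain so the output RMS equals the requested value exactly
in expectation.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| sampling / filter | 10 kHz / 5 kHz Bessel, 4-pole | standard patch-clamp chain the analyses assume |
| ramp protocol | −100 → +100 mV in 200 ms | the protocol under which I–V families are built |
| open/close rates | 50 s⁻¹ each | only amplitudes matter downstream; 20 ms dwells give well-resolved events at 10 kHz |
| `p_small` | 0.3 | sub-level openings are common but minority events; both mixture components stay well populated |
| noise RMS | 1 pA | places the 3 pA detection cut at ≈3σ |
| leak | 20 pS | small but nonzero, so leak subtraction is exercised |
| temperature | 298.15 K (RT/F = 25.7 mV) | consistent with the 180 mV·Å screened-Coulomb prefactor |

Condition fixtures package the recording conditions used throughout:
wild type at 150 and 500 mM symmetrical Cs⁺ (main/sub conductances
251/170 and 345/215 pS), wild type with 100 µM Ba²⁺ (161/89 pS), and the
pore mutants E920A (172/99 pS at −60 mV), D915E and D915A.  Rectifying
mutants are modeled phenomenologically through separate negative- and
positive-branch conductances applied on voltage ramps, because branch
slope conductances are what is empirically known about them; no mechanism
of rectification is modeled.  The hold-protocol amplitudes (γ_large,
γ_small) and the ramp branch conductances are independent fixture entries:
a chord at −60 mV and a branch slope are different observables of a
nonlinear I–V, and each fixture encodes its condition's reported value for
the protocol that measured it.  Where a condition has no reported number,
the fixture value is a synthetic choice (E920A outward branch at 90% of
wild type; E920A at 500 mM Cs⁺ converging to wild type inward; dose-
response absolute K_Ds) and only ratios or shapes, never those absolute
values, are treated as recoverable truths.

What the generator does **not** emulate: desensitization, multi-channel
patches, capacitance/series-resistance artifacts, flicker block,
state-dependent pore dilation, and baseline drift.  Passing tests
therefore demonstrate that the analysis chain is correct and unbiased
under idealized stationary recordings, not that it is robust to every
pathology of real data.

## Single-channel analysis

Leak subtraction is a pointwise difference against a paired control sweep
(forced-closed rendering of the same condition).  Event detection is
threshold-run idealization: maximal runs of consecutive samples with
|I| ≥ 3 pA lasting at least 0.5 ms (≈ one filter rise time); the 3 pA
boundary keeps points at exactly 3 pA.  This simple rule is deliberately
oracle-checkable — a per-sample brute-force scan must agree exactly, and a
property test enforces that.

Amplitude histograms at a fixed holding potential are fit with 1- and
2-component Gaussian mixtures selected by BIC.  Because the event
amplitude is a mean over a random-length run, its noise scales with
duration, producing same-mean scale mixtures that BIC alone would split;
a second component is therefore only accepted as a distinct open level
when its peak is resolved (means separated by more than twice the pooled
component width).  Conductance is |mean|/|V − V_rev|·10³ pS, with the
reversal taken from metadata (0 mV, symmetrical solutions) rather than
estimated.

Averaged open-channel I–V relations bin event samples by command voltage
(5 mV bins).  Openings to the sub-level are excluded by default: each
event's chord conductance (mean I/(V − V_rev)) is clustered per branch
with the same BIC-gated mixture, and only the main level is kept, because
a two-level average would otherwise blend the levels with a
voltage-dependent mixing fraction (the sub-level falls below the 3 pA cut
at higher |V|) and bias branch slopes.  Events with mean drive below
20 mV have unstable chords and are left unclassified; they populate only
near-gap bins.  Branch slope conductances are ordinary least squares on
the V < −20 mV and V > +20 mV limbs, additionally dropping bins whose
mean current magnitude is within 2 pA of the threshold: there the
per-point cut truncates the noise distribution and bends the limb
(measured bias ≈ −8% on a 135 pS branch when such bins are kept).  A
branch with fewer than 5 usable bins is reported absent — this is why a
very small conductance (e.g. a 10%-of-wild-type inward branch at 34 pS,
which never exceeds 5 pA over the ramp) is honestly unresolvable by this
pipeline rather than estimated badly.

## Divalent block

The voltage-dependent dissociation constant of a permeant blocker
(valence z, electrical distance δ, access barriers halfway to the site on
each side) is

    K_D(V) = K_out·e^{δzFV/RT} + K_through·e^{(δ−½)zFV/RT},

inside a Hill block fraction 1/(1 + (C/K_D(V))ⁿ).  K_D(0) = K_out +
K_through.  The wild-type fixture uses K_D(0) = 0.6 mM split evenly
between the exit routes, δ = 0.5 and n = 0.5; the even split is a fixture
choice (only the sum is empirically constrained), and mutant fixtures
encode fold-changes of affinity (3× weaker for E920A, 3× stronger for
D915E, 10× weaker for D915A).

Global fitting shares one (K_out, K_through, δ, n) across all
concentrations of a family of per-curve-normalized I–V relations.  Rate
ratios are optimized in log space, δ is bounded to [0, 1], and the loss is
unweighted least squares on normalized currents (Levenberg–Marquardt,
xtol = ftol = 10⁻¹²).  Start values are generic — K_D(0) at the median
nonzero concentration, δ = 0.3, n = 1 — and noiseless families are
recovered to ≤10⁻⁴ relative error from them.  The generator's forward map
and the fitter share the model expression by construction; independence is
instead established against a brute-force grid search in the tests.
Under-determined inputs (fewer than two nonzero concentrations, or fewer
than ten voltages) are rejected rather than fit.

Dose–response curves for impermeant blockers fit 1/(1 + (C/K_D)ⁿ)
directly; data showing no appreciable block anywhere are flagged as
K_D-unbounded instead of returning a spurious optimum, and non-monotone
data warn.

## Surface potential

Three routes to the potential change at the pore mouth are implemented:
affinity ratios Δφ = (RT/zF)·ln(K_D,mut/K_D,wt), conductance ratios
Δφ = (RT/zF)·ln(g_wt/g_mut) (conductance assumed proportional to the
local permeant concentration), and screened-Coulomb superposition
φ = D·Σ zᵢ·A·e^{−rᵢ/λ}/rᵢ with prefactor A = 180 mV·Å for water and an
explicit interface-doubling factor D ∈ {1, 2} for charges at a
water/protein boundary.  Sign convention: mutant-minus-wild-type, positive
when negative charge is removed.  The four-charge ring value (~16.5 mV
magnitude for unit charges 11 Å out, λ = 8 Å) is computed without
doubling; with doubling it would be ~33 mV, so the doubling factor is a
parameter the caller chooses per geometry rather than a baked-in truth.
The Debye length is the standard 1:1-electrolyte expression,
κ⁻¹ = √(εε₀RT/2F²I) ≈ 7.9 Å at 150 mM, 298 K, ε = 78.5.

Full numerical Poisson–Boltzmann electrostatics on channel structures is
out of scope; the analytic screened-Coulomb model is the package's
vestibule-electrostatics tool.

## Pore sizing

Cations are defined by SMILES connectivity and embedded with ETKDG
(fixed seed, default 7) followed by MMFF94 minimization; the seed is a
panel parameter, so diameters are reproducible constants of the package.
Vertices are the terminal heavy atoms of each substituent arm (heavy-graph
degree ≤ 1); the diameter is the mean over all vertex pairs of the
internuclear distance plus both van der Waals radii, and a single-vertex
species gets twice its radius.  Terminal groups carry their hydrogens
pointing outward, so united-atom group radii are used (CH₃/CH₂ 2.0 Å,
H-bearing N 2.0 Å, OH 1.7 Å, P 2.1 Å, Bondi-style group values); bare
heavy-atom radii would ignore roughly a C–H bond length of bulk at every
arm tip and systematically undersize flexible cations by ~0.5–0.9 Å.
Conformer choice contributes a few tenths of an angstrom of spread across
embedding seeds, within the ±0.5 Å the method is quoted to.

Classification is permeant when current relative to Na⁺ at −80 mV exceeds
a leak threshold (default 0.02); the panel's relative-current values are
synthetic stand-ins chosen to reproduce the published classification, and
only the classification enters the cutoff.  The cutoff estimate is the
largest permeant diameter, reported explicitly as a lower bound, with the
smallest impermeant diameter as the bracketing value; a panel where an
impermeant cation is smaller than the largest permeant one is flagged,
not rejected (permeant blockers make relative current an imperfect proxy).

## Problem sizes and determinism

The packaged analyses use 200 sweeps per condition (0.5 s holds for
histograms, 200 ms ramps for I–V relations), five blocker concentrations
× 41 voltages per block family, and 20–40 replicate fits in identifiability
checks — sizes at which every recovered quantity sits well inside its
tolerance while a full run of the suite plus the acceptance script takes
on the order of a minute.  All stochastic stages draw from
`numpy.random.default_rng` seeded explicitly; pipeline runs derive every
child seed from the config seed, and rerunning a config reproduces its
deterministic output tables byte for byte.

## Known limitations

* Gating kinetics are a convenience (exponential dwells, no modal
  gating); only amplitudes and occupancies are analysis surfaces.
* Event counts depend on idealization settings and are not comparable
  across implementations; conductances and ratios are.
* The block fitter assumes an ohmic unblocked channel, so the open-channel
  conductance cancels in normalized families; real families with intrinsic
  rectification would need the unblocked shape supplied.
* Sub-level exclusion on ramps requires the two levels to be separable in
  chord conductance; levels closer than the mixture can resolve would be
  averaged together.
* Branches whose expected current never clears the detection threshold by
  ~2 pA are reported absent rather than estimated.
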
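"""End-to-end reproducible runs: configuration, staging, provenance.

A :class:`RunConfig` captures every knob of a run - fixture names, protocol,
sweep counts, thresholds and the master seed - and round-trips losslessly
through YAML.  ``run_pipeline`` executes the requested stages in order
(simulate -> detect -> iv -> conductance -> fitblock -> surfpot -> poresize),
writing one TSV per stage plus a provenance record containing the config
hash, so a rerun with the same config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, poresize, singlechan, surfpot, synthgen
from .blockfit import fit_block_model
from .sweepio import write_manifest, write_sweep

log = logging.getLogger("trpa1pore")

ALL_STAGES = ("simulate", "detect", "iv", "conductance", "fitblock", "surfpot", "poresize")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    fixtures: tuple[str, ...] = ("WT-150",)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 1
    n_sweeps: int = 50
    hold_voltage_mV: float = -60.0
    hold_duration_s: float = 0.5
    threshold_pA: float = 3.0
    bin_mV: float = 5.0
    block_fixture: str = "WT-Ba"
    block_concentrations_mM: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 5.0)
    block_noise_fraction: float = 0.02
    leak_threshold: float = 0.02
    embed_seed: int = poresize.DEFAULT_EMBED_SEED

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        registry = synthgen.fixture_registry()
        for name in (*self.fixtures, self.block_fixture):
            if name not in registry:
                raise ValueError(f"unknown fixture {name!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        for key in ("fixtures", "stages", "block_concentrations_mM"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Per-stage output tables plus the provenance record."""

    outdir: Path
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _write_table(bundle: ResultsBundle, name: str, table: pd.DataFrame) -> None:
    path = bundle.outdir / f"{name}.tsv"
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {bundle.config.config_hash}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    bundle.tables[name] = table


def run_pipeline(config: RunConfig, outdir: str | Path) -> ResultsBundle:
    """Execute the configured stages and write their tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultsBundle(outdir=outdir, config=config)
    rng = np.random.default_rng(config.seed)
    hold = synthgen.hold_protocol(config.hold_voltage_mV, config.hold_duration_s)

    data: dict[str, tuple[list, list]] = {}
    stage = "setup"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            pairs = []
            for name in config.fixtures:
                fixture = synthgen.get_fixture(name)
                sub = int(rng.integers(0, 2**31 - 1))
                sweeps, controls = synthgen.simulate_sweep_pairs(
                    fixture, hold, config.n_sweeps, sub
                )
                data[name] = (sweeps, controls)
                fixdir = outdir / "sweeps" / name
                for k, (s, c) in enumerate(zip(sweeps, controls)):
                    sp = write_sweep(s, fixdir / f"sweep_{k:04d}.tsv")
                    cp = write_sweep(c, fixdir / f"control_{k:04d}.tsv")
                    pairs.append((sp.relative_to(outdir), cp.relative_to(outdir), name))
                log.info("simulated %d sweep pairs for %s", config.n_sweeps, name)
            write_manifest(pairs, outdir / "manifest.tsv")

        if "detect" in config.stages:
            stage = "detect"
            rows = []
            for name, (sweeps, controls) in data.items():
                for k, (s, c) in enumerate(zip(sweeps, controls)):
                    corrected = singlechan.subtract_leak(s, c)
                    events = singlechan.detect_events(
                        corrected, s.protocol.sample_rate_Hz, config.threshold_pA,
                        voltage_mV=s.protocol.voltage(),
                    )
                    events.insert(0, "sweep", k)
                    events.insert(0, "condition", name)
                    rows.append(events)
            table = (
                pd.concat(rows, ignore_index=True)
                if rows
                else pd.DataFrame(columns=["condition", "sweep"])
            )
            _write_table(bundle, "events", table)

        if "iv" in config.stages or "conductance" in config.stages:
            stage = "iv"
            ramp = synthgen.RAMP_PROTOCOL
            slopes = []
            for name in config.fixtures:
                fixture = synthgen.get_fixture(name)
                sub = int(rng.integers(0, 2**31 - 1))
                sweeps, controls = synthgen.simulate_sweep_pairs(
                    fixture, ramp, config.n_sweeps, sub
                )
                iv = singlechan.average_open_iv(
                    sweeps, controls, config.threshold_pA, config.bin_mV
                )
                iv.insert(0, "condition", name)
                _write_table(bundle, f"iv_{name}", iv)
                if "conductance" in config.stages:
                    stage = "conductance"
                    est = singlechan.slope_conductance(iv)
                    for branch, br in (("negative", est.negative), ("positive", est.positive)):
                        if br is not None:
                            slopes.append(
                                {
                                    "condition": name,
                                    "branch": branch,
                                    "slope_pS": br.slope_pS,
                                    "stderr_pS": br.stderr_pS,
                                    "n_bins": br.n_bins,
                                }
                            )
            if slopes:
                _write_table(bundle, "conductance", pd.DataFrame(slopes))

        if "fitblock" in config.stages:
            stage = "fitblock"
            params = synthgen.get_fixture(config.block_fixture)
            dataset = synthgen.simulate_block_dataset(
                params,
                unblocked_conductance_pS=synthgen.get_fixture("WT-150").gamma_large_pS,
                concentrations_mM=config.block_concentrations_mM,
                noise_fraction=config.block_noise_fraction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fit = fit_block_model(dataset, z_blocker=params.z_blocker)
            table = pd.DataFrame(
                [
                    {
                        "k_out_mM": fit.params.k_out_mM,
                        "k_through_mM": fit.params.k_through_mM,
                        "delta": fit.params.delta,
                        "hill_n": fit.params.hill_n,
                        "kd_zero_mM": fit.kd_zero_mM,
                        "kd_zero_stderr_mM": fit.kd_zero_stderr_mM,
                    }
                ]
            )
            _write_table(bundle, "blockfit", table)

        if "surfpot" in config.stages:
            stage = "surfpot"
            ring = surfpot.ChargeGeometry.ring(4, -1.0, 11.0)
            table = pd.DataFrame(
                [
                    {
                        "quantity": "delta_phi_conductance_E920A_mV",
                        "value": surfpot.delta_phi_from_conductance_ratio(0.54, 1.0),
                    },
                    {
                        "quantity": "phi_four_charge_ring_mV",
                        "value": surfpot.debye_huckel_potential(ring),
                    },
                    {
                        "quantity": "debye_length_150mM_A",
                        "value": surfpot.debye_length(150.0),
                    },
                ]
            )
            _write_table(bundle, "surfpot", table)

        if "poresize" in config.stages:
            stage = "poresize"
            diam = poresize.panel_diameters(seed=config.embed_seed)
            cls = poresize.classify_permeation(leak_threshold=config.leak_threshold)
            merged = cls.merge(diam, on="name")
            _write_table(bundle, "poresize", merged)
            cutoff = poresize.estimate_cutoff(cls, diam)
            _write_table(
                bundle,
                "poresize_cutoff",
                pd.DataFrame(
                    [
                        {
                            "cutoff_A": cutoff.cutoff_A,
                            "largest_permeant": cutoff.largest_permeant,
                            "smallest_impermeant": cutoff.smallest_impermeant,
                        }
                    ]
                ),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle.provenance = {
        "config_hash": config.config_hash,
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
    }
    (outdir / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2))
    (outdir / "config.yaml").write_text(config.to_yaml())
    return bundle
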
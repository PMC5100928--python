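"""Plain-text serialization of sweeps: TSV traces, YAML sidecars, manifests.

One sweep is stored as a three-column TSV (time_s, voltage_mV, current_pA)
plus a ``.meta.yaml`` sidecar carrying the condition, fixture name, seed,
blocker concentration and protocol parameters.  A manifest TSV lists
active/control sweep pairings for leak subtraction.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthgen import Sweep, VoltageProtocol

MANIFEST_COLUMNS = ("sweep", "control", "condition")


def _sidecar_path(trace_path: Path) -> Path:
    return trace_path.with_suffix(".meta.yaml")


def write_sweep(sweep: Sweep, path: str | Path) -> Path:
    """Write one sweep as TSV + YAML sidecar; returns the trace path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "time_s": sweep.protocol.time(),
            "voltage_mV": sweep.protocol.voltage(),
            "current_pA": sweep.current_pA,
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {
        "condition": sweep.condition,
        "blocker_concentration_mM": sweep.blocker_concentration_mM,
        "seed": sweep.seed,
        "protocol": dataclasses.asdict(sweep.protocol),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_sweep(path: str | Path) -> Sweep:
    """Read one sweep written by :func:`write_sweep`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
        current = np.asarray(frame["current_pA"], dtype=float)
    except (ValueError, KeyError, pd.errors.ParserError) as exc:
        raise ValueError(f"corrupted sweep file {path}: {exc}") from exc
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    protocol = VoltageProtocol(**meta["protocol"])
    return Sweep(
        current_pA=current,
        protocol=protocol,
        condition=meta["condition"],
        blocker_concentration_mM=meta.get("blocker_concentration_mM", 0.0),
        seed=meta.get("seed"),
    )


def write_manifest(
    pairs: list[tuple[Path, Path, str]], path: str | Path
) -> Path:
    """Write a manifest of (sweep, control, condition) rows, paths relative."""
    path = Path(path)
    rows = [
        {"sweep": str(s), "control": str(c), "condition": cond}
        for s, c, cond in pairs
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_sweepset(manifest_path: str | Path) -> tuple[list[Sweep], list[Sweep]]:
    """Read all sweep/control pairs listed in a manifest.

    Paths are resolved relative to the manifest location.  A row whose
    files are missing or malformed raises with the file and row named; a
    row without a control (orphan sweep) warns and is excluded, since it
    cannot enter leak-subtracted analyses; an empty manifest returns two
    empty lists.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    for col in MANIFEST_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"manifest {manifest_path} lacks column {col!r}")
    root = manifest_path.parent
    sweeps, controls = [], []
    for i, row in table.iterrows():
        if pd.isna(row["control"]) or str(row["control"]).strip() == "":
            warnings.warn(
                f"manifest {manifest_path} row {i}: sweep {row['sweep']} has no "
                "control; excluded from leak-subtracted analyses"
            )
            continue
        try:
            sweeps.append(read_sweep(root / row["sweep"]))
            controls.append(read_sweep(root / row["control"]))
        except (OSError, ValueError) as exc:
            raise ValueError(
                f"manifest {manifest_path} row {i}: {exc}"
            ) from exc
    return sweeps, controls
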
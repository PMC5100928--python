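#!/usr/bin/env python
"""Simulate representative single-channel recordings for every packaged
condition and write the sweeps, controls and event tables under results/.

This is the data-generation step the later analyses build on: each
condition fixture (wild type and pore mutants, several Cs+ concentrations,
with/without Ba2+) is rendered as leak- and noise-contaminated episodic
sweeps paired with openings-free control sweeps.
"""

from pathlib import Path

from trpa1pore.pipeline import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "recordings"


def main() -> None:
    config = RunConfig(
        fixtures=("WT-150", "WT-500", "WT-150-Ba100", "E920A-150"),
        stages=("simulate", "detect"),
        n_sweeps=20,
        seed=1,
    )
    bundle = run_pipeline(config, OUT)
    events = bundle.tables["events"]
    print(f"wrote {len(events)} detected events across "
          f"{len(config.fixtures)} conditions to {OUT}")
    print(events.groupby("condition")["amplitude_pA"].describe().round(2))


if __name__ == "__main__":
    main()
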
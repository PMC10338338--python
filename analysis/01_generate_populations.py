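#!/usr/bin/env python
"""Generate the synthetic MCF-10A reporter-trace cohorts.

Three cohorts of 1000 cells, all treated 12 h into the recording while in
S/G2: full growth (DMSO; only the mitosis clock runs), CDK4/6i (the two
clocks race), and CDK4/6i + CDK1i (mitosis blocked; only the exit clock
runs).  Plus the S-phase-delay series (CDK4/6i with 0/2/4/6 h stall
pulses).  Trace tables land in results/.
"""

from pathlib import Path

from clockrace import TreatmentProgram, generate_population, make_preset
from clockrace.io import write_traces

OUT = Path(__file__).resolve().parent.parent / "results"
N = 1000
SEED = 20230705

COHORTS = {
    "full_growth": TreatmentProgram("DMSO"),
    "competition": TreatmentProgram("CDK46I"),
    "mitosis_blocked": TreatmentProgram("CDK46I_CDK1I"),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    preset = make_preset("MCF10A")
    for i, (name, prog) in enumerate(COHORTS.items()):
        traces = generate_population(preset, prog, N, SEED + i)
        path = OUT / f"traces_{name}.csv"
        write_traces(traces, path)
        n_div = sum(bool(tr.division_times) for tr in traces)
        print(f"{name}: {N} cells, {n_div} with a division -> {path.name}")
    for j, delay in enumerate((0.0, 2.0, 4.0, 6.0)):
        prog = TreatmentProgram("CDK46I", delay_hours=delay)
        traces = generate_population(preset, prog, N, SEED + 10 + j)
        path = OUT / f"traces_delay{int(delay)}h.csv"
        write_traces(traces, path)
        print(f"delay {delay:g} h -> {path.name}")


if __name__ == "__main__":
    main()
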
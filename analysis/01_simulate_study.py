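#!/usr/bin/env python
"""Generate the synthetic wear study.

Emits the full default trial — 20 participants, two sensors of each of the
two systems, three 3-day study-site visits with hourly diaries (plus the
0300 record and 15-min dynamic-phase recording), meal/bolus events and BG
reference values — as delimited text files.  The trace files are bulky, so
they go under scratch/study/; downstream scripts read them from there.
"""

from pathlib import Path

from cgmtrends import StudyConfig, generate_study, write_study

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "study"
SEED = 2016


def main() -> None:
    config = StudyConfig(seed=SEED)
    study = generate_study(config)
    paths = write_study(study, OUT)
    n_by_system = {
        s: sum(1 for r in study.diary if r.system == s) for s in config.systems
    }
    print(f"synthetic study (seed {SEED}) written to {OUT}")
    print(f"  participants: {config.n_participants}")
    print(f"  sensor traces: {len(study.traces)}  (2 per system per participant)")
    print(f"  diary records: {len(study.diary)}  by system: {n_by_system}")
    print(f"  therapy events: {len(study.events)}")
    for name, p in sorted(paths.items()):
        print(f"  {name}: {p.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
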
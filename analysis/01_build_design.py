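"""Reconstruct the stimulus set and trial schedules, and export them.

Writes the 11-problem table (with full deviant series), one seeded
44-trial calculation schedule, one seeded cueing schedule, and two example
dot arrays to results/design/.
"""

import json
import sys
from pathlib import Path

import click

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from opmomentum import cli as omcli  # noqa: E402
from opmomentum import design  # noqa: E402


@click.command()
@click.option("--seed", type=int, default=1)
@click.option("--out", type=click.Path(), default="results/design")
def main(seed: int, out: str) -> None:
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)

    problems = omcli._problems_frame()
    problems.to_csv(outdir / "problems.csv", index=False)
    add = problems[problems["task"] == "addition"]["correct"]
    sub = problems[problems["task"] == "subtraction"]["correct"]
    click.echo(f"problem table: {len(problems)} problems; addition outcomes "
               f"{sorted(add)} == subtraction outcomes {sorted(sub)}")

    schedule = design.build_session_schedule(seed)
    omcli._schedule_frame(schedule).to_csv(outdir / "schedule.csv", index=False)
    tasks = [t.problem.operation for t in schedule.test.trials]
    click.echo(f"session schedule (seed {seed}): {len(tasks)} test trials "
               f"({tasks.count('memorization')} memory, "
               f"{tasks.count('addition')} addition, "
               f"{tasks.count('subtraction')} subtraction)")

    cueing = design.build_cueing_schedule(seed)
    validities = [t.validity for t in cueing.test]
    rows = [{"trial_index": i, "cue": t.cue, "target_side": t.target_side,
             "soa_ms": t.soa_ms, "validity": t.validity}
            for i, t in enumerate(cueing.test)]
    import pandas as pd
    pd.DataFrame(rows).to_csv(outdir / "cueing_schedule.csv", index=False)
    click.echo(f"cueing schedule: {validities.count('valid')} valid / "
               f"{validities.count('invalid')} invalid / "
               f"{validities.count('neutral')} neutral")

    for mode in ("fixed_total_area", "fixed_dot_size"):
        spec = design.generate_dot_array(12, mode, seed)
        record = {"n": spec.n, "mode": spec.mode,
                  "dots": [[round(x, 2), round(y, 2), round(r, 3)]
                           for x, y, r in spec.dots]}
        (outdir / f"dots_{mode}.json").write_text(json.dumps(record, indent=2))
    click.echo(f"design artifacts written to {outdir}")


if __name__ == "__main__":
    main()
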
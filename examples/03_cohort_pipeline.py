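"""Full cohort pipeline on a small synthetic phantom cohort.

Generates a 4-patient pelvic phantom cohort (two human observers R1/R2 and
an automatic observer AUTO, three MR sequences, five organs at risk) with
the paper_like noise preset — T1dixonc carries about twice the boundary
noise of T1WI/T2WI — then runs the three comparison designs and prints the
intersequence table for observer R2.
"""

import tempfile
from pathlib import Path

from contourvar import (
    PhantomParams,
    generate_cohort,
    preset_models,
    run_designs,
    write_report,
)

with tempfile.TemporaryDirectory() as tmp:
    observers, sequences = preset_models("paper_like")
    cohort = generate_cohort(
        n_patients=4,
        params=PhantomParams(),
        observer_models=observers,
        sequence_models=sequences,
        out_dir=Path(tmp) / "cohort",
        seed=0,
    )
    print(f"cohort: {len(cohort)} masks, patients {cohort.patients}")

    results = run_designs(cohort, observer="R2")
    write_report(results, Path(tmp) / "report", config={"preset": "paper_like"},
                 seed=0, cohort=cohort)

    summary = results["intersequence"].summary
    print("\nintersequence agreement for R2 (mean ± SD across patients):")
    print(summary[summary.metric == "dsc"]
          .pivot(index="structure", columns="comparison", values="formatted")
          .to_string())

    by_pair = summary[summary.metric == "dsc"].groupby("comparison")["mean"].mean()
    print(f"\nmost similar sequence pair: {by_pair.idxmax()} "
          f"(mean DSC {by_pair.max():.3f})")
    print("T1dixonc is noisier in this preset, so the T1WI-T2WI pair agrees best —")
    print("the same qualitative ordering expected from clinical delineations.")
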
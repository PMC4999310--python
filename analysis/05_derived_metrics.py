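#!/usr/bin/env python
"""Cross-species derived metrics from the published cohort means.

Computes the headline quantities — functional release sites per active
zone, AZ membrane area per Katz release site, docking-site occupancy, and
the human/rat N_frs fold change — from the reported cohort means, plus the
rat-to-human age conversion for the study's age range. Writes
results/derived_metrics.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

from synquant import metrics
from synquant.published import HUMAN, RAT

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    human = metrics.derived_report(HUMAN)
    rat = metrics.derived_report(RAT)
    fold = metrics.fold_change(HUMAN.mean_n_frs, RAT.mean_n_frs)
    report = {
        "human": asdict(human),
        "rat": asdict(rat),
        "n_frs_fold_human_over_rat": fold,
        "age_map": {
            "P18_years": metrics.rat_to_human_age(18),
            "P38_years": metrics.rat_to_human_age(38),
            "P65_years": metrics.rat_to_human_age(65),
        },
    }
    (RESULTS / "derived_metrics.json").write_text(
        json.dumps(report, indent=2))
    for rep in (human, rat):
        print(f"{rep.species}: {rep.sites_per_az:.1f} release sites/AZ, "
              f"{rep.area_per_site_um2:.3f} um^2/site, "
              f"occupancy {rep.occupancy:.1f}")
    print(f"N_frs fold change human/rat: {fold:.1f}")
    print(f"rat P18-P65 ~ human "
          f"{metrics.rat_to_human_age(18):.0f}-"
          f"{metrics.rat_to_human_age(65):.0f} years")
    print(f"wrote {RESULTS / 'derived_metrics.json'}")


if __name__ == "__main__":
    main()
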
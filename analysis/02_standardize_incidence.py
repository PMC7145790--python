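#!/usr/bin/env python
"""Indirect standardisation and overall incidence.

Computes age-sex standardised expected counts with the study-wide reference
(adding column E to the area table) and the overall incidence per 100,000
person-years with its exact Poisson CI.
"""

from pathlib import Path

from enwas.io import read_area_table, write_area_table, write_json
from enwas.pipeline import split_area_table
from enwas.standardize import expected_counts, incidence_rate

OUT = Path(__file__).resolve().parents[1] / "results" / "region"
YEARS = 11.0


def main() -> None:
    tab = read_area_table(OUT / "areas.csv")
    counts, _, _ = split_area_table(tab)
    ec = expected_counts(counts)
    tab["E"] = ec.expected.to_numpy()
    write_area_table(tab, OUT / "areas.csv")

    O = counts.observed()
    py = counts.total_population().sum() * YEARS
    inc = incidence_rate(int(O.sum()), py)
    write_json(
        {
            "incidence_per_100k": inc.rate,
            "ci": [inc.ci_low, inc.ci_high],
            "cases": inc.cases,
            "person_years": inc.person_years,
            "reference_rates": ec.reference_rates.to_dict(),
        },
        OUT / "incidence.json",
    )
    print(f"total cases {O.sum()} over {py:,.0f} person-years")
    print(f"incidence {inc.rate:.1f} (95% CI {inc.ci_low:.1f}, {inc.ci_high:.1f}) per 100,000")
    print(f"calibration: sum(E) - sum(O) = {ec.expected.sum() - O.sum():.2e}")


if __name__ == "__main__":
    main()
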
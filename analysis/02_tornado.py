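#!/usr/bin/env python
"""One-way (tornado) sensitivity analysis of the base-case ICER.

Each parameter is set to its lower and upper bound in turn, all others held
at base; results/tornado.csv lists the ICER range per parameter, widest
first.  Prevalence dominates: screening a higher-prevalence population
spreads the fixed testing cost over more detectable cancers.
"""
from pathlib import Path

from lungscreen_cea.synthetic import base_case_fixture, make_life_table
from lungscreen_cea.uncertainty import tornado, tornado_frame

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    specs = base_case_fixture()
    table = make_life_table()
    entries = tornado(specs, table)

    OUT.mkdir(exist_ok=True)
    frame = tornado_frame(entries)
    frame.to_csv(OUT / "tornado.csv", index=False)

    print("most influential parameters (ICER range, USD/QALY):")
    for e in entries[:5]:
        print(
            f"  {e.parameter:<26s} {min(e.icer_at_lower, e.icer_at_upper):>12,.0f}"
            f" - {max(e.icer_at_lower, e.icer_at_upper):>12,.0f}"
        )
    icers = [v for e in entries for v in (e.icer_at_lower, e.icer_at_upper) if v is not None]
    print(f"ICER range across all one-way runs: {min(icers):,.0f} - {max(icers):,.0f}")


if __name__ == "__main__":
    main()
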
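#!/usr/bin/env python
"""Consistency checks on the packaged 120-gene canola aquaporin table.

Validates the spacing identity (distance = le - lb - 3) on every
complete row, counts the PIP entries with the F-H-T-R selectivity
filter, verifies the single conserved NIP5 spacing, and reports the
per-genome totals.
"""

from pathlib import Path

from aqpscan.feature_scan import npa_spacing
from aqpscan.table2 import load_table2, validate_table2_fixture

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = load_table2()
    report = validate_table2_fixture(table)
    print(f"rows: {report.n_rows}; complete: {report.n_complete}; "
          f"violations: {len(report.violations)}; exempt: {report.exempt}")

    pips = table[table.subfamily == "PIP"]
    fhtr = pips[(pips.h2 == "F") & (pips.h5 == "H") & (pips.le1 == "T")
                & (pips.le2 == "R")]
    print(f"PIP entries with F-H-T-R filter: {len(fhtr)} of {len(pips)}")

    nip5 = table[table.group == "NIP5"]
    spacings = {npa_spacing(int(r.lb_pos), int(r.le_pos))
                for r in nip5.itertuples()}
    print(f"NIP5 spacings ({len(nip5)} genes): {sorted(spacings)}")

    counts = table.genome.value_counts()
    print(f"genome totals: A={counts['A']}, C={counts['C']}")
    table.to_csv(OUT / "table2_fixture_checked.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
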
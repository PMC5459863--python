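"""The packaged B. napus aquaporin feature table and its validator.

The fixture transcribes the published feature table of the 120 canola
aquaporins: per gene, the two NPA-type motifs with their 1-based start
positions, the four ar/R selectivity-filter residues and the printed
NPA-NPA distance. Rows whose motifs were curated manually in the
original analysis carry ``manual_flag``; the single incomplete entry
(BnaCNIP4-1c, one partial motif, no filter) carries ``partial_flag``
and is exempt from the spacing identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .feature_scan import npa_spacing

_FIXTURE = "table2_fixture.tsv"

_NAME_RE = re.compile(r"^Bna([AC])(PIP|TIP|NIP|SIP)(\d)-(\d)([a-z])$")


def fixture_path():
    return resources.files("aqpscan.data").joinpath(_FIXTURE)


def load_table2() -> pd.DataFrame:
    """Load the fixture with derived genome/subfamily/group columns.

    Derived columns: ``genome`` (A or C, from the gene name),
    ``subfamily``, ``group`` (e.g. NIP5), ``scaffold`` (True for genes on
    unanchored nng scaffolds, by gene-id), and ``complete`` (both motif
    positions present).
    """
    with resources.as_file(fixture_path()) as path:
        df = pd.read_csv(path, sep="\t", dtype={"lb_pos": "Int64",
                                                "le_pos": "Int64",
                                                "distance": "Int64"})
    parsed = df["name"].str.extract(
        r"^Bna(?P<genome>[AC])(?P<subfamily>PIP|TIP|NIP|SIP)(?P<gnum>\d)")
    df["genome"] = parsed["genome"]
    df["subfamily"] = parsed["subfamily"]
    df["group"] = parsed["subfamily"] + parsed["gnum"]
    df["scaffold"] = df["gene_id"].str.contains("nng")
    df["complete"] = df["lb_pos"].notna() & df["le_pos"].notna()
    return df


@dataclass
class FixtureValidation:
    n_rows: int
    n_complete: int
    violations: list = field(default_factory=list)  # (name, printed, computed)
    exempt: list = field(default_factory=list)      # partial rows

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_table2_fixture(df: pd.DataFrame | None = None) -> FixtureValidation:
    """Check distance = le_pos - lb_pos - 3 on every complete row.

    Partial rows (missing a motif position) are reported as exempt; any
    complete row whose printed distance disagrees with the computed
    spacing is a named violation.
    """
    if df is None:
        df = load_table2()
    report = FixtureValidation(n_rows=len(df), n_complete=int(df["complete"].sum()))
    for row in df.itertuples():
        if not row.complete:
            report.exempt.append(row.name)
            continue
        computed = npa_spacing(int(row.lb_pos), int(row.le_pos))
        if pd.isna(row.distance) or computed != int(row.distance):
            report.violations.append((row.name, int(row.distance)
                                      if not pd.isna(row.distance) else None,
                                      computed))
    return report
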
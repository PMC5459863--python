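#!/usr/bin/env python
"""Generate the synthetic aquaporin cohort used by the downstream steps.

Writes a protein FASTA (48 aquaporin-like sequences across 16 groups
plus 6 decoys), GFF3 gene models with group-typical intron counts, the
annotated reference profile, and the planted-truth table under
results/cohort/.
"""

from pathlib import Path

from aqpscan.feature_scan import write_reference_profile
from aqpscan.seq_core import write_fasta, write_gff3
from aqpscan.synthetic_data import (SequenceSimSpec, simulate_aqp_sequences,
                                    simulate_reference_profile)

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SequenceSimSpec()
    profile = simulate_reference_profile(spec, seed=SEED)
    records, models, truth = simulate_aqp_sequences(spec, profile=profile,
                                                    seed=SEED)
    write_reference_profile(profile, OUT / "reference_profile.tsv")
    write_fasta(records, OUT / "proteins.fasta")
    write_gff3(models, OUT / "genes.gff3")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    n_aqp = int((truth.kind == "aqp").sum())
    print(f"wrote {len(records)} proteins ({n_aqp} aquaporins, "
          f"{len(records) - n_aqp} decoys) and {len(models)} gene models "
          f"to {OUT}")


if __name__ == "__main__":
    main()
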
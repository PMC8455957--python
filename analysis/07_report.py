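"""Assemble the final family table (published column roster) and summary."""

import pandas as pd
from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    rep = run_stage("report", STUDY)
    table = pd.read_csv(f"{STUDY.outdir}/family_table.tsv", sep="\t")
    print(f"Family table with {rep['n_members']} members written; columns:")
    print("  " + " | ".join(table.columns))
    print(table.head(3).to_string(index=False))


if __name__ == "__main__":
    main()
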
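"""Classify duplicate pairs (tandem vs WGD/segmental), chain collinear
blocks, and estimate Ka/Ks selection pressure on the duplicate pairs."""

import pandas as pd
from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    dup = run_stage("duplicates", STUDY)
    run_stage("synteny", STUDY)
    run_stage("kaks", STUDY)
    print(
        f"{dup['n_hits']} similarity hits; {dup['n_blocks']} collinear blocks; "
        f"{dup['tandem_family_pairs']} tandem and "
        f"{dup['segmental_family_pairs']} WGD/segmental family pairs."
    )
    kaks = pd.read_csv(f"{STUDY.outdir}/kaks.tsv", sep="\t")
    counts = kaks["selection_class"].value_counts().to_dict()
    print(f"Ka/Ks over {len(kaks)} duplicate pairs: {counts}")


if __name__ == "__main__":
    main()
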
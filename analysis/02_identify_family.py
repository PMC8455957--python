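"""Identify family members by two-pass profile search and tabulate their
physicochemical properties (length, molecular weight, isoelectric point)."""

import pandas as pd
from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    rep = run_stage("identify", STUDY)
    run_stage("properties", STUDY)
    props = pd.read_csv(
        f"{STUDY.outdir}/protein_properties.tsv", sep="\t"
    )
    print(
        f"Identified {rep['n_members']} family members from "
        f"{rep['n_candidates']} candidates "
        f"(MW gate [{STUDY.mw_min_kda}, {STUDY.mw_max_kda}] kDa)."
    )
    print(
        f"Residues {props['aa_length'].min()}-{props['aa_length'].max()}, "
        f"MW {props['mw_kda'].min():.2f}-{props['mw_kda'].max():.2f} kDa, "
        f"pI {props['pi'].min():.2f}-{props['pi'].max():.2f}."
    )


if __name__ == "__main__":
    main()
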
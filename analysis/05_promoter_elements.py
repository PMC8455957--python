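"""Extract 1.5-kb promoters, scan the cis-element catalog and the two HSE
modules, and test the HSE / heat-up-regulation association."""

import json

import pandas as pd
from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    rep = run_stage("promoters", STUDY)
    summary = pd.read_csv(f"{STUDY.outdir}/cis_element_summary.tsv", sep="\t")
    print(f"{rep['n_cis_elements']} cis-elements; category breakdown:")
    for row in summary.itertuples(index=False):
        print(f"  {row.category}: {row.count} ({row.percent:.2f}%)")
    enr = json.load(open(f"{STUDY.outdir}/hse_enrichment.json"))
    print(
        f"{rep['n_hse_hits']} HSE hits; HSE vs heat-up association: "
        f"OR={enr['odds_ratio']:.2f}, two-tailed Fisher p={enr['p_value']:.2e}"
    )


if __name__ == "__main__":
    main()
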
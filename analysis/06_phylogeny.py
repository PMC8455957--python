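"""Build the family neighbor-joining tree (Poisson distances, pairwise
deletion) with bootstrap supports, on the profile-anchored domain alignment."""

from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    rep = run_stage("tree", STUDY)
    print(
        f"Neighbor-joining tree over {rep['n_taxa']} members with "
        f"{STUDY.bootstrap_replicates} bootstrap replicates -> "
        f"{STUDY.outdir}/family_tree.nwk"
    )


if __name__ == "__main__":
    main()
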
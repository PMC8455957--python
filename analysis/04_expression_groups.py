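"""Z-score the expression matrix, cut the linkage tree into three groups,
and call condition-specific up-regulation."""

from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    rep = run_stage("expression", STUDY)
    sizes = rep["group_sizes"]
    print(
        f"Expression groups (descending size): "
        + ", ".join(f"{k}={v}" for k, v in sorted(sizes.items()))
    )
    print(f"{rep['n_hts_up']} genes called up-regulated under heat (HTS).")


if __name__ == "__main__":
    main()
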
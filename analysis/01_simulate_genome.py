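"""Generate the synthetic study genome and its ground truth.

Writes genome.fasta, genes.gff3, proteins.fasta, cds.fasta, truth.json and
the raw expression matrix under results/pipeline/.
"""

from study_config import STUDY

from hsp20pipe.pipeline import run_stage


def main() -> None:
    report = run_stage("simulate", STUDY)
    print(
        f"Simulated {report['n_genes']} genes on "
        f"{STUDY.simulation.n_chromosomes} chromosomes: "
        f"{report['n_family']} family members, "
        f"{report['n_tandem_pairs']} tandem and "
        f"{report['n_segmental_pairs']} segmental duplicate pairs planted."
    )


if __name__ == "__main__":
    main()
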
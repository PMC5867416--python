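#!/usr/bin/env python
"""Subnetwork discovery and secreted-biomarker nomination on the A-vs-B contrast.

Reads the pipeline artefacts written by analysis/02_run_pipeline.py, ranks
dysregulated subnetworks on the simulated interaction network (permutation
null), and crosses the subgroup contrast with the secreted-protein
annotation to produce the candidate synovial-fluid biomarker table.
"""

from pathlib import Path


from oastrat import biomarkers as bm
from oastrat import io
from oastrat import pathways as pw

DATA = Path("scratch/data")
RUN = Path("scratch/run")
RESULTS = Path("results")


def main() -> None:
    de_ab = io.read_de_table(RUN / "de_B_vs_A.tsv")
    network = io.read_network(DATA / "network.tsv")
    results = pw.find_subnetworks(
        network, de_ab, max_size=30, n_perm=500, seed=0, top_n=10
    )
    sub_table = pw.subnetworks_table(results)
    RESULTS.mkdir(exist_ok=True)
    sub_table.to_csv(RESULTS / "06_subnetworks.tsv", sep="\t", index=False,
                     float_format="%.4g")
    print("top dysregulated subnetworks (A vs B):")
    print(sub_table.drop(columns="nodes").head(5).to_string(index=False))

    secreted = io.read_gene_list(DATA / "secreted.txt")
    table = bm.secreted_biomarkers(de_ab, secreted)
    table.to_csv(RESULTS / "06_biomarkers.tsv", sep="\t", index=False,
                 float_format="%.3f")
    print(f"\n{len(table)} secreted biomarker candidates "
          f"(of {len(secreted)} annotated secreted genes); top rows:")
    print(table.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
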
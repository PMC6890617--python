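"""Reference-population sizes needed for a target prediction accuracy.

Inverts the deterministic accuracy formula r = sqrt(N h2 / (N h2 + Me))
for each trait's REML heritability estimate, using the post-QC marker
count as the effective number of independent segments (the simulated
markers are unlinked).
"""

import os

import pandas as pd

from drumgs import ReferenceSizeQuery, expected_accuracy, required_reference_size
from drumgs.io import read_dosage_tsv

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
TARGETS = (0.5, 0.7, 0.8, 0.9)


def main() -> None:
    geno = read_dosage_tsv(os.path.join(RESULTS, "cohort_qc.tsv"))
    params = pd.read_csv(os.path.join(RESULTS, "genetic_parameters.tsv"), sep="\t")
    me = geno.n_markers
    rows = []
    for _, rec in params.iterrows():
        for r in TARGETS:
            n = required_reference_size(
                ReferenceSizeQuery(h2=rec["h2"], Me=me, target_accuracy=r)
            )
            rows.append({"trait": rec["trait"], "h2": rec["h2"],
                         "target_accuracy": r, "required_N": n})
        print(
            f"{rec['trait']}: h2={rec['h2']:.3f}; accuracy now "
            f"(N=334) = {expected_accuracy(334, rec['h2'], me):.3f}; "
            f"N for r=0.8: {rows[-2]['required_N']}"
        )
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "reference_sizes.tsv"), sep="\t", index=False)


if __name__ == "__main__":
    main()
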
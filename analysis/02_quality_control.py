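"""Marker QC (MAF >= 0.01, missingness <= 0.1, HWE p >= 1e-5) + imputation.

Reads the raw cohort written by 01, applies the filter chain, mean-imputes
the surviving markers and writes the analysis-ready dosage matrix plus the
per-marker QC report.
"""

import os

from drumgs import QCParams, filter_markers, impute_missing
from drumgs.io import read_dosage_tsv, write_dosage_tsv

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    geno = read_dosage_tsv(os.path.join(RESULTS, "cohort_dosages.tsv"))
    kept, report = filter_markers(geno, QCParams())
    imputed = impute_missing(kept, "mean")
    write_dosage_tsv(imputed, os.path.join(RESULTS, "cohort_qc.tsv"))
    report.to_csv(os.path.join(RESULTS, "qc_report.tsv"), sep="\t", index=False)

    dropped = report.loc[~report["kept"], "drop_reason"].value_counts().to_dict()
    print(f"markers in: {geno.n_markers}, kept: {kept.n_markers}, dropped: {dropped}")


if __name__ == "__main__":
    main()
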
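#!/usr/bin/env python
"""Family-vs-rest contrast: the screen used on a low-fitness family.

For each stratum (control, LPS) the first family's mean expression is
compared with all other samples; genes with ratio > 1.5 or < 0.67 (and
at least one mean > 1 TPM) form the up/down lists, which are then tested
for enrichment in the planted truth modules. Writes results/contrast/.
"""

from pathlib import Path

import pandas as pd

from sibxpress import ExpressionMatrix
from sibxpress.contrast import ContrastSpec, contrast_enrichment, group_contrast

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "contrast"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    c = BASE / "cohort"
    expr = ExpressionMatrix.from_tsv(c / "cohort_expr.tsv",
                                     c / "cohort_samples.tsv",
                                     c / "cohort_genes.tsv")
    truth = pd.read_csv(c / "truth_genes.tsv", sep="\t", index_col=0)
    family = sorted(set(expr.samples["family"]))[0]
    gene_sets = {m: set(truth.index[truth["module"] == m])
                 for m in truth["module"].unique()}

    for stratum in ("control", "LPS"):
        res = group_contrast(expr, ContrastSpec(family, stratum))
        res.table.to_csv(OUT / f"{family}_{stratum}_ratios.tsv", sep="\t")
        (OUT / f"{family}_{stratum}_up.txt").write_text("\n".join(res.up) + "\n")
        (OUT / f"{family}_{stratum}_down.txt").write_text("\n".join(res.down) + "\n")
        print(f"{stratum}: family {family} ({res.n_target} samples) vs rest "
              f"({res.n_other}): {len(res.up)} up, {len(res.down)} down")
        enrich = contrast_enrichment(res, gene_sets, list(expr.gene_ids))
        for direction, table in enrich.items():
            if len(table):
                top = table.iloc[0]
                print(f"  {direction}: top module '{top['set']}' "
                      f"overlap {top['overlap']} (q={top['q_value']:.3g})")


if __name__ == "__main__":
    main()
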
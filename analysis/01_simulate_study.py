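#!/usr/bin/env python
"""Generate the synthetic 4-stage expression study and write its inputs.

Produces, under results/study/: the genes x samples expression matrix (TSV),
the sample -> stage map, the annotation gene lists (transcriptional
regulators, chromatin remodelers GO:0016568, cardiac/muscle development) with
a two-column GO map, and a ground-truth summary for later steps.
"""

import json
from pathlib import Path

from vcmnet import simulate
from vcmnet.expression_io import write_expression_matrix, write_gene_set, write_go_map

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate.simulate_expression(simulate.ExpressionSimConfig(seed=SEED))
    write_expression_matrix(study.matrix, OUT / "expression.tsv")
    (OUT / "stage_map.tsv").write_text(
        "".join(
            f"{s}\t{st}\n"
            for s, st in zip(study.matrix.sample_ids, study.matrix.stage_labels)
        )
    )
    for name, genes in study.gene_sets.sets.items():
        write_gene_set(sorted(genes), OUT / f"{name}.txt")
    write_go_map(study.gene_sets.go_map, OUT / "go_map.tsv")
    (OUT / "truth_modules.tsv").write_text(
        "gene\tmodule\n"
        + "".join(
            f"{g}\t{lab}\n"
            for g, lab in zip(study.modules.gene_ids, study.modules.labels)
        )
    )
    truth = {
        "seed": SEED,
        "planted_module_sizes": {
            c: study.modules.module_sizes[c] for c in study.modules.colors
        },
        "true_candidates": study.candidates,
        "n_window_pass": len(study.window_pass),
        "n_window_fail": len(study.window_fail),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(
        f"wrote {study.matrix.n_genes} genes x {study.matrix.n_samples} samples "
        f"across stages {study.matrix.stages};"
    )
    print(f"planted modules: {truth['planted_module_sizes']}, "
          f"true candidates: {study.candidates}")


if __name__ == "__main__":
    main()
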
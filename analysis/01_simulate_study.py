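"""Generate the default synthetic co-exposure study and record its design.

Writes the raw inputs (bulk counts, marker GMT, ligand-receptor pairs,
ground truth) under scratch/ and a small design summary under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from _common import RESULTS, SCRATCH, SEED, ensure_dirs, get_study
from lumideconv.io import write_expression_matrix, write_marker_gmt, write_results_table


def main():
    ensure_dirs()
    study = get_study()
    data_dir = SCRATCH / "study_data"
    data_dir.mkdir(exist_ok=True)
    write_expression_matrix(study.bulk, data_dir / "bulk")
    write_marker_gmt(study.markers, data_dir / "markers.gmt")
    study.lr_pairs.table.to_csv(data_dir / "lr_pairs.csv", index=False)
    study.truth.to_json(data_dir / "truth.json")

    comp = study.truth.composition.copy()
    comp.index = [f"{g}_{c}" for g, c in comp.index]
    write_results_table(comp, RESULTS / "true_composition.tsv", index_label="arm")

    design = pd.DataFrame(
        {
            "value": [
                len(study.truth.gene_ids),
                study.bulk.counts.shape[1],
                study.sc.adata.n_obs,
                len(study.truth.synergy_genes),
                len(study.lr_pairs),
                SEED,
            ]
        },
        index=[
            "n_genes", "n_bulk_samples", "n_cells",
            "n_synergy_genes", "n_lr_pairs", "seed",
        ],
    )
    write_results_table(design, RESULTS / "study_design.tsv", index_label="quantity")

    print(f"study (seed {SEED}): {len(study.truth.gene_ids)} genes, "
          f"{study.bulk.counts.shape[1]} bulk samples "
          f"(4 arms x 2 compartments x 5 replicates), "
          f"{study.sc.adata.n_obs} lavage cells, "
          f"{len(study.truth.synergy_genes)} injected combination-specific genes.")
    print(f"raw inputs under {data_dir}, design summary under {RESULTS}.")


if __name__ == "__main__":
    main()
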
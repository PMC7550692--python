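"""Call DEGs between TP53 groups on a planted expression matrix.

Builds the planted DEG benchmark (2000 genes, 40 true 4-fold shifts,
boundary genes sitting exactly on the two filter thresholds), applies the
expressed-gene and minimum-level filters, and calls DEGs at P <= 0.05 and
|log2FC| >= 1.  Writes the DEG table and the passed gene list for the
enrichment stage.
"""

from pathlib import Path

from pdacdriver import call_degs, filter_expressed, filter_min_level
from pdacdriver.differential_expression import ExpressionMatrix
from pdacdriver.io import write_tsv
from pdacdriver.synthetic_data import generate_deg_benchmark

OUT = Path(__file__).resolve().parents[1] / "results" / "deg"


def main() -> None:
    matrix, groups, truth = generate_deg_benchmark(seed=20260928)
    em = ExpressionMatrix(matrix, groups)
    expressed = filter_expressed(em)
    leveled = filter_min_level(expressed)
    print(
        f"filters: {len(em.values)} genes -> {len(expressed.values)} expressed "
        f"-> {len(leveled.values)} above minimum level"
    )

    table = call_degs(leveled)
    write_tsv(table.loc[table["passed"]], OUT / "degs.tsv")
    called = table.loc[table["passed"], "gene"]
    (OUT / "deg_list.txt").parent.mkdir(parents=True, exist_ok=True)
    (OUT / "deg_list.txt").write_text("\n".join(called) + "\n")
    (OUT / "background.txt").write_text("\n".join(leveled.values.index) + "\n")

    recovered = len(set(called) & truth["true_degs"])
    false_pos = len(set(called) - truth["true_degs"])
    print(
        f"DEGs called: {len(called)} "
        f"({recovered}/{len(truth['true_degs'])} planted recovered, {false_pos} false positives)"
    )


if __name__ == "__main__":
    main()
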
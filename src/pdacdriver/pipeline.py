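"""End-to-end pipeline on synthetic data: simulate → profiles → survival
battery → differential expression → family enrichment, with a manifest.

Each stage writes its TSV output plus a JSON manifest recording the
parameters and sha256 checksums; a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from pdacdriver import (
    build_profiles,
    call_degs,
    driver_contribution_battery,
    enrich_families,
    filter_expressed,
    filter_min_level,
    frequency_summary,
    generate_cohort,
    generate_expression,
)
from pdacdriver.config import RunConfig
from pdacdriver.differential_expression import ExpressionMatrix
from pdacdriver.geneset_enrichment import GeneSet, results_to_frame
from pdacdriver.io import write_manifest, write_matrix_tsv, write_tsv
from pdacdriver.mutation_profiles import filter_exonic
from pdacdriver.survival_analysis import battery_to_frame


def full_run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic-data pipeline into ``out_dir``.

    Returns a dict of stage-output paths; raises with the failing stage's
    name on any error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "simulate"
    try:
        mutations, clinical = generate_cohort(config.cohort_params())
        outputs["mutations"] = write_tsv(mutations, out_dir / "mutations.tsv")
        outputs["clinical"] = write_tsv(clinical, out_dir / "clinical.tsv")

        stage = "profiles"
        profiles = build_profiles(filter_exonic(mutations), clinical)
        outputs["profiles"] = write_tsv(profiles, out_dir / "profiles.tsv")
        summary = frequency_summary(profiles)
        summary_path = out_dir / "frequency_summary.json"
        with open(summary_path, "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")
        outputs["frequency_summary"] = summary_path

        stage = "survival"
        battery = battery_to_frame(driver_contribution_battery(profiles))
        outputs["survival_battery"] = write_tsv(battery, out_dir / "survival_battery.tsv")

        stage = "deg"
        matrix, groups = generate_expression(config.expression_params(), profiles)
        outputs["expression"] = write_matrix_tsv(matrix, out_dir / "expression.tsv")
        em = ExpressionMatrix(matrix, groups)
        em = filter_min_level(filter_expressed(em, config.expressed_frac), config.min_level)
        degs = call_degs(
            em, p_threshold=config.deg_p, abs_log2fc_threshold=config.deg_abs_log2fc
        )
        outputs["degs"] = write_tsv(degs, out_dir / "degs.tsv")

        stage = "enrich"
        family = GeneSet(
            "planted_snoRNA_family",
            frozenset(g for g in em.values.index if g.startswith("SNOR")),
        )
        deg_genes = degs.loc[degs["passed"], "gene"].tolist()
        results = enrich_families(
            {"t_test": deg_genes},
            [family],
            em.values.index,
            reps=config.reps,
            seed=config.stage_seed("enrichment"),
        )
        outputs["enrichment"] = write_tsv(
            results_to_frame(results), out_dir / "enrichment.tsv"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs["manifest"] = write_manifest(
        out_dir / "manifest.json",
        parameters=config.to_dict(),
        outputs={k: v for k, v in outputs.items()},
    )
    return {k: str(v) for k, v in outputs.items()}
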
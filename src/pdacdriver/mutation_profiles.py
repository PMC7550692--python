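"""Per-patient driver-gene profiles from annotated somatic mutations.

Consumes pre-annotated mutation records (region and effect classes as
produced by standard annotators), applies the exonic-region filter, builds
one boolean driver-status profile per patient joined with survival data,
summarises mutation frequencies, and assigns patients to the
mutation-combination strata used by the survival contrast battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DRIVER_GENES = ("KRAS", "TP53", "SMAD4", "CDKN2A")
DRIVER_FLAGS = {gene: f"{gene.lower()}_mut" for gene in DRIVER_GENES}

REGION_VOCAB = ("exonic", "intronic", "UTR5", "UTR3", "splicing", "intergenic", "other")
EFFECT_VOCAB = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "nonframeshift",
    "unknown",
)

_MUTATION_COLUMNS = ("patient_id", "gene", "region", "effect")
_CLINICAL_COLUMNS = ("patient_id", "time", "event")


@dataclass(frozen=True)
class StratumDefinition:
    """A mutation-combination stratum: required mutant and wildtype genes."""

    name: str
    require_mutant: frozenset = field(default_factory=frozenset)
    require_wildtype: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "require_mutant", frozenset(self.require_mutant))
        object.__setattr__(self, "require_wildtype", frozenset(self.require_wildtype))
        overlap = self.require_mutant & self.require_wildtype
        if overlap:
            raise ValueError(
                f"stratum {self.name!r}: genes {sorted(overlap)} required both mutant and wildtype"
            )

    def matches(self, flags: Mapping[str, bool]) -> bool:
        return all(flags[g] for g in self.require_mutant) and not any(
            flags[g] for g in self.require_wildtype
        )


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read and normalize a mutation TSV (patient_id, gene, region, effect).

    Region/effect labels are case-folded; values outside the closed
    vocabularies are mapped to "other"/"unknown" with a logged warning.
    Rows with empty patient_id or gene are rejected with their line number.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MUTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mutation table {path} is missing required column(s): {missing}")

    table = table.loc[:, list(_MUTATION_COLUMNS)].copy()
    for idx, row in table.iterrows():
        line = idx + 2  # header is line 1
        if pd.isna(row["patient_id"]) or not str(row["patient_id"]).strip():
            raise ValueError(f"{path}: line {line}: empty patient_id")
        if pd.isna(row["gene"]) or not str(row["gene"]).strip():
            raise ValueError(f"{path}: line {line}: empty gene")

    region = table["region"].fillna("other").str.strip().str.lower()
    region_map = {v.lower(): v for v in REGION_VOCAB}
    unknown_regions = sorted(set(region) - set(region_map))
    if unknown_regions:
        logger.warning("unknown region value(s) %s mapped to 'other'", unknown_regions)
    table["region"] = region.map(region_map).fillna("other")

    effect = table["effect"].fillna("unknown").str.strip().str.lower()
    effect_map = {v.lower(): v for v in EFFECT_VOCAB}
    unknown_effects = sorted(set(effect) - set(effect_map))
    if unknown_effects:
        logger.warning("unknown effect value(s) %s mapped to 'unknown'", unknown_effects)
    table["effect"] = effect.map(effect_map).fillna("unknown")
    return table


def filter_exonic(records: pd.DataFrame, drop_synonymous: bool = False) -> pd.DataFrame:
    """Keep exon-region mutations only (strict region match, order preserved).

    Splicing variants do not count as exonic.  Synonymous variants are kept
    unless ``drop_synonymous`` is set: the region filter names the region,
    not the effect class.
    """
    keep = records["region"] == "exonic"
    if drop_synonymous:
        keep &= records["effect"] != "synonymous"
    return records.loc[keep]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical/survival TSV keyed by patient_id."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing required column(s): {missing}")
    return table


def build_profiles(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    driver_genes: Sequence[str] = DRIVER_GENES,
) -> pd.DataFrame:
    """One profile row per clinical patient with boolean driver flags.

    A driver flag is true iff at least one (exonic-filtered) record exists
    for that gene; ``n_driver_mut`` counts mutated genes, not variants.
    Patients present in only one of the two tables are reported via a
    logged warning; mutation-only patients are dropped, clinical-only
    patients get all-false flags.
    """
    if clinical["patient_id"].duplicated().any():
        dupes = clinical.loc[clinical["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id(s) in clinical table: {sorted(set(dupes))}")
    if clinical.empty:
        raise ValueError("clinical table is empty")

    clinical_ids = set(clinical["patient_id"])
    mutation_ids = set(records["patient_id"])
    orphan_mutations = mutation_ids - clinical_ids
    if orphan_mutations:
        logger.warning(
            "%d patient(s) with mutation data but no clinical row dropped: %s",
            len(orphan_mutations),
            sorted(orphan_mutations)[:10],
        )
    no_mutation_data = clinical_ids - mutation_ids
    if no_mutation_data:
        logger.warning(
            "%d clinical patient(s) without any mutation rows (all flags false)",
            len(no_mutation_data),
        )

    profiles = clinical.copy().reset_index(drop=True)
    for gene in driver_genes:
        mutated = set(records.loc[records["gene"] == gene, "patient_id"])
        profiles[f"{gene.lower()}_mut"] = profiles["patient_id"].isin(mutated)
    flag_cols = [f"{g.lower()}_mut" for g in driver_genes]
    profiles["n_driver_mut"] = profiles[flag_cols].sum(axis=1).astype(int)
    return profiles


def frequency_summary(profiles: pd.DataFrame) -> dict:
    """Per-gene mutation frequencies and co-mutation summaries, in percent.

    Reports, with numerator/denominator: each driver gene's frequency, the
    fraction of multi-mutant patients (n_driver_mut >= 2), the
    mutation-count distribution, and the fraction of multi-mutant patients
    carrying KRAS.
    """
    if profiles.empty:
        raise ValueError("cannot summarise an empty profile table")
    n = len(profiles)
    summary: dict = {"n_patients": n, "genes": {}, "count_distribution": {}}
    for gene, flag in DRIVER_FLAGS.items():
        k = int(profiles[flag].sum())
        summary["genes"][gene] = {"n_mutant": k, "n_total": n, "percent": 100.0 * k / n}
    counts = profiles["n_driver_mut"].value_counts().sort_index()
    summary["count_distribution"] = {int(c): int(v) for c, v in counts.items()}
    multi = profiles["n_driver_mut"] >= 2
    n_multi = int(multi.sum())
    summary["multi_mutant"] = {"n": n_multi, "n_total": n, "percent": 100.0 * n_multi / n}
    if n_multi:
        k = int((multi & profiles["kras_mut"]).sum())
        summary["kras_among_multi"] = {
            "n": k,
            "n_total": n_multi,
            "percent": 100.0 * k / n_multi,
        }
    else:
        summary["kras_among_multi"] = {"n": 0, "n_total": 0, "percent": float("nan")}
    return summary


def validate_strata(
    strata: Sequence[StratumDefinition], driver_genes: Sequence[str] = DRIVER_GENES
) -> None:
    """Ensure no two strata match the same driver-status combination."""
    for combo in product([False, True], repeat=len(driver_genes)):
        flags = dict(zip(driver_genes, combo))
        matching = [s.name for s in strata if s.matches(flags)]
        if len(matching) > 1:
            raise ValueError(
                f"strata {matching} overlap on driver-status combination {flags}"
            )


def assign_stratum(
    profile: Mapping[str, bool] | pd.Series,
    strata: Sequence[StratumDefinition],
    driver_genes: Sequence[str] = DRIVER_GENES,
) -> str:
    """Return the unique matching stratum label, or "unassigned".

    ``profile`` may be a profile row (with ``<gene>_mut`` flags) or a plain
    gene → bool mapping.
    """
    flags = {}
    for gene in driver_genes:
        key = f"{gene.lower()}_mut"
        flags[gene] = bool(profile[key] if key in profile else profile[gene])
    for stratum in strata:
        if stratum.matches(flags):
            return stratum.name
    return "unassigned"
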
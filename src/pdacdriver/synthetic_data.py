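"""Synthetic PDAC cohorts, expression matrices and qPCR Ct tables.

Every downstream stage of the pipeline (profiles, survival battery,
differential expression, family enrichment, rRNA quantification) is
exercised against data generated here with known planted structure:
driver-mutation marginals matching the observed PDAC frequencies, a
tunable TP53 co-occurrence link for SMAD4/CDKN2A, exponential
proportional-hazards survival, log-normal expression with a planted
family-level log2 shift in TP53-mutant samples, and Ct values encoding an
exact unprocessed-rRNA fraction.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

DRIVER_GENES = ("KRAS", "TP53", "SMAD4", "CDKN2A")

#: amplicon labels per rRNA species: one "total" amplicon and two
#: "unprocessed" (spacer-containing) amplicons, named after the primer
#: pairs that amplify them.
QPCR_AMPLICONS: Mapping[str, Mapping[str, tuple]] = {
    "18S": {"total": "pair_2_1", "unprocessed": ("pair_4_3", "pair_6_5")},
    "28S": {"total": "pair_b_a", "unprocessed": ("pair_d_c", "pair_f_e")},
}


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic mutation + survival cohort.

    Marginal mutation frequencies default to the observed PDAC values
    (KRAS 90.43%, TP53 69.13%, SMAD4 23.21%, CDKN2A 20.66%).  SMAD4 and
    CDKN2A are linked to TP53 status through a logistic shift of
    ``co_occurrence_logodds`` while their marginals are preserved exactly.
    Survival is exponential proportional hazards: the per-patient hazard is
    ``baseline_hazard`` times the product of the hazard ratios of the
    patient's mutated genes, with independent exponential censoring.

    Time unit is months: ``baseline_hazard`` of 0.035/month corresponds to
    a ~20-month median survival in the reference (KRAS-only) stratum.
    """

    n_patients: int = 762
    freq_kras: float = 0.9043
    freq_tp53: float = 0.6913
    freq_smad4: float = 0.2321
    freq_cdkn2a: float = 0.2066
    co_occurrence_logodds: float = 1.5
    hr_tp53: float = 2.0
    hr_smad4: float = 1.0
    hr_cdkn2a: float = 1.0
    baseline_hazard: float = 0.035
    censor_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_patients) != self.n_patients or self.n_patients <= 0:
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        for name in ("freq_kras", "freq_tp53", "freq_smad4", "freq_cdkn2a"):
            _check_prob(getattr(self, name), name)
        for name in ("hr_tp53", "hr_smad4", "hr_cdkn2a", "baseline_hazard", "censor_rate"):
            _check_positive(getattr(self, name), name)


@dataclass(frozen=True)
class ExpressionSimParams:
    """Parameters of the synthetic normalized expression matrix.

    Expression is log-normal on the log2 scale with per-gene baseline means
    drawn from N(``baseline_log2_mean``, ``baseline_log2_sd``).  The first
    ``n_family_genes`` genes form the planted family whose mean log2
    expression is shifted by ``family_shift_log2`` in TP53-mutant samples.
    Dropout zeros are injected uniformly at rate ``frac_zero``.
    """

    n_genes: int = 2000
    n_family_genes: int = 40
    family_shift_log2: float = 2.0
    noise_sd_log2: float = 0.3
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    frac_zero: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_family_genes < 0 or self.n_family_genes > self.n_genes:
            raise ValueError(
                f"n_family_genes must lie in [0, n_genes]; got {self.n_family_genes} "
                f"with n_genes={self.n_genes}"
            )
        _check_positive(self.noise_sd_log2, "noise_sd_log2")
        _check_prob(self.frac_zero, "frac_zero")


@dataclass(frozen=True)
class QpcrSimParams:
    """Parameters of the synthetic qPCR Ct table.

    ``unprocessed_18s`` / ``unprocessed_28s`` are the true unprocessed
    precursor fractions planted per species.  Noise-free Ct values satisfy
    ``Ct_unprocessed = Ct_total - log2(fraction)`` so that the ΔCt
    quantity ratio recovers the planted fraction exactly.
    """

    unprocessed_18s: float = 0.3
    unprocessed_28s: float = 0.3
    ct_total_mean: float = 20.0
    ct_noise_sd: float = 0.0
    n_replicates: int = 3
    samples: Sequence[str] = ("sample_1",)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unprocessed_18s", "unprocessed_28s"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value!r}")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.samples) == 0:
            raise ValueError("samples must be nonempty")


def _marginal_preserving_intercept(target: float, p_tp53: float, logodds: float) -> float:
    """Intercept b such that the TP53-mixture marginal equals ``target``.

    Solves (1-p_tp53)*sigmoid(b) + p_tp53*sigmoid(b + logodds) = target.
    """
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def gap(b: float) -> float:
        return (1 - p_tp53) * expit(b) + p_tp53 * expit(b + logodds) - target

    return brentq(gap, -40.0, 40.0)


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a mutation table and a clinical/survival table.

    Returns ``(mutations, clinical)``:

    * ``mutations`` — one row per mutated driver gene per patient with
      columns ``patient_id, gene, region, effect`` (all region "exonic").
    * ``clinical`` — one row per patient with columns
      ``patient_id, time, event, age, gender, cohort``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(params.n_patients)
    patient_ids = np.array([f"P{i + 1:05d}" for i in range(n)])

    kras = rng.random(n) < params.freq_kras
    tp53 = rng.random(n) < params.freq_tp53

    status = {"KRAS": kras, "TP53": tp53}
    for gene, freq in (("SMAD4", params.freq_smad4), ("CDKN2A", params.freq_cdkn2a)):
        b = _marginal_preserving_intercept(freq, params.freq_tp53, params.co_occurrence_logodds)
        p = expit(b + params.co_occurrence_logodds * tp53)
        status[gene] = rng.random(n) < p

    hazard = params.baseline_hazard * (
        np.where(status["TP53"], params.hr_tp53, 1.0)
        * np.where(status["SMAD4"], params.hr_smad4, 1.0)
        * np.where(status["CDKN2A"], params.hr_cdkn2a, 1.0)
    )
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / params.censor_rate, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    age = np.clip(rng.normal(65.0, 10.0, size=n), 30.0, 90.0).round(1)
    gender = rng.choice(["female", "male"], size=n)
    # three source cohorts in the observed 154:461:308 proportion
    cohort = rng.choice(["TCGA", "PACA-AU", "PACA-CA"], size=n, p=np.array([154, 461, 308]) / 923)

    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time": time,
            "event": event,
            "age": age,
            "gender": gender,
            "cohort": cohort,
        }
    )

    effects = ("nonsynonymous", "stopgain", "frameshift")
    rows = []
    for gene in DRIVER_GENES:
        mutated = np.flatnonzero(status[gene])
        gene_effects = rng.choice(effects, size=mutated.size, p=[0.7, 0.15, 0.15])
        for idx, eff in zip(mutated, gene_effects):
            rows.append((patient_ids[idx], gene, "exonic", eff))
    mutations = pd.DataFrame(rows, columns=["patient_id", "gene", "region", "effect"])
    mutations = mutations.sort_values(["patient_id", "gene"], kind="stable").reset_index(drop=True)
    return mutations, clinical


def tp53_status_from_mutations(mutations: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Attach a boolean ``tp53_mut`` column to a clinical table.

    Convenience for feeding :func:`generate_expression` without going
    through the full profile builder.
    """
    mutant = set(mutations.loc[mutations["gene"] == "TP53", "patient_id"])
    out = clinical.copy()
    out["tp53_mut"] = out["patient_id"].isin(mutant)
    return out


def generate_expression(
    params: ExpressionSimParams, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes × samples normalized expression matrix.

    ``samples`` must carry ``patient_id`` and a boolean ``tp53_mut``
    column (as produced by the profile builder or
    :func:`tp53_status_from_mutations`).  Family genes are named
    ``SNOR0001`` ... and background genes ``G000001`` ...; the family
    genes' mean log2 expression is shifted by ``family_shift_log2`` in
    TP53-mutant samples.

    Returns ``(matrix, groups)`` where ``groups`` maps each sample to
    ``"TP53_mut"`` or ``"TP53_wt"``.
    """
    if "tp53_mut" not in samples.columns:
        raise ValueError("samples table must carry a 'tp53_mut' column")
    if "patient_id" not in samples.columns:
        raise ValueError("samples table must carry a 'patient_id' column")

    rng = np.random.default_rng(params.seed)
    n_fam = params.n_family_genes
    genes = [f"SNOR{i + 1:04d}" for i in range(n_fam)] + [
        f"G{i + 1:06d}" for i in range(params.n_genes - n_fam)
    ]
    sample_ids = samples["patient_id"].to_numpy()
    mut = samples["tp53_mut"].to_numpy(dtype=bool)
    n_samples = sample_ids.size

    base = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=params.n_genes)
    shift = np.zeros((params.n_genes, n_samples))
    shift[:n_fam, mut] = params.family_shift_log2
    log2_expr = (
        base[:, None] + shift + rng.normal(0.0, params.noise_sd_log2, size=(params.n_genes, n_samples))
    )
    values = np.exp2(log2_expr)
    if params.frac_zero > 0:
        values[rng.random(values.shape) < params.frac_zero] = 0.0

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    groups = pd.Series(
        np.where(mut, "TP53_mut", "TP53_wt"), index=sample_ids, name="group"
    )
    return matrix, groups


def generate_deg_benchmark(
    n_genes: int = 2000,
    n_true: int = 40,
    n_per_group: int = 50,
    shift_log2: float = 2.0,
    noise_sd_log2: float = 0.3,
    n_dropout: int = 10,
    n_low: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Planted DEG benchmark with filter-boundary genes.

    Builds a matrix of ``n_genes`` well-expressed genes of which the first
    ``n_true`` carry a ``shift_log2`` mean shift in the mutant group, plus
    ``n_dropout`` genes positive in exactly 20% of samples (to be removed
    by the expressed-gene filter, which requires strictly more than 20%)
    and ``n_low`` genes with group means below 5 in both groups (to be
    removed by the minimum-level filter).

    Returns ``(matrix, groups, truth)`` where ``truth`` holds the gene-name
    sets ``true_degs``, ``dropout_genes`` and ``low_genes``.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    group = np.array(["TP53_mut"] * n_per_group + ["TP53_wt"] * n_per_group)
    mut = group == "TP53_mut"

    # baseline log2 means clipped away from the min-level boundary so only
    # the constructed low-level genes can fail that filter
    base = np.clip(rng.normal(6.0, 1.0, size=n_genes), 3.5, None)
    shift = np.zeros((n_genes, n_samples))
    shift[:n_true, mut] = shift_log2
    values = np.exp2(base[:, None] + shift + rng.normal(0.0, noise_sd_log2, (n_genes, n_samples)))
    genes = [f"DEG{i + 1:04d}" if i < n_true else f"NULL{i + 1:04d}" for i in range(n_genes)]

    # boundary genes: positive in exactly 20% of samples (strict ">20%" drops them)
    n_pos = int(round(0.2 * n_samples))
    drop_vals = np.zeros((n_dropout, n_samples))
    for i in range(n_dropout):
        pos = rng.choice(n_samples, size=n_pos, replace=False)
        drop_vals[i, pos] = np.exp2(rng.normal(6.0, 0.3, size=n_pos))
    drop_genes = [f"DROP{i + 1:03d}" for i in range(n_dropout)]

    # low-level genes: expressed everywhere but group means < 5 in both groups
    low_vals = np.exp2(rng.normal(1.0, 0.2, size=(n_low, n_samples)))
    low_genes = [f"LOW{i + 1:03d}" for i in range(n_low)]

    matrix = pd.DataFrame(
        np.vstack([values, drop_vals, low_vals]),
        index=pd.Index(genes + drop_genes + low_genes, name="gene"),
        columns=sample_ids,
    )
    groups = pd.Series(group, index=sample_ids, name="group")
    truth = {
        "true_degs": set(genes[:n_true]),
        "dropout_genes": set(drop_genes),
        "low_genes": set(low_genes),
    }
    return matrix, groups, truth


def generate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Simulate a long-format Ct table (sample, species, amplicon, replicate, ct).

    Noise-free Cts encode the planted fractions exactly:
    ``Ct_unprocessed = ct_total_mean - log2(fraction)``.
    """
    rng = np.random.default_rng(params.seed)
    fractions = {"18S": params.unprocessed_18s, "28S": params.unprocessed_28s}
    rows = []
    for sample in params.samples:
        for species, layout in QPCR_AMPLICONS.items():
            ct_clean = {layout["total"]: params.ct_total_mean}
            for amp in layout["unprocessed"]:
                ct_clean[amp] = params.ct_total_mean - np.log2(fractions[species])
            for amp, ct0 in ct_clean.items():
                noise = rng.normal(0.0, params.ct_noise_sd, size=params.n_replicates)
                for rep in range(params.n_replicates):
                    rows.append((sample, species, amp, rep + 1, ct0 + noise[rep]))
    return pd.DataFrame(rows, columns=["sample", "species", "amplicon", "replicate", "ct"])
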
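"""Unprocessed rRNA fractions from qPCR Ct values.

Each rRNA species is probed with one amplicon spanning a region present in
all transcripts ("total") and two amplicons spanning precursor-only spacer
regions ("unprocessed"): primer pairs 4/3 and 6/5 over 2/1 for 18S, and
d/c and f/e over b/a for 28S.  Assuming 100% amplification efficiency a
one-cycle Ct difference is a two-fold quantity difference, so each
unprocessed-over-total quantity ratio is 2^(Ct_total − Ct_unprocessed) and
the species' unprocessed fraction is the arithmetic mean of its two
amplicon ratios.  Fractions are pure ratios and need no reference-gene
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdacdriver.synthetic_data import QPCR_AMPLICONS


@dataclass(frozen=True)
class ProcessingRateResult:
    """Per-sample unprocessed fraction of one rRNA species."""

    sample: str
    species: str
    unprocessed_fraction: float
    component_ratios: tuple


def amplicon_ratio(ct_num: float, ct_den: float, efficiency: float = 2.0) -> float:
    """Relative quantity of the numerator amplicon over the denominator:
    efficiency^(Ct_den − Ct_num).  Replicate Cts must already be averaged."""
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency!r}")
    return float(efficiency ** (ct_den - ct_num))


def _mean_ct(ct_table: pd.DataFrame, sample: str, species: str, amplicon: str) -> float:
    rows = ct_table[
        (ct_table["sample"] == sample)
        & (ct_table["species"] == species)
        & (ct_table["amplicon"] == amplicon)
    ]
    if rows.empty:
        raise ValueError(
            f"missing amplicon {amplicon!r} for sample {sample!r}, species {species!r}"
        )
    return float(rows["ct"].mean())


def unprocessed_fraction(
    ct_table: pd.DataFrame, sample: str, species: str, efficiency: float = 2.0
) -> ProcessingRateResult:
    """Unprocessed fraction for one (sample, species).

    Mean of the two unprocessed-over-total amplicon ratios, replicates
    combined by mean Ct before ratioing.
    """
    if species not in QPCR_AMPLICONS:
        raise ValueError(f"unknown rRNA species {species!r}; expected one of {list(QPCR_AMPLICONS)}")
    layout = QPCR_AMPLICONS[species]
    ct_total = _mean_ct(ct_table, sample, species, layout["total"])
    ratios = tuple(
        amplicon_ratio(_mean_ct(ct_table, sample, species, amp), ct_total, efficiency)
        for amp in layout["unprocessed"]
    )
    return ProcessingRateResult(
        sample=sample,
        species=species,
        unprocessed_fraction=float(np.mean(ratios)),
        component_ratios=ratios,
    )


def fractions_table(ct_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Unprocessed fractions for every (sample, species) in a Ct table."""
    rows = []
    pairs = ct_table[["sample", "species"]].drop_duplicates()
    for sample, species in pairs.itertuples(index=False):
        r = unprocessed_fraction(ct_table, sample, species, efficiency)
        rows.append(
            {
                "sample": r.sample,
                "species": r.species,
                "unprocessed_fraction": r.unprocessed_fraction,
                "ratio_1": r.component_ratios[0],
                "ratio_2": r.component_ratios[1],
            }
        )
    return pd.DataFrame(rows)


def fold_change_vs_control(fractions: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Normalize fractions to the control-group mean, per species.

    ``fractions`` needs columns sample, species, unprocessed_fraction and
    group; the output adds ``fold_change`` so that the control group
    averages 1 within each species.
    """
    if "group" not in fractions.columns:
        raise ValueError("fractions table must carry a 'group' column")
    control = fractions[fractions["group"] == control_label]
    if control.empty:
        raise ValueError(f"control group {control_label!r} is empty")
    out = fractions.copy()
    out["fold_change"] = np.nan
    for species, sub in fractions.groupby("species"):
        ctrl_mean = control.loc[control["species"] == species, "unprocessed_fraction"].mean()
        if not ctrl_mean > 0:
            raise ValueError(f"control mean fraction for {species} is 0: cannot normalize")
        out.loc[sub.index, "fold_change"] = sub["unprocessed_fraction"] / ctrl_mean
    return out
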
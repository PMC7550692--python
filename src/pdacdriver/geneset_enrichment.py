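"""Gene-family over-representation: Fisher's exact test, the
enrichment-ratio statistic, and a random-sampling permutation test.

For a family of ``m`` genes in an ``N``-gene background with ``k`` called
DEGs of which ``a`` fall in the family:

* Fisher's exact test on the 2×2 table [[a, m−a], [k−a, N−m−(k−a)]],
  with the sample odds ratio and an exact-conditional confidence interval.
* The enrichment ratio (a/m) / ((k−a)/(N−m)) — the DEG fraction inside the
  family over the DEG fraction outside it.
* A permutation test drawing the same number of DEGs uniformly at random
  from the background 10^6 times: the Monte-Carlo P is the fraction of
  draws with a family count at least ``a``, and the permutation odds ratio
  is ``a`` over the mean simulated family count, with a CI from the
  standard error of that mean.

Drawing k genes without replacement and counting family members is
exactly a hypergeometric draw of the overlap count, which is how the
default sampling mode is implemented; a literal subset-sampling mode is
kept for validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

logger = logging.getLogger(__name__)

DEFAULT_REPS = 1_000_000


@dataclass(frozen=True)
class GeneSet:
    """A named gene family or cluster."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts underlying one family-enrichment test.

    a: family genes among the DEGs; m: family genes in the background;
    k: DEGs in the background; N: background size.
    """

    a: int
    m: int
    k: int
    N: int

    def __post_init__(self) -> None:
        if not 0 <= self.a <= min(self.m, self.k):
            raise ValueError(f"need 0 <= a <= min(m, k); got {self}")
        if not (self.m <= self.N and self.k <= self.N):
            raise ValueError(f"need m <= N and k <= N; got {self}")
        if self.k - self.a > self.N - self.m:
            raise ValueError(f"non-family DEGs exceed non-family background; got {self}")

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.a, self.m - self.a],
            [self.k - self.a, self.N - self.m - (self.k - self.a)],
        ]


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    sample_or: float
    or_ci: tuple


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    p_is_bound: bool  # True when no draw reached the observed count: P < 1/reps
    odds_ratio: float
    or_ci: tuple
    reps: int
    seed: int

    @property
    def p_display(self) -> str:
        if self.p_is_bound:
            return f"<{1.0 / self.reps:.2e}"
        return f"{self.p_value:.3g}"


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT gene-set file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {line_no}: GMT rows need name, description and >=1 gene"
                )
            members = [g.strip() for g in fields[2:] if g.strip()]
            sets.append(GeneSet(name=fields[0], members=frozenset(members)))
    if not sets:
        raise ValueError(f"GMT file {path} contains no gene sets")
    return sets


def build_contingency(
    deg_genes: Iterable[str], gene_set: GeneSet, background: Iterable[str]
) -> ContingencyTable:
    """Count the (a, m, k, N) table for one DEG list × family pair.

    DEGs outside the background are logged and dropped; the family is
    intersected with the background.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    degs = set(deg_genes)
    outside = degs - background
    if outside:
        logger.warning(
            "%d DEG(s) not in background dropped for %s: %s",
            len(outside), gene_set.name, sorted(outside)[:5],
        )
        degs &= background
    family = gene_set.members & background
    return ContingencyTable(
        a=len(degs & family), m=len(family), k=len(degs), N=len(background)
    )


def fisher_enrichment(table: ContingencyTable) -> FisherResult:
    """Two-sided Fisher exact P with sample OR and exact-conditional CI.

    The sample odds ratio is a(N−m−k+a) / ((m−a)(k−a)), with the
    conventions 0 when a = 0 and infinity when the denominator vanishes
    with a > 0.
    """
    t = table.as_2x2()
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    a, b = t[0]
    c, d = t[1]
    if a == 0:
        sample_or = 0.0
    elif b * c == 0:
        sample_or = math.inf
    else:
        sample_or = a * d / (b * c)
    ci = _conditional_odds_ratio(t, kind="conditional").confidence_interval(0.95)
    return FisherResult(p_value=p, sample_or=sample_or, or_ci=(float(ci.low), float(ci.high)))


def enrichment_ratio(table: ContingencyTable) -> float:
    """DEG fraction inside the family over the DEG fraction outside it:
    (a/m) / ((k−a)/(N−m)).  0 when a = 0; infinite when all DEGs are in
    the family (a = k > 0)."""
    if table.m == 0:
        raise ValueError("family has no genes in the background (m = 0): not evaluable")
    if table.a == 0:
        return 0.0
    outside_frac_num = table.k - table.a
    if outside_frac_num == 0:
        return math.inf
    return (table.a / table.m) / (outside_frac_num / (table.N - table.m))


def permutation_enrichment(
    table: ContingencyTable,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    alternative: str = "greater",
    mode: str = "hypergeometric",
) -> PermutationResult:
    """Random-sampling permutation test of family over-representation.

    Each of ``reps`` simulated DEG sets draws ``k`` genes uniformly
    without replacement from the ``N``-gene background and records how
    many fall in the family.  The Monte-Carlo P is the raw fraction of
    draws with count >= a ("less" tests depletion instead); a zero count
    is reported as the bound P < 1/reps.  The permutation odds ratio is
    a / mean(simulated counts), with the CI
    (a/(mean+1.96·se), a/(mean−1.96·se)) from the standard error of the
    simulated mean.
    """
    if reps < 1000:
        raise ValueError(f"reps must be >= 1000, got {reps}")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if table.m == 0 or table.k == 0:
        raise ValueError("m = 0 or k = 0: permutation test not evaluable")

    rng = np.random.default_rng(seed)
    if mode == "hypergeometric":
        counts = rng.hypergeometric(table.m, table.N - table.m, table.k, size=reps)
    elif mode == "subset":
        # literal draw of k-gene subsets; validation mode, O(reps * N)
        counts = np.empty(reps, dtype=np.int64)
        for i in range(reps):
            chosen = rng.choice(table.N, size=table.k, replace=False)
            counts[i] = int((chosen < table.m).sum())
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    if alternative == "greater":
        n_extreme = int((counts >= table.a).sum())
    else:
        n_extreme = int((counts <= table.a).sum())
    p_is_bound = n_extreme == 0
    p_value = 1.0 / reps if p_is_bound else n_extreme / reps

    mean = float(counts.mean())
    if mean == 0.0:
        raise ValueError("mean simulated family count is 0: not evaluable")
    se = float(counts.std(ddof=1)) / math.sqrt(reps)
    if table.a == 0:
        odds, ci = 0.0, (0.0, 0.0)
    else:
        odds = table.a / mean
        hi = table.a / (mean - 1.96 * se) if mean - 1.96 * se > 0 else math.inf
        ci = (table.a / (mean + 1.96 * se), hi)
    return PermutationResult(
        p_value=p_value, p_is_bound=p_is_bound, odds_ratio=odds, or_ci=ci,
        reps=reps, seed=seed,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """All statistics for one (DEG list, family) pair."""

    deg_list: str
    family: str
    table: ContingencyTable
    fisher: FisherResult
    ratio: float
    permutation: PermutationResult


def enrich_families(
    deg_sets: Mapping[str, Iterable[str]],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Run Fisher + ratio + permutation for every DEG list × family pair.

    Per-pair permutation seeds are spawned deterministically from ``seed``
    so the full result table is reproducible byte-for-byte.
    """
    if not deg_sets:
        raise ValueError("need at least one DEG list")
    if not gene_sets:
        raise ValueError("need at least one gene set")
    background = list(background)
    results: list[EnrichmentResult] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(deg_sets) * len(gene_sets))
    i = 0
    for list_name, degs in deg_sets.items():
        degs = list(degs)
        for gene_set in gene_sets:
            table = build_contingency(degs, gene_set, background)
            pair_seed = int(child_seeds[i] % (2**31))
            i += 1
            results.append(
                EnrichmentResult(
                    deg_list=list_name,
                    family=gene_set.name,
                    table=table,
                    fisher=fisher_enrichment(table),
                    ratio=enrichment_ratio(table),
                    permutation=permutation_enrichment(table, reps=reps, seed=pair_seed),
                )
            )
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Serialize enrichment results in family-table column order."""
    rows = []
    for r in results:
        rows.append(
            {
                "deg_list": r.deg_list,
                "family": r.family,
                "family_size": r.table.m,
                "family_degs": r.table.a,
                "n_degs": r.table.k,
                "background": r.table.N,
                "fisher_p": r.fisher.p_value,
                "enrichment_ratio": r.ratio,
                "fisher_or_ci_low": r.fisher.or_ci[0],
                "fisher_or_ci_high": r.fisher.or_ci[1],
                "perm_p": r.permutation.p_display,
                "perm_or": r.permutation.odds_ratio,
                "perm_or_ci_low": r.permutation.or_ci[0],
                "perm_or_ci_high": r.permutation.or_ci[1],
            }
        )
    return pd.DataFrame(rows)
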
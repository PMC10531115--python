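"""Locus-specific ancestry enrichment: random controls, classification, tests.

A locus is *enriched* for an ancestry when its cohort-average proportion for
that ancestry strictly exceeds a threshold (default 0.50; strict inequality
makes the classes disjoint for any threshold ≥ 0.5, so every locus is either
assigned to exactly one ancestry or left unclassified). Target loci are
compared against a seeded random-control panel drawn from the genome-wide
summary with the targets excluded, using a 2×C contingency test: Pearson's
chi-square when every expected cell is at least 5, otherwise Fisher's exact
test (exhaustive conditional enumeration, exact for any 2×C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .ancestry import LocusAncestrySummary
from .catalog import SnpCatalog
from .errors import DegenerateInputError, SizeError, ValidationError

UNCLASSIFIED = "unclassified"

#: Published cohort tables round proportions to 2 decimals, so their rows can
#: sum to 0.99 or 1.01; computed summaries are validated at 1e-6 upstream.
PUBLISHED_SUM_ATOL = 0.02


@dataclass(frozen=True)
class EnrichmentConfig:
    """Classification threshold (strict >) and random-panel size."""

    threshold: float = 0.50
    n_random: int = 60
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must lie in (0, 1)")
        if self.n_random < 1:
            raise ValidationError("n_random must be >= 1")


@dataclass
class EnrichmentCounts:
    """Per-ancestry enriched-locus counts over a set of loci."""

    counts: dict[str, int]
    n_loci: int
    n_unclassified: int

    def __post_init__(self):
        if sum(self.counts.values()) + self.n_unclassified != self.n_loci:
            raise ValidationError("enrichment classes must partition the loci")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def as_row(self) -> dict[str, int]:
        row = dict(self.counts)
        row[UNCLASSIFIED] = self.n_unclassified
        return row


@dataclass
class ContingencyResult:
    """Outcome of the target-vs-control comparison."""

    table: np.ndarray            # 2 x C integer counts (zero columns dropped)
    columns: tuple[str, ...]
    statistic: Optional[float]
    p_value: float
    method: str                  # "chi-square" or "fisher"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def _avg_table(
    rows: Union[LocusAncestrySummary, pd.DataFrame],
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Extract the (n, K) average-ancestry matrix and its labels."""
    if isinstance(rows, LocusAncestrySummary):
        return rows.avg, rows.labels
    df = rows
    meta = {"rsid", "chrom", "chr", "pos", "pos_bp", "position", "cm", "relation"}
    cols = [
        c
        for c in df.columns
        if c.strip().lower() not in meta and pd.api.types.is_numeric_dtype(df[c])
    ]
    if not cols:
        raise ValidationError("no ancestry-proportion columns found")
    avg = df[cols].to_numpy(dtype=float)
    return avg, tuple(c.removeprefix("avg_") for c in cols)


def count_enriched(
    rows: Union[LocusAncestrySummary, pd.DataFrame],
    cfg: EnrichmentConfig = EnrichmentConfig(),
    sum_atol: float = PUBLISHED_SUM_ATOL,
) -> EnrichmentCounts:
    """Classify loci by dominant ancestry at a strict threshold.

    A locus counts toward ancestry ``a`` when its average proportion for
    ``a`` is strictly greater than ``cfg.threshold``; loci with no ancestry
    above threshold are unclassified. Row order is irrelevant. Rows whose
    proportions do not sum to 1 within ``sum_atol`` raise
    :class:`ValidationError` (the default tolerance admits published tables
    rounded to 2 decimals).
    """
    avg, labels = _avg_table(rows)
    if avg.size:
        dev = np.abs(avg.sum(axis=1) - 1.0)
        if dev.max() > sum_atol:
            i = int(dev.argmax())
            raise ValidationError(
                f"row {i}: ancestry proportions sum to {avg[i].sum():.4g}, "
                f"outside 1±{sum_atol:g}"
            )
    counts = {lab: 0 for lab in labels}
    n_unclassified = 0
    for vec in avg:
        k = int(np.argmax(vec))
        if vec[k] > cfg.threshold:
            counts[labels[k]] += 1
        else:
            n_unclassified += 1
    return EnrichmentCounts(
        counts=counts, n_loci=avg.shape[0], n_unclassified=n_unclassified
    )


def random_control(
    universe: LocusAncestrySummary,
    exclude: Optional[SnpCatalog],
    n: int,
    seed: int,
) -> LocusAncestrySummary:
    """Draw ``n`` distinct control variants from ``universe``, targets excluded.

    Exclusion matches by rsid **or** by (chrom, pos_bp), so a target is
    removed even when the two tables disagree on naming. The remaining
    variants are shuffled with a generator seeded by ``seed`` (Fisher–Yates,
    as numpy implements permutation) and the first ``n`` are returned with
    their full ancestry columns; deterministic given the seed.
    """
    excl_rsids: set[str] = set()
    excl_pos: set[tuple[str, int]] = set()
    if exclude is not None:
        for rec in exclude:
            excl_rsids.add(rec.rsid)
            excl_pos.add((rec.chrom, rec.pos_bp))
    keep = [
        i
        for i in range(universe.n_variants)
        if universe.rsids[i] not in excl_rsids
        and (str(universe.chroms[i]), int(universe.positions_bp[i])) not in excl_pos
    ]
    if len(keep) < n:
        raise SizeError(
            f"requested {n} random controls but only {len(keep)} variants "
            "remain after exclusion"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keep))
    chosen = [keep[j] for j in order[:n]]
    return universe.select(chosen)


def _fisher_enumerate(table: np.ndarray) -> tuple[float, float]:
    """Exhaustive conditional enumeration for a 2×C table.

    Conditions on both margins, enumerates every admissible first row, and
    scores each by its multivariate hypergeometric probability. Returns
    ``(p_less, p_equal)``: total probability of tables strictly less
    probable than the observed one, and of tables equally probable
    (including the observed table itself).
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2 or (table < 0).any():
        raise ValidationError("expected a non-negative 2×C table")
    col_tot = table.sum(axis=0)
    row1 = int(table[0].sum())
    log_denom = (
        gammaln(col_tot.sum() + 1)
        - gammaln(row1 + 1)
        - gammaln(col_tot.sum() - row1 + 1)
    )

    def log_pmf(k: np.ndarray) -> float:
        # product over columns of C(col_c, k_c), over C(N, row1)
        return float(
            np.sum(gammaln(col_tot + 1) - gammaln(k + 1) - gammaln(col_tot - k + 1))
            - log_denom
        )

    obs = log_pmf(table[0])
    C = len(col_tot)
    suffix_tot = np.concatenate([np.cumsum(col_tot[::-1])[::-1][1:], [0]])
    p_less = p_equal = 0.0

    def rec(c: int, remaining: int, k: list[int]):
        nonlocal p_less, p_equal
        if c == C - 1:
            if remaining <= col_tot[c]:
                lp = log_pmf(np.array(k + [remaining]))
                if lp < obs - 1e-9:
                    p_less += np.exp(lp)
                elif lp <= obs + 1e-9:
                    p_equal += np.exp(lp)
            return
        lo = max(0, remaining - int(suffix_tot[c]))
        hi = min(int(col_tot[c]), remaining)
        for kc in range(lo, hi + 1):
            rec(c + 1, remaining - kc, k + [kc])

    rec(0, row1, [])
    return p_less, p_equal


def fisher_exact_2xc(table: np.ndarray, mid_p: bool = False) -> float:
    """Two-sided Fisher exact p for a 2×C table by exhaustive enumeration.

    Uses the probability-ordering definition (sum over tables no more
    probable than the observed one), which for 2×2 coincides with the
    classical two-sided Fisher test. With ``mid_p=True`` only half the
    probability of the equally-probable class is counted (Lancaster's
    mid-p), the standard correction for the exact test's conservatism under
    heavy discreteness; the mid-p variant is not guaranteed to bound the
    type-I error but tracks the nominal level far better for small margins.
    """
    p_less, p_equal = _fisher_enumerate(table)
    p = p_less + (0.5 * p_equal if mid_p else p_equal)
    return min(1.0, p)


def compare_enrichment(
    target: EnrichmentCounts,
    control: EnrichmentCounts,
    method: str = "auto",
) -> ContingencyResult:
    """Test whether target and control loci distribute differently over classes.

    Builds the 2×C table (rows: target, control; columns: each ancestry plus
    unclassified, with all-zero columns dropped). With ``method="auto"``,
    Pearson's chi-square (no continuity correction) is used when every
    expected cell is at least 5; sparser tables use the mid-p Fisher exact
    test, whose attained size tracks the nominal level where the classical
    exact test is conservative (the typical case for small target panels).
    ``method`` may be forced to ``"chi-square"``, ``"fisher"`` (classical),
    or ``"fisher-midp"``.
    """
    if target.labels != control.labels:
        raise ValidationError("target and control must share ancestry labels")
    cols = list(target.labels) + [UNCLASSIFIED]
    t_row = [target.counts[lab] for lab in target.labels] + [target.n_unclassified]
    c_row = [control.counts[lab] for lab in control.labels] + [control.n_unclassified]
    table = np.array([t_row, c_row], dtype=int)
    if table.min() < 0:
        raise ValidationError("contingency counts must be non-negative")
    nonzero = table.sum(axis=0) > 0
    table = table[:, nonzero]
    cols = tuple(c for c, nz in zip(cols, nonzero) if nz)
    if table.size == 0 or table.sum() == 0:
        raise DegenerateInputError("contingency table is all zero")
    if table.shape[1] == 1 or table.sum(axis=1).min() == 0:
        # only one class present, or one empty group: no association testable
        return ContingencyResult(
            table=table, columns=cols, statistic=0.0, p_value=1.0, method="chi-square"
        )

    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if method == "auto":
        method = "fisher-midp" if (expected < 5).any() else "chi-square"
    if method in ("fisher", "fisher-midp"):
        p = fisher_exact_2xc(table, mid_p=(method == "fisher-midp"))
        return ContingencyResult(
            table=table, columns=cols, statistic=None, p_value=p, method=method
        )
    if method == "chi-square":
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return ContingencyResult(
            table=table,
            columns=cols,
            statistic=float(stat),
            p_value=float(p),
            method="chi-square",
        )
    raise ValidationError(f"unknown method {method!r}")
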
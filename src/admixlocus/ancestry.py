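"""Cohort-level local-ancestry summaries per variant (the "ancestry search").

Given posterior ancestry tensors for a cohort of diploid samples, this module
computes, at every variant, each sample's diploid ancestry vector (the mean
of its two haplotypes' posteriors) and the cohort-average ancestry vector
(the unweighted mean over included samples). The result is the combined
``all_chr.anc`` table with columns rsid, chrom, pos_bp, cM, one average
column per ancestry, and one column per sample holding the K-vector as
semicolon-joined reals.

Averaging over samples with weight 1 each is identical to averaging over
haplotypes when every sample is diploid; the summary enforces diploidy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ValidationError
from .rfmix_io import AncestryPosterior, GenomePosterior, SampleSet

SUM_ATOL = 1e-6


@dataclass
class LocusAncestrySummary:
    """Per-variant cohort ancestry averages plus per-sample diploid vectors.

    Invariants: every per-sample vector and every average sums to 1 (1e-6),
    and the average equals the mean of the per-sample vectors (1e-9).
    """

    rsids: list[str]
    chroms: np.ndarray                 # (n,) str
    positions_bp: np.ndarray           # (n,) int
    locations_cm: np.ndarray           # (n,) float
    avg: np.ndarray                    # (n, K)
    per_sample: Optional[np.ndarray]   # (n, n_samples, K) or None (avg-only table)
    sample_ids: list[str]
    labels: tuple[str, ...]

    def __post_init__(self):
        n = len(self.rsids)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=int)
        self.locations_cm = np.asarray(self.locations_cm, dtype=float)
        self.avg = np.asarray(self.avg, dtype=float)
        if self.avg.shape != (n, len(self.labels)):
            raise ConsistencyError("avg shape does not match rsids/labels")
        if n and np.any(np.abs(self.avg.sum(axis=1) - 1.0) > SUM_ATOL):
            raise ValidationError("average ancestry vectors must sum to 1")
        if self.per_sample is not None:
            self.per_sample = np.asarray(self.per_sample, dtype=float)
            if self.per_sample.shape != (n, len(self.sample_ids), len(self.labels)):
                raise ConsistencyError("per_sample shape mismatch")
            if n and np.any(
                np.abs(self.per_sample.sum(axis=2) - 1.0) > SUM_ATOL
            ):
                raise ValidationError("per-sample ancestry vectors must sum to 1")
            if n and np.any(
                np.abs(self.per_sample.mean(axis=1) - self.avg) > 1e-9
            ):
                raise ConsistencyError(
                    "avg does not equal the mean of per-sample vectors"
                )

    @property
    def n_variants(self) -> int:
        return len(self.rsids)

    @property
    def K(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        """The combined table: metadata, averages, then per-sample columns."""
        data = {
            "rsid": self.rsids,
            "chrom": self.chroms,
            "pos_bp": self.positions_bp,
            "cM": self.locations_cm,
        }
        for k, lab in enumerate(self.labels):
            data[f"avg_{lab}"] = self.avg[:, k]
        if self.per_sample is not None:
            for s, sid in enumerate(self.sample_ids):
                data[sid] = [
                    ";".join(f"{v:.6g}" for v in vec)
                    for vec in self.per_sample[:, s, :]
                ]
        return pd.DataFrame(data)

    def select(self, idx) -> "LocusAncestrySummary":
        idx = np.asarray(idx, dtype=int)
        return LocusAncestrySummary(
            rsids=[self.rsids[i] for i in idx],
            chroms=self.chroms[idx],
            positions_bp=self.positions_bp[idx],
            locations_cm=self.locations_cm[idx],
            avg=self.avg[idx],
            per_sample=self.per_sample[idx] if self.per_sample is not None else None,
            sample_ids=self.sample_ids,
            labels=self.labels,
        )


def summarize_ancestry(
    gp: Union[GenomePosterior, AncestryPosterior], samples: SampleSet
) -> LocusAncestrySummary:
    """Average posterior ancestries over a cohort, per variant.

    Each sample's diploid vector is the arithmetic mean of its two haplotype
    posteriors; the cohort average weights every included sample equally.
    Output is ordered chromosome-major (input chromosome order) and by cM
    within each chromosome.
    """
    if isinstance(gp, AncestryPosterior):
        from .rfmix_io import concat_chromosomes

        gp = concat_chromosomes([gp])

    hap_index = {h: i for i, h in enumerate(gp.haplotype_ids)}
    pairs = []
    for s in samples:
        h0, h1 = f"{s}.0", f"{s}.1"
        if h0 not in hap_index or h1 not in hap_index:
            raise ConsistencyError(f"sample {s} does not have exactly 2 haplotypes")
        pairs.append((hap_index[h0], hap_index[h1]))
    pairs = np.asarray(pairs)

    # (n_variants, n_samples, K): mean of the two haplotypes per sample
    per_sample = 0.5 * (gp.probs[:, pairs[:, 0], :] + gp.probs[:, pairs[:, 1], :])
    avg = per_sample.mean(axis=1)

    # chromosome-major (first-appearance order), then by cM within chromosome
    chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(gp.chroms))}
    order = np.lexsort(
        (gp.locations_cm, np.array([chrom_rank[c] for c in gp.chroms]))
    ) if gp.n_variants else np.empty(0, dtype=int)

    rsids = (
        [gp.rsids[i] for i in order]
        if gp.rsids is not None
        else [f"var_{i + 1}" for i in order]
    )
    positions = (
        gp.positions_bp[order]
        if gp.positions_bp is not None
        else np.zeros(len(order), dtype=int)
    )
    return LocusAncestrySummary(
        rsids=rsids,
        chroms=gp.chroms[order],
        positions_bp=positions,
        locations_cm=gp.locations_cm[order],
        avg=avg[order],
        per_sample=per_sample[order],
        sample_ids=list(samples),
        labels=gp.labels,
    )


def lookup_summary(
    ls: LocusAncestrySummary, rsids: Sequence[str]
) -> tuple[LocusAncestrySummary, list[str]]:
    """Rows of ``ls`` for the queried rsids, plus the list of misses.

    A miss is data, not an error: the upstream reference panels simply may
    not cover a queried variant. found + missing always partitions the query.
    """
    index = {r: i for i, r in enumerate(ls.rsids)}
    found_idx = [index[r] for r in rsids if r in index]
    missing = [r for r in rsids if r not in index]
    return ls.select(found_idx), missing


def write_anc(ls: LocusAncestrySummary, path) -> None:
    """Write the combined table as tab-delimited text (the .anc format)."""
    ls.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_anc(path) -> LocusAncestrySummary:
    """Read a .anc table written by :func:`write_anc`.

    Per-sample cells are serialized with 6 significant digits, which breaks
    the exact avg == mean(per_sample) invariant on re-read, so a summary read
    from disk keeps the (full-precision) average columns and records the
    sample names but drops the per-sample tensor.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"chrom": str})
    avg_cols = [c for c in df.columns if c.startswith("avg_")]
    labels = tuple(c[len("avg_"):] for c in avg_cols)
    meta = {"rsid", "chrom", "pos_bp", "cM"} | set(avg_cols)
    sample_cols = [c for c in df.columns if c not in meta]
    return LocusAncestrySummary(
        rsids=list(df["rsid"].astype(str)),
        chroms=df["chrom"].to_numpy(dtype=object),
        positions_bp=df["pos_bp"].to_numpy(),
        locations_cm=df["cM"].to_numpy(),
        avg=df[avg_cols].to_numpy(),
        per_sample=None,
        sample_ids=sample_cols,
        labels=labels,
    )
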
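"""Genetic-distance proximity search between two SNP sets (the "bracket search").

Two variants are *in proximity* when they sit on the same chromosome within a
genetic-distance window of each other (default ±0.5 cM, boundary included —
the closed interval is the conservative reading for a co-localization claim).
Cross-chromosome distance is undefined because cM coordinates are
per-chromosome, so pairs are same-chromosome only.

The production search sorts each chromosome's records by cM and sweeps a
two-pointer window (O(n log n)); :func:`brute_force_pairs` is the O(|A|·|B|)
double loop kept as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import SnpCatalog, SnpRecord
from .errors import ValidationError


@dataclass(frozen=True)
class ProximityConfig:
    """Window half-width in cM; the |Δ| = window boundary is included."""

    window_cm: float = 0.5

    def __post_init__(self):
        if not self.window_cm > 0:
            raise ValidationError("window_cm must be positive")


@dataclass(frozen=True)
class ProximityPair:
    """A qualifying same-chromosome pair; delta_cm = cm_b − cm_a (signed)."""

    snp_a: SnpRecord
    snp_b: SnpRecord
    delta_cm: float

    @property
    def key(self) -> frozenset:
        return frozenset((self.snp_a.rsid, self.snp_b.rsid))


def _require_cm(cat: SnpCatalog, name: str) -> None:
    for rec in cat:
        if rec.cm is None:
            raise ValidationError(
                f"{name}: record {rec.rsid} lacks a cM coordinate; "
                "attach a genetic map first"
            )


def _canonical(pairs: list[ProximityPair]) -> list[ProximityPair]:
    """Deduplicate unordered pairs and sort by (chrom, cm_a, cm_b).

    When a pair was generated in both orientations (possible when the same
    rsid occurs in both sets, e.g. a self-search), the orientation with the
    smaller (cm, rsid) on the A side is kept, so the result is independent of
    generation order.
    """
    seen: dict[frozenset, ProximityPair] = {}
    for p in pairs:
        prev = seen.get(p.key)
        if prev is None or (p.snp_a.cm, p.snp_a.rsid) < (
            prev.snp_a.cm,
            prev.snp_a.rsid,
        ):
            seen[p.key] = p
    return sorted(
        seen.values(),
        key=lambda p: (p.snp_a.chrom, p.snp_a.cm, p.snp_b.cm, p.snp_a.rsid),
    )


def brute_force_pairs(
    set_a: SnpCatalog, set_b: SnpCatalog, cfg: ProximityConfig = ProximityConfig()
) -> list[ProximityPair]:
    """Reference double-loop implementation of the same contract as
    :func:`bracket_search`; quadratic, kept as the test oracle."""
    _require_cm(set_a, "set_a")
    _require_cm(set_b, "set_b")
    out = []
    for a in set_a:
        for b in set_b:
            if a.rsid == b.rsid or a.chrom != b.chrom:
                continue
            delta = b.cm - a.cm
            if abs(delta) <= cfg.window_cm:
                out.append(ProximityPair(a, b, delta))
    return _canonical(out)


def bracket_search(
    set_a: SnpCatalog, set_b: SnpCatalog, cfg: ProximityConfig = ProximityConfig()
) -> list[ProximityPair]:
    """All unordered pairs (a ∈ A, b ∈ B) on one chromosome with |Δ cM| ≤ window.

    Each qualifying unordered pair is reported exactly once (repeated matches
    are eliminated), never self-paired by rsid, sorted by chromosome then by
    the cM of the A-side member; deterministic. Records lacking cM raise
    :class:`ValidationError` naming the rsid.
    """
    _require_cm(set_a, "set_a")
    _require_cm(set_b, "set_b")

    by_chrom_b: dict[str, list[SnpRecord]] = {}
    for b in set_b:
        by_chrom_b.setdefault(b.chrom, []).append(b)
    for recs in by_chrom_b.values():
        recs.sort(key=lambda r: r.cm)

    out = []
    for chrom, b_recs in by_chrom_b.items():
        a_recs = sorted((a for a in set_a if a.chrom == chrom), key=lambda r: r.cm)
        if not a_recs:
            continue
        lo = 0
        for a in a_recs:
            while lo < len(b_recs) and b_recs[lo].cm < a.cm - cfg.window_cm:
                lo += 1
            j = lo
            while j < len(b_recs) and b_recs[j].cm <= a.cm + cfg.window_cm:
                b = b_recs[j]
                if b.rsid != a.rsid:
                    out.append(ProximityPair(a, b, b.cm - a.cm))
                j += 1
    return _canonical(out)


def pairs_to_frame(pairs: list[ProximityPair]) -> pd.DataFrame:
    """CSV-ready table: rsid_a, rsid_b, chrom, cm_a, cm_b, delta_cm."""
    return pd.DataFrame(
        {
            "rsid_a": [p.snp_a.rsid for p in pairs],
            "rsid_b": [p.snp_b.rsid for p in pairs],
            "chrom": [p.snp_a.chrom for p in pairs],
            "cm_a": [p.snp_a.cm for p in pairs],
            "cm_b": [p.snp_b.cm for p in pairs],
            "delta_cm": [p.delta_cm for p in pairs],
        }
    )


def write_pairs_csv(pairs: list[ProximityPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, index=False)
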
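"""Physical (bp) to genetic (cM) coordinate conversion.

A :class:`GeneticMap` is a per-chromosome list of monotone anchors
``(pos_bp, cm)``; queries are answered by piecewise-linear interpolation
between flanking anchors and by linear extrapolation (at the terminal
inter-anchor rate) beyond them, clamped at 0 cM. The file format is the
HapMap-style three-column text layout ``chrom  pos_bp  cM``.

When no empirical map is available a uniform fallback of 1 cM/Mb can be
constructed with :func:`uniform_map`; real analyses should always supply the
map their upstream local-ancestry inference used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import SnpCatalog, normalize_chrom, with_cm
from .errors import ConfigError, MapLookupError, ParseError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class GeneticMap:
    """Monotone piecewise-linear bp→cM map, one anchor track per chromosome."""

    anchors: dict[str, np.ndarray] = field(default_factory=dict)
    # anchors[chrom] is an (n, 2) float array of (pos_bp, cm), sorted by pos_bp.

    def __post_init__(self):
        clean = {}
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValidationError(f"chr{chrom}: anchors must be (n, 2)")
            pos, cm = arr[:, 0], arr[:, 1]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"chr{chrom}: anchor positions must be strictly increasing"
                )
            if np.any(np.diff(cm) < 0):
                raise ValidationError(
                    f"chr{chrom}: anchor cM must be non-decreasing"
                )
            if np.any(cm < 0):
                raise ValidationError(f"chr{chrom}: anchor cM must be >= 0")
            clean[normalize_chrom(chrom)] = arr
        self.anchors = clean

    def chromosomes(self) -> set[str]:
        return set(self.anchors)


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-style ``chrom pos_bp cM`` text map (header optional)."""
    path = Path(path)
    per_chrom: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if i == 1 and not parts[1].replace(".", "", 1).isdigit():
                continue  # header line
            if len(parts) < 3:
                raise ParseError(f"{path}: line {i}: expected 3 columns")
            try:
                chrom = normalize_chrom(parts[0])
                pos, cm = float(parts[1]), float(parts[2])
            except (ValueError, ValidationError):
                raise ParseError(f"{path}: line {i}: malformed map row") from None
            per_chrom.setdefault(chrom, []).append((pos, cm))
    anchors = {
        c: np.array(sorted(rows), dtype=float) for c, rows in per_chrom.items()
    }
    return GeneticMap(anchors=anchors)


def uniform_map(chrom_lengths_bp: dict[str, int], rate_cm_per_mb: float = 1.0) -> GeneticMap:
    """Build a uniform fallback map (default 1 cM/Mb) over the given chromosomes.

    Logged loudly because a constant-rate map is a demonstration device, not a
    substitute for the map the upstream ancestry inference actually used.
    """
    log.warning(
        "using uniform fallback genetic map at %.3g cM/Mb; "
        "supply an empirical map for real analyses",
        rate_cm_per_mb,
    )
    anchors = {}
    for chrom, length in chrom_lengths_bp.items():
        anchors[normalize_chrom(chrom)] = np.array(
            [[0.0, 0.0], [float(length), rate_cm_per_mb * length / 1e6]]
        )
    return GeneticMap(anchors=anchors)


def interpolate_cm(gmap: GeneticMap, chrom, pos_bp) -> float:
    """Genetic position of ``pos_bp`` on ``chrom``, in cM.

    Linear between flanking anchors; beyond the anchor range, extrapolated at
    the terminal inter-anchor rate and clamped at 0 cM. Exact at anchors.
    """
    chrom = normalize_chrom(chrom)
    if chrom not in gmap.anchors:
        raise MapLookupError(f"chromosome {chrom} absent from genetic map")
    arr = gmap.anchors[chrom]
    if arr.shape[0] < 2:
        raise ConfigError(
            f"chromosome {chrom} has a single map anchor; need >= 2 to interpolate"
        )
    pos, cm = arr[:, 0], arr[:, 1]
    x = float(pos_bp)
    if x <= pos[0]:
        rate = (cm[1] - cm[0]) / (pos[1] - pos[0])
        return max(0.0, float(cm[0] + (x - pos[0]) * rate))
    if x >= pos[-1]:
        rate = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
        return max(0.0, float(cm[-1] + (x - pos[-1]) * rate))
    return max(0.0, float(np.interp(x, pos, cm)))


def attach_cm(cat: SnpCatalog, gmap: GeneticMap, overwrite: bool = False) -> SnpCatalog:
    """Return a catalog copy with cM filled in from the map.

    Records that already carry a cM value are left untouched unless
    ``overwrite`` is set. Every catalog chromosome must be present in the map.
    """
    missing = cat.chroms - gmap.chromosomes()
    if missing:
        raise MapLookupError(
            f"chromosomes absent from genetic map: {sorted(missing)}"
        )
    cms = []
    for rec in cat.records:
        if rec.cm is not None and not overwrite:
            cms.append(rec.cm)
        else:
            cms.append(interpolate_cm(gmap, rec.chrom, rec.pos_bp))
    return with_cm(cat, cms)
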
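"""Reading and writing the RFMix-v1-style text dialect this pipeline consumes.

The on-disk layout (all plain whitespace-delimited text):

``<prefix>.ForwardBackward.txt``
    One row per variant. Each row holds ``n_haplotypes * K`` posterior
    probabilities, haplotype-major: the first K numbers are haplotype 1's
    posterior over the K ancestries, the next K are haplotype 2's, and so on.
``<prefix>.Viterbi.txt``
    One row per variant of ``n_haplotypes`` integer ancestry codes in 1..K.
``<prefix>.snp_locations``
    One genetic position (cM) per line, same variant order.
``samples.txt``
    One sample id per line; haplotype columns are sample-major with two
    haplotypes per sample, identified as ``<sample>.0`` and ``<sample>.1``.

Because the upstream tool's exact dialect varies by version, this module
*fixes* the contract above and the simulator emits it bit-exactly; everything
downstream depends only on this contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .catalog import normalize_chrom
from .errors import ConsistencyError, ParseError, ValidationError

DEFAULT_LABELS = ("IBS", "YRI", "NA")
PROB_SUM_ATOL_STRICT = 1e-6   # construction invariant
PROB_SUM_ATOL_READ = 1e-4     # file-reading tolerance before erroring


@dataclass
class SampleSet:
    """Ordered, unique, non-empty list of sample ids to include in an analysis."""

    sample_ids: list[str]

    def __post_init__(self):
        ids = [str(s).strip() for s in self.sample_ids]
        if not ids:
            raise ValidationError("sample set must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValidationError("sample ids must be unique")
        if any(not s for s in ids):
            raise ValidationError("sample ids must be non-empty strings")
        self.sample_ids = ids

    def __len__(self):
        return len(self.sample_ids)

    def __iter__(self):
        return iter(self.sample_ids)

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}.{h}" for s in self.sample_ids for h in (0, 1)]


def read_sample_list(path) -> SampleSet:
    """Read a one-id-per-line sample inclusion file."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return SampleSet(sample_ids=ids)


def write_sample_list(samples: SampleSet, path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(s + "\n")


def _check_probs(probs: np.ndarray, atol: float) -> None:
    if probs.ndim != 3:
        raise ValidationError("probs must be (n_variants, n_haplotypes, K)")
    if probs.size and (probs.min() < -atol or probs.max() > 1 + atol):
        raise ValidationError("posterior probabilities must lie in [0, 1]")
    if probs.size:
        sums = probs.sum(axis=2)
        bad = np.abs(sums - 1.0) > atol
        if bad.any():
            v, h = np.argwhere(bad)[0]
            raise ValidationError(
                f"posterior row (variant {v}, haplotype {h}) sums to "
                f"{sums[v, h]:.6g}, outside 1±{atol:g}"
            )


@dataclass
class AncestryPosterior:
    """Per-chromosome posterior ancestry tensor: variants x haplotypes x K."""

    chrom: str
    probs: np.ndarray                      # (n_variants, n_haplotypes, K)
    haplotype_ids: list[str]
    locations_cm: np.ndarray               # (n_variants,)
    labels: tuple[str, ...] = DEFAULT_LABELS
    positions_bp: Optional[np.ndarray] = None
    rsids: Optional[list[str]] = None

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.probs = np.asarray(self.probs, dtype=float)
        self.locations_cm = np.asarray(self.locations_cm, dtype=float)
        _check_probs(self.probs, PROB_SUM_ATOL_STRICT)
        n, h, k = self.probs.shape
        if k != len(self.labels):
            raise ValidationError("K does not match ancestry labels")
        if len(self.haplotype_ids) != h:
            raise ValidationError("haplotype_ids length does not match probs")
        if self.locations_cm.shape != (n,):
            raise ConsistencyError("locations_cm length does not match probs")
        if n and np.any(np.diff(self.locations_cm) < 0):
            raise ValidationError("locations_cm must be non-decreasing")
        if self.positions_bp is not None:
            self.positions_bp = np.asarray(self.positions_bp, dtype=int)
            if self.positions_bp.shape != (n,):
                raise ConsistencyError("positions_bp length does not match probs")
        if self.rsids is not None and len(self.rsids) != n:
            raise ConsistencyError("rsids length does not match probs")

    @property
    def n_variants(self) -> int:
        return self.probs.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.probs.shape[1]

    @property
    def K(self) -> int:
        return self.probs.shape[2]

    @property
    def sample_ids(self) -> list[str]:
        seen = dict.fromkeys(h.rsplit(".", 1)[0] for h in self.haplotype_ids)
        return list(seen)

    def restrict(self, samples: SampleSet) -> "AncestryPosterior":
        """Restrict to the haplotypes of ``samples``, in SampleSet order."""
        index = {h: i for i, h in enumerate(self.haplotype_ids)}
        cols = []
        for s in samples:
            for h in (f"{s}.0", f"{s}.1"):
                if h not in index:
                    raise ConsistencyError(f"sample {s} is missing haplotype {h}")
                cols.append(index[h])
        return replace(
            self,
            probs=self.probs[:, cols, :],
            haplotype_ids=[self.haplotype_ids[c] for c in cols],
        )


@dataclass
class ViterbiCalls:
    """Hard ancestry calls: variants x haplotypes of integer codes in 1..K."""

    chrom: str
    codes: np.ndarray                      # (n_variants, n_haplotypes), int
    haplotype_ids: list[str]
    K: int = len(DEFAULT_LABELS)

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be (n_variants, n_haplotypes)")
        if self.codes.size and (self.codes.min() < 1 or self.codes.max() > self.K):
            raise ValidationError(f"ancestry codes must lie in 1..{self.K}")
        if self.codes.shape[1] != len(self.haplotype_ids):
            raise ValidationError("haplotype_ids length does not match codes")


def _read_matrix(path: Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                rows.append(parts)
    return rows


def read_forward_backward(
    fb_path,
    locations_path,
    samples: SampleSet,
    K: int = len(DEFAULT_LABELS),
    *,
    chrom: str = "1",
    cohort: Optional[SampleSet] = None,
    labels: Optional[Sequence[str]] = None,
    renormalize: bool = False,
) -> AncestryPosterior:
    """Read a forward–backward posterior file plus its cM locations file.

    ``cohort`` gives the sample order of the file's haplotype columns; when
    omitted, ``samples`` is taken to be that order. The result is restricted
    to ``samples``, in their order. Posterior rows whose K probabilities sum
    outside 1±1e-4 raise :class:`ValidationError` unless ``renormalize`` is
    set (upstream corruption should be surfaced, not papered over).
    """
    fb_path, locations_path = Path(fb_path), Path(locations_path)
    column_order = cohort if cohort is not None else samples
    n_haps = 2 * len(column_order)

    rows = _read_matrix(fb_path)
    locs = _read_matrix(locations_path)
    if len(rows) != len(locs):
        raise ConsistencyError(
            f"{fb_path.name} has {len(rows)} variants but "
            f"{locations_path.name} has {len(locs)}"
        )
    locations = np.array([float(l[0]) for l in locs]) if locs else np.empty(0)

    n_variants = len(rows)
    probs = np.empty((n_variants, n_haps, K), dtype=float)
    for i, parts in enumerate(rows):
        if len(parts) % K != 0:
            raise ParseError(
                f"{fb_path.name}: row {i + 1} has {len(parts)} values, "
                f"not divisible by K={K}"
            )
        if len(parts) != n_haps * K:
            raise ConsistencyError(
                f"{fb_path.name}: row {i + 1} has {len(parts) // K} haplotypes, "
                f"expected {n_haps}"
            )
        try:
            probs[i] = np.array(parts, dtype=float).reshape(n_haps, K)
        except ValueError:
            raise ParseError(f"{fb_path.name}: row {i + 1}: non-numeric value") from None

    if probs.size:
        sums = probs.sum(axis=2)
        bad = np.abs(sums - 1.0) > PROB_SUM_ATOL_READ
        if bad.any():
            if not renormalize:
                v, h = np.argwhere(bad)[0]
                raise ValidationError(
                    f"{fb_path.name}: posterior row (variant {v + 1}, haplotype "
                    f"{h + 1}) sums to {sums[v, h]:.6g}; pass renormalize=True "
                    "to rescale"
                )
        probs = probs / probs.sum(axis=2, keepdims=True)

    ap = AncestryPosterior(
        chrom=chrom,
        probs=probs,
        haplotype_ids=column_order.haplotype_ids,
        locations_cm=locations,
        labels=tuple(labels) if labels else DEFAULT_LABELS[:K]
        if K <= len(DEFAULT_LABELS)
        else tuple(f"ANC{i + 1}" for i in range(K)),
    )
    if cohort is not None:
        ap = ap.restrict(samples)
    return ap


def write_forward_backward(ap: AncestryPosterior, fb_path, locations_path) -> None:
    """Write the posterior tensor and its locations in the fixed dialect.

    Probabilities are written with 10 significant digits so a write→read
    round-trip is lossless well below the 1e-6 validation tolerance.
    """
    with open(fb_path, "w") as fh:
        for row in ap.probs:
            fh.write(" ".join(f"{p:.10g}" for p in row.ravel()) + "\n")
    with open(locations_path, "w") as fh:
        for cm in ap.locations_cm:
            fh.write(f"{cm:.10g}\n")


def read_viterbi(
    path, samples: SampleSet, K: int = len(DEFAULT_LABELS), *, chrom: str = "1"
) -> ViterbiCalls:
    rows = _read_matrix(Path(path))
    n_haps = 2 * len(samples)
    codes = np.empty((len(rows), n_haps), dtype=int)
    for i, parts in enumerate(rows):
        if len(parts) != n_haps:
            raise ConsistencyError(
                f"{path}: row {i + 1} has {len(parts)} calls, expected {n_haps}"
            )
        try:
            codes[i] = np.array(parts, dtype=int)
        except ValueError:
            raise ParseError(f"{path}: row {i + 1}: non-integer ancestry code") from None
    return ViterbiCalls(
        chrom=chrom, codes=codes, haplotype_ids=samples.haplotype_ids, K=K
    )


def write_viterbi(vc: ViterbiCalls, path) -> None:
    with open(path, "w") as fh:
        for row in vc.codes:
            fh.write(" ".join(str(int(c)) for c in row) + "\n")


@dataclass
class GenomePosterior:
    """Chromosome-major concatenation of per-chromosome posterior tensors."""

    chroms: np.ndarray                     # (n_variants,) of str labels
    probs: np.ndarray                      # (n_variants, n_haplotypes, K)
    haplotype_ids: list[str]
    locations_cm: np.ndarray
    labels: tuple[str, ...]
    positions_bp: Optional[np.ndarray] = None
    rsids: Optional[list[str]] = None

    @property
    def n_variants(self) -> int:
        return self.probs.shape[0]

    @property
    def K(self) -> int:
        return self.probs.shape[2]


def concat_chromosomes(parts: Sequence[AncestryPosterior]) -> GenomePosterior:
    """Concatenate per-chromosome posteriors into one genome-wide table.

    Parts must agree on haplotype ids (same samples, same order) and on the
    ancestry labels; the result is ordered as given, chromosome-major.
    """
    if not parts:
        raise ConsistencyError("no chromosomes to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.haplotype_ids != first.haplotype_ids:
            raise ConsistencyError("haplotype sets differ between chromosomes")
        if p.labels != first.labels:
            raise ConsistencyError("ancestry labels differ between chromosomes")
    chroms = np.concatenate([[p.chrom] * p.n_variants for p in parts]) if any(
        p.n_variants for p in parts
    ) else np.empty(0, dtype=str)
    have_bp = all(p.positions_bp is not None for p in parts)
    have_rs = all(p.rsids is not None for p in parts)
    return GenomePosterior(
        chroms=np.asarray(chroms, dtype=object),
        probs=np.concatenate([p.probs for p in parts], axis=0),
        haplotype_ids=list(first.haplotype_ids),
        locations_cm=np.concatenate([p.locations_cm for p in parts]),
        labels=first.labels,
        positions_bp=np.concatenate([p.positions_bp for p in parts])
        if have_bp
        else None,
        rsids=[r for p in parts for r in p.rsids] if have_rs else None,
    )
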
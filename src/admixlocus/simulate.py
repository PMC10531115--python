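"""Synthetic admixed cohorts: single-pulse ancestry mosaics with truth tracks.

Model
-----
Each haplotype of each diploid sample is an independent ancestry mosaic on a
chromosome of genetic length L cM: g generations after a single admixture
pulse, recombination has accumulated breakpoints as a Poisson process of rate
g/100 per cM (breakpoint count ~ Poisson(g·L/100), positions uniform), and
each inter-breakpoint segment draws its ancestry independently from the
cohort mixing proportions. Segment ancestries are iid — there is no drift,
no shared pedigree between haplotypes, and no linkage between segments —
which reproduces the per-locus marginal structure that local-ancestry
post-processing consumes without being a demographic model.

Locally enriched "risk loci" are injected with :class:`EnrichmentSpike`: the
spike interval's boundaries become forced breakpoints and segments inside it
draw the focal ancestry with a boosted probability b, the other ancestries
rescaled proportionally.

The emitted files are the fixed RFMix-style dialect of :mod:`.rfmix_io`:
per-chromosome forward–backward posteriors (probability 1−ε on the true
ancestry, ε/(K−1) on each other; ε is the posterior-noise parameter), Viterbi
files with the true codes, cM location files, a SNP-info table, a sample
list, and a truth JSON. SNP grids are evenly spaced in cM with base-pair
positions from the uniform 1 cM/Mb fallback map, so the genetic-map and
proximity stages are exercised consistently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ancestry import LocusAncestrySummary
from .errors import ConfigError, DegenerateInputError
from .rfmix_io import (
    AncestryPosterior,
    SampleSet,
    ViterbiCalls,
    write_forward_backward,
    write_sample_list,
    write_viterbi,
)

DEFAULT_LABELS = ("IBS", "YRI", "NA")
#: Default mixing proportions: typical global-ancestry estimates for a
#: Caribbean Hispanic (Puerto Rican) cohort — majority European (Iberian),
#: then African (Yoruba), then Native American.
DEFAULT_MIX = (0.64, 0.21, 0.15)
CM_PER_MB = 1.0  # fallback uniform map used for bp positions


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level simulation parameters.

    ``posterior_noise`` (ε) is the posterior mass leaked off the true
    ancestry, split evenly over the K−1 others; any ε < (K−1)/K keeps the
    argmax on the truth, and ε is capped below 0.5.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    mix: tuple[float, ...] = DEFAULT_MIX
    generations: int = 10
    n_samples: int = 500
    chrom_lengths_cm: dict[str, float] = field(default_factory=lambda: {"1": 100.0})
    n_snps: int = 1000
    posterior_noise: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.mix) != len(self.labels):
            raise ConfigError("mix length must match ancestry labels")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ConfigError("mixing proportions must sum to 1 (1e-9)")
        if any(m < 0 for m in self.mix):
            raise ConfigError("mixing proportions must be non-negative")
        if self.generations < 1:
            raise ConfigError("generations since admixture must be >= 1")
        if self.n_samples < 1:
            raise ConfigError("cohort must have at least one sample")
        if not 0 <= self.posterior_noise < 0.5:
            raise ConfigError("posterior_noise must lie in [0, 0.5)")
        if self.n_snps < 1:
            raise ConfigError("need at least one SNP per chromosome")
        for c, L in self.chrom_lengths_cm.items():
            if L <= 0:
                raise ConfigError(f"chromosome {c}: length must be positive")

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample_{i + 1}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class EnrichmentSpike:
    """A locally enriched interval: the focal ancestry's segment probability
    is boosted to ``boost`` inside [cm_start, cm_end] on ``chrom``."""

    chrom: str
    cm_start: float
    cm_end: float
    ancestry: str
    boost: float

    def __post_init__(self):
        if not self.cm_start < self.cm_end:
            raise ConfigError("spike interval must have cm_start < cm_end")
        if not 0 < self.boost <= 1:
            raise ConfigError("spike boost must lie in (0, 1]")


@dataclass
class TruthTracks:
    """Ground-truth ancestry mosaics: per haplotype, per chromosome, the
    interior breakpoints (cM) and the ancestry code (1..K) of each segment.

    Segments tile [0, L]; adjacent segments may share an ancestry (segment
    boundaries record recombination events, not ancestry switches).
    """

    chrom_lengths_cm: dict[str, float]
    # tracks[hap_id][chrom] = (breakpoints ascending within (0, L), codes len+1)
    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    K: int

    def n_breakpoints(self) -> int:
        return sum(
            len(bp) for per_chrom in self.tracks.values() for bp, _ in per_chrom.values()
        )

    def total_length_cm(self) -> float:
        return sum(
            self.chrom_lengths_cm[c]
            for per_chrom in self.tracks.values()
            for c in per_chrom
        )

    def mean_tract_length_cm(self) -> float:
        """Maximum-likelihood estimate of the mean inter-breakpoint distance.

        Total simulated genetic length divided by total breakpoint count —
        the MLE of 1/rate for the Poisson breakpoint process, which is
        unbiased by the chromosome-edge segments (the naive mean of segment
        lengths is pulled low by the two censored edge segments).
        """
        n = self.n_breakpoints()
        if n == 0:
            raise DegenerateInputError("no breakpoints observed")
        return self.total_length_cm() / n

    def codes_at(self, hap_id: str, chrom: str, cm: np.ndarray) -> np.ndarray:
        bp, codes = self.tracks[hap_id][chrom]
        return codes[np.searchsorted(bp, cm, side="right")]

    def to_json(self, path) -> None:
        payload = {
            "chrom_lengths_cm": self.chrom_lengths_cm,
            "K": self.K,
            "tracks": {
                h: {
                    c: {"breakpoints": bp.tolist(), "codes": codes.tolist()}
                    for c, (bp, codes) in per_chrom.items()
                }
                for h, per_chrom in self.tracks.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthTracks":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            chrom_lengths_cm=payload["chrom_lengths_cm"],
            K=payload["K"],
            tracks={
                h: {
                    c: (
                        np.asarray(entry["breakpoints"], dtype=float),
                        np.asarray(entry["codes"], dtype=int),
                    )
                    for c, entry in per_chrom.items()
                }
                for h, per_chrom in payload["tracks"].items()
            },
        )


def _segment_probs(
    params: SimulationParams,
    chrom: str,
    seg_mid: np.ndarray,
    spikes: Sequence[EnrichmentSpike],
) -> np.ndarray:
    """Per-segment categorical probabilities, spike-boosted where applicable."""
    probs = np.tile(np.asarray(params.mix), (len(seg_mid), 1))
    for spike in spikes:
        if spike.chrom != chrom:
            continue
        a = params.labels.index(spike.ancestry)
        if spike.boost <= params.mix[a]:
            raise ConfigError(
                f"spike boost {spike.boost} must exceed baseline mix "
                f"{params.mix[a]} for {spike.ancestry}"
            )
        inside = (seg_mid >= spike.cm_start) & (seg_mid <= spike.cm_end)
        if inside.any():
            rest = 1.0 - params.mix[a]
            scale = (1.0 - spike.boost) / rest if rest > 0 else 0.0
            boosted = np.asarray(params.mix) * scale
            boosted[a] = spike.boost
            probs[inside] = boosted
    return probs


def simulate_haplotype(
    params: SimulationParams,
    chrom: str,
    rng: np.random.Generator,
    spikes: Sequence[EnrichmentSpike] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one haplotype's mosaic on ``chrom``.

    Returns ``(breakpoints, codes)``: interior breakpoints in (0, L) and the
    ancestry code (1..K) of each of the ``len(breakpoints) + 1`` segments.
    Spike boundaries are added as forced breakpoints so the boosted interval
    is exactly [cm_start, cm_end].
    """
    L = params.chrom_lengths_cm[chrom]
    n_bp = rng.poisson(params.generations * L / 100.0)
    bp = np.sort(rng.uniform(0.0, L, size=n_bp))
    forced = [
        x
        for s in spikes
        if s.chrom == chrom
        for x in (s.cm_start, s.cm_end)
        if 0.0 < x < L
    ]
    if forced:
        bp = np.unique(np.concatenate([bp, np.asarray(forced)]))
    edges = np.concatenate([[0.0], bp, [L]])
    seg_mid = 0.5 * (edges[:-1] + edges[1:])
    probs = _segment_probs(params, chrom, seg_mid, spikes)
    u = rng.random(len(seg_mid))
    codes = 1 + (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    return bp, codes.astype(int)


def snp_grid(params: SimulationParams, chrom: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Evenly spaced SNP grid on (0, L): rsids, cM positions, bp positions.

    Grid points sit at segment midoffsets ((i + 0.5)·L/n) so none coincides
    with 0 or L; bp = cM × 1e6 under the uniform 1 cM/Mb fallback map.
    """
    L = params.chrom_lengths_cm[chrom]
    cm = (np.arange(params.n_snps) + 0.5) * L / params.n_snps
    bp = np.maximum(1, np.round(cm * 1e6 / CM_PER_MB).astype(int))
    rsids = [f"snp_{chrom}_{i + 1}" for i in range(params.n_snps)]
    return rsids, cm, bp


def simulate_cohort(
    params: SimulationParams,
    spikes: Sequence[EnrichmentSpike] = (),
) -> tuple[list[AncestryPosterior], list[ViterbiCalls], TruthTracks, SampleSet]:
    """Simulate the full cohort in memory.

    All randomness flows from ``params.seed`` through a spawned seed per
    chromosome (haplotypes drawn sequentially within a chromosome), so every
    chromosome's output is reproducible independently of the others.
    """
    samples = SampleSet(sample_ids=params.sample_ids)
    hap_ids = samples.haplotype_ids
    root = np.random.SeedSequence(params.seed)
    chrom_seeds = root.spawn(len(params.chrom_lengths_cm))

    eps = params.posterior_noise
    K = params.K
    off = eps / (K - 1) if K > 1 else 0.0

    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
        h: {} for h in hap_ids
    }
    posteriors, viterbis = [], []
    for (chrom, L), ss in zip(params.chrom_lengths_cm.items(), chrom_seeds):
        rng = np.random.default_rng(ss)
        rsids, cm, bp = snp_grid(params, chrom)
        codes = np.empty((params.n_snps, len(hap_ids)), dtype=int)
        for j, h in enumerate(hap_ids):
            hbp, hcodes = simulate_haplotype(params, chrom, rng, spikes)
            tracks[h][chrom] = (hbp, hcodes)
            codes[:, j] = hcodes[np.searchsorted(hbp, cm, side="right")]
        probs = np.full((params.n_snps, len(hap_ids), K), off)
        idx = np.ogrid[: params.n_snps, : len(hap_ids)]
        probs[idx[0], idx[1], codes - 1] = 1.0 - eps
        posteriors.append(
            AncestryPosterior(
                chrom=chrom,
                probs=probs,
                haplotype_ids=hap_ids,
                locations_cm=cm,
                labels=params.labels,
                positions_bp=bp,
                rsids=rsids,
            )
        )
        viterbis.append(
            ViterbiCalls(chrom=chrom, codes=codes, haplotype_ids=hap_ids, K=K)
        )
    truth = TruthTracks(
        chrom_lengths_cm=dict(params.chrom_lengths_cm), tracks=tracks, K=K
    )
    return posteriors, viterbis, truth, samples


def emit_cohort(
    params: SimulationParams,
    spikes: Sequence[EnrichmentSpike] = (),
    out_dir=None,
) -> Path:
    """Simulate a cohort and write it in the RFMix-style dialect.

    Writes, per chromosome: ``chr<c>.ForwardBackward.txt``,
    ``chr<c>.Viterbi.txt``, ``chr<c>.snp_locations``, ``chr<c>.snp_info.tsv``
    (rsid, chrom, pos_bp, cm); plus ``samples.txt``, ``truth.json`` and
    ``params.json``. Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    posteriors, viterbis, truth, samples = simulate_cohort(params, spikes)
    for ap, vc in zip(posteriors, viterbis):
        prefix = out / f"chr{ap.chrom}"
        write_forward_backward(
            ap, f"{prefix}.ForwardBackward.txt", f"{prefix}.snp_locations"
        )
        write_viterbi(vc, f"{prefix}.Viterbi.txt")
        with open(f"{prefix}.snp_info.tsv", "w") as fh:
            fh.write("rsid\tchrom\tpos_bp\tcm\n")
            for r, b, c in zip(ap.rsids, ap.positions_bp, ap.locations_cm):
                fh.write(f"{r}\t{ap.chrom}\t{b}\t{c:.10g}\n")
    write_sample_list(samples, out / "samples.txt")
    truth.to_json(out / "truth.json")
    with open(out / "params.json", "w") as fh:
        json.dump(
            {
                "labels": list(params.labels),
                "mix": list(params.mix),
                "generations": params.generations,
                "n_samples": params.n_samples,
                "chrom_lengths_cm": params.chrom_lengths_cm,
                "n_snps": params.n_snps,
                "posterior_noise": params.posterior_noise,
                "seed": params.seed,
                "spikes": [
                    {
                        "chrom": s.chrom,
                        "cm_start": s.cm_start,
                        "cm_end": s.cm_end,
                        "ancestry": s.ancestry,
                        "boost": s.boost,
                    }
                    for s in spikes
                ],
            },
            fh,
            indent=2,
        )
    return out


def recover_mixing(summary: LocusAncestrySummary) -> np.ndarray:
    """Genome-wide mixing-proportion estimate: mean of per-variant averages.

    For an unspiked single-pulse simulation this estimates the cohort mixing
    proportions; it sums to 1 by construction.
    """
    if summary.n_variants == 0:
        raise DegenerateInputError("cannot estimate mixing from an empty summary")
    est = summary.avg.mean(axis=0)
    return est / est.sum()
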
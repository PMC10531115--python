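#!/usr/bin/env python
"""Simulate a synthetic admixed cohort and emit it in the RFMix-style dialect.

Generates a 40-sample, two-chromosome (100 cM each, 200 SNPs each) cohort
under the default Caribbean-Hispanic-like mixing proportions, with one
Native-American enrichment spike (0.9 over 45–50 cM on chromosome 1) playing
the role of a locus cluster with strong local ancestry enrichment. The raw
per-haplotype posterior files are bulky, so they go under scratch/; later
analysis steps read them back from disk exactly as they would read real
local-ancestry output.
"""

from pathlib import Path

from admixlocus import EnrichmentSpike, SimulationParams, emit_cohort

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim_cohort"

PARAMS = SimulationParams(
    n_samples=40,
    generations=10,
    chrom_lengths_cm={"1": 100.0, "2": 100.0},
    n_snps=200,
    posterior_noise=0.02,
    seed=20240901,
)
SPIKE = EnrichmentSpike(chrom="1", cm_start=45.0, cm_end=50.0, ancestry="NA", boost=0.9)


def main() -> None:
    out = emit_cohort(PARAMS, [SPIKE], OUT)
    files = sorted(p.name for p in out.iterdir())
    print(f"simulated cohort of {PARAMS.n_samples} samples -> {out}")
    print(f"  mixing proportions {dict(zip(PARAMS.labels, PARAMS.mix))}")
    print(f"  spike: {SPIKE.ancestry} boosted to {SPIKE.boost} on "
          f"chr{SPIKE.chrom}:{SPIKE.cm_start}-{SPIKE.cm_end} cM")
    print(f"  files: {', '.join(files)}")


if __name__ == "__main__":
    main()
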
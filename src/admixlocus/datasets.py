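"""Packaged reference tables from the published admixed-cohort study.

Three small TSVs ship with the package:

``snp_catalog.tsv``
    60 variants: 20 associated with acute coronary syndrome (ACS), 20 with
    coronary artery disease (CAD), 10 with peripheral artery disease (PAD)
    from prior GWAS literature, and the 10 top signals of a clopidogrel
    high-on-treatment-platelet-reactivity GWAS in Caribbean Hispanics.
    GRCh37 positions.

``cvd_loci_ancestry.tsv``
    The 10 CVD-associated loci for which local ancestry could be inferred in
    the 510-patient cohort, with genetic position (cM) and the cohort-average
    IBS/YRI/NA proportions at each locus.

``random_loci_ancestry.tsv``
    60 randomly drawn control loci from the same cohort with the same
    columns; the published enrichment control panel.

Proportions in the published tables are rounded to two decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import SnpCatalog, SnpRecord, read_catalog


def _data_path(name: str):
    return resources.files("admixlocus.data").joinpath(name)


def load_snp_catalog() -> SnpCatalog:
    """The 60-variant catalog (ACS/CAD/PAD/clopidogrel relations)."""
    with resources.as_file(_data_path("snp_catalog.tsv")) as p:
        return read_catalog(p)


def load_cvd_locus_ancestry() -> pd.DataFrame:
    """Cohort-average ancestry at the 10 inferable CVD loci (rsid, chrom,
    pos_bp, cm, IBS, YRI, NA)."""
    with resources.as_file(_data_path("cvd_loci_ancestry.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_random_locus_ancestry() -> pd.DataFrame:
    """Cohort-average ancestry at the 60 published random control loci."""
    with resources.as_file(_data_path("random_loci_ancestry.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def cvd_loci_catalog() -> SnpCatalog:
    """The 10 CVD loci as a catalog carrying their published cM coordinates."""
    df = load_cvd_locus_ancestry()
    return SnpCatalog(
        records=[
            SnpRecord(
                rsid=row.rsid,
                chrom=str(row.chrom),
                pos_bp=int(row.pos_bp),
                cm=float(row.cm),
            )
            for row in df.itertuples(index=False)
        ]
    )
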
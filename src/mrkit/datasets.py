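"""Bundled example data.

The package ships one small fixture: the three cis instruments for morning
plasma cortisol at the SERPINA1/SERPINA6 locus on chromosome 14
(rs11621961, rs12589136, rs2749527) with their published exposure-side
summary statistics from the CORtisol NETwork (CORNET) GWAS meta-analysis
(n = 12,597, effects in SD of cortisol per allele).
"""

from __future__ import annotations

from importlib import resources

from .gwas_io import VariantAssociation, read_summary_stats


def load_cortisol_instruments() -> list[VariantAssociation]:
    """The three cortisol cis-instrument SNPs with their GWAS summary statistics."""
    ref = resources.files("mrkit.data").joinpath("cortisol_instruments.tsv")
    with resources.as_file(ref) as path:
        return read_summary_stats(path)


def cortisol_instruments_path():
    """Filesystem path to the bundled cortisol instrument table (context-free copy)."""
    return resources.files("mrkit.data").joinpath("cortisol_instruments.tsv")
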
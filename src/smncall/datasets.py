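"""Loaders for the packaged study fixtures.

Three small TSVs ship with the package: the 44 reference-cohort genotype
configurations with their three-way assay results, the 16 discordant
samples, and the joint exon-7/exon-8 genotype tally of the 1400-sample
screening cohort.  Genotypes are encoded in the compact haplotype notation
parsed by :func:`smncall.simulate.parse_haplotype_string`.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .simulate import AssayResult, SampleSpec, parse_haplotype_string

_DATA = files("smncall") / "data"


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1_genotypes() -> pd.DataFrame:
    """The 44 concordant-cohort genotypes with MLPA/qPCR/long-read columns."""
    return _read("table1_genotypes.tsv")


def load_table2_discordant() -> pd.DataFrame:
    """The 16 samples with discordant MLPA vs qPCR SMN1 exon-7 calls."""
    return _read("table2_discordant.tsv")


def load_table3_cohort() -> pd.DataFrame:
    """Joint genotype counts of the 1400-sample screening cohort."""
    return _read("table3_cohort.tsv")


def sample_spec_from_row(
    row, depth_per_copy: float = 100.0, substitution_error: float = 0.01, seed: int = 0
) -> SampleSpec:
    """Build a simulation SampleSpec from a fixture row."""
    return SampleSpec(
        sample_id=row["sample"],
        haplotypes=parse_haplotype_string(row["haplotypes"]),
        depth_per_copy=depth_per_copy,
        substitution_error=substitution_error,
        seed=seed,
    )


def assay_results_from_discordant_row(row) -> tuple[AssayResult, AssayResult]:
    """Reconstruct the recorded MLPA and qPCR results for a discordant sample."""
    mlpa_flags = {}
    if row["mlpa_e7_flag"] != ".":
        mlpa_flags["smn1_e7"] = row["mlpa_e7_flag"]
    if row["mlpa_e8_flag"] != ".":
        mlpa_flags["smn1_e8"] = row["mlpa_e8_flag"]
    mlpa = AssayResult(
        method="MLPA",
        smn1_e7=int(row["mlpa_smn1_e7"]),
        smn1_e8=int(row["mlpa_smn1_e8"]),
        smn2_e7=int(row["mlpa_smn2_e7"]),
        smn2_e8=int(row["mlpa_smn2_e8"]),
        flags=mlpa_flags,
    )
    qpcr_flags = {}
    if row["qpcr_e7_flag"] != ".":
        qpcr_flags["smn1_e7"] = row["qpcr_e7_flag"]
    if row["qpcr_e8_flag"] != ".":
        qpcr_flags["smn1_e8"] = row["qpcr_e8_flag"]
    qpcr = AssayResult(
        method="qPCR",
        smn1_e7=int(row["qpcr_smn1_e7"]),
        smn1_e8=int(row["qpcr_smn1_e8"]),
        smn2_e7=None,
        smn2_e8=None,
        flags=qpcr_flags,
    )
    return mlpa, qpcr
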
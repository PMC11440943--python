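"""Gene assignment, conversion detection, variant calling and sample profiles.

A haplotype's PSV pentad decides everything: the exon-7 PSV (c.840, index 2)
names the gene the copy functions as, the exon-8 PSV (c.*239, index 5) names
the gene its exon 8 derives from, and any of PSV indices 3-5 disagreeing
with the exon-7 gene marks a gene-conversion (hybrid) allele with the
corresponding region (intron 7 and/or exon 8).  A PSV-site mismatch is
always reported as conversion; when the catalogue carries an equivalent
variant name for the swap (e.g. c.*239A>G) that label is echoed as well,
since the field uses both phrasings for the same event.

The per-sample profile tabulates exon-7 and exon-8 copy numbers per gene:
an exon-8-converted copy counts toward its exon-7 gene's exon-7 column and
toward the other gene's exon-8 column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from .haplotyper import HaplotypeCall
from .reference import SMN1, SMN2, AmpliconModel, aligned_profile, psv_string


class UnclassifiableHaplotypeError(ValueError):
    """Raised when a haplotype carries a non-canonical allele at a gene-defining PSV."""


@dataclass
class GeneAssignment:
    exon7_gene: str  # by PSV 2 (c.840)
    exon8_gene: str  # by PSV 5 (c.*239)
    converted: bool
    conversion_region: frozenset[str]  # subset of {"intron7", "exon8"}
    variant_calls: list[str] = field(default_factory=list)
    pentad: str = ""


@dataclass
class SampleSmnProfile:
    """The per-sample result table row: exon-7/exon-8 copies per gene."""

    sample_id: str
    haplotypes: list[tuple[HaplotypeCall, int, GeneAssignment]]
    smn1_e7: int
    smn1_e8: int
    smn2_e7: int
    smn2_e8: int
    comments: list[str] = field(default_factory=list)

    @property
    def total_copies(self) -> int:
        return self.smn1_e7 + self.smn2_e7


def classify_pentad(pentad: str, model: AmpliconModel) -> GeneAssignment:
    """Pure pentad classification (no variant calling)."""
    if len(pentad) != len(model.psvs):
        raise ValueError("pentad must have one allele per PSV")
    psv2, psv5 = model.psv_by_index(2), model.psv_by_index(5)
    allele2, allele5 = pentad[1], pentad[4]
    if allele2 == psv2.smn1_allele:
        exon7_gene = SMN1
    elif allele2 == psv2.smn2_allele:
        exon7_gene = SMN2
    else:
        raise UnclassifiableHaplotypeError(
            f"non-canonical allele {allele2!r} at the exon-7 PSV (c.840)"
        )
    if allele5 == psv5.smn1_allele:
        exon8_gene = SMN1
    elif allele5 == psv5.smn2_allele:
        exon8_gene = SMN2
    else:
        raise UnclassifiableHaplotypeError(
            f"non-canonical allele {allele5!r} at the exon-8 PSV (c.*239)"
        )

    region = set()
    for psv in model.psvs:
        if psv.index < 3:
            continue
        if pentad[psv.index - 1] != model.psv_allele(exon7_gene, psv.index):
            region.add(psv.region)
    return GeneAssignment(
        exon7_gene=exon7_gene,
        exon8_gene=exon8_gene,
        converted=bool(region),
        conversion_region=frozenset(region),
        pentad=pentad,
    )


def assign_gene(hap: HaplotypeCall, model: AmpliconModel) -> GeneAssignment:
    """Classify a reconstructed haplotype and call its intragenic variants."""
    assignment = classify_pentad(psv_string(hap.consensus, model), model)
    assignment.variant_calls = call_small_variants(hap, assignment, model)
    return assignment


def call_small_variants(
    hap: HaplotypeCall, assignment: GeneAssignment, model: AmpliconModel
) -> list[str]:
    """Differences between the haplotype and its exon-7 gene's reference.

    Catalogued variants are reported by label (including PSV-site allele
    swaps, whose labels double as the conversion's variant-style name);
    uncatalogued PSV mismatches surface only through ``conversion_region``;
    any other uncatalogued difference gets a positional ``g.`` label.
    """
    gene = assignment.exon7_gene
    ref = model.reference(gene)
    profile, _ = aligned_profile(hap.consensus, ref)
    psv_positions = set(model.psv_positions)

    diff_positions = [i + 1 for i, (a, b) in enumerate(zip(profile, ref)) if a != b]
    calls: list[tuple[int, str]] = []

    # deletions: maximal runs of '-'
    deletions = []
    for is_del, grp in groupby(diff_positions, key=lambda p: profile[p - 1] == "-"):
        positions = list(grp)
        if is_del:
            # split non-adjacent runs
            run = [positions[0]]
            for p in positions[1:]:
                if p == run[-1] + 1:
                    run.append(p)
                else:
                    deletions.append(run)
                    run = [p]
            deletions.append(run)
    del_positions = {p for run in deletions for p in run}

    for run in deletions:
        start, length = run[0], len(run)
        # a small positional tolerance absorbs alignment ambiguity in repeats
        for v in model.variants.values():
            if (
                v.is_deletion
                and abs(v.position - start) <= 5
                and len(v.ref) == length
                and v.gene_context in (gene, "either")
            ):
                calls.append((start, v.hgvs_label))
                break
        else:
            calls.append((start, f"g.{start}_{start + length - 1}del"))

    for p in diff_positions:
        if p in del_positions:
            continue
        obs, refc = profile[p - 1], ref[p - 1]
        label = None
        for v in model.variants.values():
            if (
                not v.is_deletion
                and v.position == p
                and v.ref == refc
                and v.alt == obs
                and v.gene_context in (gene, "either")
            ):
                label = v.hgvs_label
                break
        if label is None:
            if p in psv_positions:
                continue  # uncatalogued PSV swap: conversion only
            label = f"g.{p}{refc}>{obs}"
        calls.append((p, label))

    return [label for _, label in sorted(calls)]


def profile_sample(
    sample_id: str,
    haplotypes_with_copies: list[tuple[HaplotypeCall, int]],
    model: AmpliconModel,
) -> SampleSmnProfile:
    """Assemble the exon-7/exon-8 copy-number profile of one sample."""
    rows = []
    smn1_e7 = smn1_e8 = smn2_e7 = smn2_e8 = 0
    comments: list[str] = []
    for hap, copies in haplotypes_with_copies:
        assignment = assign_gene(hap, model)
        rows.append((hap, copies, assignment))
        if assignment.exon7_gene == SMN1:
            smn1_e7 += copies
        else:
            smn2_e7 += copies
        if assignment.exon8_gene == SMN1:
            smn1_e8 += copies
        else:
            smn2_e8 += copies
        comments.extend(_haplotype_comments(assignment, copies))

    total = sum(c for _, c in haplotypes_with_copies)
    assert smn1_e7 + smn2_e7 == total and smn1_e8 + smn2_e8 == total
    return SampleSmnProfile(
        sample_id=sample_id,
        haplotypes=rows,
        smn1_e7=smn1_e7,
        smn1_e8=smn1_e8,
        smn2_e7=smn2_e7,
        smn2_e8=smn2_e8,
        comments=comments,
    )


def _haplotype_comments(assignment: GeneAssignment, copies: int) -> list[str]:
    gene = assignment.exon7_gene
    out = []
    if assignment.variant_calls:
        noun = "variants" if len(assignment.variant_calls) > 1 else "variant"
        out.append(f"{gene} {noun}: {', '.join(assignment.variant_calls)}")
    if assignment.converted:
        other = assignment.exon8_gene if assignment.exon8_gene != gene else (
            SMN2 if gene == SMN1 else SMN1
        )
        if assignment.conversion_region == frozenset({"exon8"}):
            region = "exon 8"
        elif "intron7" in assignment.conversion_region:
            region = "part of intron 7 and exon 8" if "exon8" in assignment.conversion_region else "part of intron 7"
        else:
            region = "exon 8"
        target = f"{other} exon 8" if "exon8" in assignment.conversion_region else other
        out.append(
            f"{copies} {'copies' if copies > 1 else 'copy'} of {gene} {region} "
            f"converted to {target}"
        )
    return out


def write_profiles(profiles: list[SampleSmnProfile], path) -> None:
    """Profile TSV mirroring the per-sample result-table layout."""
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tsmn1_e7\tsmn1_e8\tsmn2_e7\tsmn2_e8\tpsv_strings\tcomments\n"
        )
        for p in profiles:
            pentads = "; ".join(
                f"{a.pentad}, n={copies}" for _, copies, a in p.haplotypes
            )
            comments = "; ".join(p.comments) or "."
            fh.write(
                f"{p.sample_id}\t{p.smn1_e7}\t{p.smn1_e8}\t{p.smn2_e7}\t"
                f"{p.smn2_e8}\t{pentads}\t{comments}\n"
            )
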
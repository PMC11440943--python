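"""Synthetic SMN1/SMN2 amplicon pair, PSV map and intragenic variant catalogue.

SMN1 and SMN2 are near-identical paralogs on 5q13 that differ at only five
fixed bases (paralogous sequence variants, PSVs) near exons 7 and 8.  The
exon-7 PSV (c.840C/T) determines which gene a copy functions as; the exon-8
PSV (c.*239G/A) anchors the second MLPA probe.  Everything downstream of
read alignment depends only on this relative structure, so the package works
on a self-contained ~3 kb synthetic amplicon pair generated with a fixed
seed rather than on genomic sequence: the two references share a random
background and differ at exactly the five PSV positions.

Coordinates are 1-based and inclusive on the amplicon.  Variant names such
as ``c.-39A>G`` are display labels resolved through the catalogue; they are
never parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

SMN1 = "SMN1"
SMN2 = "SMN2"

#: Amplicon length (the full-length amplicon a CCS read covers).
AMPLICON_LENGTH = 3000

#: Fixed seed for the random sequence background shared by both references.
_BACKGROUND_SEED = 715517

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class PsvSite:
    """One of the five fixed SMN1/SMN2 differences.

    ``index`` runs 1-5 along the amplicon; index 2 is the exon-7 base
    c.840C/T and index 5 the exon-8 base c.*239G/A.
    """

    index: int
    position: int  # 1-based amplicon coordinate
    smn1_allele: str
    smn2_allele: str
    region: str  # exon7 | intron7 | exon8


@dataclass(frozen=True)
class VariantDef:
    """Catalogued intragenic variant.

    ``alt`` is empty for a deletion.  A variant whose position coincides
    with a PSV is an allele swap at that PSV (a single-site conversion
    surrogate); its label is display-only.
    """

    hgvs_label: str
    gene_context: str  # SMN1 | SMN2 | either
    position: int
    ref: str
    alt: str

    @property
    def is_deletion(self) -> bool:
        return self.alt == ""


@dataclass(frozen=True)
class AmpliconModel:
    """Paired references plus every annotation the pipeline needs."""

    smn1_ref: str
    smn2_ref: str
    psvs: tuple[PsvSite, ...]
    variants: dict[str, VariantDef]
    exon7_window: tuple[int, int]
    exon8_window: tuple[int, int]
    mlpa_probe_windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def reference(self, gene: str) -> str:
        if gene == SMN1:
            return self.smn1_ref
        if gene == SMN2:
            return self.smn2_ref
        raise ValueError(f"unknown gene {gene!r}")

    def psv_by_index(self, index: int) -> PsvSite:
        return self.psvs[index - 1]

    @property
    def psv_positions(self) -> tuple[int, ...]:
        return tuple(p.position for p in self.psvs)

    def psv_allele(self, gene: str, index: int) -> str:
        psv = self.psv_by_index(index)
        return psv.smn1_allele if gene == SMN1 else psv.smn2_allele

    def pentad(self, gene: str) -> str:
        return "".join(self.psv_allele(gene, p.index) for p in self.psvs)


def build_default_model() -> AmpliconModel:
    """Construct the deterministic default amplicon model.

    PSV layout (SMN1/SMN2 alleles G,C,A,A,G / A,T,G,G,A in index order):

    ====== ======== ========
    index  position region
    ====== ======== ========
    1      1260     exon7
    2      1320     exon7   (c.840 C/T, exon-7 probe anchor)
    3      1700     intron7
    4      1950     intron7
    5      2300     exon8   (c.*239 G/A, exon-8 probe anchor)
    ====== ======== ========
    """
    rng = np.random.default_rng(_BACKGROUND_SEED)
    bases = np.array(list("ACGT"))
    background = rng.choice(bases, size=AMPLICON_LENGTH)

    psvs = (
        PsvSite(1, 1260, "G", "A", "exon7"),
        PsvSite(2, 1320, "C", "T", "exon7"),
        PsvSite(3, 1700, "A", "G", "intron7"),
        PsvSite(4, 1950, "A", "G", "intron7"),
        PsvSite(5, 2300, "G", "A", "exon8"),
    )

    # Fix the bases that catalogued variant labels refer to.
    background[250 - 1] = "A"  # c.-39A>G reference base
    # Locally non-repetitive context around the catalogued 2-nt deletion
    # (2297-2298) so its alignment placement next to the exon-8 PSV is
    # unambiguous.
    background[2295 - 1 : 2302 - 1] = list("CTACTGC")

    smn1 = background.copy()
    smn2 = background.copy()
    for p in psvs:
        smn1[p.position - 1] = p.smn1_allele
        smn2[p.position - 1] = p.smn2_allele
    smn1_ref = "".join(smn1)
    smn2_ref = "".join(smn2)

    del_start = 2297  # two bases immediately upstream of the exon-8 PSV
    variants = {
        v.hgvs_label: v
        for v in (
            VariantDef("c.-39A>G", SMN1, 250, "A", "G"),
            # PSV-site allele swaps: display labels from the field, defined
            # as the SMN2->SMN1 (or SMN1->SMN2) base change at the PSV.
            VariantDef("c.*3+100A>C", SMN2, 1700, "G", "A"),
            VariantDef("c.*3+215A>G", SMN2, 1950, "G", "A"),
            VariantDef("c.*239A>G", SMN2, 2300, "A", "G"),
            VariantDef("c.*239G>A", SMN1, 2300, "G", "A"),
            VariantDef(
                "c.*237_*238del",
                SMN1,
                del_start,
                smn1_ref[del_start - 1 : del_start + 1],
                "",
            ),
        )
    }

    return AmpliconModel(
        smn1_ref=smn1_ref,
        smn2_ref=smn2_ref,
        psvs=psvs,
        variants=variants,
        exon7_window=(1200, 1400),
        exon8_window=(2201, 2500),
        mlpa_probe_windows={"exon7": (1310, 1330), "exon8": (2290, 2310)},
    )


def apply_variants(base: str, variant_labels: list[str], model: AmpliconModel) -> str:
    """Return the ``base`` gene reference with the catalogued variants applied.

    Variants are applied right-to-left by position so earlier coordinates
    stay valid after a deletion.  Raises ``KeyError`` for an unknown label
    and ``ValueError`` for overlapping variants or a reference-allele
    mismatch (e.g. an SMN1-context swap applied to SMN2).
    """
    ref = model.reference(base)
    defs = []
    for label in variant_labels:
        if label not in model.variants:
            raise KeyError(f"unknown variant label {label!r}")
        defs.append(model.variants[label])

    spans = sorted((v.position, v.position + max(len(v.ref), 1) - 1) for v in defs)
    for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
        if start_b <= end_a:
            raise ValueError("overlapping variants")

    seq = list(ref)
    for v in sorted(defs, key=lambda v: v.position, reverse=True):
        i = v.position - 1
        observed = ref[i : i + len(v.ref)]
        if observed != v.ref:
            raise ValueError(
                f"{v.hgvs_label}: reference allele {v.ref!r} not present on "
                f"{base} at position {v.position} (found {observed!r})"
            )
        seq[i : i + len(v.ref)] = list(v.alt)
    return "".join(seq)


def aligned_profile(seq: str, ref: str) -> tuple[str, float]:
    """Project ``seq`` onto ``ref`` coordinates by global alignment.

    Returns ``(profile, identity)`` where ``profile`` has one character per
    reference position: the aligned read base, or ``-`` where the read has
    a deletion.  Insertions relative to the reference are dropped.  The
    fast path handles the common CCS case (substitution errors only, equal
    length); edlib global alignment covers everything else.
    """
    if len(seq) == len(ref):
        matches = sum(a == b for a, b in zip(seq, ref))
        return seq, matches / len(ref)

    res = edlib.align(seq, ref, mode="NW", task="path")
    out = []
    qi = ti = 0
    matches = 0
    for n_str, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        if op in "=XM":
            out.append(seq[qi : qi + n])
            if op == "=":
                matches += n
            elif op == "M":
                matches += sum(seq[qi + k] == ref[ti + k] for k in range(n))
            qi += n
            ti += n
        elif op == "D":  # read misses reference bases
            out.append("-" * n)
            ti += n
        elif op == "I":  # read has extra bases; not representable on ref axis
            qi += n
    profile = "".join(out)
    if len(profile) != len(ref):  # pragma: no cover - alignment bookkeeping guard
        raise RuntimeError("alignment projection length mismatch")
    return profile, matches / len(ref)


def psv_string(seq: str, model: AmpliconModel) -> str:
    """The five PSV alleles observed in ``seq``, in index order.

    ``seq`` must be globally alignable to the amplicon (identity >= 90%);
    catalogued indels shift downstream lookups through the alignment.
    """
    profile, identity = aligned_profile(seq, model.smn1_ref)
    if identity < 0.90:
        raise ValueError("sequence does not align to the amplicon (identity < 90%)")
    return "".join(profile[p.position - 1] for p in model.psvs)


def write_model(model: AmpliconModel, fasta_path, tsv_path) -> None:
    """Serialize the model as a two-record FASTA plus an annotation TSV."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(model.smn1_ref), id=SMN1, description="synthetic amplicon"),
        SeqRecord(Seq(model.smn2_ref), id=SMN2, description="synthetic amplicon"),
    ]
    seqio_write(records, str(fasta_path), "fasta")

    with open(tsv_path, "w") as fh:
        fh.write("record_type\tname\tposition\tsmn1_or_ref\tsmn2_or_alt\tregion\n")
        for p in model.psvs:
            fh.write(
                f"psv\t{p.index}\t{p.position}\t{p.smn1_allele}\t{p.smn2_allele}\t{p.region}\n"
            )
        for v in model.variants.values():
            fh.write(
                f"variant\t{v.hgvs_label}\t{v.position}\t{v.ref}\t{v.alt or '.'}\t{v.gene_context}\n"
            )
        for name, (lo, hi) in (
            ("exon7", model.exon7_window),
            ("exon8", model.exon8_window),
        ):
            fh.write(f"window\t{name}\t{lo}\t{hi}\t.\t.\n")
        for name, (lo, hi) in model.mlpa_probe_windows.items():
            fh.write(f"probe_window\t{name}\t{lo}\t{hi}\t.\t.\n")
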
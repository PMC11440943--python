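"""Silent "2+0" carrier inference from parents plus one child.

An individual with two SMN1 copies may carry them one per chromosome
("1+1", a true negative) or both in cis on a single chromosome ("2+0", a
silent carrier whose other chromosome has no SMN1 at all).  Copy number
cannot tell these apart, but haplotype identity can: if a child carries two
copies of a gene and both haplotype fingerprints trace to the same parent,
the parent transmitted a single chromosome bearing both copies -- the
child is "2+0", and so is the parent whenever those two copies are all the
parent has.

Fingerprints are the defining-allele maps produced by the haplotyper
(positions where a haplotype differs from the SMN1 reference).  Matching
is exact: a child fingerprint matches a parent only when every defining
allele agrees.  A fingerprint present in both parents cannot be assigned
(ambiguous); one present in neither is flagged de novo / recombinant and
blocks the call, since it violates Mendelian transmission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .reference import SMN1, SMN2

Fingerprint = frozenset  # of (position, allele) pairs

CONFIGURATIONS = ("2+0", "1+1", "1+0", "0+0", "indeterminate")


@dataclass
class MemberHaplotypes:
    """Per-gene haplotype fingerprints with copy numbers for one person."""

    member_id: str
    role: str  # father | mother | child
    genes: dict[str, list[tuple[Fingerprint, int]]] = field(default_factory=dict)

    def total_copies(self, gene: str) -> int:
        return sum(cn for _, cn in self.genes.get(gene, []))

    def carries(self, gene: str, fingerprint: Fingerprint) -> bool:
        return any(fp == fingerprint for fp, _ in self.genes.get(gene, []))


@dataclass
class OriginAssignment:
    gene: str
    hap_index: int
    copy_number: int
    origin: str  # father | mother | ambiguous | unmatched


@dataclass
class CisTransCall:
    member_id: str
    gene: str
    configuration: str
    support: str = ""


def match_haplotypes(
    child: MemberHaplotypes, father: MemberHaplotypes, mother: MemberHaplotypes
) -> dict[str, list[OriginAssignment]]:
    """Assign each child haplotype to the parent(s) carrying it."""
    out: dict[str, list[OriginAssignment]] = {}
    for gene, haps in child.genes.items():
        assignments = []
        for i, (fp, cn) in enumerate(haps):
            in_f = father.carries(gene, fp)
            in_m = mother.carries(gene, fp)
            if in_f and in_m:
                origin = "ambiguous"
            elif in_f:
                origin = "father"
            elif in_m:
                origin = "mother"
            else:
                origin = "unmatched"
            assignments.append(
                OriginAssignment(gene=gene, hap_index=i, copy_number=cn, origin=origin)
            )
        out[gene] = assignments
    return out


def _parent_background_call(member: MemberHaplotypes, gene: str) -> CisTransCall:
    total = member.total_copies(gene)
    if total == 0:
        return CisTransCall(member.member_id, gene, "0+0", "no copies")
    if total == 1:
        return CisTransCall(member.member_id, gene, "1+0", "single copy")
    return CisTransCall(
        member.member_id, gene, "indeterminate", "phase not resolvable from this trio"
    )


def infer_two_plus_zero(
    origins: dict[str, list[OriginAssignment]],
    child: MemberHaplotypes,
    father: MemberHaplotypes,
    mother: MemberHaplotypes,
) -> list[CisTransCall]:
    """Cis/trans configuration calls for the child and both parents.

    A child with two copies of a gene that both trace to one parent sits
    "2+0" (both copies on the transmitted chromosome); the transmitting
    parent is also "2+0" when those two copies are its entire complement.
    One copy from each parent is "1+1".  Ambiguous origins, non-Mendelian
    fingerprints, and totals above two are never called.
    """
    calls: list[CisTransCall] = []
    parents = {"father": father, "mother": mother}
    genes = sorted(set(child.genes) | set(father.genes) | set(mother.genes))
    for gene in genes:
        assignments = origins.get(gene, [])
        total = child.total_copies(gene)
        parent_calls = {
            role: _parent_background_call(member, gene) for role, member in parents.items()
        }

        if any(a.origin == "unmatched" for a in assignments):
            child_call = CisTransCall(
                child.member_id,
                gene,
                "indeterminate",
                "non-Mendelian: child haplotype absent from both parents",
            )
        elif total == 0:
            child_call = CisTransCall(child.member_id, gene, "0+0", "no copies")
        elif total == 1:
            child_call = CisTransCall(child.member_id, gene, "1+0", "single copy")
        elif total == 2:
            per_copy = [a.origin for a in assignments for _ in range(a.copy_number)]
            collapsed = any(a.copy_number >= 2 for a in assignments)
            if "ambiguous" in per_copy:
                child_call = CisTransCall(
                    child.member_id,
                    gene,
                    "indeterminate",
                    "haplotype carried by both parents",
                )
            elif len(set(per_copy)) == 1:
                parent_role = per_copy[0]
                note = (
                    "collapsed identical copies, absent from the other parent"
                    if collapsed
                    else "both haplotypes inherited from the "
                    + parent_role
                )
                child_call = CisTransCall(child.member_id, gene, "2+0", note)
                parent = parents[parent_role]
                if parent.total_copies(gene) == 2:
                    parent_calls[parent_role] = CisTransCall(
                        parent.member_id,
                        gene,
                        "2+0",
                        "transmitted both copies on one chromosome to "
                        + child.member_id,
                    )
            else:
                child_call = CisTransCall(
                    child.member_id, gene, "1+1", "one haplotype from each parent"
                )
        else:
            child_call = CisTransCall(
                child.member_id,
                gene,
                "indeterminate",
                f"{total} copies: configuration beyond biallelic cis/trans calling",
            )
        calls.append(child_call)
        calls.extend(parent_calls[r] for r in ("father", "mother"))
    return calls


def analyze_trio(
    child: MemberHaplotypes, father: MemberHaplotypes, mother: MemberHaplotypes
) -> list[CisTransCall]:
    """Convenience wrapper: match origins then infer configurations."""
    return infer_two_plus_zero(match_haplotypes(child, father, mother), child, father, mother)


# ---------------------------------------------------------------------------
# Synthetic trios (known phase) for validating the caller
# ---------------------------------------------------------------------------

def simulate_trio(
    seed: int,
    configuration: str = "2+0",
    gene: str = SMN1,
    distinct: bool = True,
):
    """Generate a random trio with known child configuration for ``gene``.

    Each parental chromosome carries 0-2 gene copies with random haplotype
    fingerprints; ``configuration`` fixes how the child's two copies of the
    target gene were transmitted.  With ``distinct=False`` the same
    fingerprint may be planted in both parents, which makes the origin
    ambiguous -- such trios must never be called 2+0 or 1+1.

    Returns ``(child, father, mother, truth)`` where truth is the planted
    child configuration ("2+0" or "1+1").
    """
    if configuration not in ("2+0", "1+1"):
        raise ValueError("configuration must be '2+0' or '1+1'")
    rng = np.random.default_rng(seed)

    def fingerprint() -> Fingerprint:
        n = int(rng.integers(2, 6))
        positions = rng.choice(np.arange(10, 2990), size=n, replace=False)
        return frozenset((int(p), "ACGT"[int(rng.integers(0, 4))]) for p in positions)

    if configuration == "2+0":
        fp_a, fp_b = fingerprint(), fingerprint()
        father = MemberHaplotypes("F", "father", {gene: [(fp_a, 1), (fp_b, 1)]})
        mother_haps: list[tuple[Fingerprint, int]] = []
        child_haps = [(fp_a, 1), (fp_b, 1)]
    else:
        fp_a, fp_b = fingerprint(), fingerprint()
        father = MemberHaplotypes("F", "father", {gene: [(fp_a, 1), (fingerprint(), 1)]})
        mother_haps = [(fp_b, 1)]
        child_haps = [(fp_a, 1), (fp_b, 1)]
    if not distinct:
        # plant one child fingerprint in the other parent too
        shared = child_haps[0][0]
        mother_haps = mother_haps + [(shared, 1)]
    mother = MemberHaplotypes("M", "mother", {gene: mother_haps})
    child = MemberHaplotypes("C", "child", {gene: child_haps})
    return child, father, mother, configuration


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _parse_fingerprint(text: str) -> Fingerprint:
    if text in (".", ""):
        return frozenset()
    pairs = []
    for item in text.split(";"):
        pos, allele = item.split(":")
        pairs.append((int(pos), allele))
    return frozenset(pairs)


def load_pedigree(path) -> dict[str, MemberHaplotypes]:
    """Read a pedigree TSV: member, role, gene, fingerprint, copy_number.

    The fingerprint column is ``pos:allele`` pairs joined by ``;`` (``.``
    for a haplotype identical to the SMN1 reference).
    """
    members: dict[str, MemberHaplotypes] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            member_id, role, gene = f[idx["member"]], f[idx["role"]], f[idx["gene"]]
            fp = _parse_fingerprint(f[idx["fingerprint"]])
            cn = int(f[idx["copy_number"]])
            m = members.setdefault(member_id, MemberHaplotypes(member_id, role, {}))
            m.genes.setdefault(gene, []).append((fp, cn))
    roles = {m.role for m in members.values()}
    if not {"father", "mother", "child"} <= roles:
        raise ValueError("pedigree must contain a father, a mother and a child")
    return members


def write_calls(calls: list[CisTransCall], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "member_id": c.member_id,
                    "gene": c.gene,
                    "configuration": c.configuration,
                    "support": c.support,
                }
                for c in calls
            ],
            fh,
            indent=2,
        )
        fh.write("\n")


__all__ = [
    "SMN1",
    "SMN2",
    "MemberHaplotypes",
    "OriginAssignment",
    "CisTransCall",
    "match_haplotypes",
    "infer_two_plus_zero",
    "analyze_trio",
    "simulate_trio",
    "load_pedigree",
    "write_calls",
]
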
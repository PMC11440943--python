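"""Read-backed haplotype reconstruction by recursive SNP bipartition.

Each CCS read covers the full amplicon, so haplotyping reduces to grouping
reads by the heterozygous sites they share.  Within a read group, a site is
a usable SNP when its minor-allele frequency lies in the 20-80% window
(inclusive); lower frequencies are sequencing error, higher ones are not
informative for a split.  The group is split on the SNP with the highest
minor-allele frequency (ties broken toward the lowest coordinate) and the
procedure recurses on both halves until no group has a usable SNP left.
The frequency window is re-evaluated inside every subgroup, which is what
lets nested mixtures (e.g. 1:1:2) resolve.  Every emitted group is one
haplotype; its read count feeds the Poisson copy-number caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import AmpliconModel, aligned_profile

#: Alphabet observed per aligned position ('-' marks a deletion).
_ALPHABET = np.frombuffer(b"ACGT-", dtype="S1")

DEFAULT_MIN_FREQ = 0.20
DEFAULT_MAX_FREQ = 0.80
DEFAULT_MIN_GROUP_SIZE = 10
DEFAULT_MIN_IDENTITY = 0.90


@dataclass
class AlleleMatrix:
    """Per-read, per-position observed alleles on reference coordinates."""

    matrix: np.ndarray  # shape (n_reads, amplicon_length), dtype S1
    read_ids: list[str]
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SnpSite:
    position: int  # 1-based
    major_allele: str
    minor_allele: str
    minor_frequency: float


@dataclass
class HaplotypeCall:
    """One reconstructed haplotype and its read support."""

    consensus: str
    defining_alleles: dict[int, str]  # 1-based position -> allele ('-' = deleted)
    read_ids: tuple[str, ...]
    read_count: int


def build_allele_matrix(
    reads,
    model: AmpliconModel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> AlleleMatrix:
    """Align every read to the SMN1 reference and stack the allele profiles.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs or Biopython
    SeqRecords.  Reads with alignment identity below ``min_identity`` are
    dropped (and reported through ``dropped_ids``).
    """
    ref = model.smn1_ref
    rows, kept, dropped = [], [], []
    n_input = 0
    for read in reads:
        n_input += 1
        if hasattr(read, "seq"):
            read_id, seq = read.id, str(read.seq)
        else:
            read_id, seq = read
        profile, identity = aligned_profile(seq.upper(), ref)
        if identity < min_identity:
            dropped.append(read_id)
            continue
        rows.append(np.frombuffer(profile.encode(), dtype="S1"))
        kept.append(read_id)
    if n_input == 0:
        raise ValueError("no reads supplied")
    if not rows:
        raise ValueError("all reads failed alignment to the amplicon")
    return AlleleMatrix(matrix=np.vstack(rows), read_ids=kept, dropped_ids=dropped)


def _allele_counts(sub: np.ndarray) -> np.ndarray:
    """(5, L) counts of A/C/G/T/- per column."""
    return np.stack([(sub == b).sum(axis=0) for b in _ALPHABET])


def call_snps(
    matrix: AlleleMatrix | np.ndarray,
    min_freq: float = DEFAULT_MIN_FREQ,
    max_freq: float = DEFAULT_MAX_FREQ,
) -> list[SnpSite]:
    """Sites whose minor-allele frequency falls inside the retention window.

    The frequency is taken over the two most frequent alleles in the group
    (the site is treated as bi-allelic once rarer observations are masked
    as sequencing error).  Both window edges are inclusive; sites below the
    window are sequencing error, sites above it are near-fixed.  Result is
    sorted by position.
    """
    sub = matrix.matrix if isinstance(matrix, AlleleMatrix) else matrix
    counts = _allele_counts(sub)
    order = np.argsort(counts, axis=0)  # ascending; ties resolved by allele index
    major_i, minor_i = order[-1], order[-2]
    cols = np.arange(sub.shape[1])
    major_n = counts[major_i, cols]
    minor_n = counts[minor_i, cols]
    with np.errstate(invalid="ignore"):
        freq = minor_n / np.maximum(major_n + minor_n, 1)
    passing = np.nonzero((minor_n > 0) & (freq >= min_freq) & (freq <= max_freq))[0]
    return [
        SnpSite(
            position=int(p) + 1,
            major_allele=_ALPHABET[major_i[p]].decode(),
            minor_allele=_ALPHABET[minor_i[p]].decode(),
            minor_frequency=float(freq[p]),
        )
        for p in passing
    ]


def consensus(sub: np.ndarray, model: AmpliconModel) -> tuple[str, dict[int, str]]:
    """Majority-vote consensus of a read group.

    Per-position ties break toward the SMN1 reference allele.  Returns the
    consensus sequence (majority deletions removed) together with the map
    of positions where the group differs from the SMN1 reference -- the
    haplotype's defining alleles / fingerprint.
    """
    ref = np.frombuffer(model.smn1_ref.encode(), dtype="S1")
    counts = _allele_counts(sub)
    best = counts.argmax(axis=0)
    top = counts.max(axis=0)
    # prefer the reference allele wherever it ties the plurality allele
    ref_idx = np.searchsorted(_ALPHABET[:4], ref)
    cols = np.arange(sub.shape[1])
    ref_count = counts[ref_idx, cols]
    best = np.where(ref_count == top, ref_idx, best)
    profile = _ALPHABET[best]
    differs = np.nonzero(profile != ref)[0]
    defining = {int(p) + 1: profile[p].decode() for p in differs}
    seq = profile[profile != b"-"].tobytes().decode()
    return seq, defining


def partition_reads(
    matrix: AlleleMatrix,
    model: AmpliconModel,
    min_freq: float = DEFAULT_MIN_FREQ,
    max_freq: float = DEFAULT_MAX_FREQ,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> tuple[list[HaplotypeCall], list[str]]:
    """Recursively bipartition the reads into haplotypes.

    Returns ``(haplotypes, discarded_read_ids)``.  Groups that fall below
    ``min_group_size`` during splitting are discarded rather than emitted.
    Conservation holds: emitted read ids plus discarded ids partition the
    matrix's reads.
    """
    if matrix.n_reads < min_group_size:
        raise ValueError(
            f"only {matrix.n_reads} aligned reads; need at least {min_group_size}"
        )
    haplotypes: list[HaplotypeCall] = []
    discarded: list[str] = []

    def recurse(idx: np.ndarray) -> None:
        sub = matrix.matrix[idx]
        snps = call_snps(sub, min_freq=min_freq, max_freq=max_freq)
        if not snps:
            seq, defining = consensus(sub, model)
            ids = tuple(matrix.read_ids[i] for i in idx)
            haplotypes.append(
                HaplotypeCall(
                    consensus=seq,
                    defining_alleles=defining,
                    read_ids=ids,
                    read_count=len(ids),
                )
            )
            return
        site = max(snps, key=lambda s: (s.minor_frequency, -s.position))
        col = matrix.matrix[idx, site.position - 1]
        minor_mask = col == site.minor_allele.encode()
        for part in (idx[~minor_mask], idx[minor_mask]):
            if part.size == 0:
                continue
            if part.size < min_group_size:
                discarded.extend(matrix.read_ids[i] for i in part)
            else:
                recurse(part)

    recurse(np.arange(matrix.n_reads))
    haplotypes.sort(key=lambda h: (-h.read_count, h.consensus))
    return haplotypes, discarded


def write_haplotypes(haplotypes: list[HaplotypeCall], fasta_path, tsv_path) -> None:
    """Serialize haplotypes as FASTA plus a support/defining-allele TSV."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(h.consensus), id=f"hap{i + 1}", description=f"reads={h.read_count}")
        for i, h in enumerate(haplotypes)
    ]
    seqio_write(records, str(fasta_path), "fasta")
    with open(tsv_path, "w") as fh:
        fh.write("haplotype\tread_count\tdefining_alleles\n")
        for i, h in enumerate(haplotypes):
            alleles = ";".join(f"{p}:{a}" for p, a in sorted(h.defining_alleles.items())) or "."
            fh.write(f"hap{i + 1}\t{h.read_count}\t{alleles}\n")
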
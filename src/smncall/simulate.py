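"""Synthetic-data generation: CCS read sets and MLPA/qPCR assay readouts.

The read model emulates full-length amplicon CCS sequencing: every read
covers the whole amplicon, the number of reads per haplotype is Poisson
with mean proportional to its copy number, and the only errors are i.i.d.
substitutions (CCS consensus error at this scale is dominated by rare
substitutions; no per-base quality or chimera modelling).  Defaults are the
study conditions used throughout: 100 reads per gene copy and a 1%
substitution rate.

The assay simulators reproduce what hybridisation/amplification chemistry
can and cannot see.  MLPA probes interrogate a short window around each
discriminating PSV, so a small variant inside a probe window silently
removes that copy from the probe count; dosage noise scales with the
square root of the true copy count and near-threshold dosages are flagged
NLT/NUT (near lower/upper threshold).  qPCR reports SMN1 only (SMN2 is
suppressed by chemical blocking) and its characteristic failure is a
discrete +/-1 miscall rather than continuous dosage noise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .reference import SMN1, SMN2, AmpliconModel, aligned_profile, apply_variants

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Study-condition defaults for the read generator.
DEFAULT_DEPTH_PER_COPY = 100.0
DEFAULT_SUBSTITUTION_ERROR = 0.01


@dataclass
class HaplotypeSpec:
    """One distinct allele of the amplicon and its multiplicity."""

    label: str
    base_gene: str
    variant_labels: list[str] = field(default_factory=list)
    copy_number: int = 1

    def validate(self) -> None:
        if self.base_gene not in (SMN1, SMN2):
            raise ValueError(f"base_gene must be SMN1 or SMN2, got {self.base_gene!r}")
        if not 1 <= self.copy_number <= 4:
            raise ValueError("copy_number must be in 1..4")


@dataclass
class SampleSpec:
    """Genotype plus sequencing parameters for one simulated sample."""

    sample_id: str
    haplotypes: list[HaplotypeSpec]
    depth_per_copy: float = DEFAULT_DEPTH_PER_COPY
    substitution_error: float = DEFAULT_SUBSTITUTION_ERROR
    seed: int = 0

    def validate(self) -> None:
        if not self.haplotypes:
            raise ValueError("sample must declare at least one haplotype")
        if not self.depth_per_copy > 0:
            raise ValueError("depth_per_copy must be > 0")
        if not 0 <= self.substitution_error < 0.05:
            raise ValueError("substitution_error must be in [0, 0.05)")
        for hap in self.haplotypes:
            hap.validate()

    @property
    def total_copies(self) -> int:
        return sum(h.copy_number for h in self.haplotypes)


@dataclass
class AssayNoise:
    """Noise model for the simulated assays (all rates in [0, 0.5]).

    ``qpcr_miscall_direction`` forces the +/-1 perturbation downward (-1) or
    upward (+1); ``None`` draws the sign at random.
    """

    mlpa_sigma: float = 0.0
    gray_band: float = 0.15
    qpcr_miscall: float = 0.0
    qpcr_gray: float = 0.0
    qpcr_miscall_direction: int | None = None

    def validate(self) -> None:
        for name in ("mlpa_sigma", "gray_band"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        for name in ("qpcr_miscall", "qpcr_gray"):
            # probabilities; 1.0 permits deterministic forced-miscall runs
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class AssayResult:
    """Copy-number calls from a simulated assay.

    qPCR reports SMN1 only; its SMN2 fields are ``None``.  ``flags`` maps a
    reported field name (e.g. ``"smn1_e7"``) to ``"NLT"`` or ``"NUT"``.
    """

    method: str  # MLPA | qPCR
    smn1_e7: int
    smn1_e8: int
    smn2_e7: int | None
    smn2_e8: int | None
    flags: dict[str, str] = field(default_factory=dict)


def haplotype_sequence(hap: HaplotypeSpec, model: AmpliconModel) -> str:
    return apply_variants(hap.base_gene, hap.variant_labels, model)


_HAP_RE = re.compile(r"^(SMN[12])(?:\[([^\]]*)\])?\*(\d+)$")


def parse_haplotype_string(text: str) -> list[HaplotypeSpec]:
    """Parse the compact genotype notation used by the packaged fixtures.

    Example: ``"SMN1*2 + SMN2[c.*239A>G]*1"`` is two SMN1 copies plus one
    SMN2 copy carrying c.*239A>G.
    """
    haps = []
    for i, part in enumerate(text.split(" + ")):
        part = part.strip()
        m = _HAP_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse haplotype term {part!r}")
        gene, labels, n = m.groups()
        variant_labels = [v for v in (labels or "").split(";") if v]
        haps.append(
            HaplotypeSpec(
                label=f"hap{i + 1}",
                base_gene=gene,
                variant_labels=variant_labels,
                copy_number=int(n),
            )
        )
    return haps


def format_haplotype_string(haps: list[HaplotypeSpec]) -> str:
    parts = []
    for h in haps:
        labels = f"[{';'.join(h.variant_labels)}]" if h.variant_labels else ""
        parts.append(f"{h.base_gene}{labels}*{h.copy_number}")
    return " + ".join(parts)


def simulate_ccs(spec: SampleSpec, model: AmpliconModel) -> list[SeqRecord]:
    """Generate a CCS read set for one sample.

    Deterministic given ``spec.seed``.  The per-haplotype read counts are
    drawn first, one ``Poisson(copy_number * depth_per_copy)`` draw per
    haplotype in declaration order, before any read is built; reads are then
    shuffled and renamed so names carry no information about their origin.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = [int(rng.poisson(h.copy_number * spec.depth_per_copy)) for h in spec.haplotypes]

    reads: list[str] = []
    for hap, count in zip(spec.haplotypes, counts):
        template = np.frombuffer(haplotype_sequence(hap, model).encode(), dtype="S1")
        base_idx = np.searchsorted(_BASES, template)
        for _ in range(count):
            if spec.substitution_error > 0:
                hit = rng.random(template.size) < spec.substitution_error
                k = int(hit.sum())
                if k:
                    read_idx = base_idx.copy()
                    # substitute with one of the three other bases, uniformly
                    read_idx[hit] = (read_idx[hit] + rng.integers(1, 4, size=k)) % 4
                    reads.append(_BASES[read_idx].tobytes().decode())
                    continue
            reads.append(template.tobytes().decode())

    order = rng.permutation(len(reads))
    records = []
    for new_i, old_i in enumerate(order):
        seq = reads[old_i]
        rec = SeqRecord(Seq(seq), id=f"read{new_i:06d}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path) -> None:
    seqio_write(records, path if hasattr(path, "write") else str(path), "fastq")


# ---------------------------------------------------------------------------
# MLPA
# ---------------------------------------------------------------------------

def _probe_matches(profile: str, model: AmpliconModel, exon: str, allele: str) -> bool:
    """Does the haplotype hybridise the probe for ``allele`` at this exon?

    The probe covers a short window around its anchor PSV; the haplotype
    must carry the probe allele at the anchor and match the amplicon
    background at every other window position (any variant or deletion in
    the window disrupts ligation).
    """
    anchor = model.psv_by_index(2 if exon == "exon7" else 5)
    lo, hi = model.mlpa_probe_windows[exon]
    for pos in range(lo, hi + 1):
        expected = allele if pos == anchor.position else model.smn1_ref[pos - 1]
        if profile[pos - 1] != expected:
            return False
    return True


def mlpa_true_counts(spec: SampleSpec, model: AmpliconModel) -> dict[str, int]:
    """Probe-countable truth: copies hybridising each of the four probes."""
    counts = {"smn1_e7": 0, "smn1_e8": 0, "smn2_e7": 0, "smn2_e8": 0}
    probes = {
        "smn1_e7": ("exon7", model.psv_by_index(2).smn1_allele),
        "smn2_e7": ("exon7", model.psv_by_index(2).smn2_allele),
        "smn1_e8": ("exon8", model.psv_by_index(5).smn1_allele),
        "smn2_e8": ("exon8", model.psv_by_index(5).smn2_allele),
    }
    for hap in spec.haplotypes:
        profile, _ = aligned_profile(haplotype_sequence(hap, model), model.smn1_ref)
        for key, (exon, allele) in probes.items():
            if _probe_matches(profile, model, exon, allele):
                counts[key] += hap.copy_number
    return counts


def dosage_call(dosage: float, gray_band: float) -> tuple[int, str | None]:
    """Round a continuous dosage to an integer call, flagging the gray zone.

    Calls at most ``gray_band`` below a rounding threshold (x.5) are NLT,
    at most ``gray_band`` at/above it are NUT.
    """
    dosage = max(dosage, 0.0)
    call = math.floor(dosage + 0.5)
    threshold = math.floor(dosage) + 0.5
    flag = None
    if abs(dosage - threshold) <= gray_band:
        flag = "NLT" if dosage < threshold else "NUT"
    return call, flag


def simulate_mlpa(
    spec: SampleSpec,
    model: AmpliconModel,
    noise: AssayNoise | None = None,
    seed: int = 0,
) -> AssayResult:
    """Simulate the four-probe MLPA readout for one sample.

    Dosage noise is Normal with standard deviation
    ``mlpa_sigma * sqrt(true count)`` (counting statistics on peak areas).
    """
    noise = noise or AssayNoise()
    noise.validate()
    rng = np.random.default_rng(seed)
    true = mlpa_true_counts(spec, model)
    calls: dict[str, int] = {}
    flags: dict[str, str] = {}
    for key in ("smn1_e7", "smn1_e8", "smn2_e7", "smn2_e8"):
        t = true[key]
        dosage = float(t)
        if noise.mlpa_sigma > 0 and t > 0:
            dosage += rng.normal(0.0, noise.mlpa_sigma * math.sqrt(t))
        call, flag = dosage_call(dosage, noise.gray_band if noise.mlpa_sigma > 0 else -1.0)
        calls[key] = call
        if flag:
            flags[key] = flag
    return AssayResult(method="MLPA", flags=flags, **calls)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def qpcr_true_counts(spec: SampleSpec, model: AmpliconModel) -> dict[str, int]:
    """Amplification truth: copies carrying the SMN1 allele at each PSV."""
    counts = {"smn1_e7": 0, "smn1_e8": 0}
    for hap in spec.haplotypes:
        profile, _ = aligned_profile(haplotype_sequence(hap, model), model.smn1_ref)
        if profile[model.psv_by_index(2).position - 1] == model.psv_by_index(2).smn1_allele:
            counts["smn1_e7"] += hap.copy_number
        if profile[model.psv_by_index(5).position - 1] == model.psv_by_index(5).smn1_allele:
            counts["smn1_e8"] += hap.copy_number
    return counts


def simulate_qpcr(
    spec: SampleSpec,
    model: AmpliconModel,
    noise: AssayNoise | None = None,
    seed: int = 0,
) -> AssayResult:
    """Simulate the SMN1-only qPCR readout (SMN2 chemically blocked)."""
    noise = noise or AssayNoise()
    noise.validate()
    rng = np.random.default_rng(seed)
    true = qpcr_true_counts(spec, model)
    calls: dict[str, int] = {}
    flags: dict[str, str] = {}
    for key in ("smn1_e7", "smn1_e8"):
        reported = true[key]
        if noise.qpcr_miscall > 0 and rng.random() < noise.qpcr_miscall:
            delta = noise.qpcr_miscall_direction
            if delta is None:
                delta = int(rng.choice([-1, 1]))
            reported = max(0, reported + delta)
        if noise.qpcr_gray > 0 and rng.random() < noise.qpcr_gray:
            flags[key] = "NLT" if reported <= true[key] else "NUT"
        calls[key] = reported
    return AssayResult(
        method="qPCR",
        smn1_e7=calls["smn1_e7"],
        smn1_e8=calls["smn1_e8"],
        smn2_e7=None,
        smn2_e8=None,
        flags=flags,
    )


def cq_to_cn(delta_delta_cq: float) -> tuple[float, int]:
    """Relative quantification: ratio ``2**(-ddCq)`` against a 2-copy reference."""
    if not math.isfinite(delta_delta_cq):
        raise ValueError("delta_delta_cq must be finite")
    ratio = 2.0 ** (-delta_delta_cq)
    return ratio, math.floor(2.0 * ratio + 0.5)


def write_assay_results(results: list[tuple[str, AssayResult]], path) -> None:
    """Write (sample_id, AssayResult) pairs as TSV."""
    with open(path, "w") as fh:
        fh.write("sample_id\tmethod\tsmn1_e7\tsmn1_e8\tsmn2_e7\tsmn2_e8\tflags\n")
        for sample_id, r in results:
            flags = ";".join(f"{k}={v}" for k, v in sorted(r.flags.items())) or "."
            fh.write(
                f"{sample_id}\t{r.method}\t{r.smn1_e7}\t{r.smn1_e8}\t"
                f"{r.smn2_e7 if r.smn2_e7 is not None else '.'}\t"
                f"{r.smn2_e8 if r.smn2_e8 is not None else '.'}\t{flags}\n"
            )
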
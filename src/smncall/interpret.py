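"""Carrier classification, cohort tallies and three-way method concordance.

Carrier status is read off the SMN1 exon-7 copy number: 0 copies is
affected, 1 copy is a carrier, >=2 copies is negative.  A carrier with
three SMN2 exon-7 copies arose by SMN1->SMN2 conversion (total copy number
preserved); any other carrier arose by deletion.  A negative sample with
exactly 2 SMN1 copies may still be a silent "2+0" carrier (both copies in
cis), which copy number alone cannot resolve -- the profile is flagged so
pedigree follow-up (see ``smncall.trio``) can be offered.

The discrepancy taxonomy compares the two probe assays against the
long-read truth for SMN1 exon 7.  qPCR undercalls of a 2-copy sample are
false positives for heterozygous deletion (counted whether or not the call
was flagged near-threshold); qPCR undercalls of a duplication are false
negatives unless the qPCR call itself sat in the gray zone; MLPA
undercalls of a duplication are false negatives (these typically do sit
near the threshold, and are still counted as such); remaining flagged
disagreements are gray-zone-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import SampleSmnProfile
from .simulate import AssayResult

CARRIER_STATUSES = ("affected", "carrier", "negative")
DISCREPANCY_CLASSES = (
    "qpcr_fp_het_deletion",
    "qpcr_fn_duplication",
    "mlpa_fn_duplication",
    "gray_zone_only",
    "concordant",
)

_GENOTYPE_COLS = ["smn1_e7", "smn1_e8", "smn2_e7", "smn2_e8"]


@dataclass
class CarrierCall:
    status: str  # affected | carrier | negative
    mechanism: str  # deletion | conversion | n.a.
    silent_risk_note: bool  # negative with smn1_e7 == 2: possible silent 2+0


@dataclass
class CohortTally:
    """Joint genotype table plus the marginals and carrier summary."""

    table: pd.DataFrame  # columns smn1_e7..smn2_e8, n, ratio_pct
    total_n: int
    smn1_e7_marginals: dict[int, tuple[int, float]]  # copies -> (count, ratio %)
    smn2_e7_marginals: dict[int, tuple[int, float]]
    carrier_count: int
    carrier_rate_pct: float
    carrier_prevalence: str  # e.g. "1/61"
    deletion_carriers: tuple[int, float]  # (count, ratio %)
    conversion_carriers: tuple[int, float]
    smn2_homozygous_deletions: tuple[int, float]


@dataclass
class DiscrepancyRecord:
    sample_id: str
    mlpa_smn1_e7: int
    qpcr_smn1_e7: int
    truth_smn1_e7: int
    klass: str
    gray_flags: dict[str, str] = field(default_factory=dict)

    @property
    def mlpa_vs_qpcr_discordant(self) -> bool:
        return self.mlpa_smn1_e7 != self.qpcr_smn1_e7


def classify_carrier(profile: SampleSmnProfile | tuple[int, int]) -> CarrierCall:
    """Carrier status from SMN1/SMN2 exon-7 copy numbers.

    Accepts a full profile or a bare ``(smn1_e7, smn2_e7)`` pair.
    """
    if isinstance(profile, SampleSmnProfile):
        smn1_e7, smn2_e7 = profile.smn1_e7, profile.smn2_e7
    else:
        smn1_e7, smn2_e7 = profile
    if smn1_e7 < 0 or smn2_e7 < 0:
        raise ValueError("copy numbers must be non-negative")
    if smn1_e7 == 0:
        return CarrierCall(status="affected", mechanism="n.a.", silent_risk_note=False)
    if smn1_e7 == 1:
        mechanism = "conversion" if smn2_e7 >= 3 else "deletion"
        return CarrierCall(status="carrier", mechanism=mechanism, silent_risk_note=False)
    return CarrierCall(
        status="negative", mechanism="n.a.", silent_risk_note=smn1_e7 == 2
    )


def tally_cohort(data: pd.DataFrame | list[SampleSmnProfile]) -> CohortTally:
    """Aggregate a genotype-count table or a list of profiles.

    A DataFrame input needs the four exon copy-number columns plus ``n``;
    ratios are reported as percentages rounded to 2 decimals, matching how
    cohort tables are printed.
    """
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        rows = [
            {c: getattr(p, c) for c in _GENOTYPE_COLS} for p in data
        ]
        if rows:
            df = (
                pd.DataFrame(rows)
                .value_counts()
                .rename("n")
                .reset_index()
                .sort_values(_GENOTYPE_COLS)
                .reset_index(drop=True)
            )
        else:
            df = pd.DataFrame(columns=_GENOTYPE_COLS + ["n"])

    total = int(df["n"].sum()) if len(df) else 0

    def pct(count: int) -> float:
        return round(100.0 * count / total, 2) if total else 0.0

    df["ratio_pct"] = [pct(int(n)) for n in df["n"]] if len(df) else []

    def marginals(col: str) -> dict[int, tuple[int, float]]:
        out = {}
        if not len(df):
            return out
        for copies, count in df.groupby(col)["n"].sum().items():
            out[int(copies)] = (int(count), pct(int(count)))
        return out

    carriers = int(df.loc[df["smn1_e7"] == 1, "n"].sum()) if len(df) else 0
    conv = (
        int(df.loc[(df["smn1_e7"] == 1) & (df["smn2_e7"] >= 3), "n"].sum())
        if len(df)
        else 0
    )
    dele = carriers - conv
    smn2_zero = int(df.loc[df["smn2_e7"] == 0, "n"].sum()) if len(df) else 0

    prevalence = f"1/{round(total / carriers)}" if carriers else "0"
    return CohortTally(
        table=df,
        total_n=total,
        smn1_e7_marginals=marginals("smn1_e7"),
        smn2_e7_marginals=marginals("smn2_e7"),
        carrier_count=carriers,
        carrier_rate_pct=pct(carriers),
        carrier_prevalence=prevalence,
        deletion_carriers=(dele, pct(dele)),
        conversion_carriers=(conv, pct(conv)),
        smn2_homozygous_deletions=(smn2_zero, pct(smn2_zero)),
    )


def classify_discrepancy(
    mlpa: AssayResult,
    qpcr: AssayResult,
    truth: SampleSmnProfile | int,
    sample_id: str = "",
) -> DiscrepancyRecord:
    """Compare MLPA and qPCR SMN1 exon-7 calls against the long-read truth."""
    for result in (mlpa, qpcr):
        if result.smn1_e7 is None:
            raise ValueError("missing SMN1 exon-7 call")
    t = truth.smn1_e7 if isinstance(truth, SampleSmnProfile) else int(truth)
    m, q = mlpa.smn1_e7, qpcr.smn1_e7
    m_flag = mlpa.flags.get("smn1_e7")
    q_flag = qpcr.flags.get("smn1_e7")
    any_flags = bool(mlpa.flags) or bool(qpcr.flags)

    if q < t and t == 2:
        klass = "qpcr_fp_het_deletion"
    elif m < t and t >= 3:
        klass = "mlpa_fn_duplication"
    elif q < t and t >= 3:
        klass = "qpcr_fn_duplication" if not q_flag else "gray_zone_only"
    elif m == t and q == t:
        klass = "concordant" if not any_flags else "gray_zone_only"
    else:
        # remaining disagreement patterns (overcalls) are near-threshold noise
        klass = "gray_zone_only"

    gray_flags = {}
    if m_flag:
        gray_flags["mlpa_smn1_e7"] = m_flag
    if q_flag:
        gray_flags["qpcr_smn1_e7"] = q_flag
    return DiscrepancyRecord(
        sample_id=sample_id,
        mlpa_smn1_e7=m,
        qpcr_smn1_e7=q,
        truth_smn1_e7=t,
        klass=klass,
        gray_flags=gray_flags,
    )


def write_tally(tally: CohortTally, path) -> None:
    with open(path, "w") as fh:
        fh.write("# total_n\t%d\n" % tally.total_n)
        fh.write(
            "# carriers\t%d\trate\t%.2f%%\tprevalence\t%s\n"
            % (tally.carrier_count, tally.carrier_rate_pct, tally.carrier_prevalence)
        )
        fh.write(
            "# mechanism\tdeletion\t%d\t%.2f%%\tconversion\t%d\t%.2f%%\n"
            % (*tally.deletion_carriers, *tally.conversion_carriers)
        )
        fh.write(
            "# smn2_homozygous_deletion\t%d\t%.2f%%\n"
            % tally.smn2_homozygous_deletions
        )
        tally.table.to_csv(fh, sep="\t", index=False)
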
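"""Somatic mutation I/O, artifact post-filters, and sample-level QC.

The recurrence analysis is extremely sensitive to recurrent calling
artifacts, so beyond the upstream caller's own filters we remove likely
germline leakage (population allele frequency), systematic sequencing errors
(panel-of-normals fraction), mapping errors near common indels, and indels in
long mononucleotide runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .intervals import IntervalSet

log = logging.getLogger(__name__)

SUBTYPES = ("EBV", "MSI", "CIN", "GS", "NA")


@dataclass
class MutationRecord:
    """One somatic call after normalization to 0-based coordinates."""

    sample_id: str
    chrom: str
    pos: int  # 0-based leftmost reference coordinate
    ref: str
    alt: str
    vaf: float | None = None
    population_af: float | None = None
    pon_fraction: float | None = None

    def __post_init__(self):
        if self.vaf is not None and not (0 <= self.vaf <= 1):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def mut_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


@dataclass
class CohortMetadata:
    """Per-sample subtype, signature-1/17 fractions, and purity."""

    subtype: dict[str, str]
    mutsig1: dict[str, float] = field(default_factory=dict)
    mutsig17: dict[str, float] = field(default_factory=dict)
    purity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for s, st in self.subtype.items():
            if st not in SUBTYPES:
                raise ValueError(f"sample {s}: unknown subtype {st!r}")
        for name, d in (("mutsig1", self.mutsig1), ("mutsig17", self.mutsig17), ("purity", self.purity)):
            for s, v in d.items():
                if not (0 <= v <= 1):
                    raise ValueError(f"sample {s}: {name}={v} outside [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "CohortMetadata":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        kw = {"subtype": dict(zip(df.sample_id, df.subtype))}
        for col in ("mutsig1", "mutsig17", "purity"):
            if col in df:
                kw[col] = dict(zip(df.sample_id, df[col].astype(float)))
        return cls(**kw)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "pop_af", "pon_frac"]


def _opt(v) -> float | None:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def read_mutations(
    path,
    format: str = "tsv",
    sample_id: str | None = None,
    af_key: str = "POP_AF",
    pon_key: str = "PON_FRAC",
    vaf_key: str = "VAF",
    known_contigs: Iterable[str] | None = None,
) -> list[MutationRecord]:
    """Read somatic calls from a VCF (per sample) or MAF-like TSV.

    VCF coordinates (1-based) are shifted to 0-based; multi-allelic records
    are split into one record per ALT allele. TSV positions are already
    0-based (column ``pos``).
    """
    contigs = set(known_contigs) if known_contigs is not None else None
    records: list[MutationRecord] = []
    if format == "vcf":
        import pysam

        if sample_id is None:
            raise ValueError("sample_id is required when reading a VCF")
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if contigs is not None and rec.chrom not in contigs:
                    raise ValueError(f"unknown contig {rec.chrom} at {rec.chrom}:{rec.pos}")
                for alt in rec.alts or ():
                    records.append(
                        MutationRecord(
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=rec.start,
                            ref=rec.ref,
                            alt=alt,
                            vaf=_opt(rec.info.get(vaf_key)),
                            population_af=_opt(rec.info.get(af_key)),
                            pon_fraction=_opt(rec.info.get(pon_key)),
                        )
                    )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
        missing = set(_TSV_COLUMNS[:5]) - set(df.columns)
        if missing:
            raise ValueError(f"TSV is missing required columns: {sorted(missing)}")
        for i, row in enumerate(df.itertuples(index=False)):
            if contigs is not None and row.chrom not in contigs:
                raise ValueError(f"line {i + 2}: unknown contig {row.chrom}")
            records.append(
                MutationRecord(
                    sample_id=row.sample_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    vaf=_opt(getattr(row, "vaf", None)),
                    population_af=_opt(getattr(row, "pop_af", None)),
                    pon_fraction=_opt(getattr(row, "pon_frac", None)),
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        warnings.warn(f"no mutation records read from {path}")
    return records


def write_mutations_tsv(muts: Sequence[MutationRecord], path) -> None:
    df = pd.DataFrame(
        [
            (m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.vaf, m.population_af, m.pon_fraction)
            for m in muts
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# artifact filters
# ---------------------------------------------------------------------------


def _has_homopolymer(genome: GenomeSequence, m: MutationRecord, min_len: int) -> bool:
    # inspect the reference covering the indel footprint expanded by 1 bp
    start = max(0, m.pos - 1)
    # long enough context that a run touching the site is fully visible
    end = min(genome.lengths[m.chrom], m.end + 1 + min_len)
    start = max(0, start - min_len)
    seq = genome.fetch(m.chrom, start, end)
    run_start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[run_start]:
            if i - run_start >= min_len and seq[run_start] in "ACGT":
                run_lo, run_hi = start + run_start, start + i
                # overlap with the expanded indel footprint
                if run_lo < m.end + 1 and run_hi > m.pos - 1:
                    return True
            run_start = i
    return False


def _distance_to_nearest(ivals: IntervalSet, chrom: str, start: int, end: int) -> float:
    """Edge-to-edge distance from [start, end) to the nearest interval."""
    arr = ivals.arrays(chrom)
    if not arr.size:
        return np.inf
    if np.any((arr[:, 0] < end) & (arr[:, 1] > start)):
        return 0.0
    left = arr[arr[:, 1] <= start]
    right = arr[arr[:, 0] >= end]
    d = np.inf
    if left.size:
        d = min(d, start - left[-1, 1] + 1)
    if right.size:
        d = min(d, right[0, 0] - end + 1)
    return float(d)


def filter_artifacts(
    muts: Sequence[MutationRecord],
    genome: GenomeSequence,
    common_indels: IntervalSet | None = None,
    af_cut: float = 0.01,
    pon_cut: float = 0.10,
    pon_near_indel_cut: float = 0.01,
    indel_window: int = 20,
    homopolymer_min: int = 8,
):
    """Apply the artifact post-filters; returns (kept, removed) where removed
    pairs each record with its rule id:

    1. population allele frequency > ``af_cut`` (likely germline);
    2. panel-of-normals fraction > ``pon_cut`` (systematic error);
    3. panel-of-normals fraction > ``pon_near_indel_cut`` and within
       ``indel_window`` bp (edge-to-edge) of a common indel;
    4. indel overlapping a reference mononucleotide run >= ``homopolymer_min`` bp.

    Missing annotations are treated as 0 (pass).
    """
    common_indels = common_indels or IntervalSet()
    kept, removed = [], []
    for m in muts:
        af = m.population_af or 0.0
        pon = m.pon_fraction or 0.0
        if af > af_cut:
            removed.append((m, "pop_af"))
        elif pon > pon_cut:
            removed.append((m, "pon"))
        elif pon > pon_near_indel_cut and _distance_to_nearest(
            common_indels, m.chrom, m.pos, m.end
        ) <= indel_window:
            removed.append((m, "pon_near_indel"))
        elif m.mut_class == "indel" and _has_homopolymer(genome, m, homopolymer_min):
            removed.append((m, "homopolymer"))
        else:
            kept.append(m)
    return kept, removed


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

_PYRIMIDINE_CA = {("C", "A"), ("G", "T")}  # pyrimidine-strand C>A


def c_to_a_fraction(muts: Sequence[MutationRecord]) -> float:
    """Fraction of SNVs that are C>A after pyrimidine-strand normalization."""
    snvs = [m for m in muts if m.mut_class == "SNV"]
    if not snvs:
        return 0.0
    n_ca = sum((m.ref, m.alt) in _PYRIMIDINE_CA for m in snvs)
    return n_ca / len(snvs)


def sample_qc(
    muts_by_sample: Mapping[str, Sequence[MutationRecord]],
    min_calls: int = 400,
    oxidative_check: bool = True,
    oxidative_sd: float = 3.0,
):
    """Exclude low-count samples and oxidative-damage outliers.

    Samples with fewer than ``min_calls`` calls are excluded. If
    ``oxidative_check``, samples whose pyrimidine-strand C>A fraction exceeds
    the cohort mean + ``oxidative_sd`` * SD are excluded (skipped with a
    warning for cohorts of < 3 samples).
    """
    kept, excluded = [], []
    survivors = {}
    for s, mm in muts_by_sample.items():
        if len(mm) < min_calls:
            excluded.append((s, "low_count"))
        else:
            survivors[s] = mm
    if oxidative_check:
        if len(survivors) < 3:
            warnings.warn("fewer than 3 samples; oxidative C>A check skipped")
        else:
            fracs = {s: c_to_a_fraction(mm) for s, mm in survivors.items()}
            vals = np.array(list(fracs.values()))
            cut = vals.mean() + oxidative_sd * vals.std(ddof=1)
            for s in list(survivors):
                if fracs[s] > cut:
                    excluded.append((s, "oxidative_ca"))
                    del survivors[s]
    kept = sorted(survivors)
    return kept, excluded
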
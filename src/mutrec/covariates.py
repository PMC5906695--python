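"""Per-site covariate construction.

Continuous epigenomic tracks are consumed as interval/value pairs (bedGraph
semantics). For model fitting they are reduced to categorical form: binary
(signal present at the chosen significance cutoff), or ordinal via
equal-genomic-occupancy quantile bins. Sequence context is encoded as
reverse-complement-canonical 1/3/5-mers plus flank motifs, and poly-run flags
for the indel model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import GenomeSequence, MaskedGenome, revcomp
from .intervals import IntervalSet

log = logging.getLogger(__name__)


@dataclass
class CovariateTrack:
    """A named genomic track stored as per-chromosome (starts, ends, values)."""

    name: str
    kind: str  # {"binary", "ordinal", "continuous"}
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    n_levels: int | None = None
    bin_edges: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"unknown track kind {self.kind!r}")

    @classmethod
    def from_records(cls, name, kind, records, **kw) -> "CovariateTrack":
        """records: iterable of (chrom, start, end, value)."""
        by_chrom: dict[str, list] = {}
        for chrom, s, e, v in records:
            by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=float)
            data[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(name=name, kind=kind, data=data, **kw)

    @classmethod
    def from_bedgraph(cls, path, name=None, kind="continuous") -> "CovariateTrack":
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                c, s, e, v = line.split("\t")[:4]
                recs.append((c, int(s), int(e), float(v)))
        return cls.from_records(name or str(path), kind, recs)

    def iter_records(self):
        for chrom, (s, e, v) in sorted(self.data.items()):
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Track value at each position; NaN where the track has no record."""
        positions = np.asarray(positions)
        out = np.full(positions.shape, np.nan)
        if chrom not in self.data:
            return out
        starts, ends, vals = self.data[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = vals[idx[ok]]
        return out

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Missing-aware arithmetic mean of per-base values over [start, end)."""
        vals = self.values_at(chrom, np.arange(start, end))
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else np.nan

    def transform(self, fn, kind=None, **kw) -> "CovariateTrack":
        data = {c: (s.copy(), e.copy(), fn(v)) for c, (s, e, v) in self.data.items()}
        return CovariateTrack(name=self.name, kind=kind or self.kind, data=data, **kw)


def binarize_track(track: CovariateTrack, cutoff: float = 1e-4, scale: str = "neglog10") -> CovariateTrack:
    """Binarize a p-value signal track at a significance cutoff.

    ``scale="neglog10"`` treats values as -log10 p (signal >= -log10(cutoff)
    maps to 1); ``scale="raw"`` treats them as raw p-values (value <= cutoff
    maps to 1).
    """
    if scale == "neglog10":
        thr = -np.log10(cutoff)

        def fn(v):
            if np.any(v < 0):
                raise ValueError(f"track {track.name}: negative -log10 values")
            return (v >= thr).astype(float)

    elif scale == "raw":
        def fn(v):
            return (v <= cutoff).astype(float)

    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = track.transform(fn, kind="binary")
    out.n_levels = 2
    return out


def discretize_track(track: CovariateTrack, n_bins: int) -> CovariateTrack:
    """Quantile-bin a continuous track into equal-genomic-occupancy levels.

    Bin edges are bp-weighted quantiles, so each level covers approximately
    total_bp / n_bins bases. Level 0 holds the lowest values. Heavy ties can
    collapse edges; the result then has fewer levels (warned).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.concatenate([v for (_, _, v) in track.data.values()])
    weights = np.concatenate([(e - s) for (s, e, _) in track.data.values()]).astype(float)
    order = np.argsort(vals, kind="stable")
    vals_s, w_s = vals[order], weights[order]
    cum = np.cumsum(w_s) / w_s.sum()
    qs = np.arange(1, n_bins) / n_bins
    edges = np.unique(vals_s[np.searchsorted(cum, qs, side="left")])
    # values <= edge fall in the lower bin
    out = track.transform(
        lambda v: np.searchsorted(edges, v, side="left").astype(float), kind="ordinal"
    )
    observed = np.unique(np.concatenate([v for (_, _, v) in out.data.values()]))
    remap = {lev: i for i, lev in enumerate(observed)}
    out = out.transform(
        lambda v: np.vectorize(remap.get)(v).astype(float), kind="ordinal"
    )
    out.n_levels = len(observed)
    out.bin_edges = edges
    if out.n_levels < n_bins:
        warnings.warn(
            f"track {track.name}: ties reduce {n_bins} requested bins to {out.n_levels}"
        )
    return out


def local_mutation_rate(
    muts: Sequence,
    masked: MaskedGenome,
    bin_bp: int = 100_000,
) -> CovariateTrack:
    """Cohort mutation rate per analyzable bp in non-overlapping genomic bins.

    Bins with zero analyzable bases carry NaN and are excluded downstream.
    """
    counts: dict[tuple[str, int], int] = {}
    for m in muts:
        counts[(m.chrom, m.pos // bin_bp)] = counts.get((m.chrom, m.pos // bin_bp), 0) + 1
    recs = []
    for chrom, n in masked.genome.lengths.items():
        for b in range(0, n, bin_bp):
            end = min(n, b + bin_bp)
            denom = masked.analyzable.overlap_bp(chrom, b, end)
            rate = counts.get((chrom, b // bin_bp), 0) / denom if denom > 0 else np.nan
            recs.append((chrom, b, end, rate))
    return CovariateTrack.from_records("local_rate", "continuous", recs)


# ---------------------------------------------------------------------------
# sequence context
# ---------------------------------------------------------------------------


def canonical_kmer(kmer: str) -> str:
    """Collapse a k-mer with its reverse complement to the smaller key."""
    rc = revcomp(kmer)
    return min(kmer, rc)


@dataclass
class SiteFeatures:
    chrom: str
    pos: int
    context: dict[str, str]  # feature name -> canonical key (missing keys dropped)
    poly_run: dict[str, int] = field(default_factory=dict)  # {"polyAT": 0/1, "polyGC": 0/1}


def _poly_run_flags(genome: GenomeSequence, chrom: str, pos: int, end: int, min_run: int) -> dict[str, int]:
    lo = max(0, pos - min_run)
    hi = min(genome.lengths[chrom], end + min_run)
    seq = genome.fetch(chrom, lo, hi)
    flags = {"polyAT": 0, "polyGC": 0}
    run_start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[run_start]:
            if i - run_start >= min_run:
                run_lo, run_hi = lo + run_start, lo + i
                if run_lo < end and run_hi > pos:
                    base = seq[run_start]
                    if base in "AT":
                        flags["polyAT"] = 1
                    elif base in "GC":
                        flags["polyGC"] = 1
            run_start = i
    return flags


def context_features(
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    mut_class: str = "SNV",
    ref_len: int = 1,
    poly_run_min: int = 4,
) -> SiteFeatures | None:
    """Sequence-context features for one site.

    1/3/5-mers centered at the site are collapsed with their reverse
    complements; left/right 1-bp and 2-bp flank motifs are collapsed jointly
    as a strand pair (left+right concatenated vs its reverse complement).
    Sites near chromosome ends lose only the k-mer features that would run
    off the end. Returns None (site excluded) for a non-ACGT center base.
    """
    center = genome.fetch(chrom, pos, pos + 1, pad="N")
    if center not in "ACGT" or len(center) != 1:
        return None
    ctx: dict[str, str] = {}
    for k in (1, 3, 5):
        half = k // 2
        kmer = genome.fetch(chrom, pos - half, pos + half + 1, pad="N")
        if "N" not in kmer:
            ctx[f"kmer{k}"] = canonical_kmer(kmer)
    for w in (1, 2):
        left = genome.fetch(chrom, pos - w, pos, pad="N")
        right = genome.fetch(chrom, pos + 1, pos + 1 + w, pad="N")
        pair = left + "." + right
        if "N" not in left + right:
            # strand pair: flanks on the minus strand are revcomp(right).revcomp(left)
            alt = revcomp(right) + "." + revcomp(left)
            ctx[f"flank{w}"] = min(pair, alt)
    poly = {}
    if mut_class == "indel":
        poly = _poly_run_flags(genome, chrom, pos, pos + max(1, ref_len), poly_run_min)
    return SiteFeatures(chrom=chrom, pos=pos, context=ctx, poly_run=poly)


def lasso_feature_signal(
    tracks: Sequence[CovariateTrack],
    chrom: str,
    pos: int,
    lengths: Mapping[str, int],
    window_bp: int = 11,
) -> np.ndarray:
    """Mean continuous signal of each track over a window centered at the site.

    The window is clipped at chromosome bounds; a fully missing window yields
    NaN for that feature.
    """
    half = window_bp // 2
    start = max(0, pos - half)
    end = min(lengths[chrom], pos + half + 1)
    return np.array([t.mean_over(chrom, start, end) for t in tracks])
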
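"""Reference genome representation, masking, and region construction.

The analyzable genome is what remains after masking coding sequence,
immunoglobulin loci and poorly mappable regions; its base count is the
Bonferroni hypothesis universe for the focal-window scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, genome_intervals

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Per-chromosome nucleotide strings with unique names and known lengths."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self.sequences = {str(c): str(s).upper() for c, s in sequences.items()}
        for c, s in self.sequences.items():
            if len(s) == 0:
                raise ValueError(f"chromosome {c} has zero length")
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {c} contains non-ACGTN characters: {sorted(bad)}")
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for c, s in self.sequences.items():
                fh.write(f">{c}\n")
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start: int, end: int, pad: str = "") -> str:
        """Sequence of [start, end); optionally pad out-of-bounds bases with `pad`."""
        n = self.lengths[chrom]
        s, e = max(0, start), min(n, end)
        seq = self.sequences[chrom][s:e]
        if pad:
            seq = pad * (s - start) + seq + pad * (end - e)
        return seq

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence({c: revcomp(s) for c, s in self.sequences.items()})


@dataclass
class MaskedGenome:
    """Reference plus the analyzable interval set defining the test universe."""

    genome: GenomeSequence
    analyzable: IntervalSet

    @property
    def n_test_bases(self) -> int:
        return self.analyzable.total_bp


def _check_bounds(ivals: IntervalSet, lengths: Mapping[str, int], label: str) -> None:
    for chrom, start, end in ivals:
        if chrom not in lengths:
            raise ValueError(f"{label} interval {chrom}:{start}-{end}: unknown chromosome")
        if end > lengths[chrom]:
            raise ValueError(
                f"{label} interval {chrom}:{start}-{end} extends beyond "
                f"chromosome end ({lengths[chrom]})"
            )


def build_masked_genome(
    genome: GenomeSequence,
    cds: IntervalSet | None = None,
    ig_loci: IntervalSet | None = None,
    low_mappability: IntervalSet | None = None,
) -> MaskedGenome:
    """Analyzable genome = whole genome minus CDS, Ig loci and low-mappability masks."""
    empty = IntervalSet()
    cds = cds or empty
    ig_loci = ig_loci or empty
    low_mappability = low_mappability or empty
    for label, ivals in (("CDS", cds), ("Ig", ig_loci), ("mappability", low_mappability)):
        _check_bounds(ivals, genome.lengths, label)
    mask = cds.union(ig_loci).union(low_mappability)
    analyzable = genome_intervals(genome.lengths).subtract(mask)
    return MaskedGenome(genome=genome, analyzable=analyzable)


@dataclass
class Window:
    """A candidate focal window with its member mutations."""

    chrom: str
    start: int
    end: int
    sample_ids: frozenset = field(default_factory=frozenset)
    positions: tuple = ()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def candidate_windows(mutations: Sequence, masked: MaskedGenome, flank: int = 10):
    """One window of width 2*flank+1 per distinct mutated position.

    Mutations outside the analyzable genome are dropped (counted via the
    returned ``n_rejected``). Indels anchor at their leftmost reference
    coordinate. Windows at chromosome ends are clipped.

    Returns (windows, n_rejected).
    """
    n_rejected = 0
    by_pos: dict[tuple[str, int], set] = {}
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for m in mutations:
        if not masked.analyzable.contains(m.chrom, m.pos):
            n_rejected += 1
            continue
        by_pos.setdefault((m.chrom, m.pos), set()).add(m.sample_id)
        by_chrom.setdefault(m.chrom, []).append((m.pos, m.sample_id))
    if n_rejected:
        warnings.warn(f"{n_rejected} mutations outside the analyzable genome were ignored")
    pos_arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos_arrays[chrom] = (
            np.array([p for p, _ in pairs], dtype=np.int64),
            [s for _, s in pairs],
        )

    # dedupe windows that share identical coordinates after clipping; window
    # membership covers every mutation inside the span, not just the anchor
    by_span: dict[tuple[str, int, int], list] = {}
    for (chrom, pos) in sorted(by_pos):
        n = masked.genome.lengths[chrom]
        start, end = max(0, pos - flank), min(n, pos + flank + 1)
        by_span.setdefault((chrom, start, end), []).append(pos)
    windows = []
    for (chrom, start, end), anchors in sorted(by_span.items()):
        positions, samples = pos_arrays[chrom]
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="left"))
        members = frozenset(samples[lo:hi])
        windows.append(
            Window(chrom=chrom, start=start, end=end, sample_ids=members,
                   positions=tuple(anchors))
        )
    return windows, n_rejected


def merge_significant(results: Sequence, alpha_adjusted: float = 0.01):
    """Merge overlapping significant windows into maximal hotspot intervals.

    Each merged hotspot reports the minimum constituent adjusted (and raw)
    p-value and the union of mutated samples. Non-significant windows are
    dropped. ``results`` are RecurrenceResult-like objects.
    """
    sig = [r for r in results if r.p_adjusted < alpha_adjusted]
    sig.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged = []
    for r in sig:
        if merged and merged[-1]["chrom"] == r.chrom and r.start < merged[-1]["end"]:
            h = merged[-1]
            h["end"] = max(h["end"], r.end)
            h["p_value"] = min(h["p_value"], r.p_value)
            h["p_adjusted"] = min(h["p_adjusted"], r.p_adjusted)
            h["sample_ids"] = h["sample_ids"] | set(r.sample_ids)
        else:
            merged.append(
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                    "sample_ids": set(r.sample_ids),
                }
            )
    for h in merged:
        h["k"] = len(h["sample_ids"])
    merged.sort(key=lambda h: (h["p_value"], h["chrom"], h["start"]))
    return merged


def gene_noncoding_regions(
    gene_models: pd.DataFrame,
    masked: MaskedGenome,
    promoter_ext: int = 1000,
) -> dict[str, IntervalSet]:
    """Per-gene merged non-coding regions.

    ``gene_models`` columns: gene_id, chrom, start, end plus a ``cds``
    column holding a list of (start, end) CDS blocks (may be empty).
    The gene span is extended by ``promoter_ext`` at both boundaries
    (clipped to the chromosome), CDS blocks and the genome mask are
    subtracted, and genes with no remaining bases are dropped.
    """
    regions: dict[str, IntervalSet] = {}
    for row in gene_models.itertuples(index=False):
        chrom = row.chrom
        n = masked.genome.lengths.get(chrom)
        if n is None:
            raise ValueError(f"gene {row.gene_id}: unknown chromosome {chrom}")
        start = max(0, int(row.start) - promoter_ext)
        end = min(n, int(row.end) + promoter_ext)
        span = IntervalSet([(chrom, start, end)])
        cds_blocks = list(getattr(row, "cds", []) or [])
        if cds_blocks:
            span = span.subtract(IntervalSet((chrom, s, e) for s, e in cds_blocks))
        span = span.intersect(masked.analyzable)
        if span.is_empty():
            log.info("gene %s has no analyzable non-coding bases; excluded", row.gene_id)
            continue
        regions[row.gene_id] = span
    return regions
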
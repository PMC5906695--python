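"""Downstream characterization statistics.

Everything that follows hotspot discovery: enrichment of hotspot mutations in
functional region classes, CBS/flank mutation-rate profiles by tumor subtype,
motif-oriented substitution spectra, PCA of feature/mutation-rate
correlations, SCNA breakpoint coupling, VAF clonality comparison, TAD-scoped
expression association, and pluggable motif gain/loss calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSequence, revcomp
from .intervals import IntervalSet

log = logging.getLogger(__name__)

DIPLOID_LOWER = float(np.log2(1.5 / 2))  # ~ -0.415, assuming 50% tumor purity
DIPLOID_UPPER = float(np.log2(2.5 / 2))  # ~ +0.322


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    p1: float  # observed mutation fraction in the region class
    p2: float  # expected fraction = the class's bp share of the genome
    lod: float
    se_lod: float
    z: float
    p_value: float


def lod_enrichment(
    muts_in_class: int, total_muts: int, class_bp: int, genome_bp: int
) -> EnrichmentResult:
    """Log odds ratio of mutation enrichment in a region class.

    LOD = ln[(p1/(1-p1)) / (p2/(1-p2))] with p1 the observed fraction of
    mutations in the class and p2 the class's share of genome bases. The SE is
    the delta-method propagation of the binomial SE of p1 (p2 is a fixed bp
    share); significance is a two-sided Z-test. Zero cells get a +0.5
    continuity correction.
    """
    if total_muts <= 0 or genome_bp <= 0 or class_bp <= 0 or class_bp >= genome_bp:
        raise ValueError("counts must be positive and class_bp strictly inside the genome")
    k = muts_in_class
    n = total_muts
    if k == 0 or k == n:
        k, n = k + 0.5, n + 1.0
    p1 = k / n
    p2 = class_bp / genome_bp
    lod = float(np.log(p1 / (1 - p1)) - np.log(p2 / (1 - p2)))
    se_p1 = np.sqrt(p1 * (1 - p1) / n)
    se = float(se_p1 / (p1 * (1 - p1)))
    z = lod / se
    p = float(2 * stats.norm.sf(abs(z)))
    return EnrichmentResult(p1=float(p1), p2=float(p2), lod=lod, se_lod=se, z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# CBS rate profile
# ---------------------------------------------------------------------------


def cbs_rate_profile(
    muts: Sequence,
    cbs_sites: Sequence,
    lengths: Mapping[str, int],
    samples: Sequence[str],
    flank_bp: int = 1000,
    group_by: Mapping[str, str] | None = None,
    profile_halfwidth: int = 0,
) -> pd.DataFrame:
    """Mutation rates (mutations/Mb/tumor) inside CBS intervals and their
    flanking regions, per sample group, plus the CBS/flank fold ratio.

    Flank regions are the +/- ``flank_bp`` extensions of each CBS with every
    CBS base excluded, so the two region sets are disjoint. Rates are pooled
    within a group: total mutation count / (region bp * group size) * 1e6.
    """
    if not cbs_sites:
        raise ValueError("CBS set is empty")
    cbs_iv = IntervalSet((s.chrom, s.start, s.end) for s in cbs_sites)
    ext = IntervalSet(
        (s.chrom, max(0, s.start - flank_bp), min(lengths[s.chrom], s.end + flank_bp))
        for s in cbs_sites
    )
    flank_iv = ext.subtract(cbs_iv)
    groups = group_by or {s: "all" for s in samples}
    counts: dict[tuple[str, str], int] = {}
    for m in muts:
        g = groups.get(m.sample_id)
        if g is None:
            continue
        if cbs_iv.contains(m.chrom, m.pos):
            where = "cbs"
        elif flank_iv.contains(m.chrom, m.pos):
            where = "flank"
        else:
            continue
        counts[(g, where)] = counts.get((g, where), 0) + 1
    sizes: dict[str, int] = {}
    for s in samples:
        g = groups.get(s)
        if g is not None:
            sizes[g] = sizes.get(g, 0) + 1
    rows = []
    for g, n_g in sorted(sizes.items()):
        cbs_rate = counts.get((g, "cbs"), 0) / (cbs_iv.total_bp * n_g) * 1e6
        flank_rate = counts.get((g, "flank"), 0) / (flank_iv.total_bp * n_g) * 1e6
        if flank_rate == 0:
            warnings.warn(f"group {g}: zero flank mutations; fold ratio is infinite")
            fold = np.inf
        else:
            fold = cbs_rate / flank_rate
        rows.append(
            {
                "group": g,
                "n_samples": n_g,
                "cbs_bp": cbs_iv.total_bp,
                "flank_bp": flank_iv.total_bp,
                "cbs_rate_per_mb": cbs_rate,
                "flank_rate_per_mb": flank_rate,
                "fold": fold,
            }
        )
    return pd.DataFrame(rows)


def cbs_position_profile(muts: Sequence, cbs_sites: Sequence, halfwidth: int = 1000) -> pd.Series:
    """Mutation counts by signed distance from the CBS midpoint (motif strand)."""
    mids = {}
    for s in cbs_sites:
        mids.setdefault(s.chrom, []).append((s.start + (s.end - s.start) // 2, s.strand))
    for v in mids.values():
        v.sort()
    counts = pd.Series(0, index=np.arange(-halfwidth, halfwidth + 1))
    for m in muts:
        sites = mids.get(m.chrom)
        if not sites:
            continue
        arr = np.array([p for p, _ in sites])
        i = int(np.argmin(np.abs(arr - m.pos)))
        d = m.pos - arr[i]
        if sites[i][1] == "-":
            d = -d
        if -halfwidth <= d <= halfwidth:
            counts[d] += 1
    return counts


# ---------------------------------------------------------------------------
# motif-oriented substitution spectrum
# ---------------------------------------------------------------------------


def motif_spectrum(muts: Sequence, motif_hits: Sequence, flank: int = 5) -> pd.DataFrame:
    """Position x substitution counts, oriented to the motif strand.

    Positions run from -flank to motif_length-1+flank relative to the motif 5'
    end on its own strand; a genomic A>C inside a minus-strand motif is
    reported as T>G at the mirrored position. Mutations outside motif+flank
    are ignored.
    """
    if not motif_hits:
        raise ValueError("no motif hits supplied")
    L = motif_hits[0].end - motif_hits[0].start
    positions = np.arange(-flank, L + flank)
    subs = [f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a]
    mat = pd.DataFrame(0, index=positions, columns=subs)
    by_chrom: dict[str, list] = {}
    for h in motif_hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    for m in muts:
        if m.mut_class != "SNV":
            continue
        for h in by_chrom.get(m.chrom, []):
            if h.start - flank <= m.pos < h.end + flank:
                if h.strand == "+":
                    rel = m.pos - h.start
                    ref, alt = m.ref, m.alt
                else:
                    rel = (h.end - 1) - m.pos
                    ref, alt = revcomp(m.ref), revcomp(m.alt)
                mat.loc[rel, f"{ref}>{alt}"] += 1
                break
    return mat


# ---------------------------------------------------------------------------
# PCA of feature/mutation-rate correlations
# ---------------------------------------------------------------------------


def window_rate_matrix(
    muts: Sequence,
    masked,
    tracks: Sequence,
    window_bp: int = 1_000_000,
    min_analyzable_bp: int = 250_000,
):
    """Per-tumor mutation rates and mean feature signals over genomic windows.

    Windows with fewer than ``min_analyzable_bp`` analyzable bases after
    masking are removed. Returns (rates windows x tumors, features windows x
    tracks) ready for :func:`pca_feature_contributions`.
    """
    samples = sorted({m.sample_id for m in muts})
    counts: dict[tuple, dict] = {}
    for m in muts:
        key = (m.chrom, m.pos // window_bp)
        counts.setdefault(key, {}).setdefault(m.sample_id, 0)
        counts[key][m.sample_id] += 1
    rate_rows, feat_rows, index = [], [], []
    for chrom, n in masked.genome.lengths.items():
        for b0 in range(0, n, window_bp):
            b1 = min(n, b0 + window_bp)
            bp = masked.analyzable.overlap_bp(chrom, b0, b1)
            if bp < min_analyzable_bp:
                continue
            key = (chrom, b0 // window_bp)
            rate_rows.append(
                [counts.get(key, {}).get(s, 0) / bp * 1e6 for s in samples]
            )
            feat_rows.append([t.mean_over(chrom, b0, b1) for t in tracks])
            index.append(f"{chrom}:{b0}-{b1}")
    rates = pd.DataFrame(rate_rows, index=index, columns=samples)
    features = pd.DataFrame(feat_rows, index=index, columns=[t.name for t in tracks])
    return rates, features


@dataclass
class PcaContributions:
    correlations: pd.DataFrame  # tumors x features
    loadings: pd.DataFrame  # features x PCs
    contributions: pd.DataFrame  # features x PCs (loading / sum of loadings)
    explained_variance_ratio: np.ndarray


def pca_feature_contributions(
    rates: pd.DataFrame, features: pd.DataFrame, n_components: int | None = None
) -> PcaContributions:
    """PCA of the Pearson correlation matrix between per-tumor mutation rates
    and feature signals across qualifying genomic windows.

    ``rates``: windows x tumors; ``features``: windows x features (same
    index). Constant features are dropped with a warning. Contributions are
    each feature's loading divided by the sum of loadings for that component
    (reported as NaN when the sum is near zero, where the ratio is unstable).
    """
    if rates.shape[1] < 2 or features.shape[1] < 2:
        raise ValueError("need at least 2 tumors and 2 features")
    keep = features.columns[features.std(ddof=0) > 0]
    dropped = set(features.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant features dropped: {sorted(dropped)}")
    features = features[keep]
    corr = pd.DataFrame(
        np.corrcoef(rates.T.to_numpy(), features.T.to_numpy())[
            : rates.shape[1], rates.shape[1] :
        ],
        index=rates.columns,
        columns=features.columns,
    )
    X = corr.to_numpy()
    Xc = X - X.mean(axis=0, keepdims=True)  # prcomp default: center, no scale
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or len(S)
    pcs = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(Vt[:k].T, index=features.columns, columns=pcs)
    sums = loadings.sum(axis=0)
    contributions = loadings / sums
    contributions.loc[:, np.abs(sums) < 1e-8] = np.nan
    evr = (S**2) / np.sum(S**2)
    return PcaContributions(
        correlations=corr,
        loadings=loadings,
        contributions=contributions,
        explained_variance_ratio=evr[:k],
    )


# ---------------------------------------------------------------------------
# SCNA breakpoints
# ---------------------------------------------------------------------------


@dataclass
class SegmentRecord:
    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float


def scna_breakpoints(
    segments: Sequence[SegmentRecord],
    lower: float = DIPLOID_LOWER,
    upper: float = DIPLOID_UPPER,
    include_terminal: bool = True,
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Breakpoint positions = both ends of every non-diploid segment.

    A segment is non-diploid iff its tumor/normal log2 coverage ratio falls
    outside (lower, upper). Chromosome-terminal ends are included by default;
    pass ``include_terminal=False`` with ``lengths`` to drop them.
    """
    rows = []
    for seg in segments:
        if not np.isfinite(seg.log2_ratio):
            raise ValueError("log2_ratio must be finite")
        if lower < seg.log2_ratio < upper:
            continue
        for pos in (seg.start, seg.end):
            if not include_terminal and lengths is not None:
                if pos == 0 or pos == lengths.get(seg.chrom):
                    continue
            rows.append({"sample_id": seg.sample_id, "chrom": seg.chrom, "pos": pos})
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos"])


def _nearest_breakpoint_distance(
    breakpoints: pd.DataFrame, sample: str, chrom: str, pos: int
) -> float:
    sel = breakpoints[(breakpoints.sample_id == sample) & (breakpoints.chrom == chrom)]
    if sel.empty:
        return np.inf
    return float(np.abs(sel.pos.to_numpy() - pos).min())


def breakpoint_distance_test(
    sites_a: Sequence[tuple[str, str, int]],
    sites_b: Sequence[tuple[str, str, int]],
    breakpoints: pd.DataFrame,
):
    """Nearest same-sample breakpoint distance for two site sets, compared by
    a two-sided Wilcoxon rank-sum test.

    Sites are (sample_id, chrom, pos); a site with no same-chromosome
    breakpoint in its sample gets +inf (ranked last). Returns
    (distances_a, distances_b, statistic, p_value).
    """
    if not sites_a or not sites_b:
        raise ValueError("both site sets must be non-empty")
    da = np.array([_nearest_breakpoint_distance(breakpoints, *s) for s in sites_a])
    db = np.array([_nearest_breakpoint_distance(breakpoints, *s) for s in sites_b])
    if np.array_equal(np.sort(da), np.sort(db)):
        return da, db, np.nan, 1.0
    stat, p = stats.mannwhitneyu(da, db, alternative="two-sided")
    return da, db, float(stat), float(p)


def breakpoint_density_rate(
    muts: Sequence,
    breakpoints: pd.DataFrame,
    rate_model,
    masked,
    bin_bp: int = 1_000_000,
    group_edges: Sequence[int] = (1, 3),
) -> pd.DataFrame:
    """Observed and background-normalized mutation rates vs breakpoint density.

    The genome is tiled into ``bin_bp`` bins; each bin's expected count is the
    sum of per-base background probabilities over patients, the observed count
    is the cohort mutation count, and bins are grouped by their total SCNA
    breakpoint count at the ``group_edges`` cut points. Bins with zero
    expectation are dropped.
    """
    from .recurrence import region_probability  # noqa: F401  (shared conventions)

    obs: dict[tuple[str, int], int] = {}
    for m in muts:
        key = (m.chrom, m.pos // bin_bp)
        obs[key] = obs.get(key, 0) + 1
    bp_count: dict[tuple[str, int], int] = {}
    for row in breakpoints.itertuples(index=False):
        key = (row.chrom, int(row.pos) // bin_bp)
        bp_count[key] = bp_count.get(key, 0) + 1
    rows = []
    for chrom, n in masked.genome.lengths.items():
        for b0 in range(0, n, bin_bp):
            b1 = min(n, b0 + bin_bp)
            region = IntervalSet([(chrom, b0, b1)]).intersect(masked.analyzable)
            if region.is_empty():
                continue
            expected = 0.0
            for c2, s, e in region:
                positions = np.arange(s, e)
                if hasattr(rate_model, "q_matrix"):
                    expected += float(rate_model.q_matrix(c2, positions).sum())
                else:
                    for pat in rate_model.patients:
                        expected += float(np.sum(rate_model.q(pat, c2, positions)))
            if expected <= 0:
                continue
            key = (chrom, b0 // bin_bp)
            rows.append(
                {
                    "chrom": chrom,
                    "start": b0,
                    "end": b1,
                    "n_breakpoints": bp_count.get(key, 0),
                    "observed": obs.get(key, 0),
                    "expected": expected,
                }
            )
    bins = pd.DataFrame(rows)
    edges = [0, *group_edges, np.inf]
    labels = [f"[{edges[i]},{edges[i+1]})" for i in range(len(edges) - 1)]
    bins["density_group"] = pd.cut(
        bins.n_breakpoints, bins=edges, labels=labels, right=False
    )
    grouped = (
        bins.groupby("density_group", observed=True)[["observed", "expected"]]
        .sum()
        .reset_index()
    )
    grouped["normalized"] = grouped.observed / grouped.expected
    return grouped


# ---------------------------------------------------------------------------
# VAF clonality
# ---------------------------------------------------------------------------


def vaf_compare(
    hotspot_muts: Sequence,
    driver_muts: Sequence,
    diploid_regions: Mapping[str, IntervalSet],
):
    """Paired (signed-rank) comparison of per-sample median VAFs between
    hotspot mutations and driver-gene coding mutations from the same samples.

    Only mutations falling in each sample's diploid regions enter; samples
    need at least one qualifying mutation in both sets to form a pair.
    Returns (pairs DataFrame, statistic, p_value).
    """

    def _sample_medians(muts):
        vals: dict[str, list[float]] = {}
        for m in muts:
            if m.vaf is None:
                continue
            dip = diploid_regions.get(m.sample_id)
            if dip is None or not dip.contains(m.chrom, m.pos):
                continue
            vals.setdefault(m.sample_id, []).append(m.vaf)
        return {s: float(np.median(v)) for s, v in vals.items()}

    med_h = _sample_medians(hotspot_muts)
    med_d = _sample_medians(driver_muts)
    shared = sorted(set(med_h) & set(med_d))
    if not shared:
        raise ValueError("no samples with both hotspot and driver mutations in diploid regions")
    pairs = pd.DataFrame(
        {"sample_id": shared, "hotspot_vaf": [med_h[s] for s in shared],
         "driver_vaf": [med_d[s] for s in shared]}
    )
    diffs = pairs.hotspot_vaf - pairs.driver_vaf
    if np.allclose(diffs, 0):
        return pairs, np.nan, 1.0
    stat, p = stats.wilcoxon(pairs.hotspot_vaf, pairs.driver_vaf, alternative="two-sided")
    return pairs, float(stat), float(p)


# ---------------------------------------------------------------------------
# TAD-scoped expression association
# ---------------------------------------------------------------------------


def expression_association(
    mutated_samples: set[str],
    expression: pd.DataFrame,
    tads,
    gene_locations: pd.DataFrame,
    hotspot: tuple[str, int],
    min_mutated: int = 3,
    min_expressed_count: float = 10.0,
) -> pd.DataFrame:
    """Per-gene mutated-vs-wildtype expression test within the two TADs
    adjacent to the hotspot's nearest TAD boundary.

    ``tads`` is an iterable of (chrom, start, end); adjacent TADs are kept
    distinct (they are a partition, not a mask). ``expression``: genes x
    samples normalized counts. Genes below ``min_expressed_count`` in every
    sample are flagged non-expressed and excluded from testing; p-values are
    two-sided Wilcoxon rank-sum, BH adjusted within the tested region.
    """
    chrom, pos = hotspot
    spans = sorted((s, e) for c, s, e in tads if c == chrom)
    arr = np.asarray(spans, dtype=np.int64).reshape(-1, 2)
    if not arr.size:
        raise ValueError(f"hotspot {chrom}:{pos} lies outside every TAD")
    idx = None
    for i, (s, e) in enumerate(arr):
        if s <= pos < e:
            idx = i
            break
    if idx is None:
        raise ValueError(f"hotspot {chrom}:{pos} lies outside every TAD")
    s, e = arr[idx]
    # nearest flanking boundary, then the TAD across it
    neighbor = None
    if pos - s <= e - pos and idx > 0:
        neighbor = idx - 1
    elif idx + 1 < len(arr):
        neighbor = idx + 1
    elif idx > 0:
        neighbor = idx - 1
    spans = [tuple(arr[idx])] + ([tuple(arr[neighbor])] if neighbor is not None else [])
    region = IntervalSet((chrom, int(a), int(b)) for a, b in spans)
    genes = gene_locations[
        gene_locations.apply(
            lambda g: g.chrom == chrom and region.overlaps(g.chrom, g.start, g.end), axis=1
        )
    ].gene_id.tolist()
    genes = [g for g in genes if g in expression.index]
    samples = list(expression.columns)
    mut = [s2 for s2 in samples if s2 in mutated_samples]
    wt = [s2 for s2 in samples if s2 not in mutated_samples]
    if len(mut) < min_mutated:
        raise ValueError(
            f"only {len(mut)} mutated samples with expression data (need >= {min_mutated})"
        )
    rows = []
    for g in genes:
        vals = expression.loc[g]
        expressed = bool((vals >= min_expressed_count).any())
        if not expressed:
            rows.append({"gene_id": g, "expressed": False, "p_value": np.nan,
                         "log2_fold": np.nan})
            continue
        a, b = vals[mut].to_numpy(float), vals[wt].to_numpy(float)
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        lfc = float(np.log2((np.median(a) + 0.5) / (np.median(b) + 0.5)))
        rows.append({"gene_id": g, "expressed": True, "p_value": float(p), "log2_fold": lfc})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    tested = out.expressed & out.p_value.notna()
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        out.loc[tested, "p_adjusted"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# motif gain/loss calls
# ---------------------------------------------------------------------------


def motif_gain_loss(
    mutations: Sequence,
    scorer: Callable[[str], float],
    genome: GenomeSequence,
    background_muts: Sequence,
    context_bp: int = 40,
    percentile: float = 0.999,
) -> pd.DataFrame:
    """Empirical-threshold motif disruption/creation calls for one TF scorer.

    The scorer's background distribution is estimated on randomly sampled
    non-hotspot mutations: a mutation is motif-disrupting when its reference
    sequence scores above the ``percentile`` of background reference scores
    AND its alt-ref score difference is below the (1 - percentile) background
    quantile; motif-creating symmetrically on alt scores and high deltas.
    Scorer failures skip the mutation (logged).
    """

    def _seqs(m):
        start = max(0, m.pos - context_bp)
        end = min(genome.lengths[m.chrom], m.end + context_bp)
        ref_seq = genome.fetch(m.chrom, start, end)
        offset = m.pos - start
        alt_seq = ref_seq[:offset] + m.alt + ref_seq[offset + len(m.ref):]
        return ref_seq, alt_seq

    def _score_rows(muts):
        rows = []
        for m in muts:
            try:
                ref_seq, alt_seq = _seqs(m)
                r, a = scorer(ref_seq), scorer(alt_seq)
            except Exception as exc:  # scorer is pluggable; tolerate failures
                log.warning("scorer failed at %s:%d (%s); mutation skipped", m.chrom, m.pos, exc)
                continue
            rows.append((m, r, a, a - r))
        return rows

    bg = _score_rows(background_muts)
    if len(bg) < 2:
        raise ValueError("background sample too small after scoring failures")
    bg_ref = np.array([r for _, r, _, _ in bg])
    bg_alt = np.array([a for _, _, a, _ in bg])
    bg_delta = np.array([d for _, _, _, d in bg])
    ref_hi = np.quantile(bg_ref, percentile)
    alt_hi = np.quantile(bg_alt, percentile)
    delta_lo = np.quantile(bg_delta, 1 - percentile)
    delta_hi = np.quantile(bg_delta, percentile)
    rows = []
    for m, r, a, d in _score_rows(mutations):
        disrupt = bool(r > ref_hi and d < delta_lo)
        create = bool(a > alt_hi and d > delta_hi)
        call = "disrupting" if disrupt else ("creating" if create else "none")
        rows.append(
            {"sample_id": m.sample_id, "chrom": m.chrom, "pos": m.pos,
             "ref_score": r, "alt_score": a, "delta": d, "call": call}
        )
    return pd.DataFrame(rows)


def signature_cbs_correlation(
    cbs_fraction: Mapping[str, float], signatures: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation between per-tumor CBS mutation fraction and each
    signature's per-tumor contribution; zero-variance signatures are skipped."""
    samples = [s for s in signatures.index if s in cbs_fraction]
    if len(samples) < 3:
        raise ValueError("need at least 3 tumors")
    y = np.array([cbs_fraction[s] for s in samples])
    rows = []
    for sig in signatures.columns:
        x = signatures.loc[samples, sig].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.info("signature %s has zero variance; skipped", sig)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"signature": sig, "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
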
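"""Synthetic tumor cohorts with known ground truth.

Cohorts are generated under exactly the likelihood the inference assumes:
mutations are independent Bernoulli draws per (base, patient) with
``q = logit^-1(b0 + b_patient + sum(beta * x))``, optionally multiplied inside
planted hotspot windows, CTCF binding sites (CBSs), and transcription-factor
binding site (TFBS) intervals. Shipped presets encode the cohort-level rate
structure the method is designed to detect: a genome-wide CBS rate elevation
with subtype-specific folds, TFBS mutation depletion, focal recurrent
hotspots, and CBSs under positive selection beyond the CBS-wide elevation.

Counts are sampled per (patient, constant-rate segment) as binomials with
uniform placement, which is distributionally identical to per-base Bernoulli
sampling but scales to tens of megabases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .covariates import CovariateTrack
from .genome import GenomeSequence, MaskedGenome, build_masked_genome
from .intervals import IntervalSet
from .motifs import CbsSite
from .downstream import SegmentRecord
from .variants import CohortMetadata, MutationRecord

# printed cohort-level observations the presets reproduce
CBS_RATE_PER_MB = 11.0
FLANK_RATE_PER_MB = 3.6
SUBTYPE_CBS_FOLD = {"CIN": 7.1, "GS": 4.7, "EBV": 1.7, "MSI": 1.0}
TFBS_BP_FRACTION = 0.01
TFBS_MUT_FRACTION = 0.0058


@dataclass
class CovariatePlan:
    """Piecewise-constant continuous tracks with planted logit-scale effects."""

    n_informative: int = 5
    n_noise: int = 20
    block_bp: int = 1000
    beta: tuple = ()  # one per informative track; default 1.0 each

    def betas(self) -> np.ndarray:
        if self.beta:
            if len(self.beta) != self.n_informative:
                raise ValueError("beta length must equal n_informative")
            return np.asarray(self.beta, dtype=float)
        return np.ones(self.n_informative)


@dataclass
class HotspotPlan:
    chrom: str
    start: int
    end: int
    per_patient_prob: float = 0.2  # probability a patient carries >=1 mutation here


@dataclass
class CbsPlan:
    count: int = 10_000
    motif_len: int = 19
    flank_bp: int = 1000
    subtype_fold: dict = field(default_factory=lambda: dict(SUBTYPE_CBS_FOLD))
    boundary_fraction: float = 0.3
    boundary_fold: float = 1.0
    n_selected: int = 0
    selected_fold: float = 10.0


@dataclass
class TfbsPlan:
    bp_fraction: float = TFBS_BP_FRACTION
    target_mut_fraction: float = TFBS_MUT_FRACTION
    site_bp: int = 50

    def rate_ratio(self) -> float:
        """Inside/outside rate ratio r solving f*r / (f*r + (1-f)) = target."""
        f, t = self.bp_fraction, self.target_mut_fraction
        return (t * (1 - f)) / (f * (1 - t))


@dataclass
class ScnaPlan:
    couple_prob: float = 0.8  # breakpoint placed near each CBS-mutated site
    near_sd_bp: int = 100_000
    background_per_chrom: float = 1.0  # Poisson mean of uncoupled non-diploid segments
    segment_bp: int = 2_000_000
    log2_gain: float = 0.5
    log2_loss: float = -0.7


@dataclass
class ExpressionPlan:
    n_tads: int = 6
    tad_bp: int = 1_000_000
    genes_per_tad: int = 5
    effect_log2: float = 1.0  # planted shift in mutated samples, affected genes
    sigma: float = 0.3
    n_affected: int = 2


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic cohort."""

    seed: int
    chrom_lengths: dict = field(default_factory=lambda: {f"chr{i+1}": 10_000_000 for i in range(5)})
    n_patients: int = 50
    subtype_weights: dict = field(default_factory=lambda: {"NA": 1.0})
    base_rate: float = 1e-6  # per-bp per-patient background mutation probability
    subtype_base_rates: dict | None = None  # overrides base_rate per subtype
    burden_sigma: float = 0.3  # lognormal (mean-1) per-patient burden dispersion
    indel_fraction: float = 0.0
    purity: float = 0.5
    covariates: CovariatePlan | None = None
    hotspots: list = field(default_factory=list)
    cbs: CbsPlan | None = None
    tfbs: TfbsPlan | None = None
    scna: ScnaPlan | None = None
    expression: ExpressionPlan | None = None
    cbs_spectrum: bool = False  # bias CBS mutations to A.T>C.G / A.T>G.C

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not (0 < self.base_rate < 1):
            raise ValueError("base_rate must be a probability in (0, 1)")
        if self.burden_sigma < 0:
            raise ValueError("burden_sigma must be >= 0")
        for h in self.hotspots:
            if h.chrom not in self.chrom_lengths or h.end > self.chrom_lengths[h.chrom]:
                raise ValueError(f"hotspot {h.chrom}:{h.start}-{h.end} outside the genome")
            if not (0 <= h.per_patient_prob <= 1):
                raise ValueError("hotspot per-patient probability outside [0, 1]")
        if self.cbs is not None:
            need = self.cbs.count * (self.cbs.motif_len + 60)
            if need > sum(self.chrom_lengths.values()):
                raise ValueError("CBS plan does not fit in the genome")
        if abs(sum(self.subtype_weights.values()) - 1.0) > 1e-9 and len(self.subtype_weights) > 1:
            raise ValueError("subtype weights must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted parameters serialized alongside every cohort."""

    config: dict
    patient_rates: dict  # sample -> background per-bp rate (burden-scaled)
    class_rates: dict  # per (subtype, class) per-bp rate
    hotspots: list
    selected_cbs: list  # indices of positively selected CBSs
    expected_mutations: float
    expected_variance: float
    expression_affected: list = field(default_factory=list)

    SCHEMA_VERSION = 1

    def to_json(self) -> str:
        d = {"schema_version": self.SCHEMA_VERSION, **dataclasses.asdict(self)}
        return json.dumps(d, indent=1, sort_keys=True, default=str)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truth: SyntheticTruth
    genome: GenomeSequence
    masked: MaskedGenome
    patients: list
    metadata: CohortMetadata
    mutations: list
    cbs_sites: list = field(default_factory=list)
    tfbs: IntervalSet | None = None
    tracks: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    expression: pd.DataFrame | None = None
    tads: IntervalSet | None = None

    def mutations_by_sample(self) -> dict:
        out: dict[str, list] = {p: [] for p in self.patients}
        for m in self.mutations:
            out[m.sample_id].append(m)
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


def _subtype_counts(weights: dict, n: int) -> dict:
    """Largest-remainder apportionment of n patients to subtypes."""
    items = sorted(weights.items())
    raw = {k: w * n for k, w in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]], reverse=True)
    for k, _ in order[:rem]:
        counts[k] += 1
    return {k: c for k, c in counts.items() if c > 0}


def _interval_offsets(ivals: IntervalSet):
    cached = getattr(ivals, "_offsets_cache", None)
    if cached is None:
        spans = list(ivals)
        lens = np.array([e - s for _, s, e in spans], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens)])
        cached = (spans, cum)
        ivals._offsets_cache = cached
    return cached


def _offsets_to_positions(spans, cum, offsets: np.ndarray):
    idx = np.searchsorted(cum, offsets, side="right") - 1
    return [(spans[i][0], int(spans[i][1] + off - cum[i])) for i, off in zip(idx, offsets)]


def _sample_positions(rng, ivals: IntervalSet, n: int):
    """n distinct uniform positions within an interval set."""
    total = ivals.total_bp
    if n > total:
        n = total
    spans, cum = _interval_offsets(ivals)
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(0, total, size=(n - len(chosen)) * 2 + 8)
        for o in draw:
            chosen.add(int(o))
            if len(chosen) == n:
                break
    offs = np.fromiter(chosen, dtype=np.int64)
    offs.sort()
    return _offsets_to_positions(spans, cum, offs)


_TRANSVERSION = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
_CBS_BIAS = {"A": "CG", "T": "GC", "C": "AGT", "G": "ACT"}  # A.T>C.G and A.T>G.C


def _alt_base(rng, ref: str, cbs_bias: bool) -> str:
    choices = _CBS_BIAS[ref] if (cbs_bias and ref in "AT") else _TRANSVERSION[ref]
    return choices[rng.integers(0, len(choices))]


def _draw_vaf(rng, purity: float) -> float:
    if rng.random() < 0.8:  # clonal: centered at purity/2
        mean = purity / 2
    else:  # subclonal mixture
        mean = purity / 5
    kappa = 50.0
    return float(np.clip(rng.beta(mean * kappa, (1 - mean) * kappa), 1e-4, 1.0))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genome = GenomeSequence(
        {c: _random_sequence(rng, n) for c, n in cfg.chrom_lengths.items()}
    )
    masked = build_masked_genome(genome)
    patients = [f"P{i:04d}" for i in range(cfg.n_patients)]

    counts = _subtype_counts(cfg.subtype_weights, cfg.n_patients)
    subtype = {}
    i = 0
    for st in sorted(counts):
        for _ in range(counts[st]):
            subtype[patients[i]] = st
            i += 1
    metadata = CohortMetadata(
        subtype=subtype,
        mutsig1={p: float(rng.beta(2, 6)) for p in patients},
        mutsig17={p: float(rng.beta(2, 10)) for p in patients},
        purity={p: cfg.purity for p in patients},
    )

    # per-patient burden multiplier, mean 1
    if cfg.burden_sigma > 0:
        burden = np.exp(rng.normal(-cfg.burden_sigma**2 / 2, cfg.burden_sigma, cfg.n_patients))
    else:
        burden = np.ones(cfg.n_patients)

    def base_rate_of(p: str) -> float:
        if cfg.subtype_base_rates is not None:
            return cfg.subtype_base_rates[subtype[p]]
        return cfg.base_rate

    # ---- region classes -------------------------------------------------
    cbs_sites: list[CbsSite] = []
    selected_idx: list[int] = []
    if cfg.cbs is not None:
        cbs_sites = _place_cbs(rng, cfg, genome)
        if cfg.cbs.n_selected:
            selected_idx = sorted(
                rng.choice(len(cbs_sites), size=cfg.cbs.n_selected, replace=False).tolist()
            )
    tfbs = _place_tfbs(rng, cfg, genome) if cfg.tfbs is not None else None

    whole = masked.analyzable
    class_ivals: dict[str, IntervalSet] = {}
    if cbs_sites:
        sel_set = set(selected_idx)
        cbs_plain = IntervalSet(
            (s.chrom, s.start, s.end) for i, s in enumerate(cbs_sites) if i not in sel_set
        )
        class_ivals["cbs"] = cbs_plain
        if sel_set:
            class_ivals["cbs_selected"] = IntervalSet(
                (s.chrom, s.start, s.end) for i, s in enumerate(cbs_sites) if i in sel_set
            )
    if tfbs is not None:
        class_ivals["tfbs"] = tfbs
    special = IntervalSet()
    for iv in class_ivals.values():
        special = special.union(iv)
    class_ivals["background"] = whole.subtract(special)

    boundary_iv = IntervalSet(
        (s.chrom, s.start, s.end) for s in cbs_sites if s.boundary
    ) if cbs_sites else IntervalSet()

    def class_multiplier(cls: str, p: str) -> float:
        if cls == "cbs" or cls == "cbs_selected":
            fold = cfg.cbs.subtype_fold.get(subtype[p], 1.0)
            if cls == "cbs_selected":
                fold *= cfg.cbs.selected_fold
            return fold
        if cls == "tfbs":
            return cfg.tfbs.rate_ratio()
        return 1.0

    # ---- covariate tracks ------------------------------------------------
    tracks: list[CovariateTrack] = []
    block_values: dict[str, np.ndarray] = {}
    betas = np.zeros(0)
    if cfg.covariates is not None:
        plan = cfg.covariates
        betas = plan.betas()
        n_tracks = plan.n_informative + plan.n_noise
        for t in range(n_tracks):
            recs = []
            vals_by_chrom = {}
            for chrom, n in cfg.chrom_lengths.items():
                nb = int(np.ceil(n / plan.block_bp))
                vals = rng.normal(0, 1, nb)
                vals_by_chrom[chrom] = vals
                for b in range(nb):
                    recs.append((chrom, b * plan.block_bp, min(n, (b + 1) * plan.block_bp), vals[b]))
            name = f"inf{t}" if t < plan.n_informative else f"noise{t - plan.n_informative}"
            tr = CovariateTrack.from_records(name, "continuous", recs)
            tracks.append(tr)
            block_values[name] = vals_by_chrom

    # ---- mutation sampling ----------------------------------------------
    mutations: list[MutationRecord] = []
    expected = 0.0
    expected_var = 0.0
    class_rates: dict[str, float] = {}

    def _emit(p: str, chrom: str, pos: int, in_cbs: bool):
        ref = genome.sequences[chrom][pos]
        if cfg.indel_fraction > 0 and rng.random() < cfg.indel_fraction:
            if pos + 1 < genome.lengths[chrom]:
                ref2 = genome.sequences[chrom][pos : pos + 2]
                mutations.append(
                    MutationRecord(p, chrom, pos, ref2, ref2[0], vaf=_draw_vaf(rng, cfg.purity))
                )
                return
        alt = _alt_base(rng, ref, cfg.cbs_spectrum and in_cbs)
        mutations.append(MutationRecord(p, chrom, pos, ref, alt, vaf=_draw_vaf(rng, cfg.purity)))

    if cfg.covariates is None:
        for pi, p in enumerate(patients):
            for cls, ivals in class_ivals.items():
                if ivals.is_empty():
                    continue
                q = min(0.5, base_rate_of(p) * burden[pi] * class_multiplier(cls, p))
                if cls in ("cbs", "cbs_selected") and cfg.cbs.boundary_fold != 1.0:
                    # split boundary vs non-boundary CBS bases
                    parts = [
                        (ivals.intersect(boundary_iv), q * cfg.cbs.boundary_fold),
                        (ivals.subtract(boundary_iv), q),
                    ]
                else:
                    parts = [(ivals, q)]
                for part, qq in parts:
                    L = part.total_bp
                    if L == 0 or qq <= 0:
                        continue
                    qq = min(qq, 0.5)
                    n = int(rng.binomial(L, qq))
                    expected += L * qq
                    expected_var += L * qq * (1 - qq)
                    class_rates[f"{subtype[p]}:{cls}"] = qq
                    for chrom, pos in _sample_positions(rng, part, n):
                        _emit(p, chrom, pos, cls in ("cbs", "cbs_selected"))
    else:
        plan = cfg.covariates
        b0 = logit(cfg.base_rate)
        for pi, p in enumerate(patients):
            b_pat = np.log(burden[pi])
            for chrom, n in cfg.chrom_lengths.items():
                nb = int(np.ceil(n / plan.block_bp))
                lin = np.full(nb, b0 + b_pat)
                for t in range(plan.n_informative):
                    lin += betas[t] * block_values[f"inf{t}"][chrom]
                qs = expit(lin)
                lens = np.full(nb, plan.block_bp, dtype=np.int64)
                lens[-1] = n - (nb - 1) * plan.block_bp
                draws = rng.binomial(lens, qs)
                expected += float((lens * qs).sum())
                expected_var += float((lens * qs * (1 - qs)).sum())
                for b in np.nonzero(draws)[0]:
                    lo = b * plan.block_bp
                    width = int(lens[b])
                    k = int(draws[b])
                    offs = set()
                    while len(offs) < k:
                        for o in rng.integers(0, width, size=k - len(offs) + 4):
                            offs.add(int(o))
                            if len(offs) == k:
                                break
                    for o in sorted(offs):
                        _emit(p, chrom, lo + o, False)

    # ---- planted hotspots -------------------------------------------------
    hotspot_truth = []
    for h in cfg.hotspots:
        mutated = []
        for p in patients:
            if rng.random() < h.per_patient_prob:
                pos = int(rng.integers(h.start, h.end))
                _emit(p, h.chrom, pos, False)
                mutated.append(p)
        hotspot_truth.append(
            {"chrom": h.chrom, "start": h.start, "end": h.end,
             "per_patient_prob": h.per_patient_prob, "mutated_samples": mutated}
        )

    mutations.sort(key=lambda m: (m.chrom, m.pos, m.sample_id))

    # ---- SCNA segments ------------------------------------------------------
    segments: list[SegmentRecord] = []
    if cfg.scna is not None:
        segments = _simulate_scna(rng, cfg, genome, patients, mutations, class_ivals)

    # ---- expression -----------------------------------------------------------
    expression, tads, affected = None, None, []
    if cfg.expression is not None:
        expression, tads, affected = _simulate_expression(
            rng, cfg, patients, hotspot_truth, cbs_sites
        )

    truth = SyntheticTruth(
        config={k: str(v) for k, v in dataclasses.asdict(cfg).items()},
        patient_rates={p: base_rate_of(p) * burden[i] for i, p in enumerate(patients)},
        class_rates=class_rates,
        hotspots=hotspot_truth,
        selected_cbs=selected_idx,
        expected_mutations=expected,
        expected_variance=expected_var,
        expression_affected=affected,
    )
    return SyntheticCohort(
        config=cfg,
        truth=truth,
        genome=genome,
        masked=masked,
        patients=patients,
        metadata=metadata,
        mutations=mutations,
        cbs_sites=cbs_sites,
        tfbs=tfbs,
        tracks=tracks,
        segments=segments,
        expression=expression,
        tads=tads,
    )


def _place_cbs(rng, cfg: SimulationConfig, genome: GenomeSequence) -> list[CbsSite]:
    plan = cfg.cbs
    total = sum(cfg.chrom_lengths.values())
    per_chrom = {c: int(round(plan.count * n / total)) for c, n in cfg.chrom_lengths.items()}
    # adjust rounding drift on the largest chromosome
    drift = plan.count - sum(per_chrom.values())
    if drift:
        big = max(cfg.chrom_lengths, key=cfg.chrom_lengths.get)
        per_chrom[big] += drift
    sites = []
    for chrom in cfg.chrom_lengths:
        n = cfg.chrom_lengths[chrom]
        k = per_chrom[chrom]
        if k <= 0:
            continue
        spacing = n // k
        jitter_max = max(1, spacing - plan.motif_len - 1)
        starts = np.arange(k) * spacing + rng.integers(0, jitter_max, size=k)
        starts = np.minimum(starts, n - plan.motif_len)
        strands = rng.choice(["+", "-"], size=k)
        bnd = rng.random(k) < plan.boundary_fraction
        for s, st, b in zip(starts, strands, bnd):
            sites.append(
                CbsSite(chrom=chrom, start=int(s), end=int(s) + plan.motif_len,
                        strand=str(st), motif_score=float(rng.normal(12, 2)),
                        boundary=bool(b), tissue_active=True)
            )
    sites.sort(key=lambda s: (s.chrom, s.start))
    return sites


def _place_tfbs(rng, cfg: SimulationConfig, genome: GenomeSequence) -> IntervalSet:
    plan = cfg.tfbs
    recs = []
    for chrom, n in cfg.chrom_lengths.items():
        target_bp = plan.bp_fraction * n
        k = int(round(target_bp / plan.site_bp))
        spacing = n // max(1, k)
        starts = np.arange(k) * spacing + rng.integers(
            0, max(1, spacing - plan.site_bp), size=k
        )
        for s in np.minimum(starts, n - plan.site_bp):
            recs.append((chrom, int(s), int(s) + plan.site_bp))
    return IntervalSet(recs)


def _simulate_scna(rng, cfg, genome, patients, mutations, class_ivals) -> list:
    plan = cfg.scna
    cbs_iv = class_ivals.get("cbs", IntervalSet()).union(
        class_ivals.get("cbs_selected", IntervalSet())
    )
    by_patient: dict[str, list] = {p: [] for p in patients}
    for m in mutations:
        if cbs_iv.contains(m.chrom, m.pos):
            by_patient[m.sample_id].append((m.chrom, m.pos))
    segments = []
    for p in patients:
        nondiploid: dict[str, list] = {}
        for chrom, pos in by_patient[p]:
            if rng.random() < plan.couple_prob:
                center = pos + int(rng.normal(0, plan.near_sd_bp))
                start = max(0, center - plan.segment_bp // 2)
                end = min(genome.lengths[chrom], start + plan.segment_bp)
                if end > start:
                    nondiploid.setdefault(chrom, []).append((start, end))
        for chrom, n in genome.lengths.items():
            for _ in range(rng.poisson(plan.background_per_chrom)):
                start = int(rng.integers(0, max(1, n - plan.segment_bp)))
                nondiploid.setdefault(chrom, []).append((start, min(n, start + plan.segment_bp)))
        for chrom, n in genome.lengths.items():
            spans = sorted(nondiploid.get(chrom, []))
            merged = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            cur = 0
            for s, e in merged:
                if s > cur:
                    segments.append(SegmentRecord(p, chrom, cur, s, 0.0))
                lr = plan.log2_loss if rng.random() < 0.5 else plan.log2_gain
                segments.append(SegmentRecord(p, chrom, s, e, float(lr)))
                cur = e
            if cur < n:
                segments.append(SegmentRecord(p, chrom, cur, n, 0.0))
    return segments


def _simulate_expression(rng, cfg, patients, hotspot_truth, cbs_sites):
    plan = cfg.expression
    if hotspot_truth:
        chrom = hotspot_truth[0]["chrom"]
        locus = (hotspot_truth[0]["start"] + hotspot_truth[0]["end"]) // 2
        mutated = set(hotspot_truth[0]["mutated_samples"])
    elif cbs_sites:
        site = cbs_sites[0]
        chrom, locus, mutated = site.chrom, site.start, set()
    else:
        raise ValueError("expression plan requires a hotspot or CBS plan")
    first_tad = max(0, locus - plan.tad_bp * plan.n_tads // 2)
    # a partition into adjacent TADs (kept as tuples: boundaries matter)
    tads = [
        (chrom, first_tad + i * plan.tad_bp, first_tad + (i + 1) * plan.tad_bp)
        for i in range(plan.n_tads)
    ]
    genes = []
    for ti, (c, s, e) in enumerate(tads):
        for g in range(plan.genes_per_tad):
            gs = s + (g + 1) * plan.tad_bp // (plan.genes_per_tad + 2)
            genes.append((f"G{ti}_{g}", c, gs, gs + 20_000))
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])
    # affected genes: nearest genes in the hotspot's TAD pair
    near = gene_df.assign(d=(gene_df.start - locus).abs()).sort_values("d")
    affected = near.gene_id.head(plan.n_affected).tolist()
    base = rng.lognormal(np.log(200), 1.0, size=len(gene_df))
    mat = np.empty((len(gene_df), len(patients)))
    for j, p in enumerate(patients):
        noise = rng.lognormal(0, plan.sigma, size=len(gene_df))
        mat[:, j] = base * noise
        if p in mutated:
            for gi, g in enumerate(gene_df.gene_id):
                if g in affected:
                    mat[gi, j] *= 2**plan.effect_log2
    expression = pd.DataFrame(np.round(mat, 3), index=gene_df.gene_id, columns=patients)
    expression.attrs["gene_locations"] = gene_df
    return expression, tads, affected


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

CBS_RATES_SUBTYPE_WEIGHTS = {"CIN": 0.40, "GS": 0.35, "EBV": 0.15, "MSI": 0.10}


def solve_cbs_rates(
    weights: dict = None,
    folds: dict = None,
    pooled_cbs: float = CBS_RATE_PER_MB,
    pooled_flank: float = FLANK_RATE_PER_MB,
) -> dict:
    """Per-subtype flank rates (per Mb per tumor) reproducing the pooled CBS
    and flank rates with the given subtype folds.

    The CIN/GS/EBV groups share a flank rate f0 and MSI takes its own rate fm
    (mismatch-repair-deficient tumors carry much higher burdens):
    sum(w*f) = pooled_flank and sum(w*fold*f) = pooled_cbs, a 2x2 linear solve.
    """
    weights = weights or CBS_RATES_SUBTYPE_WEIGHTS
    folds = folds or SUBTYPE_CBS_FOLD
    others = [s for s in weights if s != "MSI"]
    w_o = sum(weights[s] for s in others)
    w_m = weights.get("MSI", 0.0)
    a = sum(weights[s] * folds[s] for s in others)
    if w_m == 0:
        return {s: pooled_flank / w_o for s in others}
    # [w_o, w_m][f0, fm] = pooled_flank ; [a, w_m*fold_m][f0, fm] = pooled_cbs
    f0 = (pooled_cbs - pooled_flank * folds["MSI"]) / (a - w_o * folds["MSI"])
    fm = (pooled_flank - w_o * f0) / w_m
    rates = {s: f0 for s in others}
    rates["MSI"] = fm
    return rates


def presets(seed: int = 1) -> dict[str, SimulationConfig]:
    """Named study-condition configurations."""
    genome_50mb = {f"chr{i+1}": 10_000_000 for i in range(5)}
    out = {}
    out["null"] = SimulationConfig(
        seed=seed, chrom_lengths=dict(genome_50mb), n_patients=50, base_rate=1e-6
    )
    out["planted-hotspots"] = replace(
        out["null"],
        hotspots=[HotspotPlan(chrom="chr1", start=5_000_000, end=5_000_021, per_patient_prob=0.2)],
    )
    # solve the per-subtype flank rates against the realized integer group
    # sizes so the pooled expectations hit the target rates exactly
    n_cbs_cohort = 150
    counts = _subtype_counts(CBS_RATES_SUBTYPE_WEIGHTS, n_cbs_cohort)
    realized = {s: c / n_cbs_cohort for s, c in counts.items()}
    flank_rates = solve_cbs_rates(weights=realized)
    out["cbs-rates"] = SimulationConfig(
        seed=seed,
        chrom_lengths=dict(genome_50mb),
        n_patients=n_cbs_cohort,
        subtype_weights=realized,
        subtype_base_rates={s: r * 1e-6 for s, r in flank_rates.items()},
        base_rate=FLANK_RATE_PER_MB * 1e-6,
        burden_sigma=0.0,
        cbs=CbsPlan(count=100_000, flank_bp=1000),
        cbs_spectrum=True,
    )
    out["tfbs-depletion"] = SimulationConfig(
        seed=seed,
        chrom_lengths=dict(genome_50mb),
        n_patients=300,
        base_rate=10.6e-6,
        burden_sigma=0.0,
        tfbs=TfbsPlan(),
    )
    # CBS-wide 3x elevation with a small positively selected subset; the CBS
    # universe and cohort are sized so a 10x selected site clears Bonferroni
    # while non-selected sites stay calibrated
    out["cbs-selection"] = SimulationConfig(
        seed=seed,
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        n_patients=250,
        subtype_weights={"CIN": 0.5, "GS": 0.5},
        base_rate=5e-4 / 3,
        burden_sigma=0.0,
        cbs=CbsPlan(
            count=4010,
            subtype_fold={"CIN": 3.0, "GS": 3.0},
            n_selected=10,
            selected_fold=10.0,
        ),
        cbs_spectrum=True,
    )
    return out


# ---------------------------------------------------------------------------
# bundle I/O and detection evaluation
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir) -> list[str]:
    """Emit the cohort as a plain-text file bundle; returns the file list."""
    import os

    from .variants import write_mutations_tsv

    os.makedirs(outdir, exist_ok=True)
    written = []

    def path(name):
        written.append(name)
        return os.path.join(outdir, name)

    cohort.genome.to_fasta(path("genome.fa"))
    write_mutations_tsv(cohort.mutations, path("mutations.tsv"))
    pd.DataFrame(
        {
            "sample_id": cohort.patients,
            "subtype": [cohort.metadata.subtype[p] for p in cohort.patients],
            "mutsig1": [cohort.metadata.mutsig1[p] for p in cohort.patients],
            "mutsig17": [cohort.metadata.mutsig17[p] for p in cohort.patients],
            "purity": [cohort.metadata.purity[p] for p in cohort.patients],
        }
    ).to_csv(path("metadata.tsv"), sep="\t", index=False)
    if cohort.cbs_sites:
        with open(path("cbs.bed"), "w") as fh:
            for i, s in enumerate(cohort.cbs_sites):
                fh.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\tCBS{i}\t{s.motif_score:.3f}\t{s.strand}"
                    f"\t{int(s.boundary)}\t{int(s.tissue_active)}\n"
                )
    if cohort.tfbs is not None:
        cohort.tfbs.to_bed(path("tfbs.bed"))
    for tr in cohort.tracks:
        with open(path(f"track_{tr.name}.bedgraph"), "w") as fh:
            for chrom, s, e, v in tr.iter_records():
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    if cohort.segments:
        pd.DataFrame(
            [(s.sample_id, s.chrom, s.start, s.end, s.log2_ratio) for s in cohort.segments],
            columns=["sample_id", "chrom", "start", "end", "log2_ratio"],
        ).to_csv(path("segments.tsv"), sep="\t", index=False)
    if cohort.expression is not None:
        cohort.expression.to_csv(path("expression.tsv"), sep="\t")
        with open(path("tads.bed"), "w") as fh:
            for c, s, e in cohort.tads:
                fh.write(f"{c}\t{s}\t{e}\n")
    with open(path("truth.json"), "w") as fh:
        fh.write(cohort.truth.to_json())
    return written


def evaluate_detection(
    calls: list, truth: SyntheticTruth, lengths=None
) -> pd.DataFrame:
    """Classify called hotspots against planted loci by interval overlap.

    ``calls``: merged-hotspot dicts (chrom/start/end). Returns one row per
    planted locus (detected or missed) plus a summary of false positives,
    with sensitivity = TP / planted and the FP count.
    """
    planted = truth.hotspots
    rows = []
    used = set()
    for t in planted:
        hit = None
        for i, c in enumerate(calls):
            if c["chrom"] == t["chrom"] and c["start"] < t["end"] and c["end"] > t["start"]:
                hit = i
                break
        if hit is not None:
            used.add(hit)
        rows.append(
            {"chrom": t["chrom"], "start": t["start"], "end": t["end"],
             "detected": hit is not None}
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "detected"])
    df.attrs["n_false_positives"] = len(calls) - len(used)
    df.attrs["sensitivity"] = float(df.detected.mean()) if len(df) else float("nan")
    return df
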
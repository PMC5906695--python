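"""Poisson-binomial recurrence testing over focal windows, genes, and CBSs.

For a region of length l, each tumor i has probability
``p_i = 1 - prod_j (1 - q_ij)`` of carrying at least one mutation, with q_ij
the per-base background probability. The number of mutated tumors K is then
Poisson-binomial, and a region's recurrence p-value is the exact upper tail
Pr(K >= k) for the observed number of distinct mutated samples k. Bonferroni
universes: the masked-genome base count for the focal-window scan, the gene
count for the gene scan, and the CBS count for the CBS scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from . import poibin
from .genome import MaskedGenome, Window, candidate_windows, merge_significant
from .intervals import IntervalSet

DEFAULT_MIN_RECURRENCE = {"SNV": 3, "indel": 2}


class RateModel(Protocol):
    """Per-base, per-patient mutation probability source."""

    patients: list[str]

    def q(self, sample_id: str, chrom: str, positions: np.ndarray) -> np.ndarray: ...


@dataclass
class UniformRateModel:
    """Constant q for every base and patient (useful baseline and for tests)."""

    q_value: float
    patients: list[str] = field(default_factory=list)

    def q(self, sample_id, chrom, positions):
        return np.full(len(positions), self.q_value)


@dataclass
class PerPatientRateModel:
    """Per-patient constant q (e.g. patient burden-scaled intercept model)."""

    q_by_patient: Mapping[str, float]

    @property
    def patients(self) -> list[str]:
        return list(self.q_by_patient)

    def q(self, sample_id, chrom, positions):
        return np.full(len(positions), self.q_by_patient[sample_id])


@dataclass
class GlmRateModel:
    """Bridges a fitted BackgroundMutationModel and a per-base feature source.

    ``features_fn(chrom, positions)`` must return a DataFrame with one row per
    position carrying the model's positional covariate columns (everything
    except 'patient' and patient-level attributes). Patient-level covariates
    (subtype, signature fractions) are supplied via ``patient_attrs``. Because
    the model is additive on the logit scale and patient-level covariates are
    constant along the genome, per-patient logit offsets are precomputed once
    and region scans reduce to a single positional design per region.
    """

    model: object
    features_fn: object
    patients: list[str] = field(default_factory=list)
    patient_attrs: Mapping[str, Mapping] | None = None

    def _attrs(self, sample_id) -> dict:
        return dict(self.patient_attrs.get(sample_id, {})) if self.patient_attrs else {}

    def _row(self, sample_id, chrom, positions):
        import pandas as pd

        X = self.features_fn(chrom, np.asarray(positions)).copy()
        for k, v in self._attrs(sample_id).items():
            X[k] = v
        X["patient"] = sample_id
        return X

    def q(self, sample_id, chrom, positions):
        return self.model.predict_proba(self._row(sample_id, chrom, positions))[:, 1]

    def _patient_offsets(self, chrom, pos0: int) -> np.ndarray:
        if getattr(self, "_offsets_cache", None) is None:
            ref = self.patients[0]
            base = self.model.decision_function(self._row(ref, chrom, np.array([pos0])))[0]
            offs = np.empty(len(self.patients))
            for i, pat in enumerate(self.patients):
                offs[i] = (
                    self.model.decision_function(self._row(pat, chrom, np.array([pos0])))[0]
                    - base
                )
            self._offsets_cache = offs
        return self._offsets_cache

    def q_matrix(self, chrom, positions, patients=None) -> np.ndarray:
        """(n_patients, n_positions) per-base probabilities, vectorized."""
        from scipy.special import expit

        positions = np.asarray(positions)
        offs = self._patient_offsets(chrom, int(positions[0]))
        if patients is not None and list(patients) != list(self.patients):
            index = {p: i for i, p in enumerate(self.patients)}
            offs = offs[[index[p] for p in patients]]
        base_logit = self.model.decision_function(self._row(self.patients[0], chrom, positions))
        return expit(base_logit[None, :] + offs[:, None])


@dataclass
class RegionProbability:
    region: IntervalSet
    patients: list[str]
    p: np.ndarray  # per-patient probability of >=1 mutation in the region

    @property
    def n(self) -> int:
        return len(self.p)


@dataclass
class RecurrenceResult:
    chrom: str
    start: int
    end: int
    k: int
    n: int
    sample_ids: frozenset
    p_value: float
    p_adjusted: float
    method: str = "exact_dp"
    region: IntervalSet | None = None
    name: str | None = None
    patient_p: np.ndarray | None = None


def region_probability(
    rate_model: RateModel,
    region: IntervalSet,
    patients: Sequence[str] | None = None,
    analyzable: IntervalSet | None = None,
) -> RegionProbability:
    """Per-patient p_i = 1 - exp(sum log(1 - q_ij)) over the region's
    analyzable bases (bases outside the analyzable set contribute q = 0)."""
    patients = list(patients) if patients is not None else list(rate_model.patients)
    if analyzable is not None:
        region = region.intersect(analyzable)
    pos_by_chrom = {
        chrom: np.concatenate([np.arange(s, e) for c2, s, e in region if c2 == chrom])
        for chrom in {c for c, _, _ in region}
    }
    log_surv = np.zeros(len(patients))
    for chrom, positions in pos_by_chrom.items():
        if hasattr(rate_model, "q_matrix"):
            qm = np.asarray(rate_model.q_matrix(chrom, positions, patients), dtype=float)
            if np.any(qm >= 1) or np.any(qm < 0):
                raise ValueError("model pathology: per-base q outside [0, 1)")
            log_surv += np.log1p(-qm).sum(axis=1)
        else:
            for i, pat in enumerate(patients):
                q = np.asarray(rate_model.q(pat, chrom, positions), dtype=float)
                if np.any(q >= 1) or np.any(q < 0):
                    raise ValueError("model pathology: per-base q outside [0, 1)")
                log_surv[i] += np.log1p(-q).sum()
    p = -np.expm1(log_surv)
    return RegionProbability(region=region, patients=patients, p=p)


def _test_region(
    rate_model,
    region: IntervalSet,
    mutated_samples: frozenset,
    patients,
    analyzable,
    n_tests: int,
    keep_patient_p: bool = False,
) -> dict:
    rp = region_probability(rate_model, region, patients, analyzable)
    k = len(mutated_samples)
    p_val = poibin.tail_exact(rp.p, k)
    return {
        "k": k,
        "n": rp.n,
        "sample_ids": mutated_samples,
        "p_value": p_val,
        "p_adjusted": min(1.0, p_val * n_tests),
        "patient_p": rp.p if keep_patient_p else None,
    }


def scan_hotspots(
    muts: Sequence,
    rate_model: RateModel,
    masked: MaskedGenome,
    flank: int = 10,
    min_recurrence: Mapping[str, int] | None = None,
    mut_class: str = "SNV",
    alpha: float = 0.01,
    patients: Sequence[str] | None = None,
):
    """Focal-window recurrence scan.

    Windows of width 2*flank+1 are placed around every distinct mutated
    position; windows with at least ``min_recurrence[mut_class]`` distinct
    mutated samples are tested. p-values are exact DP tails, Bonferroni-
    adjusted by the masked-genome base count; overlapping significant windows
    are merged into hotspots (minimum constituent p, union of samples).

    Returns (results, hotspots).
    """
    min_recurrence = dict(DEFAULT_MIN_RECURRENCE, **(min_recurrence or {}))
    muts = [m for m in muts if m.mut_class == mut_class]
    windows, _ = candidate_windows(muts, masked, flank=flank)
    min_k = min_recurrence[mut_class]
    n_tests = masked.n_test_bases
    results: list[RecurrenceResult] = []
    for w in windows:
        if w.n_samples < min_k:
            continue
        region = IntervalSet([(w.chrom, w.start, w.end)])
        d = _test_region(rate_model, region, w.sample_ids, patients, masked.analyzable, n_tests)
        results.append(RecurrenceResult(chrom=w.chrom, start=w.start, end=w.end, **d))
    hotspots = merge_significant(results, alpha_adjusted=alpha)
    return results, hotspots


def scan_genes_indel(
    indels: Sequence,
    gene_regions: Mapping[str, IntervalSet],
    rate_model: RateModel,
    analyzable: IntervalSet | None = None,
    alpha: float = 0.01,
    patients: Sequence[str] | None = None,
) -> list[RecurrenceResult]:
    """Per-gene indel recurrence over each gene's merged non-coding region.

    Genes sharing bases are tested independently; the Bonferroni universe is
    the number of genes tested.
    """
    indels = [m for m in indels if m.mut_class == "indel"]
    genes = {g: r for g, r in gene_regions.items() if not r.is_empty()}
    n_tests = len(genes)
    results = []
    for gene, region in genes.items():
        samples = frozenset(
            m.sample_id for m in indels if region.overlaps(m.chrom, m.pos, m.end)
        )
        d = _test_region(rate_model, region, samples, patients, analyzable, n_tests)
        spans = list(region)
        results.append(
            RecurrenceResult(
                chrom=spans[0][0],
                start=min(s for _, s, _ in spans),
                end=max(e for _, _, e in spans),
                region=region,
                name=gene,
                **d,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.chrom, r.start))
    return results


def scan_cbs(
    muts: Sequence,
    cbs_sites: Sequence,
    rate_model: RateModel,
    lengths: Mapping[str, int],
    flank: int = 5,
    analyzable: IntervalSet | None = None,
    alpha: float = 0.01,
    patients: Sequence[str] | None = None,
    keep_patient_p: bool = True,
) -> list[RecurrenceResult]:
    """One recurrence test per CBS over the motif +/- ``flank`` bp.

    The Bonferroni universe is the number of CBSs tested. ``patient_p`` is
    retained on each result so calibration diagnostics can recompute
    randomized tail probabilities.
    """
    n_tests = len(cbs_sites)
    # index mutations once; binary search per region
    by_chrom: dict[str, list] = {}
    for m in muts:
        by_chrom.setdefault(m.chrom, []).append(m)
    pos_index = {}
    max_ref = {}
    for c, v in by_chrom.items():
        v.sort(key=lambda m: m.pos)
        pos_index[c] = np.array([m.pos for m in v], dtype=np.int64)
        max_ref[c] = max(len(m.ref) for m in v)
    results = []
    for site in cbs_sites:
        start = max(0, site.start - flank)
        end = min(lengths[site.chrom], site.end + flank)
        region = IntervalSet([(site.chrom, start, end)])
        chrom_muts = by_chrom.get(site.chrom, [])
        if chrom_muts:
            pa = pos_index[site.chrom]
            lo = int(np.searchsorted(pa, start - max_ref[site.chrom], side="left"))
            hi = int(np.searchsorted(pa, end, side="left"))
            samples = frozenset(
                m.sample_id for m in chrom_muts[lo:hi] if m.pos < end and m.end > start
            )
        else:
            samples = frozenset()
        d = _test_region(
            rate_model, region, samples, patients, analyzable, n_tests,
            keep_patient_p=keep_patient_p,
        )
        results.append(RecurrenceResult(chrom=site.chrom, start=start, end=end, region=region, **d))
    return results


def results_to_dataframe(results: Sequence[RecurrenceResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": r.name,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n": r.n,
                "k": r.k,
                "samples": ",".join(sorted(r.sample_ids)),
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
            }
            for r in results
        ]
    )
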
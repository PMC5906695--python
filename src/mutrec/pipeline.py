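"""End-to-end orchestration over a file bundle.

A run is a pure function of (inputs, config, seed): somatic calls are read
and filtered, a patient-intercept background model (optionally with
local-rate bins) is fitted by exhaustive aggregation over the analyzable
genome, focal windows are scanned for SNV and indel recurrence, and tidy TSV
tables plus a JSON manifest (config, seed, file checksums) are written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .background import BackgroundMutationModel, build_frequency_table
from .genome import GenomeSequence, build_masked_genome
from .intervals import IntervalSet
from .recurrence import GlmRateModel, results_to_dataframe, scan_cbs, scan_hotspots
from .variants import filter_artifacts, read_mutations, sample_qc

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mutations: str
    genome: str
    outdir: str
    seed: int = 0
    cds_bed: str | None = None
    ig_bed: str | None = None
    lowmap_bed: str | None = None
    cbs_bed: str | None = None
    metadata: str | None = None
    flank: int = 10
    alpha: float = 0.01
    min_calls: int = 0  # sample-QC call-count floor (0 disables)
    af_cut: float = 0.01
    pon_cut: float = 0.10

    def validate(self) -> None:
        for p in (self.mutations, self.genome):
            if not os.path.exists(p):
                raise FileNotFoundError(f"input not found: {p}")
        for p in (self.cds_bed, self.ig_bed, self.lowmap_bed, self.cbs_bed, self.metadata):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"input not found: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_bed(path) -> IntervalSet:
    return IntervalSet.from_bed(path) if path else IntervalSet()


def fit_patient_background(muts, masked, patients, model_class="snv"):
    """Patient-intercept logistic background model by exhaustive aggregation."""
    class_muts = [m for m in muts if (m.mut_class == "SNV") == (model_class == "snv")]
    combos = pd.DataFrame({"unit": ["all"], "n_sites": [masked.n_test_bases]})
    mutated = pd.DataFrame(
        {"unit": "all", "patient": [m.sample_id for m in class_muts]}
    )
    freq = build_frequency_table(combos, mutated, patients, covariate_cols=["unit"])
    model = BackgroundMutationModel(model_class=model_class).fit_frequency_table(freq)
    features_fn = lambda chrom, positions: pd.DataFrame(
        {"unit": ["all"] * len(positions)}
    )
    return GlmRateModel(model=model, features_fn=features_fn, patients=list(patients))


def cbs_model_from_cohort(cohort, flank: int = 5, patient_effects: bool = False):
    """Fit the CBS-specific background model on a (synthetic) cohort.

    The model universe is every CBS motif +/- ``flank`` bp; covariates are the
    boundary flag, tumor subtype (GS reference), and the per-patient
    signature-1/17 fractions. Returns (model, rate_model, freq_table).
    """
    from .background import fit_cbs_background

    sites = cohort.cbs_sites
    lengths = cohort.genome.lengths
    regions = []
    for s in sites:
        regions.append((s.chrom, max(0, s.start - flank), min(lengths[s.chrom], s.end + flank)))
    combos = pd.DataFrame(
        {
            "boundary": [str(int(s.boundary)) for s in sites],
            "n_sites": [e - st for _, st, e in regions],
        }
    )
    # map each mutation to its CBS region (regions are disjoint by construction)
    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, (c, st, e) in enumerate(regions):
        starts_by_chrom.setdefault(c, ([], [], []))
        starts_by_chrom[c][0].append(st)
        starts_by_chrom[c][1].append(e)
        starts_by_chrom[c][2].append(i)
    for c, (st, e, idx) in starts_by_chrom.items():
        order = np.argsort(st)
        starts_by_chrom[c] = (
            np.asarray(st)[order], np.asarray(e)[order], np.asarray(idx)[order]
        )
    mut_rows = []
    for m in cohort.mutations:
        entry = starts_by_chrom.get(m.chrom)
        if entry is None:
            continue
        st, e, idx = entry
        j = int(np.searchsorted(st, m.pos, side="right")) - 1
        if j >= 0 and m.pos < e[j]:
            site = sites[int(idx[j])]
            mut_rows.append({"boundary": str(int(site.boundary)), "patient": m.sample_id})
    mutated = pd.DataFrame(mut_rows, columns=["boundary", "patient"])
    freq = build_frequency_table(combos, mutated, cohort.patients, covariate_cols=["boundary"])
    model = fit_cbs_background(freq, cohort.metadata, patient_effects=patient_effects)

    boundary_iv = IntervalSet(
        (s.chrom, max(0, s.start - flank), min(lengths[s.chrom], s.end + flank))
        for s in sites
        if s.boundary
    )

    def features_fn(chrom, positions):
        flags = boundary_iv.contains_points(chrom, np.asarray(positions))
        return pd.DataFrame({"boundary": np.where(flags, "1", "0")})

    attrs = {
        p: {
            "subtype": cohort.metadata.subtype[p],
            "mutsig1": cohort.metadata.mutsig1[p],
            "mutsig17": cohort.metadata.mutsig17[p],
        }
        for p in cohort.patients
    }
    rate_model = GlmRateModel(
        model=model, features_fn=features_fn, patients=list(cohort.patients),
        patient_attrs=attrs,
    )
    return model, rate_model, freq


def run_pipeline(cfg: RunConfig) -> dict:
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    genome = GenomeSequence.from_fasta(cfg.genome)
    masked = build_masked_genome(
        genome, _load_bed(cfg.cds_bed), _load_bed(cfg.ig_bed), _load_bed(cfg.lowmap_bed)
    )
    muts = read_mutations(cfg.mutations, format="tsv")
    kept, removed = filter_artifacts(muts, genome, af_cut=cfg.af_cut, pon_cut=cfg.pon_cut)
    by_sample: dict[str, list] = {}
    for m in kept:
        by_sample.setdefault(m.sample_id, []).append(m)
    if cfg.min_calls > 0:
        samples, excluded = sample_qc(by_sample, min_calls=cfg.min_calls)
    else:
        samples, excluded = sorted(by_sample), []
    muts = [m for m in kept if m.sample_id in set(samples)]

    outputs = {}

    def write(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(cfg.outdir, name)
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = _checksum(path)
        return path

    write(
        "removed_calls.tsv",
        pd.DataFrame(
            [(m.sample_id, m.chrom, m.pos, m.ref, m.alt, rule) for m, rule in removed],
            columns=["sample_id", "chrom", "pos", "ref", "alt", "rule"],
        ),
    )

    tables = {}
    for model_class, mut_class in (("snv", "SNV"), ("indel", "indel")):
        class_muts = [m for m in muts if m.mut_class == mut_class]
        if not class_muts:
            continue
        rate_model = fit_patient_background(muts, masked, samples, model_class=model_class)
        results, hotspots = scan_hotspots(
            muts, rate_model, masked, flank=cfg.flank, mut_class=mut_class, alpha=cfg.alpha
        )
        res_df = results_to_dataframe(results)
        hs_df = pd.DataFrame(
            [
                {
                    "chrom": h["chrom"],
                    "start": h["start"],
                    "end": h["end"],
                    "k": h["k"],
                    "samples": ",".join(sorted(h["sample_ids"])),
                    "p_value": h["p_value"],
                    "p_adjusted": h["p_adjusted"],
                }
                for h in hotspots
            ],
            columns=["chrom", "start", "end", "k", "samples", "p_value", "p_adjusted"],
        )
        write(f"windows_{model_class}.tsv", res_df)
        write(f"hotspots_{model_class}.tsv", hs_df)
        # BED6+: score column carries -log10 adjusted p (capped at 999)
        bed_path = os.path.join(cfg.outdir, f"hotspots_{model_class}.bed")
        with open(bed_path, "w") as fh:
            for i, h in enumerate(hotspots):
                score = min(999.0, -np.log10(max(h["p_adjusted"], 1e-300)))
                fh.write(
                    f"{h['chrom']}\t{h['start']}\t{h['end']}\thotspot_{model_class}_{i}"
                    f"\t{score:.3f}\t.\t{h['k']}\t{h['p_value']:.6g}\n"
                )
        outputs[f"hotspots_{model_class}.bed"] = _checksum(bed_path)
        tables[model_class] = (res_df, hs_df)

    if cfg.cbs_bed:
        from .motifs import CbsSite

        cbs_sites = []
        with open(cfg.cbs_bed) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                cbs_sites.append(
                    CbsSite(
                        chrom=f[0], start=int(f[1]), end=int(f[2]),
                        strand=f[5] if len(f) > 5 else "+",
                        motif_score=float(f[4]) if len(f) > 4 else 0.0,
                        boundary=bool(int(f[6])) if len(f) > 6 else False,
                        tissue_active=bool(int(f[7])) if len(f) > 7 else True,
                    )
                )
        rate_model = fit_patient_background(muts, masked, samples, model_class="snv")
        cbs_results = scan_cbs(
            muts, cbs_sites, rate_model, genome.lengths,
            analyzable=masked.analyzable, alpha=cfg.alpha, keep_patient_p=False,
        )
        write("cbs_recurrence.tsv", results_to_dataframe(cbs_results))

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_samples": len(samples),
        "n_mutations": len(muts),
        "n_removed": len(removed),
        "excluded_samples": excluded,
        "n_test_bases": masked.n_test_bases,
        "outputs": outputs,
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
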
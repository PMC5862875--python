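"""End-to-end driver: synthetic cohort -> CNV -> SV -> SNV -> statistics.

Each stage writes its tables under the run directory together with a
resolved-config snapshot, a seed manifest, and a checksum manifest; rerunning
with the same config reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv, io, snv, stats, sv
from ._rng import substream
from .synthetic import (
    DEFAULT_SV_REGIONS,
    CnvEvent,
    CnvTruth,
    CohortConfig,
    make_panel,
    simulate_aid_sequence,
    simulate_depths,
    simulate_mutation_matrix,
    simulate_survival,
    simulate_sv_candidates,
)

logger = logging.getLogger(__name__)

__all__ = ["demo_annotation", "run_pipeline"]

# Cohort-typical non-silent mutation frequencies used by the demo generator.
DEMO_GENE_FREQS = {
    "NRAS": 0.24, "KRAS": 0.21, "FAM46C": 0.17, "IGLL5": 0.18,
    "TP53": 0.09, "DIS3": 0.09, "BRAF": 0.03,
}
DEMO_INTERACTIONS = [("IGLL5", "KRAS", -2.5)]

_GENE_CHROMS = {
    "NRAS": ("chr1", "p"), "FAM46C": ("chr1", "p"), "CKS1B": ("chr1", "q"),
    "BRAF": ("chr7", "q"), "CCND1": ("chr11", "q"),
    "KRAS": ("chr12", "p"), "DIS3": ("chr13", "q"), "RB1": ("chr13", "q"),
    "TP53": ("chr17", "p"), "MAF": ("chr16", "q"), "IGLL5": ("chr22", "q"),
}


def demo_annotation() -> dict:
    """A compact capture-panel annotation for demo/synthetic cohorts.

    Covers both arms of the chromosomes the analysis exercises (1, 3, 5 for
    hyperdiploidy scoring; 13, 16, 17 for deletions; 14 for IGH; 8 for MYC;
    22 for the lambda locus) with a filler gene per arm so every arm has
    probes, plus the myeloma genes at their native arms.
    """
    chroms = []
    genes = []
    specs = {
        "chr1": 249_000_000, "chr3": 198_000_000, "chr4": 191_000_000,
        "chr5": 181_000_000, "chr7": 159_000_000, "chr8": 146_000_000,
        "chr11": 135_000_000, "chr12": 133_000_000, "chr13": 115_000_000,
        "chr14": 107_000_000, "chr16": 90_000_000, "chr17": 81_000_000,
        "chr22": 51_000_000,
    }
    acro = {"chr13", "chr14", "chr22"}
    for name, length in specs.items():
        cen = length // 2 if name not in acro else length // 6
        chroms.append({"name": name, "length": length, "centromere": cen})
        arms = ["q"] if name in acro else ["p", "q"]
        for arm in arms:
            lo, hi = (1_000_000, cen - 1) if arm == "p" else (cen + 1, length - 1_000_000)
            span = hi - lo
            genes.append(
                {
                    "name": f"{name.removeprefix('chr')}{arm}_filler",
                    "chrom": name,
                    "start": lo + span // 4,
                    "end": lo + span // 2,
                    "region_class": "gene",
                }
            )
    for gene, (chrom, arm) in _GENE_CHROMS.items():
        length = specs[chrom]
        cen = length // 2 if chrom not in acro else length // 6
        lo, hi = (2_000_000, cen - 2) if arm == "p" else (cen + 2, length - 2_000_000)
        offset = (zlib.crc32(gene.encode()) % 1000) * 1000  # spread genes along the arm
        start = lo + (hi - lo) * 3 // 4 + offset
        genes.append(
            {"name": gene, "chrom": chrom, "start": start, "end": start + 60_000,
             "region_class": "gene"}
        )
    genes.append(
        {"name": "IGH", "chrom": "chr14", "start": 105_580_000, "end": 106_880_000,
         "region_class": "IGH"}
    )
    genes.append(
        {"name": "MYC", "chrom": "chr8", "start": 128_700_000, "end": 128_760_000,
         "region_class": "MYC"}
    )
    return {"chromosomes": chroms, "genes": genes, "probe_length": 120}


def _demo_truths(config: CohortConfig, annotation: dict) -> list[CnvTruth]:
    """Plant a rotating schedule of clonal events across the cohort."""
    lengths = {c["name"]: c["length"] for c in annotation["chromosomes"]}
    cens = {c["name"]: c["centromere"] for c in annotation["chromosomes"]}
    truths = []
    for i in range(config.n_samples):
        sid = f"S{i:03d}"
        events = []
        kind = i % 4
        if kind == 0:  # hyperdiploid-like: whole-chromosome trisomies
            for chrom in ("chr3", "chr5", "chr11"):
                events.append(CnvEvent(chrom, 3, 1, lengths[chrom]))
        elif kind == 1:  # arm deletions
            for chrom in ("chr13", "chr16"):
                events.append(CnvEvent(chrom, 1, cens[chrom], lengths[chrom]))
        elif kind == 2:  # 1q amplification
            events.append(CnvEvent("chr1", 3, cens["chr1"], lengths["chr1"]))
        truths.append(CnvTruth(sample_id=sid, events=events))
    return truths


def _demo_variants(
    matrix: pd.DataFrame, panel, config: CohortConfig
) -> pd.DataFrame:
    """Emit a MAF-like call table consistent with the mutation matrix.

    Mutated genes get one missense call with binomial read support around a
    clonal diploid VAF; a sprinkling of silent, IGH, and germline-flagged
    calls exercises the downstream filter.
    """
    rng = substream(config.seed, "variants")
    gene_pos = (
        panel.probes[panel.probes["region_class"] == "gene"]
        .groupby("gene")
        .first()
    )
    rows = []

    def add(sample, gene, effect, in_igh=False, germline=False, vaf_mean=0.45):
        if gene in gene_pos.index:
            g = gene_pos.loc[gene]
            chrom, pos = g["chrom"], int(g["start"]) + int(rng.integers(0, 2000))
        else:
            chrom, pos = "chr14", 105_600_000 + int(rng.integers(0, 100_000))
        depth = max(int(rng.poisson(config.mean_depth_tumor)), 8)
        alt = int(rng.binomial(depth, vaf_mean))
        rows.append(
            dict(
                sample_id=sample, chrom=chrom, pos=pos + 1, ref="C", alt="T",
                gene=gene, effect=effect, ref_count=depth - alt, alt_count=alt,
                vaf=alt / depth, caller_flags="mutect;strelka",
                germline_flagged=germline, in_igh=in_igh,
                cosmic_annotated=bool(rng.random() < 0.2),
                deleterious_predicted=bool(rng.random() < 0.5),
            )
        )

    for sample in matrix.index:
        for gene in matrix.columns:
            if matrix.loc[sample, gene] == 1:
                add(sample, gene, "missense")
        if rng.random() < 0.5:
            add(sample, "RB1", "silent")
        if rng.random() < 0.3:
            add(sample, "IGH", "missense", in_igh=True)
        if rng.random() < 0.3:
            add(sample, "TP53", "missense", germline=True)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> Path:
    """Run all stages on a synthetic cohort and write results to ``out_dir``.

    ``config`` follows :func:`mmcap.io.load_config`; omitted blocks take the
    defaults below. Returns the run directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cohort_kw = dict(config.get("cohort") or {})
    cohort_kw.setdefault("n_samples", 20)
    cfg = CohortConfig(seed=seed, **cohort_kw)
    cnv_par = {"alpha": 0.05, "min_probes": 10, "stat_threshold": 5.0,
               "min_normal_depth": 10, "min_arm_fraction": 0.6,
               "max_components": 3, **(config.get("cnv") or {})}
    stats_par = {"alpha": 0.05, "hypermutator_iqr_factor": 3.0, "panel_mb": 3.3,
                 **(config.get("stats") or {})}

    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(
            {"seed": seed, "cohort": cohort_kw, "cnv": cnv_par, "stats": stats_par},
            fh, sort_keys=True,
        )

    logging.basicConfig(level=config.get("log_level", "INFO"))
    logger.info("stage=synth n_samples=%d seed=%d", cfg.n_samples, seed)

    # --- synthesize ---------------------------------------------------
    annotation = demo_annotation()
    panel = make_panel(cfg, annotation)
    io.write_bed(panel.probes, out / "panel.bed")
    truths = _demo_truths(cfg, annotation)

    matrix = simulate_mutation_matrix(
        DEMO_GENE_FREQS, DEMO_INTERACTIONS, cfg.n_samples, seed=seed
    )
    variants = _demo_variants(matrix, panel, cfg)
    io.write_variants(variants, out / "variants.tsv")

    sv_cands, sv_truth = simulate_sv_candidates(
        n_true=max(cfg.n_samples // 2, 2), n_artifact=cfg.n_samples,
        true_sr_rate=20, true_pe_rate=20, artifact_sr_rate=1, artifact_pe_rate=1,
        include_normals=True, seed=seed, n_samples=cfg.n_samples,
    )
    io.write_bedpe(sv_cands, out / "sv_candidates.bedpe")

    # --- CNV -----------------------------------------------------------
    logger.info("stage=cnv")
    all_calls, all_arms, hrd_rows = [], [], []
    for truth in truths:
        tumor, normal = simulate_depths(panel, truth, cfg)
        track = cnv.compute_log2_ratios(
            tumor, normal, min_normal_depth=cnv_par["min_normal_depth"], panel=panel
        )
        segs = cnv.segment_track(
            track, min_probes=cnv_par["min_probes"],
            stat_threshold=cnv_par["stat_threshold"],
        )
        noise = cnv.fit_noise_model(
            track.unmasked()["log2_ratio"].to_numpy(),
            max_components=cnv_par["max_components"], seed=seed,
            alpha=cnv_par["alpha"],
        )
        calls = cnv.filter_segments(segs, noise, alpha=cnv_par["alpha"])
        calls.insert(0, "sample_id", truth.sample_id)
        arm_ev = cnv.call_arm_events(
            calls, track, min_arm_fraction=cnv_par["min_arm_fraction"]
        )
        arm_ev.insert(0, "sample_id", truth.sample_id)
        flag, score = cnv.detect_hyperdiploidy(arm_ev)
        all_calls.append(calls)
        all_arms.append(arm_ev)
        hrd_rows.append((truth.sample_id, flag, score))
    # drop empty per-sample frames: concatenating them is deprecated and they
    # carry no rows anyway
    cnv_calls = pd.concat(
        [c for c in all_calls if len(c)] or [all_calls[0]], ignore_index=True
    )
    arm_events = pd.concat(
        [a for a in all_arms if len(a)] or [all_arms[0]], ignore_index=True
    )
    hyperdiploidy = pd.DataFrame(hrd_rows, columns=["sample_id", "hyperdiploid", "score"])
    cnv_calls.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
    arm_events.to_csv(out / "arm_events.tsv", sep="\t", index=False)
    hyperdiploidy.to_csv(out / "hyperdiploidy.tsv", sep="\t", index=False)

    # --- SV ------------------------------------------------------------
    logger.info("stage=sv")
    tumor_cands = sv_cands[~sv_cands["is_normal"]].reset_index(drop=True)
    thresholds = sv.tune_thresholds(
        tumor_cands, sv_truth.candidate_labels[: len(tumor_cands)]
    )
    retained = sv.apply_thresholds(tumor_cands, thresholds)
    classes = [
        sv.classify_translocation(c, DEFAULT_SV_REGIONS)
        for c in retained.itertuples()
    ]
    sv_calls = retained.assign(**{"class": classes})
    sv_calls.to_csv(out / "sv_calls.tsv", sep="\t", index=False)
    with open(out / "sv_thresholds.json", "w") as fh:
        json.dump(thresholds.__dict__, fh, indent=2, sort_keys=True)

    # --- SNV -----------------------------------------------------------
    logger.info("stage=snv")
    kept, dropped = snv.filter_variants(variants)
    kept.to_csv(out / "variants_filtered.tsv", sep="\t", index=False)
    dropped.to_csv(out / "variants_dropped.tsv", sep="\t", index=False)
    clonality = snv.summarize_clonality(kept, cnv_calls)
    clonality.to_csv(out / "clonality.tsv", sep="\t", index=False)

    # --- integrative statistics ----------------------------------------
    logger.info("stage=stats")
    feature_spec = {
        "samples": list(matrix.index),
        "snv_genes": list(DEMO_GENE_FREQS),
        "cnv_arms": [("chr1", "q", "gain"), ("chr13", "q", "loss"),
                     ("chr16", "q", "loss")],
        "translocations": ["t(11;14)", "t(4;14)"],
        "composites": {"RAS": ["KRAS", "NRAS"]},
    }
    sv_samples = sv_calls[["sample_id", "class"]]
    full_matrix = stats.build_matrix(kept, arm_events, sv_samples, feature_spec)
    burden = stats.mutation_burden(kept, list(full_matrix.index), stats_par["panel_mb"])
    reduced, hypermutators = stats.exclude_hypermutators(
        full_matrix, burden, iqr_factor=stats_par["hypermutator_iqr_factor"]
    )
    assoc = stats.pairwise_association(reduced, alpha=stats_par["alpha"])
    full_matrix.to_csv(out / "mutation_matrix.tsv", sep="\t")
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)

    sequence, aid_variants = simulate_aid_sequence(
        length=10_000, target_wrcy_density=0.01, n_mutations=40,
        aid_fraction=0.6, seed=seed,
    )
    aid = stats.aid_signature_test(aid_variants, sequence)

    survival = simulate_survival(
        matrix, "IGLL5", hazard_ratio=1.46, baseline_rate=1 / 1000,
        censor_rate=1 / 2000, seed=seed,
    )
    io.write_survival(survival, out / "survival.tsv")
    km = stats.km_curve(survival)
    km.to_csv(out / "km_curve.tsv", sep="\t", index=False)
    if survival["group"].nunique() == 2:
        lr_stat, lr_p = stats.logrank_test(survival)
        cox = stats.cox_hr(survival)
    else:
        # small cohorts can lack carriers of the survival feature entirely;
        # the two-group comparisons are then undefined
        logger.warning("only one survival group present; skipping log-rank/Cox")
        lr_stat, lr_p = float("nan"), float("nan")
        cox = stats.CoxResult(*(float("nan"),) * 5, estimable=False)

    summary = {
        "n_samples": cfg.n_samples,
        "hypermutators_excluded": hypermutators,
        "n_cnv_calls": int((cnv_calls["state"] != "neutral").sum()),
        "n_arm_events": int(len(arm_events)),
        "n_hyperdiploid": int(hyperdiploidy["hyperdiploid"].sum()),
        "sv_thresholds": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                          for k, v in thresholds.__dict__.items()},
        "n_sv_calls": int(len(sv_calls)),
        "n_variants_kept": int(len(kept)),
        "aid_signature": {
            "n_mutations": aid.n_mutations, "n_at_motif": aid.n_at_motif,
            "background_p": aid.background_p, "p_value": aid.p_value,
        },
        "logrank": {"statistic": lr_stat, "p_value": lr_p},
        "cox": {"hazard_ratio": cox.hazard_ratio,
                "ci": [cox.ci_low, cox.ci_high], "estimable": cox.estimable},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "checksums.json"
    }
    with open(out / "checksums.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
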
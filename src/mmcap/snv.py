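"""Somatic variant filtering, concordance, and depth-yield analysis.

Consumes merged multi-caller output (a MAF-like table; the callers themselves
run upstream). Filtering keeps high-confidence, biologically relevant calls:
silent variants, variants in intronic/intergenic/flanking regions, variants
inside the IGH locus (somatic hypermutation territory), and calls flagged as
likely germline by any caller are removed, with per-call provenance.

Concordance between two sequencing runs of the same samples is summarized by
the squared Pearson correlation of shared-variant VAFs plus tallies of
run-unique variants (notably the low-VAF ones extra depth is expected to
add). The saturation analysis thins read counts binomially to emulate
shallower sequencing and reports the detected-variant yield per depth
fraction, with a flattening point where extra depth adds little.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "EXCLUDED_EFFECTS",
    "DEFAULT_DETECTION_RULE",
    "ConcordanceReport",
    "filter_variants",
    "match_variants",
    "vaf_concordance",
    "downsample_counts",
    "yield_curve",
    "summarize_clonality",
]

#: effect classes removed by the high-confidence filter
EXCLUDED_EFFECTS = frozenset({"silent", "intronic", "intergenic", "flanking"})

#: a variant counts as detected with at least 4 alternate reads at VAF >= 5%
DEFAULT_DETECTION_RULE = {"min_alt": 4, "min_vaf": 0.05}

_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


def filter_variants(
    calls: pd.DataFrame, rules: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the high-confidence variant filter.

    A call survives iff its effect is not silent/intronic/intergenic/flanking
    AND it is not in IGH AND it was not germline-flagged by any caller.
    Returns (kept, dropped) where dropped carries a ``reason`` column (first
    matching rule: effect class, then "igh", then "germline").
    """
    rules = rules or {}
    excluded_effects = frozenset(rules.get("excluded_effects", EXCLUDED_EFFECTS))
    reasons = pd.Series("", index=calls.index, dtype=object)
    eff = calls["effect"].astype(str)
    reasons[eff.isin(excluded_effects)] = eff[eff.isin(excluded_effects)]
    igh = calls["in_igh"].astype(bool) & (reasons == "")
    reasons[igh] = "igh"
    germ = calls["germline_flagged"].astype(bool) & (reasons == "")
    reasons[germ] = "germline"
    dropped = calls[reasons != ""].copy()
    dropped["reason"] = reasons[reasons != ""]
    return calls[reasons == ""].copy(), dropped


def match_variants(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition two call sets into shared and run-unique variants.

    The match key is (sample_id, chrom, pos, ref, alt); a multi-allelic site
    yields distinct keys per alternate allele. Returns (shared, unique_a,
    unique_b); shared holds the paired rows with ``_a``/``_b`` suffixes.
    """
    for name, df in (("A", set_a), ("B", set_b)):
        if df.duplicated(subset=_KEY).any():
            raise ValueError(f"set {name} has duplicate variant keys")
    merged = set_a.merge(set_b, on=_KEY, how="outer", suffixes=("_a", "_b"),
                         indicator=True)
    shared = merged[merged["_merge"] == "both"].drop(columns="_merge")
    only_a = merged.loc[merged["_merge"] == "left_only", _KEY]
    only_b = merged.loc[merged["_merge"] == "right_only", _KEY]
    unique_a = set_a.merge(only_a, on=_KEY)
    unique_b = set_b.merge(only_b, on=_KEY)
    return shared.reset_index(drop=True), unique_a, unique_b


@dataclass(frozen=True)
class ConcordanceReport:
    n_shared: int
    r_squared: float  # NaN when fewer than 3 shared pairs
    n_unique_a: int
    n_unique_b: int
    n_unique_low_vaf_a: int
    n_unique_low_vaf_b: int
    max_alt_count_unique_a: int


def vaf_concordance(
    set_a: pd.DataFrame, set_b: pd.DataFrame, low_vaf: float = 0.10
) -> ConcordanceReport:
    """Between-run VAF concordance of two call sets.

    R^2 is the squared Pearson correlation of shared-variant VAFs (undefined,
    reported as NaN, below 3 shared pairs). Unique-variant tallies count the
    low-VAF (< 10% by default) calls on each side and the largest alternate
    read count among A-unique calls.
    """
    shared, ua, ub = match_variants(set_a, set_b)
    if len(shared) >= 3:
        v1 = shared["vaf_a"].to_numpy(dtype=float)
        v2 = shared["vaf_b"].to_numpy(dtype=float)
        if np.std(v1) == 0 or np.std(v2) == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(v1, v2)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return ConcordanceReport(
        n_shared=len(shared),
        r_squared=r2,
        n_unique_a=len(ua),
        n_unique_b=len(ub),
        n_unique_low_vaf_a=int((ua["vaf"] < low_vaf).sum()),
        n_unique_low_vaf_b=int((ub["vaf"] < low_vaf).sum()),
        max_alt_count_unique_a=int(ua["alt_count"].max()) if len(ua) else 0,
    )


def downsample_counts(calls: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Binomially thin ref/alt read counts to a depth fraction.

    Emulates resequencing at ``fraction`` of the original depth: each read is
    kept independently. VAF is recomputed (0 where no reads remain).
    Fraction 1 is the identity; fraction 0 zeroes all counts.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    out = calls.copy()
    if fraction == 1.0:
        return out
    rng = substream(seed, f"downsample/{fraction:.6f}")
    out["ref_count"] = rng.binomial(calls["ref_count"].to_numpy(dtype=int), fraction)
    out["alt_count"] = rng.binomial(calls["alt_count"].to_numpy(dtype=int), fraction)
    total = out["ref_count"] + out["alt_count"]
    out["vaf"] = np.where(total > 0, out["alt_count"] / total.replace(0, 1), 0.0)
    return out


def _detected(calls: pd.DataFrame, rule: dict) -> np.ndarray:
    return (
        (calls["alt_count"].to_numpy() >= rule["min_alt"])
        & (calls["vaf"].to_numpy() >= rule["min_vaf"])
    )


def yield_curve(
    calls: pd.DataFrame,
    fractions: list[float],
    detection_rule: dict | None = None,
    seed: int = 0,
    plateau_gain: float = 0.02,
) -> tuple[pd.DataFrame, float, float | None]:
    """Detected-variant yield as a function of sequencing depth.

    For each depth fraction the read counts are thinned and variants passing
    the detection rule counted. Returns (table, r_squared, plateau_fraction):
    the table has (fraction, mean_depth, n_detected); r_squared is of
    n_detected against mean depth; plateau_fraction is the smallest fraction
    beyond which every subsequent step adds less than ``plateau_gain`` of
    the full-depth yield (None if the curve keeps rising).
    """
    rule = detection_rule or DEFAULT_DETECTION_RULE
    rows = []
    for f in sorted(fractions):
        thinned = downsample_counts(calls, f, seed=seed)
        depth = (thinned["ref_count"] + thinned["alt_count"]).mean()
        rows.append((f, float(depth), int(_detected(thinned, rule).sum())))
    table = pd.DataFrame(rows, columns=["fraction", "mean_depth", "n_detected"])

    x = table["mean_depth"].to_numpy(dtype=float)
    y = table["n_detected"].to_numpy(dtype=float)
    if len(table) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    else:
        r2 = float("nan")

    plateau = None
    full_yield = y[-1]
    if len(table) >= 2 and full_yield > 0:
        gains = np.diff(y) / full_yield
        for i in range(len(gains)):
            if (gains[i:] < plateau_gain).all():
                plateau = float(table["fraction"].iloc[i])
                break
        if plateau is not None and plateau == table["fraction"].iloc[-1]:
            plateau = None
    return table, r2, plateau


def summarize_clonality(
    calls: pd.DataFrame, cnv_calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene VAF quantiles over variants at copy-neutral (diploid) loci.

    Variants overlapping any retained (non-neutral) CNV call of their sample
    are excluded; at a diploid locus a clonal heterozygous mutation sits near
    VAF 50%, so the median/Q1 summarize clonality. Quantiles use linear
    interpolation between order statistics. Positions are 1-based (VCF/MAF
    convention); CNV intervals are 0-based half-open.
    """
    keep = np.ones(len(calls), dtype=bool)
    non_neutral = cnv_calls[cnv_calls["state"] != "neutral"]
    per_sample = "sample_id" in non_neutral.columns
    for i, v in enumerate(calls.itertuples()):
        sub = non_neutral
        if per_sample:
            sub = sub[sub["sample_id"] == v.sample_id]
        pos0 = int(v.pos) - 1
        hit = (
            (sub["chrom"] == v.chrom) & (sub["start"] <= pos0) & (pos0 < sub["end"])
        )
        if hit.any():
            keep[i] = False
    diploid = calls[keep]
    rows = []
    for gene, grp in diploid.groupby("gene", sort=True):
        v = grp["vaf"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append((gene, len(v), float(med), float(q1), float(q3)))
    return pd.DataFrame(rows, columns=["gene", "n_variants", "median_vaf", "q1_vaf", "q3_vaf"])
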
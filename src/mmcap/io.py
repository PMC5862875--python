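"""Readers and writers for the pipeline's text formats.

All genomic intervals are 0-based half-open on disk and in memory (BED
convention); variant positions are 1-based (VCF/MAF convention) and noted as
such in the column docs. Parsers reject malformed input with the file and
line number rather than coercing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_depths",
    "write_depths",
    "read_variants",
    "write_variants",
    "read_survival",
    "write_survival",
    "load_config",
]

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sr", "pe", "sample_id", "is_normal",
]

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "effect",
    "ref_count", "alt_count", "vaf", "caller_flags", "germline_flagged",
    "in_igh", "cosmic_annotated", "deleterious_predicted",
]


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file; the name field may carry "gene|region_class|arm".

    Returns columns chrom, start, end, name and — when every name has the
    three-part form — gene, region_class, arm.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _parse_error(path, lineno, "BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            if start < 0 or start >= end:
                raise _parse_error(path, lineno, f"invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if len(df) and df["name"].str.count(r"\|").eq(2).all():
        split = df["name"].str.split("|", expand=True)
        df[["gene", "region_class", "arm"]] = split
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        if {"gene", "region_class", "arm"} <= set(out.columns):
            out["name"] = out["gene"] + "|" + out["region_class"] + "|" + out["arm"]
        else:
            out["name"] = "."
    out[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedpe(path) -> pd.DataFrame:
    """Read translocation candidates: BEDPE plus SR/PE/sample columns."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in BEDPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: BEDPE is missing columns {missing}")
    for lineno, row in enumerate(df.itertuples(), 2):
        for s, e in ((row.start1, row.end1), (row.start2, row.end2)):
            if s < 0 or s >= e:
                raise _parse_error(path, lineno, f"invalid interval [{s}, {e})")
        if row.sr < 0 or row.pe < 0:
            raise _parse_error(path, lineno, "negative SR/PE support")
    df["is_normal"] = df["is_normal"].astype(bool)
    return df


def write_bedpe(candidates: pd.DataFrame, path) -> None:
    """Write candidates; point breakpoints become 1 bp intervals."""
    df = candidates.copy()
    if "start1" not in df.columns:  # internal point-breakpoint form
        df["start1"], df["end1"] = df["pos1"], df["pos1"] + 1
        df["start2"], df["end2"] = df["pos2"], df["pos2"] + 1
        df["name"] = df.get("name", ".")
        df["score"] = df["sr"] + df["pe"]
    df[BEDPE_COLUMNS].to_csv(path, sep="\t", index=False)


def bedpe_to_candidates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse BEDPE intervals to the point-breakpoint candidate form."""
    out = df.copy()
    out["pos1"] = out["start1"]
    out["pos2"] = out["start2"]
    return out


def read_depths(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    req = ["probe_id", "chrom", "start", "end", "sample_id", "depth"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: depth table is missing columns {missing}")
    if (df["depth"] < 0).any():
        lineno = int(df.index[df["depth"] < 0][0]) + 2
        raise _parse_error(path, lineno, "negative depth")
    return df


def write_depths(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    """Read the MAF-like somatic variant table (1-based positions)."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant table is missing columns {missing}")
    for col in ("germline_flagged", "in_igh", "cosmic_annotated", "deleterious_predicted"):
        df[col] = df[col].astype(bool)
    bad = (df["vaf"] < 0) | (df["vaf"] > 1) | (df["alt_count"] < 0)
    if bad.any():
        lineno = int(df.index[bad][0]) + 2
        raise _parse_error(path, lineno, "VAF outside [0,1] or negative alt count")
    total = df["ref_count"] + df["alt_count"]
    implied = df["alt_count"] / total.where(total > 0, 1)
    off = (total > 0) & ((df["vaf"] - implied).abs() > 1e-9)
    if off.any():
        lineno = int(df.index[off][0]) + 2
        raise _parse_error(path, lineno, "vaf inconsistent with read counts")
    return df


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    req = ["sample_id", "time", "event", "group"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: survival table is missing columns {missing}")
    if (df["time"] <= 0).any():
        lineno = int(df.index[df["time"] <= 0][0]) + 2
        raise _parse_error(path, lineno, "non-positive survival time")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level",
    "cohort", "cnv", "sv", "snv", "stats",
}
_KNOWN_SUBKEYS = {
    "cohort": {
        "n_samples", "mean_depth_tumor", "mean_depth_normal", "depth_dispersion",
        "purity", "probe_count",
    },
    "cnv": {"alpha", "min_probes", "stat_threshold", "min_normal_depth",
            "min_arm_fraction", "max_components"},
    "sv": {"mode", "myc_min_separation", "annotation_window"},
    "snv": {"min_alt", "min_vaf", "fractions"},
    "stats": {"alpha", "hypermutator_iqr_factor", "panel_mb"},
}


def load_config(path) -> dict:
    """Load and validate a pipeline config (YAML). Unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for block, allowed in _KNOWN_SUBKEYS.items():
        sub = cfg.get(block) or {}
        extra = set(sub) - allowed
        if extra:
            raise ValueError(f"{path}: unknown keys in {block!r}: {sorted(extra)}")
    for block in ("cnv", "stats"):
        alpha = (cfg.get(block) or {}).get("alpha")
        if alpha is not None and not (0 < alpha < 1):
            raise ValueError(f"{path}: {block}.alpha must be in (0,1), got {alpha}")
    purity = (cfg.get("cohort") or {}).get("purity")
    if purity is not None and not (0 < purity <= 1):
        raise ValueError(f"{path}: cohort.purity must be in (0,1], got {purity}")
    return cfg
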
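"""Synthetic myeloma-cohort generator.

Emulates the inputs of a targeted-capture tumor/normal study so the analysis
stages can be exercised and validated end to end: negative-binomial per-probe
capture depths with planted clonal copy-number events at a given tumor purity,
Poisson split-read/discordant-pair support for true and artifact translocation
candidates (optionally echoed into normal samples, as capture artifacts are),
Bernoulli mutation matrices with planted pairwise log-odds interactions,
sequences with a controlled density of AID hotspot motifs, and exponential
progression times with a planted hazard ratio.

All randomness flows from a single root seed through named substreams
(:func:`mmcap._rng.substream`), so identical configuration yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .stats import find_motif_sites

__all__ = [
    "CohortConfig",
    "CnvEvent",
    "CnvTruth",
    "SvTruthSet",
    "ProbePanel",
    "make_panel",
    "simulate_depths",
    "simulate_sv_candidates",
    "simulate_mutation_matrix",
    "simulate_aid_sequence",
    "simulate_survival",
    "DEFAULT_SV_REGIONS",
]

# Mean on-target depths of the emulated study design: ~104x across tumors,
# ~107x across normals.
DEFAULT_TUMOR_DEPTH = 104.0
DEFAULT_NORMAL_DEPTH = 107.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-level parameters for the simulated cohort.

    Parameters
    ----------
    n_samples : int
        Number of tumor/normal pairs.
    mean_depth_tumor, mean_depth_normal : float
        Mean per-probe sequencing depth (reads).
    depth_dispersion : float
        Negative-binomial overdispersion ``d``; per-probe depth has variance
        ``m * (1 + d*m)``. ``d = 0`` reduces to Poisson.
    purity : float
        Tumor cell fraction in (0, 1]; scales the depth shift of planted
        copy-number events.
    probe_count : int
        Total probes to tile across the panel when the annotation does not
        fix per-gene probe counts.
    seed : int
        Root seed; every generator derives a named substream from it.
    """

    n_samples: int
    mean_depth_tumor: float = DEFAULT_TUMOR_DEPTH
    mean_depth_normal: float = DEFAULT_NORMAL_DEPTH
    depth_dispersion: float = 0.002
    purity: float = 0.8
    probe_count: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if self.mean_depth_tumor <= 0 or self.mean_depth_normal <= 0:
            raise ValueError("mean depths must be > 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if self.probe_count < 1:
            raise ValueError("probe_count must be >= 1")


@dataclass(frozen=True)
class CnvEvent:
    """A planted clonal copy-number event (total copies, half-open interval)."""

    chrom: str
    copy_number: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 2, 3, 4):
            raise ValueError("copy_number must be in {0,1,2,3,4}")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is diploid — a no-op event is disallowed")
        if self.start >= self.end:
            raise ValueError("event start must be < end")


@dataclass
class CnvTruth:
    """Planted events for one tumor sample; events may not overlap."""

    sample_id: str
    events: list[CnvEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CnvEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for evs in by_chrom.values():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping events in {self.sample_id}: {a} and {b}"
                    )


@dataclass
class SvTruthSet:
    """Truth for a simulated translocation candidate set.

    ``candidate_labels`` aligns with the candidate table rows (True = real
    somatic event); ``sample_classes`` is the FISH-like sample-level truth
    (one row per true translocation class present in a sample).
    """

    candidate_labels: np.ndarray
    sample_classes: pd.DataFrame


@dataclass
class ProbePanel:
    """Capture panel: probes with gene, region-class, and arm annotation.

    ``probes`` columns: probe_id, chrom, start, end, gene, region_class, arm.
    Intervals are 0-based half-open, sorted by (chrom, start) in the
    chromosome order of the annotation.
    """

    probes: pd.DataFrame
    chrom_order: list[str]

    def arm_probe_counts(self) -> pd.Series:
        return self.probes.groupby(["chrom", "arm"], sort=False).size()

    def __len__(self) -> int:
        return len(self.probes)


def make_panel(config: CohortConfig, annotation_spec: dict) -> ProbePanel:
    """Tile probes across the gene footprints of an annotation spec.

    ``annotation_spec`` keys:

    - ``chromosomes``: list of ``{name, length, centromere}``;
    - ``genes``: list of ``{name, chrom, start, end, region_class?, n_probes?}``
      (region_class defaults to ``"gene"``; n_probes defaults to an even split
      of ``config.probe_count`` across genes);
    - ``arms`` (optional): explicit ``{chrom, arm, start, end}`` rows
      overriding the centromere split; overlaps are a configuration error;
    - ``probe_length`` (optional, default 120).
    """
    chroms = annotation_spec.get("chromosomes", [])
    genes = annotation_spec.get("genes", [])
    if not genes:
        raise ValueError("annotation_spec has an empty gene list")
    if not chroms:
        raise ValueError("annotation_spec names no chromosomes")
    probe_length = int(annotation_spec.get("probe_length", 120))

    chrom_order = [c["name"] for c in chroms]
    chrom_info = {c["name"]: c for c in chroms}

    arm_lookup = _build_arm_lookup(annotation_spec, chrom_info)

    n_genes = len(genes)
    base = config.probe_count // n_genes
    extra = config.probe_count % n_genes

    rows = []
    for gi, g in enumerate(genes):
        if g["chrom"] not in chrom_info:
            raise ValueError(f"gene {g['name']} on unknown chromosome {g['chrom']}")
        n_probes = int(g.get("n_probes", base + (1 if gi < extra else 0)))
        if n_probes < 1:
            continue
        span = g["end"] - g["start"]
        if span <= 0:
            raise ValueError(f"gene {g['name']} has non-positive footprint")
        step = span / n_probes
        width = max(1, min(probe_length, int(step)))
        for i in range(n_probes):
            start = g["start"] + int(round(i * step))
            end = min(start + width, g["end"])
            rows.append(
                (
                    g["chrom"],
                    start,
                    end,
                    g["name"],
                    g.get("region_class", "gene"),
                    arm_lookup(g["chrom"], start),
                )
            )

    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene", "region_class", "arm"]
    )
    df["chrom"] = pd.Categorical(df["chrom"], categories=chrom_order, ordered=True)
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    # probes must not overlap within a chromosome
    same = df["chrom"].values[1:] == df["chrom"].values[:-1]
    if np.any(same & (df["start"].values[1:] < df["end"].values[:-1])):
        raise ValueError("annotation produces overlapping probes")
    df.insert(0, "probe_id", [f"p{i:06d}" for i in range(len(df))])
    return ProbePanel(probes=df, chrom_order=chrom_order)


def _build_arm_lookup(annotation_spec: dict, chrom_info: dict):
    explicit = annotation_spec.get("arms")
    if explicit:
        by_chrom: dict[str, list[dict]] = {}
        for a in explicit:
            by_chrom.setdefault(a["chrom"], []).append(a)
        for arms in by_chrom.values():
            arms.sort(key=lambda a: a["start"])
            for x, y in zip(arms, arms[1:]):
                if x["end"] > y["start"]:
                    raise ValueError(
                        f"overlapping arm definitions on {x['chrom']}: "
                        f"{x['arm']} and {y['arm']}"
                    )

        def lookup(chrom: str, pos: int) -> str:
            for a in by_chrom.get(chrom, []):
                if a["start"] <= pos < a["end"]:
                    return a["arm"]
            return "q"

        return lookup

    def lookup(chrom: str, pos: int) -> str:
        cen = chrom_info[chrom].get("centromere")
        if cen is None:
            cen = chrom_info[chrom]["length"] // 2
        return "p" if pos < cen else "q"

    return lookup


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) with variance m*(1 + d*m)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_depths(
    panel: ProbePanel, truth: CnvTruth, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw paired per-probe depth tables for one tumor/normal pair.

    Normal depth is NB(mean_depth_normal, d) at every probe. Tumor depth is
    NB(mean_depth_tumor * (purity*CN/2 + 1 - purity), d), i.e. the clonal
    copy-number shift diluted by normal-cell contamination.
    """
    probes = panel.probes
    cn = np.full(len(probes), 2.0)
    for ev in truth.events:
        on_chrom = probes["chrom"].values == ev.chrom
        if not on_chrom.any():
            raise ValueError(f"event chromosome {ev.chrom} not covered by panel")
        span_lo = probes.loc[on_chrom, "start"].min()
        span_hi = probes.loc[on_chrom, "end"].max()
        if ev.end <= span_lo or ev.start >= span_hi:
            raise ValueError(
                f"event {ev} lies outside the panel span of {ev.chrom} "
                f"[{span_lo}, {span_hi})"
            )
        hit = on_chrom & (probes["start"].values < ev.end) & (probes["end"].values > ev.start)
        cn[hit] = ev.copy_number

    p = config.purity
    tumor_mean = config.mean_depth_tumor * (p * cn / 2.0 + (1.0 - p))
    rng = substream(config.seed, f"depths/{truth.sample_id}")
    tumor_depth = _nb_draw(rng, tumor_mean, config.depth_dispersion)
    normal_depth = _nb_draw(
        rng, np.full(len(probes), config.mean_depth_normal), config.depth_dispersion
    )

    def table(depth: np.ndarray) -> pd.DataFrame:
        out = probes[["probe_id", "chrom", "start", "end"]].copy()
        out["sample_id"] = truth.sample_id
        out["depth"] = depth.astype(np.int64)
        return out

    return table(tumor_depth), table(normal_depth)


# ---------------------------------------------------------------------------
# Translocation candidates

# Region windows on a GRCh37-like coordinate frame: the IGH locus on chr14,
# canonical partner oncogene windows, the tiled MYC region on chr8, and the
# lambda light-chain locus spanning IGLL5 on chr22.
DEFAULT_SV_REGIONS = pd.DataFrame(
    [
        ("IGH", "chr14", 105_580_000, 106_880_000),
        ("t(11;14)", "chr11", 69_000_000, 69_500_000),  # CCND1
        ("t(4;14)", "chr4", 1_800_000, 2_100_000),  # WHSC1/FGFR3
        ("t(8;14)", "chr8", 128_700_000, 128_760_000),  # MYC
        ("t(6;14)", "chr6", 41_800_000, 42_100_000),  # CCND3
        ("t(14;20)", "chr20", 39_000_000, 39_500_000),  # MAFB
        ("t(14;16)", "chr16", 79_500_000, 79_900_000),  # MAF
        ("t(14;22)", "chr22", 23_200_000, 23_300_000),  # IGLL5 / lambda locus
        ("MYC", "chr8", 128_700_000, 128_760_000),
    ],
    columns=["label", "chrom", "start", "end"],
)

_TRUE_CLASSES = [
    "t(11;14)",
    "t(4;14)",
    "t(8;14)",
    "t(6;14)",
    "t(14;20)",
    "t(14;16)",
    "t(14;22)",
]

_ARTIFACT_CHROMS = ["chr1", "chr2", "chr3", "chr5", "chr7", "chr9", "chr10", "chr12"]


def _canonical_pair(c1: str, p1: int, c2: str, p2: int) -> tuple[str, int, str, int]:
    def key(c: str) -> tuple[int, str]:
        s = c.removeprefix("chr")
        return (0, f"{int(s):02d}") if s.isdigit() else (1, s)

    if (key(c1), p1) <= (key(c2), p2):
        return c1, p1, c2, p2
    return c2, p2, c1, p1


def simulate_sv_candidates(
    n_true: int,
    n_artifact: int,
    true_sr_rate: float,
    true_pe_rate: float,
    artifact_sr_rate: float,
    artifact_pe_rate: float,
    include_normals: bool = False,
    seed: int = 0,
    n_samples: int = 10,
    region_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SvTruthSet]:
    """Simulate translocation candidates with Poisson read support.

    True candidates cycle through the canonical IGH partner classes with one
    breakpoint in the IGH window and one in the partner window; artifacts get
    random non-recurrent breakpoints. With ``include_normals``, artifact
    candidates are additionally emitted for (non-tumor) normal samples,
    mimicking the recurrent capture artifacts a panel of normals reveals.
    """
    for name, rate in [
        ("true_sr_rate", true_sr_rate),
        ("true_pe_rate", true_pe_rate),
        ("artifact_sr_rate", artifact_sr_rate),
        ("artifact_pe_rate", artifact_pe_rate),
    ]:
        if rate <= 0:
            raise ValueError(f"{name} must be > 0")
    regions = DEFAULT_SV_REGIONS if region_table is None else region_table
    reg = {r.label: r for r in regions.itertuples()}
    rng = substream(seed, "sv_candidates")

    rows = []
    labels = []
    sample_rows = []
    for i in range(n_true):
        cls = _TRUE_CLASSES[i % len(_TRUE_CLASSES)]
        sample = f"S{i % n_samples:03d}"
        igh = reg["IGH"]
        partner = reg[cls]
        pa = int(rng.integers(igh.start, igh.end))
        pb = int(rng.integers(partner.start, partner.end))
        c1, p1, c2, p2 = _canonical_pair(igh.chrom, pa, partner.chrom, pb)
        rows.append(
            dict(
                chrom1=c1, pos1=p1, strand1="+",
                chrom2=c2, pos2=p2, strand2="-",
                sr=int(rng.poisson(true_sr_rate)),
                pe=int(rng.poisson(true_pe_rate)),
                sample_id=sample, is_normal=False,
            )
        )
        labels.append(True)
        sample_rows.append((sample, cls))

    def artifact_row(sample: str, is_normal: bool) -> dict:
        c1 = _ARTIFACT_CHROMS[int(rng.integers(len(_ARTIFACT_CHROMS)))]
        c2 = _ARTIFACT_CHROMS[int(rng.integers(len(_ARTIFACT_CHROMS)))]
        p1 = int(rng.integers(1_000_000, 100_000_000))
        p2 = int(rng.integers(1_000_000, 100_000_000))
        c1, p1, c2, p2 = _canonical_pair(c1, p1, c2, p2)
        return dict(
            chrom1=c1, pos1=p1, strand1="+",
            chrom2=c2, pos2=p2, strand2="-",
            sr=int(rng.poisson(artifact_sr_rate)),
            pe=int(rng.poisson(artifact_pe_rate)),
            sample_id=sample, is_normal=is_normal,
        )

    for i in range(n_artifact):
        rows.append(artifact_row(f"S{i % n_samples:03d}", False))
        labels.append(False)
    if include_normals:
        for i in range(n_artifact):
            rows.append(artifact_row(f"N{i % n_samples:03d}", True))
            labels.append(False)

    candidates = pd.DataFrame(
        rows,
        columns=[
            "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
            "sr", "pe", "sample_id", "is_normal",
        ],
    )
    truth = SvTruthSet(
        candidate_labels=np.asarray(labels, dtype=bool),
        sample_classes=pd.DataFrame(sample_rows, columns=["sample_id", "class"])
        .drop_duplicates()
        .reset_index(drop=True),
    )
    return candidates, truth


# ---------------------------------------------------------------------------
# Mutation matrix


def _joint_from_odds(p_a: float, p_b: float, log_odds: float) -> float:
    """P(A=1, B=1) for given marginals and log odds ratio (Plackett family)."""
    lower = max(0.0, p_a + p_b - 1.0)
    upper = min(p_a, p_b)
    if np.isneginf(log_odds):
        if lower > 0:
            raise ValueError(
                "infeasible: hard exclusivity (log-odds -inf) requires "
                f"p_a + p_b <= 1; feasible co-occurrence lower bound is {lower:.4f}"
            )
        return 0.0
    if np.isposinf(log_odds):
        return upper
    psi = float(np.exp(log_odds))
    if psi == 1.0:
        return p_a * p_b
    s = 1.0 + (p_a + p_b) * (psi - 1.0)
    disc = s * s - 4.0 * psi * (psi - 1.0) * p_a * p_b
    p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    return float(min(max(p11, lower), upper))


def simulate_mutation_matrix(
    marginal_freqs: dict[str, float],
    interactions: list[tuple[str, str, float]],
    n_samples: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a binary samples x features matrix with planted pairwise log-odds.

    Interacting pairs are drawn from the 2x2 joint matching their marginals
    and odds ratio; every other feature is independent Bernoulli. A feature
    may appear in at most one interaction.
    """
    for f, p in marginal_freqs.items():
        if not (0.0 < p < 1.0):
            raise ValueError(f"marginal for {f} must be in (0,1), got {p}")
    seen: set[str] = set()
    for a, b, _ in interactions:
        if a == b:
            raise ValueError("interaction features must be distinct")
        for f in (a, b):
            if f not in marginal_freqs:
                raise ValueError(f"interaction names unknown feature {f}")
            if f in seen:
                raise ValueError(f"feature {f} appears in more than one interaction")
            seen.add(f)

    rng = substream(seed, "mutation_matrix")
    features = list(marginal_freqs)
    data = {}
    for a, b, lo in interactions:
        p_a, p_b = marginal_freqs[a], marginal_freqs[b]
        p11 = _joint_from_odds(p_a, p_b, lo)
        probs = [1.0 - p_a - p_b + p11, p_b - p11, p_a - p11, p11]  # 00,01,10,11
        cells = rng.choice(4, size=n_samples, p=np.clip(probs, 0, None) / np.sum(np.clip(probs, 0, None)))
        data[a] = (cells >= 2).astype(np.int8)
        data[b] = (cells % 2 == 1).astype(np.int8)
    for f in features:
        if f not in data:
            data[f] = (rng.random(n_samples) < marginal_freqs[f]).astype(np.int8)

    idx = pd.Index([f"S{i:03d}" for i in range(n_samples)], name="sample_id")
    return pd.DataFrame({f: data[f] for f in features}, index=idx)


# ---------------------------------------------------------------------------
# AID signature sequences

_BASES = np.array(list("ACGT"))


def simulate_aid_sequence(
    length: int,
    target_wrcy_density: float,
    n_mutations: int,
    aid_fraction: float,
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Build a sequence with a controlled AID hotspot density plus mutations.

    WRCY motifs (and their reverse-complement RGYW) are planted until the
    hotspot density reaches ``target_wrcy_density`` sites per base. A fraction
    ``aid_fraction`` of the ``n_mutations`` emitted variants are AID-type
    deaminations (C>T/C>G at a motif C, or G>A/G>C at a motif G on the
    reverse strand); the remainder fall uniformly on non-motif positions.
    """
    if not (0.0 <= aid_fraction <= 1.0):
        raise ValueError("aid_fraction must be in [0,1]")
    rng = substream(seed, "aid_sequence")
    seq = rng.choice(_BASES, size=length)

    w = np.array(list("AT"))
    r = np.array(list("AG"))
    y = np.array(list("CT"))

    def motif_positions() -> np.ndarray:
        sites = find_motif_sites("".join(seq))
        return np.array([s.position for s in sites], dtype=int)

    target_sites = int(np.ceil(target_wrcy_density * length))
    attempts = 0
    # plant in deficit-sized batches so the full-sequence motif scan runs once
    # per batch rather than once per planted 4-mer
    while attempts < 20 * max(target_sites, 1):
        deficit = target_sites - len(motif_positions())
        if deficit <= 0:
            break
        for i in rng.integers(0, length - 4, size=deficit):
            i = int(i)
            seq[i : i + 4] = [rng.choice(w), rng.choice(r), "C", rng.choice(y)]
        attempts += deficit

    sites = find_motif_sites("".join(seq))
    site_pos = np.array(sorted({s.position for s in sites}), dtype=int)
    strand_of = {s.position: s.strand for s in sites}

    n_aid = int(round(aid_fraction * n_mutations))
    n_bg = n_mutations - n_aid
    if n_aid > len(site_pos):
        raise ValueError(
            f"n_mutations requires {n_aid} AID sites but only {len(site_pos)} exist"
        )
    non_sites = np.setdiff1d(np.arange(length), site_pos)
    if n_bg > len(non_sites):
        raise ValueError("n_mutations exceeds available non-motif positions")

    rows = []
    for pos in rng.choice(site_pos, size=n_aid, replace=False):
        pos = int(pos)
        ref = seq[pos]
        if strand_of[pos] == "+":
            alt = rng.choice(["T", "G"])  # C deamination footprint
        else:
            alt = rng.choice(["A", "C"])  # G on reverse strand
        rows.append((pos, ref, alt, True))
    for pos in rng.choice(non_sites, size=n_bg, replace=False):
        pos = int(pos)
        ref = seq[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        rows.append((pos, ref, alt, False))

    variants = pd.DataFrame(rows, columns=["pos", "ref", "alt", "is_aid"]).sort_values(
        "pos", kind="mergesort"
    ).reset_index(drop=True)
    return "".join(seq), variants


# ---------------------------------------------------------------------------
# Survival


def simulate_survival(
    matrix: pd.DataFrame,
    feature: str,
    hazard_ratio: float,
    baseline_rate: float,
    censor_rate: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential progression times with a planted hazard ratio.

    Event rate is ``baseline_rate * hazard_ratio**x`` where x is the sample's
    binary feature status; censoring is an independent exponential clock.
    Returns a table (sample_id, time, event, group) with group mutant/WT.
    """
    if baseline_rate <= 0 or hazard_ratio <= 0:
        raise ValueError("rates must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    if feature not in matrix.columns:
        raise ValueError(f"feature {feature!r} not in matrix")
    x = matrix[feature].to_numpy().astype(int)
    rng = substream(seed, "survival")
    rate = baseline_rate * hazard_ratio**x
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_censor = rng.exponential(1.0 / censor_rate, size=len(x))
    else:
        t_censor = np.full(len(x), np.inf)
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    return pd.DataFrame(
        {
            "sample_id": matrix.index.astype(str),
            "time": time,
            "event": event.astype(int),
            "group": np.where(x == 1, "mutant", "WT"),
        }
    )
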
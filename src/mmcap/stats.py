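"""Cohort-level integrative statistics.

Builds the samples x features mutation matrix spanning point mutations,
arm-level copy-number events, and translocations; tests pairwise
co-occurrence and mutual exclusivity with Fisher's exact test; quantifies the
activation-induced cytidine deaminase (AID) hypermutation signature at
WRCY/RGYW hotspot motifs with an exact binomial test; flags expression
outliers by the upper Tukey fence; and provides Kaplan-Meier, log-rank, and
single-covariate Cox proportional-hazards analysis of time to progression.

The survival estimators are implemented here rather than delegated, so that
the package's oracle tests (hand-computed product limits, permutation nulls,
grid-search partial likelihood) exercise the actual code paths.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "NON_SYNONYMOUS_EFFECTS",
    "MotifSite",
    "AssociationResult",
    "SignatureTestResult",
    "build_matrix",
    "mutation_burden",
    "exclude_hypermutators",
    "pairwise_association",
    "fisher_exact_1x",
    "find_motif_sites",
    "aid_signature_test",
    "expression_outliers",
    "km_curve",
    "logrank_test",
    "cox_hr",
]

#: Effect classes that count as protein-altering when building gene features.
NON_SYNONYMOUS_EFFECTS = frozenset(
    {"missense", "nonsense", "frameshift_ins", "frameshift_del", "splice"}
)


# ---------------------------------------------------------------------------
# Mutation matrix


def build_matrix(
    variant_calls: pd.DataFrame,
    cnv_arm_events: pd.DataFrame | None,
    translocation_calls: pd.DataFrame | None,
    feature_spec: dict,
) -> pd.DataFrame:
    """Assemble the binary samples x features mutation matrix.

    ``feature_spec`` keys:

    - ``samples``: ordered sample ids (columns of the study);
    - ``snv_genes``: genes scored 1 when the sample has >= 1 protein-altering
      call (effect in :data:`NON_SYNONYMOUS_EFFECTS`);
    - ``cnv_arms`` (optional): list of (chrom, arm, direction) triples scored
      from the arm-event table;
    - ``translocations`` (optional): class labels scored from the
      translocation call table (columns sample_id, class);
    - ``composites`` (optional): mapping name -> list of member features,
      recomputed as the OR of the members (e.g. RAS = KRAS | NRAS).

    Returns a 0/1 DataFrame indexed by sample with a ``feature_type`` row
    annotation stored in ``attrs``.
    """
    samples = list(feature_spec["samples"])
    idx = pd.Index(samples, name="sample_id")
    cols: dict[str, np.ndarray] = {}
    ftype: dict[str, str] = {}

    snv_genes = feature_spec.get("snv_genes", [])
    if snv_genes:
        ns = variant_calls[variant_calls["effect"].isin(NON_SYNONYMOUS_EFFECTS)]
        hit = ns.groupby(["sample_id", "gene"]).size()
        for g in snv_genes:
            cols[g] = np.array(
                [int((s, g) in hit.index) for s in samples], dtype=np.int8
            )
            ftype[g] = "snv_gene"

    for chrom, arm, direction in feature_spec.get("cnv_arms", []):
        name = f"{'amp' if direction == 'gain' else 'del'}({chrom.removeprefix('chr')}{arm})"
        if cnv_arm_events is not None and len(cnv_arm_events):
            sub = cnv_arm_events[
                (cnv_arm_events["chrom"] == chrom)
                & (cnv_arm_events["arm"] == arm)
                & (cnv_arm_events["event"] == direction)
            ]
            carriers = set(sub["sample_id"])
        else:
            carriers = set()
        cols[name] = np.array([int(s in carriers) for s in samples], dtype=np.int8)
        ftype[name] = "cnv_arm"

    for label in feature_spec.get("translocations", []):
        if translocation_calls is not None and len(translocation_calls):
            carriers = set(
                translocation_calls.loc[
                    translocation_calls["class"] == label, "sample_id"
                ]
            )
        else:
            carriers = set()
        cols[label] = np.array([int(s in carriers) for s in samples], dtype=np.int8)
        ftype[label] = "translocation"

    matrix = pd.DataFrame(cols, index=idx, dtype=np.int8)
    # composites are ORs of their members, recomputed from the member columns
    for name, members in feature_spec.get("composites", {}).items():
        missing = [m for m in members if m not in matrix.columns]
        if missing:
            raise ValueError(f"composite {name} references unknown features {missing}")
        matrix[name] = (matrix[members].sum(axis=1) > 0).astype(np.int8)
        ftype[name] = "composite"

    matrix.attrs["feature_type"] = ftype
    matrix.attrs["composites"] = dict(feature_spec.get("composites", {}))
    return matrix


def mutation_burden(
    variant_calls: pd.DataFrame, samples: list[str], panel_mb: float
) -> pd.Series:
    """Mutations per megabase of panel footprint, per sample."""
    if panel_mb <= 0:
        raise ValueError("panel_mb must be > 0")
    counts = variant_calls.groupby("sample_id").size()
    return pd.Series(
        [counts.get(s, 0) / panel_mb for s in samples], index=samples, name="burden"
    )


def exclude_hypermutators(
    matrix: pd.DataFrame, burden: pd.Series, iqr_factor: float = 3.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose burden exceeds the Q3 + ``iqr_factor``*IQR fence.

    Hypermutators inflate every pairwise 2x2 table's co-occurrence cell and
    sap power from the exclusivity tests, so they are removed before testing.
    Returns the reduced matrix and the dropped sample ids.
    """
    b = burden.reindex(matrix.index)
    q1, q3 = np.percentile(b.to_numpy(dtype=float), [25, 75])
    fence = q3 + iqr_factor * (q3 - q1)
    dropped = list(matrix.index[b > fence])
    if dropped:
        logger.info("excluding %d hypermutator sample(s): %s", len(dropped), dropped)
    return matrix.drop(index=dropped), dropped


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_1x(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """One-sided Fisher p-values for a 2x2 table, by hypergeometric tail sums.

    Table layout: a = both features present, b = only feature B, c = only
    feature A, d = neither. Conditional on the margins, the count ``a``
    follows a hypergeometric distribution; the co-occurrence p-value is
    P(X >= a) and the exclusivity p-value is P(X <= a).

    Returns (odds_ratio, p_cooccur, p_exclusive); odds ratio is NaN for a
    degenerate (zero-margin) table, where both p-values are 1.
    """
    n = a + b + c + d
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return float("nan"), 1.0, 1.0
    # X = count in the (A,B) cell given margins: Hypergeom(N=n, K=a+c, n=a+b)
    dist = sps.hypergeom(n, a + c, a + b)
    lo = max(0, (a + b) + (a + c) - n)
    hi = min(a + b, a + c)
    pmf = dist.pmf(np.arange(lo, hi + 1))
    k = a - lo
    p_co = float(np.sum(pmf[k:]))
    p_ex = float(np.sum(pmf[: k + 1]))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, min(p_co, 1.0), min(p_ex, 1.0)


@dataclass(frozen=True)
class AssociationResult:
    feature_a: str
    feature_b: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_cooccur: float
    p_exclusive: float
    direction: str  # "cooccur" | "exclusive" | "none"


def pairwise_association(
    matrix: pd.DataFrame,
    feature_subset: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact test for every feature pair of the mutation matrix.

    Raw one-sided p-values in both directions are primary; a
    Benjamini-Hochberg column over min(p) is appended for reference.
    Zero-variance features are skipped (logged).
    """
    feats = list(feature_subset) if feature_subset is not None else list(matrix.columns)
    usable = []
    for f in feats:
        col = matrix[f].to_numpy()
        if col.min() == col.max():
            logger.info("skipping zero-variance feature %s", f)
        else:
            usable.append(f)

    rows = []
    n = len(matrix)
    for i, fa in enumerate(usable):
        xa = matrix[fa].to_numpy().astype(bool)
        for fb in usable[i + 1 :]:
            xb = matrix[fb].to_numpy().astype(bool)
            a = int(np.sum(xa & xb))
            b = int(np.sum(~xa & xb))
            c = int(np.sum(xa & ~xb))
            d = n - a - b - c
            odds, p_co, p_ex = fisher_exact_1x(a, b, c, d)
            if min(p_co, p_ex) < alpha:
                direction = "cooccur" if p_co < p_ex else "exclusive"
            else:
                direction = "none"
            rows.append(
                AssociationResult(fa, fb, a, b, c, d, odds, p_co, p_ex, direction)
            )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out):
        p_min = out[["p_cooccur", "p_exclusive"]].min(axis=1)
        out["p_bh"] = multipletests(p_min, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# AID hypermutation signature

# WRCY with the deaminated C third (forward), RGYW with the G second (reverse
# strand of WRCY). W={A,T}, R={A,G}, Y={C,T}. Lookahead so overlaps all match.
_WRCY = re.compile(r"(?=([AT][AG]C[CT]))")
_RGYW = re.compile(r"(?=([AG]G[CT][AT]))")


@dataclass(frozen=True)
class MotifSite:
    position: int  # 0-based index of the mutable C (forward) or G (reverse)
    strand: str  # "+" for WRCY C, "-" for RGYW G


def find_motif_sites(sequence: str) -> list[MotifSite]:
    """All AID hotspot positions in a sequence, both strands, overlaps kept."""
    seq = sequence.upper()
    sites = [MotifSite(m.start() + 2, "+") for m in _WRCY.finditer(seq)]
    sites += [MotifSite(m.start() + 1, "-") for m in _RGYW.finditer(seq)]
    return sorted(sites, key=lambda s: (s.position, s.strand))


@dataclass(frozen=True)
class SignatureTestResult:
    n_mutations: int
    n_at_motif: int
    background_p: float
    p_value: float


def aid_signature_test(variants: pd.DataFrame, sequence: str) -> SignatureTestResult:
    """Exact binomial test for AID-signature enrichment.

    A variant counts toward the signature when it is C>T or C>G at the C of a
    WRCY motif, or G>A/G>C at the G of an RGYW motif (the reverse-strand
    footprint). The null probability is the fraction of C/G positions in the
    footprint that sit in a motif context; the p-value is the one-sided upper
    binomial tail P(X >= observed).
    """
    seq = sequence.upper()
    cg_total = seq.count("C") + seq.count("G")
    if cg_total == 0:
        raise ValueError("sequence has no C/G positions; background undefined")
    sites = find_motif_sites(seq)
    motif_by_pos: dict[int, set[str]] = {}
    for s in sites:
        motif_by_pos.setdefault(s.position, set()).add(s.strand)
    background_p = len(motif_by_pos) / cg_total

    n = len(variants)
    n_at = 0
    for v in variants.itertuples():
        strands = motif_by_pos.get(int(v.pos), set())
        if v.ref == "C" and v.alt in ("T", "G") and "+" in strands:
            n_at += 1
        elif v.ref == "G" and v.alt in ("A", "C") and "-" in strands:
            n_at += 1
    # P(X >= n_at) with X ~ Binomial(n, background_p)
    p_value = 1.0 if n_at == 0 else float(sps.binom.sf(n_at - 1, n, background_p))
    return SignatureTestResult(n, n_at, background_p, min(p_value, 1.0))


# ---------------------------------------------------------------------------
# Expression outliers


def expression_outliers(values: pd.Series, iqr_factor: float = 1.5) -> pd.Series:
    """Upper-tail Tukey fence: flag values above Q3 + ``iqr_factor``*IQR.

    Upper-tail only, matching the overexpression reading of outlier calls;
    quantiles use linear interpolation between order statistics.
    """
    v = values.to_numpy(dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    fence = q3 + iqr_factor * (q3 - q1)
    return pd.Series(v > fence, index=values.index, name="outlier")


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier, log-rank, Cox


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    req = {"time", "event"}
    if not req <= set(records.columns):
        raise ValueError(f"survival records need columns {sorted(req)}")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    return records


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns one row per distinct event time: time, n_risk, n_events,
    n_censored (censorings in [previous event time, time)), survival.
    With no censoring this equals the empirical survival function.
    """
    rec = _check_records(records).sort_values("time", kind="mergesort")
    times = rec["time"].to_numpy(dtype=float)
    events = rec["event"].to_numpy(dtype=bool)
    n = len(rec)
    out = []
    s = 1.0
    for t in np.unique(times[events]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / at_risk
        out.append((t, at_risk, d, s))
    return pd.DataFrame(out, columns=["time", "n_risk", "n_events", "survival"])


def logrank_test(records: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; records must carry a ``group`` column.

    Returns (chi-square statistic on 1 df, p-value).
    """
    rec = _check_records(records)
    groups = rec["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {list(groups)}")
    g = (rec["group"] == groups[0]).to_numpy()
    times = rec["time"].to_numpy(dtype=float)
    events = rec["event"].to_numpy(dtype=bool)

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & g).sum())
        e1 = d * n1 / n_t
        o_minus_e += d1 - e1
        if n_t > 1:
            var += d * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d) / (n_t - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    estimable: bool


def cox_hr(records: pd.DataFrame, max_iter: int = 50, tol: float = 1e-10) -> CoxResult:
    """Cox proportional hazards for one binary covariate (Breslow ties).

    The partial likelihood is maximized by Newton iteration on the log hazard
    ratio; the 95% CI is Wald. When either group has no events the estimate
    diverges and the result is flagged non-estimable.
    """
    rec = _check_records(records)
    if "group" in rec.columns and "x" not in rec.columns:
        groups = sorted(rec["group"].unique())
        if len(groups) != 2:
            raise ValueError("need exactly 2 groups")
        # convention: "mutant" (or the second sorted label) is the exposed arm
        exposed = "mutant" if "mutant" in groups else groups[1]
        x = (rec["group"] == exposed).to_numpy(dtype=float)
    else:
        x = rec["x"].to_numpy(dtype=float)
    times = rec["time"].to_numpy(dtype=float)
    events = rec["event"].to_numpy(dtype=bool)

    if events[x == 1].sum() == 0 or events[x == 0].sum() == 0:
        return CoxResult(float("nan"), float("nan"), float("nan"), float("nan"),
                         float("nan"), estimable=False)

    order = np.argsort(-times, kind="mergesort")  # descending: risk sets by cumsum
    times, events, x = times[order], events[order], x[order]

    event_times, inv = np.unique(times[events], return_inverse=True)

    def loglik_terms(beta: float):
        w = np.exp(beta * x)
        cum_w = np.cumsum(w)
        cum_wx = np.cumsum(w * x)
        ll = 0.0
        grad = 0.0
        hess = 0.0
        # Breslow: for each distinct event time, the risk set is everyone with
        # time >= t; in descending order that is a prefix ending at the last
        # index with that time.
        idx_of_time = {}
        for i, t in enumerate(times):
            idx_of_time[t] = i  # last occurrence wins (descending sort)
        for t in event_times:
            j = idx_of_time[t]
            s0 = cum_w[j]
            s1 = cum_wx[j]
            at_t = events & (times == t)
            d = int(at_t.sum())
            sx = float(x[at_t].sum())
            ll += beta * sx - d * np.log(s0)
            grad += sx - d * s1 / s0
            hess += -d * (s1 / s0) * (1 - s1 / s0)
        return ll, grad, hess

    beta = 0.0
    last_ll = -np.inf
    info = 0.0
    for _ in range(max_iter):
        ll, grad, hess = loglik_terms(beta)
        if hess == 0:
            break
        step = -grad / hess
        beta_new = beta + np.clip(step, -2.0, 2.0)
        info = -hess
        if abs(beta_new - beta) < tol and ll >= last_ll - 1e-12:
            beta = beta_new
            break
        beta, last_ll = beta_new, ll
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # a near-flat likelihood gives an inf CI
        ci_low, ci_high = float(np.exp(beta - z * se)), float(np.exp(beta + z * se))
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=ci_low,
        ci_high=ci_high,
        log_hr=float(beta),
        se=se,
        estimable=True,
    )
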
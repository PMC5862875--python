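"""Copy-number calling from targeted-capture depth ratios.

The pipeline mirrors how clonal CNVs present in paired tumor/normal capture
data: a single-copy gain sits at a log2 depth ratio of log2(3/2) = 0.58 and a
heterozygous loss at log2(1/2) = -1, with purity shrinking both toward 0.
Probes are reduced to median-centered log2 tumor/normal ratios, segmented by
recursive binary splitting on a mean-shift t-statistic, and filtered against
a diploid noise band estimated by a Gaussian mixture model: a segment is a
call only when its mean ratio falls outside the band and its tail probability
under the diploid component is small. Arm-level events and hyperdiploidy
(trisomies of the odd-numbered chromosomes) are derived from the calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "LogRatioTrack",
    "NoiseModel",
    "DiploidNoiseModel",
    "RatioSegmenter",
    "compute_log2_ratios",
    "segment_track",
    "fit_noise_model",
    "filter_segments",
    "call_arm_events",
    "detect_hyperdiploidy",
    "STATE_CUTPOINTS",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

#: mean log2-ratio cut-points bracketing the clonal landmarks log2(1/2) = -1
#: and log2(3/2) = 0.58 with margin for purity below 1.
STATE_CUTPOINTS = {"homozygous_loss": -1.6, "amplification": 1.0}

ODD_CHROMS = ["chr3", "chr5", "chr7", "chr9", "chr11", "chr15", "chr19", "chr21"]
ACROCENTRIC = {"chr13", "chr14", "chr15", "chr21", "chr22"}


@dataclass
class LogRatioTrack:
    """Per-probe log2 tumor/normal depth ratios for one sample.

    ``probes`` columns: probe_id, chrom, start, end, arm, tumor_depth,
    normal_depth, log2_ratio, masked. Masked probes (normal depth below the
    floor) carry NaN ratios and are excluded from all downstream statistics.
    """

    probes: pd.DataFrame
    normalization_factor: float
    sample_id: str = ""

    def unmasked(self) -> pd.DataFrame:
        return self.probes[~self.probes["masked"]]


def compute_log2_ratios(
    tumor_depths: pd.DataFrame,
    normal_depths: pd.DataFrame,
    min_normal_depth: int = 10,
    pseudocount: float = 0.5,
    panel=None,
) -> LogRatioTrack:
    """Median-centered log2 tumor/normal depth ratio per probe.

    The raw ratio is log2((t + eps) / (n + eps)) with a pseudo-count eps; the
    autosomal median of the raw ratios (over unmasked probes) is subtracted
    so a diploid genome centers at 0. Probes with normal depth below
    ``min_normal_depth`` are masked. When a :class:`ProbePanel` is supplied
    its arm labels are carried onto the track.
    """
    for col in ("probe_id", "chrom", "start", "end", "depth"):
        for name, df in [("tumor", tumor_depths), ("normal", normal_depths)]:
            if col not in df.columns:
                raise ValueError(f"{name} depth table lacks column {col!r}")
    t = tumor_depths.reset_index(drop=True)
    n = normal_depths.reset_index(drop=True)
    if len(t) != len(n) or not (t["probe_id"].values == n["probe_id"].values).all():
        mism = None
        ids_t, ids_n = list(t["probe_id"]), list(n["probe_id"])
        for i in range(max(len(ids_t), len(ids_n))):
            a = ids_t[i] if i < len(ids_t) else "<missing>"
            b = ids_n[i] if i < len(ids_n) else "<missing>"
            if a != b:
                mism = (i, a, b)
                break
        raise ValueError(
            f"tumor/normal probe sets differ; first mismatch at row "
            f"{mism[0]}: tumor={mism[1]!r} normal={mism[2]!r}"
        )

    td = t["depth"].to_numpy(dtype=float)
    nd = n["depth"].to_numpy(dtype=float)
    raw = np.log2((td + pseudocount) / (nd + pseudocount))
    masked = nd < min_normal_depth
    autosomal = ~t["chrom"].isin(SEX_CHROMS).to_numpy()
    usable = autosomal & ~masked
    if not usable.any():
        raise ValueError("no unmasked autosomal probes to normalize against")
    m = float(np.median(raw[usable]))
    lr = raw - m
    lr[masked] = np.nan

    probes = t[["probe_id", "chrom", "start", "end"]].copy()
    if panel is not None:
        arm_map = panel.probes.set_index("probe_id")["arm"]
        probes["arm"] = probes["probe_id"].map(arm_map).fillna(".")
    else:
        probes["arm"] = "."
    probes["tumor_depth"] = td
    probes["normal_depth"] = nd
    probes["log2_ratio"] = lr
    probes["masked"] = masked
    sample = str(t["sample_id"].iloc[0]) if "sample_id" in t.columns and len(t) else ""
    return LogRatioTrack(probes=probes, normalization_factor=m, sample_id=sample)


# ---------------------------------------------------------------------------
# Segmentation


class RatioSegmenter(BaseEstimator):
    """Recursive binary segmentation of a 1-D signal on mean shift.

    At each step the candidate breakpoint maximizing the pooled two-sample
    t-statistic between left and right means is found; the split is accepted
    when the statistic exceeds ``stat_threshold`` and both sides keep at
    least ``min_probes`` points. Fitting exposes ``breakpoints_`` (sorted
    split indices: a breakpoint at k separates x[:k] from x[k:]) and
    ``segments_`` (half-open index pairs partitioning the signal).
    """

    def __init__(self, min_probes: int = 10, stat_threshold: float = 5.0):
        self.min_probes = min_probes
        self.stat_threshold = stat_threshold

    def _best_split(self, x: np.ndarray) -> tuple[int, float]:
        n = len(x)
        k = np.arange(self.min_probes, n - self.min_probes + 1)
        if len(k) == 0:
            return -1, 0.0
        cs = np.cumsum(x)
        css = np.cumsum(x * x)
        total, total_sq = cs[-1], css[-1]
        left_n = k.astype(float)
        right_n = n - left_n
        left_sum = cs[k - 1]
        left_sq = css[k - 1]
        mean_l = left_sum / left_n
        mean_r = (total - left_sum) / right_n
        ss_l = left_sq - left_n * mean_l**2
        ss_r = (total_sq - left_sq) - right_n * mean_r**2
        pooled = (ss_l + ss_r) / np.maximum(n - 2, 1)
        pooled = np.maximum(pooled, 1e-12)
        t = np.abs(mean_r - mean_l) / np.sqrt(pooled * (1 / left_n + 1 / right_n))
        j = int(np.argmax(t))
        return int(k[j]), float(t[j])

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if np.isnan(x).any():
            raise ValueError("signal contains NaN; mask probes upstream")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        breakpoints: list[int] = []
        if len(x) < self.min_probes:
            warnings.warn(
                f"signal shorter than min_probes ({len(x)} < {self.min_probes}); "
                "returning a single segment",
                stacklevel=2,
            )
        else:
            stack = [(0, len(x))]
            while stack:
                lo, hi = stack.pop()
                if hi - lo < 2 * self.min_probes:
                    continue
                split, t = self._best_split(x[lo:hi])
                if split > 0 and t > self.stat_threshold:
                    breakpoints.append(lo + split)
                    stack.append((lo, lo + split))
                    stack.append((lo + split, hi))
        self.breakpoints_ = sorted(breakpoints)
        bounds = [0, *self.breakpoints_, len(x)]
        self.segments_ = list(zip(bounds[:-1], bounds[1:]))
        self.n_features_in_ = 1
        return self

    def predict(self, X=None) -> np.ndarray:
        """Segment label per input point of the fitted signal."""
        labels = np.empty(self.segments_[-1][1], dtype=int)
        for i, (lo, hi) in enumerate(self.segments_):
            labels[lo:hi] = i
        return labels


def segment_track(
    track: LogRatioTrack, min_probes: int = 10, stat_threshold: float = 5.0
) -> pd.DataFrame:
    """Partition each chromosome's unmasked probes into mean-shift segments.

    Returns a table (chrom, start, end, n_probes, mean_lr) where start/end
    are the genomic bounds of the first/last probe in the segment.
    """
    seg_rows = []
    probes = track.unmasked()
    segmenter = RatioSegmenter(min_probes=min_probes, stat_threshold=stat_threshold)
    for chrom, grp in probes.groupby("chrom", sort=False):
        x = grp["log2_ratio"].to_numpy()
        if len(x) == 0:
            continue
        segs = segmenter.fit(x).segments_
        for lo, hi in segs:
            sub = grp.iloc[lo:hi]
            seg_rows.append(
                (
                    chrom,
                    int(sub["start"].iloc[0]),
                    int(sub["end"].iloc[-1]),
                    hi - lo,
                    float(sub["log2_ratio"].mean()),
                )
            )
    return pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "n_probes", "mean_lr"])


# ---------------------------------------------------------------------------
# Gaussian-mixture noise model


@dataclass
class NoiseModel:
    """Fitted diploid-noise description of a log-ratio track.

    ``components`` is a list of (weight, mean, sd); the diploid component is
    the one with mean nearest 0, and the noise band is its mean plus/minus
    z_{1-alpha/2} standard deviations.
    """

    components: list[tuple[float, float, float]]
    diploid_index: int
    band_low: float
    band_high: float
    alpha: float

    @property
    def diploid_mean(self) -> float:
        return self.components[self.diploid_index][1]

    @property
    def diploid_sd(self) -> float:
        return self.components[self.diploid_index][2]


class DiploidNoiseModel(BaseEstimator):
    """Univariate Gaussian mixture fitted by EM, K selected by BIC.

    Used to estimate the diploid noise level of a log-ratio track: the
    component with mean nearest 0 is taken as diploid, and the noise band
    ``[band_low_, band_high_]`` spans z_{1-alpha/2} diploid standard
    deviations. EM restarts from k-means++-style initial means; the
    log-likelihood is non-decreasing across iterations (exposed in
    ``loglik_history_``). Zero-variance data is handled by flooring
    component standard deviations at ``sd_floor``.
    """

    def __init__(
        self,
        max_components: int = 3,
        alpha: float = 0.05,
        n_restarts: int = 3,
        max_iter: int = 200,
        tol: float = 1e-8,
        sd_floor: float = 1e-4,
        random_state: int | None = 0,
    ):
        self.max_components = max_components
        self.alpha = alpha
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.sd_floor = sd_floor
        self.random_state = random_state

    def _init_means(self, x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        # k-means++-style: spread initial means by squared-distance weighting
        means = [x[rng.integers(len(x))]]
        for _ in range(k - 1):
            d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
            if d2.sum() == 0:
                means.append(x[rng.integers(len(x))])
            else:
                means.append(x[rng.choice(len(x), p=d2 / d2.sum())])
        return np.array(means)

    def _em(self, x: np.ndarray, k: int, rng: np.random.Generator):
        n = len(x)
        mu = self._init_means(x, k, rng)
        sd = np.full(k, max(np.std(x), self.sd_floor))
        w = np.full(k, 1.0 / k)
        history = []
        ll_old = -np.inf
        for _ in range(self.max_iter):
            logpdf = (
                np.log(w)[None, :]
                - 0.5 * np.log(2 * np.pi)
                - np.log(sd)[None, :]
                - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            )
            m = logpdf.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
            ll = float(lse.sum())
            history.append(ll)
            resp = np.exp(logpdf - lse[:, None])
            nk = resp.sum(axis=0)
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(
                nk, 1e-300
            )
            sd = np.sqrt(np.maximum(var, self.sd_floor**2))
            if ll - ll_old < self.tol and np.isfinite(ll_old):
                break
            ll_old = ll
        return ll, w, mu, sd, history

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[~np.isnan(x)]
        if len(x) < 50:
            raise ValueError(f"need >= 50 observations to fit noise model, got {len(x)}")
        if np.std(x) == 0:
            warnings.warn("degenerate (zero-variance) data; sd floored", stacklevel=2)
        rng = np.random.default_rng(self.random_state)
        best = None
        self.bic_ = {}
        for k in range(1, self.max_components + 1):
            best_k = None
            for _ in range(self.n_restarts):
                ll, w, mu, sd, hist = self._em(x, k, rng)
                if best_k is None or ll > best_k[0]:
                    best_k = (ll, w, mu, sd, hist)
            ll = best_k[0]
            bic = -2 * ll + (3 * k - 1) * np.log(len(x))
            self.bic_[k] = float(bic)
            if best is None or bic < best[0]:
                best = (bic, k, *best_k)
        _, k, ll, w, mu, sd, hist = best
        order = np.argsort(mu)
        self.n_components_ = k
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sds_ = sd[order]
        self.loglik_history_ = hist
        self.diploid_index_ = int(np.argmin(np.abs(self.means_)))
        z = sps.norm.ppf(1 - self.alpha / 2)
        m0 = self.means_[self.diploid_index_]
        s0 = self.sds_[self.diploid_index_]
        self.band_low_ = float(m0 - z * s0)
        self.band_high_ = float(m0 + z * s0)
        self.n_features_in_ = 1
        return self

    def to_noise_model(self) -> NoiseModel:
        return NoiseModel(
            components=[
                (float(w), float(m), float(s))
                for w, m, s in zip(self.weights_, self.means_, self.sds_)
            ],
            diploid_index=self.diploid_index_,
            band_low=self.band_low_,
            band_high=self.band_high_,
            alpha=self.alpha,
        )


def fit_noise_model(
    values: np.ndarray,
    max_components: int = 3,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> NoiseModel:
    """Fit the diploid-noise Gaussian mixture to pooled per-probe log ratios."""
    est = DiploidNoiseModel(
        max_components=max_components, alpha=alpha, random_state=seed
    ).fit(values)
    return est.to_noise_model()


# ---------------------------------------------------------------------------
# Filtering and state assignment


def _state_for(mean_lr: float, noise: NoiseModel) -> str:
    if mean_lr <= STATE_CUTPOINTS["homozygous_loss"]:
        return "homozygous_loss"
    if mean_lr < noise.band_low:
        return "loss"
    if mean_lr >= STATE_CUTPOINTS["amplification"]:
        return "amplification"
    if mean_lr > noise.band_high:
        return "gain"
    return "neutral"


def filter_segments(
    segments: pd.DataFrame, noise: NoiseModel, alpha: float = 0.05
) -> pd.DataFrame:
    """Retain segments whose mean exceeds the diploid noise.

    A segment is a CNV call when its mean log ratio lies outside the noise
    band AND the two-sided tail probability of that mean under the diploid
    component (sd scaled by 1/sqrt(n_probes)) is below ``alpha``. Everything
    else is annotated state ``neutral``.
    """
    out = segments.copy()
    mu, sd = noise.diploid_mean, noise.diploid_sd
    se = sd / np.sqrt(out["n_probes"].to_numpy(dtype=float))
    z = np.abs(out["mean_lr"].to_numpy() - mu) / np.maximum(se, 1e-300)
    out["p_value"] = 2 * sps.norm.sf(z)
    outside = (out["mean_lr"] < noise.band_low) | (out["mean_lr"] > noise.band_high)
    retained = outside & (out["p_value"] < alpha)
    out["state"] = [
        _state_for(m, noise) if keep else "neutral"
        for m, keep in zip(out["mean_lr"], retained)
    ]
    return out


GAIN_STATES = {"gain", "amplification"}
LOSS_STATES = {"loss", "homozygous_loss"}


def call_arm_events(
    calls: pd.DataFrame, track: LogRatioTrack, min_arm_fraction: float = 0.6
) -> pd.DataFrame:
    """Arm-level gain/loss calls from retained segments.

    An arm is called when same-sign retained segments jointly cover at least
    ``min_arm_fraction`` of its unmasked probes. Returns (chrom, arm, event,
    fraction) rows for called arms only.
    """
    probes = track.unmasked()
    rows = []
    for (chrom, arm), grp in probes.groupby(["chrom", "arm"], sort=False):
        if arm == ".":
            continue
        total = len(grp)
        if total == 0:
            continue
        gain_cov = np.zeros(total, dtype=bool)
        loss_cov = np.zeros(total, dtype=bool)
        sub = calls[(calls["chrom"] == chrom) & (calls["state"] != "neutral")]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for call in sub.itertuples():
            inside = (starts >= call.start) & (ends <= call.end)
            if call.state in GAIN_STATES:
                gain_cov |= inside
            elif call.state in LOSS_STATES:
                loss_cov |= inside
        for event, cov in (("gain", gain_cov), ("loss", loss_cov)):
            frac = cov.sum() / total
            if frac >= min_arm_fraction:
                rows.append((chrom, arm, event, float(frac)))
    return pd.DataFrame(rows, columns=["chrom", "arm", "event", "fraction"])


def detect_hyperdiploidy(
    arm_events: pd.DataFrame,
    odd_chromosomes: list[str] = ODD_CHROMS,
    acrocentric: set[str] = ACROCENTRIC,
    min_trisomies: int = 2,
) -> tuple[bool, int]:
    """Score hyperdiploidy: odd-numbered chromosomes with whole-chromosome gain.

    A chromosome counts when both its arms are gained, or — for acrocentric
    chromosomes, whose p arm is not capturable — when its q arm is gained.
    The flag is set at ``min_trisomies`` or more such chromosomes. Sex
    chromosomes never contribute.
    """
    gains = arm_events[arm_events["event"] == "gain"]
    score = 0
    for chrom in odd_chromosomes:
        if chrom in SEX_CHROMS:
            continue
        arms = set(gains.loc[gains["chrom"] == chrom, "arm"])
        if chrom in acrocentric:
            if "q" in arms:
                score += 1
        elif {"p", "q"} <= arms:
            score += 1
    return score >= min_trisomies, score
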
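"""Cancer-cell-fraction estimation and subclone dynamics across treatment.

Variant allele fractions are converted to cancer cell fractions (CCF) with the
standard purity/copy-number transform, mutations are grouped into subclones by
a finite binomial-mixture model fit with EM (model size chosen by BIC), and
each subclone's prevalence trajectory across pre/on/post treatment timepoints
is classified as newly generated, eliminated, or persistent
(increasing/decreasing/stable).  Cohort-level helpers tally mutations gained or
lost in multiple cases and run hypergeometric gene-set over-representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TIMEPOINTS",
    "FATES",
    "VariantCall",
    "CCFRecord",
    "SubcloneTrack",
    "FateThresholds",
    "compute_ccf",
    "compute_ccfs",
    "cluster_ccfs",
    "classify_fate",
    "tally_shared_events",
    "enrichment_test",
]

TIMEPOINTS = ("pre", "on", "post")

FATES = (
    "newly_generated",
    "eliminated",
    "persistent_increasing",
    "persistent_decreasing",
    "persistent_stable",
)


@dataclass(frozen=True)
class VariantCall:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    cn_tumor: int = 2
    cn_normal: int = 2
    purity: float = 1.0
    timepoint: str = "pre"

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CCFRecord:
    key: str
    gene: str
    timepoint: str
    multiplicity: int
    ccf: float
    ccf_unclipped: float
    clipped: bool


@dataclass
class SubcloneTrack:
    subclone_id: int
    members: list[str]
    prevalence: dict[str, float]  # timepoint -> cluster mean CCF
    fate: Optional[str] = None


@dataclass(frozen=True)
class FateThresholds:
    """presence_min: CCF below which a clone counts as absent (default 1%).

    stable_band: half-width, in percentage points of CCF, of the band treated
    as no change for persistent clones.
    """

    presence_min: float = 0.01
    stable_band: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.presence_min < 0.5):
            raise ValueError("presence_min must lie in (0, 0.5)")
        if self.stable_band < 0:
            raise ValueError("stable_band must be non-negative")


def _vaf_to_ccf_factor(purity: float, cn_tumor: int, cn_normal: int) -> float:
    return (purity * cn_tumor + (1.0 - purity) * cn_normal) / purity


def compute_ccf(v: VariantCall) -> CCFRecord:
    """CCF of a variant from VAF, purity, and local copy number.

    Multiplicity is the nearest integer to VAF * (rho*CN_t + (1-rho)*CN_n)/rho,
    clamped to [1, CN_t]; the CCF is the same quantity divided by the
    multiplicity.  Values above 1 are clipped (the pre-clip value is retained
    and logged).
    """
    if v.depth <= 0:
        raise ValueError(f"{v.key}: depth must be positive")
    if not (0.0 < v.purity <= 1.0):
        raise ValueError(f"{v.key}: purity must lie in (0, 1]")
    if v.cn_tumor < 1:
        raise ValueError(f"{v.key}: tumor copy number at a mutated locus must be >= 1")
    factor = _vaf_to_ccf_factor(v.purity, v.cn_tumor, v.cn_normal)
    m = int(np.clip(round(v.vaf * factor), 1, v.cn_tumor))
    phi_raw = v.vaf * factor / m
    clipped = phi_raw > 1.0
    if clipped:
        logger.info("CCF of %s clipped from %.4f to 1.0", v.key, phi_raw)
    return CCFRecord(key=v.key, gene=v.gene, timepoint=v.timepoint,
                     multiplicity=m, ccf=min(phi_raw, 1.0),
                     ccf_unclipped=phi_raw, clipped=clipped)


def compute_ccfs(variants: Iterable[VariantCall]) -> tuple[list[CCFRecord], list[VariantCall]]:
    """Vector form of :func:`compute_ccf`; inconsistent variants (CN_t = 0 with
    alt reads) are excluded and returned separately with a log entry."""
    records, excluded = [], []
    for v in variants:
        if v.cn_tumor == 0 and v.alt_reads > 0:
            logger.warning("excluding %s: alt reads at CN 0 locus", v.key)
            excluded.append(v)
            continue
        records.append(compute_ccf(v))
    return records, excluded


# ---------------------------------------------------------------------------
# Binomial-mixture subclone clustering
# ---------------------------------------------------------------------------

def _cluster_loglik(alt, depth, factor, log_binom_coef, phi, log_pi):
    """Total log-likelihood and per-variant-cluster log joint.

    alt, depth, factor: (N, T); phi: (K, T); log_pi: (K,).
    The success probability of variant i in cluster k at timepoint t is
    phi[k, t] / factor[i, t] (factor maps CCF down to expected VAF).
    """
    p = phi[None, :, :] / factor[:, None, :]  # (N, K, T)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = (alt[:, None, :] * np.log(p)
          + (depth[:, None, :] - alt[:, None, :]) * np.log1p(-p))
    log_joint = log_pi[None, :] + ll.sum(axis=2) + log_binom_coef[:, None]
    total = special.logsumexp(log_joint, axis=1).sum()
    return total, log_joint


def _mstep_phi(alt, depth, inv_factor, resp_k) -> float:
    """Weighted binomial MLE of one cluster prevalence at one timepoint.

    Maximizes sum_i r_i [a_i log(c_i phi) + (d_i - a_i) log(1 - c_i phi)] with
    c_i = 1/factor_i.  Closed form when all c_i agree; otherwise the score is
    strictly decreasing in phi, so a bracketed root suffices.
    """
    a = resp_k * alt
    d = resp_k * depth
    sa, sd = a.sum(), d.sum()
    if sd <= 0:
        return 0.5
    if np.allclose(inv_factor, inv_factor[0]):
        return float(np.clip(sa / sd / inv_factor[0], 1e-9, 1.0))

    def score(phi):
        p = np.clip(inv_factor * phi, 1e-12, 1 - 1e-12)
        return np.sum(a / phi - (d - a) * inv_factor / (1.0 - p))

    lo, hi = 1e-9, 1.0 - 1e-9
    if score(hi) >= 0:
        return 1.0
    if score(lo) <= 0:
        return lo
    return float(optimize.brentq(score, lo, hi, xtol=1e-10))


def _run_em(alt, depth, factor, log_binom_coef, phi0, max_iter=200, tol=1e-7):
    n, t = alt.shape
    k = phi0.shape[0]
    phi = phi0.copy()
    log_pi = np.full(k, -np.log(k))
    inv_factor = 1.0 / factor
    prev = -np.inf
    trace = []
    for _ in range(max_iter):
        total, log_joint = _cluster_loglik(alt, depth, factor, log_binom_coef, phi, log_pi)
        # EM guarantees ascent; a violation beyond rounding is a bug.
        if total < prev - 1e-6 * (1.0 + abs(prev)):
            raise RuntimeError("EM log-likelihood decreased")
        trace.append(total)
        resp = np.exp(log_joint - special.logsumexp(log_joint, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        log_pi = np.log(np.maximum(nk, 1e-12)) - np.log(n)
        for j in range(k):
            for s in range(t):
                phi[j, s] = _mstep_phi(alt[:, s], depth[:, s], inv_factor[:, s], resp[:, j])
        if abs(total - prev) < tol * (1.0 + abs(total)):
            prev = total
            break
        prev = total
    total, log_joint = _cluster_loglik(alt, depth, factor, log_binom_coef, phi, log_pi)
    trace.append(total)
    resp = np.exp(log_joint - special.logsumexp(log_joint, axis=1, keepdims=True))
    return total, phi, log_pi, resp, trace


def _seed_phi(ccf_mat, k, rng):
    """k-means++-style spread seeding on the naive CCF matrix."""
    n = ccf_mat.shape[0]
    centers = [ccf_mat[rng.integers(n)]]
    while len(centers) < k:
        d2 = np.min([np.sum((ccf_mat - c) ** 2, axis=1) for c in centers], axis=0)
        tot = d2.sum()
        if tot <= 0:
            centers.append(ccf_mat[rng.integers(n)])
            continue
        centers.append(ccf_mat[rng.choice(n, p=d2 / tot)])
    return np.clip(np.array(centers), 1e-3, 1.0)


def cluster_ccfs(table: pd.DataFrame, k_max: int = 10, seed: int = 0,
                 n_restarts: int = 20) -> tuple[list[SubcloneTrack], dict]:
    """Group variants into subclones with a binomial mixture over timepoints.

    ``table`` is long-form with columns key, timepoint, alt_reads, depth and
    optionally purity, cn_tumor, cn_normal, multiplicity (defaults 1.0, 2, 2
    and 1).  Every variant must be observed at every shared timepoint.  The
    mixture has one prevalence parameter per cluster per timepoint; K is chosen
    by BIC over 1..k_max with spread-seeded restarts.  Deterministic given
    ``seed``.

    Returns the subclone tracks (cluster-mean CCF per timepoint, hard member
    assignment) and a model-selection report with the BIC table, the
    log-likelihood trace of the winning fit, and the mean assignment entropy.
    """
    df = table.copy()
    for col, default in (("purity", 1.0), ("cn_tumor", 2), ("cn_normal", 2),
                         ("multiplicity", 1)):
        if col not in df.columns:
            df[col] = default
    keys = sorted(df["key"].unique())
    tps = [t for t in TIMEPOINTS if t in set(df["timepoint"])]
    if not tps:
        tps = sorted(df["timepoint"].unique())
    if len(keys) < 2:
        raise ValueError("need at least two variants to cluster")
    wide_a = df.pivot_table(index="key", columns="timepoint", values="alt_reads")
    wide_d = df.pivot_table(index="key", columns="timepoint", values="depth")
    if wide_a.loc[keys, tps].isna().any().any():
        raise ValueError("every variant must be observed at every shared timepoint")
    alt = wide_a.loc[keys, tps].to_numpy(float)
    depth = wide_d.loc[keys, tps].to_numpy(float)
    meta = df.drop_duplicates("key").set_index("key").loc[keys]
    base = np.array([
        _vaf_to_ccf_factor(p, ct, cn) / m
        for p, ct, cn, m in zip(meta["purity"], meta["cn_tumor"],
                                meta["cn_normal"], meta["multiplicity"])
    ])
    factor = np.tile(base[:, None], (1, len(tps)))  # CCF -> VAF divisor
    log_binom_coef = sum(
        special.gammaln(depth[:, s] + 1) - special.gammaln(alt[:, s] + 1)
        - special.gammaln(depth[:, s] - alt[:, s] + 1)
        for s in range(len(tps))
    )
    ccf_naive = np.clip(alt / depth * factor, 0.0, 1.0)

    n, t = alt.shape
    degenerate = bool(np.all(alt == alt[0]) and np.all(depth == depth[0]))
    if degenerate:
        warnings.warn("all variants have identical counts; returning K=1")
        k_max = 1

    rng = np.random.default_rng(seed)
    report: dict = {"bic": {}, "tested_k": []}
    best = None
    for k in range(1, min(k_max, n) + 1):
        best_k = None
        restarts = 1 if k == 1 else n_restarts
        for _ in range(restarts):
            phi0 = _seed_phi(ccf_naive, k, rng) if k > 1 else \
                np.clip(ccf_naive.mean(axis=0, keepdims=True), 1e-3, 1.0)
            try:
                fit = _run_em(alt, depth, factor, log_binom_coef, phi0)
            except RuntimeError:
                continue
            if best_k is None or fit[0] > best_k[0]:
                best_k = fit
        if best_k is None:
            continue
        total = best_k[0]
        n_params = k * t + (k - 1)
        bic = -2.0 * total + n_params * np.log(n * t)
        report["bic"][k] = float(bic)
        report["tested_k"].append(k)
        if best is None or bic < best[0]:
            best = (bic, k, best_k)

    bic, k, (total, phi, log_pi, resp, trace) = best
    labels = resp.argmax(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(resp * np.log(np.clip(resp, 1e-300, 1.0)), axis=1)
    report.update({
        "k": int(k),
        "loglik": float(total),
        "loglik_trace": [float(x) for x in trace],
        "assignment_entropy": float(ent.mean()),
        "timepoints": tps,
    })
    tracks = []
    used = [j for j in range(k) if np.any(labels == j)]
    for new_id, j in enumerate(sorted(used, key=lambda j: -phi[j, 0])):
        members = [keys[i] for i in np.flatnonzero(labels == j)]
        prevalence = {tp: float(np.clip(phi[j, s], 0.0, 1.0))
                      for s, tp in enumerate(tps)}
        tracks.append(SubcloneTrack(subclone_id=new_id, members=members,
                                    prevalence=prevalence))
    return tracks, report


# ---------------------------------------------------------------------------
# Fate classification and cohort tallies
# ---------------------------------------------------------------------------

def classify_fate(track: SubcloneTrack,
                  thresholds: FateThresholds = FateThresholds()) -> str:
    """Fate of a subclone from its pre- and post-treatment prevalence.

    Presence is prevalence >= presence_min.  Appearing -> newly_generated,
    vanishing -> eliminated; otherwise persistent with the direction taken
    from the prevalence change in percentage points against stable_band.
    The intermediate "on" timepoint, when present, is carried in the track but
    the fate is defined by pre -> post.
    """
    if "pre" not in track.prevalence or "post" not in track.prevalence:
        raise ValueError("fate requires both pre and post prevalence")
    pre = track.prevalence["pre"]
    post = track.prevalence["post"]
    present_pre = pre >= thresholds.presence_min
    present_post = post >= thresholds.presence_min
    if not present_pre and present_post:
        fate = "newly_generated"
    elif present_pre and not present_post:
        fate = "eliminated"
    else:
        delta_pp = 100.0 * (post - pre)
        if delta_pp > thresholds.stable_band:
            fate = "persistent_increasing"
        elif delta_pp < -thresholds.stable_band:
            fate = "persistent_decreasing"
        else:
            fate = "persistent_stable"
    track.fate = fate
    return fate


def tally_shared_events(per_case: Mapping[str, set]) -> dict:
    """Histogram of how many cases share each gained (or lost) mutation.

    Returns union size, a degree -> count histogram, and degree -> sorted key
    lists, where degree is the number of cases containing the key.
    """
    if not per_case:
        raise ValueError("need at least one case")
    counts: dict[str, int] = {}
    for s in per_case.values():
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    hist: dict[int, int] = {}
    members: dict[int, list] = {}
    for key, d in counts.items():
        hist[d] = hist.get(d, 0) + 1
        members.setdefault(d, []).append(key)
    for d in members:
        members[d].sort()
    return {"union": len(counts), "histogram": hist, "members": members}


def enrichment_test(gene_list: Sequence[str], gene_sets: Mapping[str, Sequence[str]],
                    universe: Sequence[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    Gene sets are intersected with the universe; the query list must be a
    subset of the universe.  Sets with zero overlap report p = 1.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_list)
    if not query <= uni:
        raise ValueError("gene list must be a subset of the universe")
    rows = []
    m = len(uni)
    n_query = len(query)
    for name, genes in gene_sets.items():
        members = set(genes) & uni
        k = len(query & members)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query))
        rows.append({"set": name, "set_size": len(members), "overlap": k,
                     "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows).sort_values(["p_value", "set"]).reset_index(drop=True)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
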
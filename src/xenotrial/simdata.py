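"""Synthetic PDX-clinical-trial cohorts with known ground truth.

Each case is a small clone population grown under a logistic law with
multiplicative drug kill and reversible drug-tolerant persister (DTP)
switching:

    dA_k/dt = g_k * A_k * (1 - V/Vmax) - s_k * c(t) * A_k
              - q_in,k * [c>0] * A_k + q_out,k * [c=0] * P_k
    dP_k/dt = q_in,k * [c>0] * A_k - q_out,k * [c=0] * P_k

where A_k/P_k are the active/persister volumes of clone k, c(t) is the drug
exposure (1 during a treatment round, 0 otherwise) and V the total volume.
Persisters neither grow nor die under drug.  Clones whose total volume falls
below an extinction threshold are eradicated.  Observed volumes get
multiplicative lognormal measurement noise and are emitted as caliper
width/length pairs.

Archetypes map onto the trial decision tree: sensitive (eradicated, no
relapse), intrinsic (progression in round 1), acquired (resistant minor clone
expands, relapse, round-2 progression), dtp (persister relapse, round-2
response), individual_differences (constructed per-mouse sensitivity
heterogeneity), unevaluable (early termination).

The module also emits variant tables (binomial read sampling from clone CCFs),
expression matrices with planted markers, and Loewe/Hill dose matrices.  All
randomness flows from one seed through per-case/per-assay child streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .trial import (CaseRecord, MouseSeries, ResponseCutoffs, VolumeMeasurement,
                    detect_relapse)
from .trajectories import GL, CloneTree

__all__ = [
    "ARCHETYPES",
    "SimClone",
    "SimConfig",
    "SimTruth",
    "Cohort",
    "archetype_clones",
    "simulate_volume_series",
    "simulate_case",
    "simulate_cohort",
    "simulate_variant_tables",
    "simulate_expression",
    "simulate_dose_matrix",
    "clone_tree",
]

ARCHETYPES = ("sensitive", "intrinsic", "acquired", "dtp",
              "individual_differences", "unevaluable")

#: Default archetype proportions: the discovery-cohort distribution
#: (21/9/8/4/4/3 of 49 cases).
DEFAULT_MIX = {
    "intrinsic": 21 / 49,
    "sensitive": 9 / 49,
    "acquired": 8 / 49,
    "individual_differences": 4 / 49,
    "unevaluable": 4 / 49,
    "dtp": 3 / 49,
}


@dataclass(frozen=True)
class SimClone:
    clone_id: str
    parent_id: str = GL
    birth_ccf: float = 1.0
    growth_rate: float = 0.08        # per day
    kill_rate: float = 0.0           # per day per unit drug
    persister_entry_rate: float = 0.0
    persister_exit_rate: float = 0.0
    driver_events: tuple[tuple[str, str], ...] = ()  # (gene, SNV|AMP|DEL)

    def __post_init__(self) -> None:
        if not (0.0 <= self.birth_ccf <= 1.0):
            raise ValueError(f"{self.clone_id}: birth_ccf must lie in [0, 1]")
        for name in ("growth_rate", "kill_rate",
                     "persister_entry_rate", "persister_exit_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.clone_id}: {name} must be non-negative")


def _validate_clones(clones: Sequence[SimClone]) -> None:
    if not clones:
        raise ValueError("empty clone list")
    ids = {c.clone_id for c in clones}
    by_id = {c.clone_id: c for c in clones}
    root_children = 0.0
    for c in clones:
        if c.parent_id == GL:
            root_children += c.birth_ccf
        elif c.parent_id not in ids:
            raise ValueError(f"{c.clone_id}: unknown parent {c.parent_id}")
        elif c.birth_ccf > by_id[c.parent_id].birth_ccf + 1e-9:
            raise ValueError(f"{c.clone_id}: birth_ccf exceeds its parent's")
    if root_children > 1.0 + 1e-9:
        raise ValueError("birth CCFs of the root's children exceed 1")


@dataclass(frozen=True)
class SimConfig:
    n_cases: int = 12
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX))
    mice_per_arm: int = 3
    v0: float = 200.0                # baseline volume per mouse, mm^3
    vmax: float = 4000.0             # carrying capacity, mm^3
    measurement_cv: float = 0.10     # lognormal noise scale on volumes
    mouse_jitter_cv: float = 0.05    # per-mouse multiplicative rate jitter
    seq_depth: int = 500
    purity: float = 0.8
    extinction_threshold: float = 0.5  # mm^3 per clone
    treatment_days: float = 21.0
    monitor_days: float = 90.0
    dt: float = 0.25                 # RK4 step, days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_arm < 1:
            raise ValueError("mice_per_arm must be >= 1")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("archetype_mix must sum to 1")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if self.seq_depth < 1:
            raise ValueError("seq_depth must be >= 1")


@dataclass
class SimTruth:
    case_id: str
    archetype: str
    relapse_day: Optional[float]
    has_round2: bool
    clone_fractions: dict[str, dict[str, float]]  # timepoint -> clone -> fraction


@dataclass
class Cohort:
    cases: list[CaseRecord]
    truth: dict[str, SimTruth]
    clones: dict[str, list[SimClone]]
    config: SimConfig


# ---------------------------------------------------------------------------
# Growth dynamics
# ---------------------------------------------------------------------------

def twice_weekly(end: float, start: float = 0.0) -> list[float]:
    """Twice-weekly measurement schedule (alternating 3/4-day gaps)."""
    days, d, step3 = [], start, True
    while d <= end + 1e-9:
        days.append(round(d, 6))
        d += 3.0 if step3 else 4.0
        step3 = not step3
    return days


def _derivs(a, p, g, s, q_in, q_out, c, vmax):
    v = a.sum() + p.sum()
    logistic = 1.0 - v / vmax
    if c > 0:
        da = g * a * logistic - s * c * a - q_in * a
        dp = q_in * a
    else:
        da = g * a * logistic + q_out * p
        dp = -q_out * p
    return da, dp


def _integrate(a, p, g, s, q_in, q_out, c, vmax, t0, t1, dt):
    """Fixed-step RK4 over [t0, t1] with constant drug exposure c."""
    n_steps = max(1, int(math.ceil((t1 - t0) / dt)))
    h = (t1 - t0) / n_steps
    for _ in range(n_steps):
        k1a, k1p = _derivs(a, p, g, s, q_in, q_out, c, vmax)
        k2a, k2p = _derivs(a + h / 2 * k1a, p + h / 2 * k1p, g, s, q_in, q_out, c, vmax)
        k3a, k3p = _derivs(a + h / 2 * k2a, p + h / 2 * k2p, g, s, q_in, q_out, c, vmax)
        k4a, k4p = _derivs(a + h * k3a, p + h * k3p, g, s, q_in, q_out, c, vmax)
        a = a + h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
        p = p + h / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
        a = np.maximum(a, 0.0)
        p = np.maximum(p, 0.0)
    return a, p


def simulate_volume_series(clones: Sequence[SimClone], arm: str,
                           days: Sequence[float], config: SimConfig,
                           seed: Optional[int] = None,
                           rng: Optional[np.random.Generator] = None,
                           drug_window: Optional[tuple[float, float]] = None,
                           rate_scale: tuple[float, float] = (1.0, 1.0),
                           initial_fractions: Optional[Mapping[str, float]] = None,
                           ) -> dict:
    """Simulate one mouse's volume series for one arm.

    Returns measurement days, true and observed total volumes, the per-clone
    state matrix (active + persister) at each measurement day, and caliper
    measurements.  ``rate_scale`` multiplies (growth, kill) rates to express
    per-mouse variability; ``initial_fractions`` overrides birth CCFs (used
    when passaging a relapsed tumor into round 2).  Noise is off when
    ``config.measurement_cv`` is 0.
    """
    _validate_clones(clones)
    if arm not in ("treatment", "vehicle"):
        raise ValueError(f"arm must be 'treatment' or 'vehicle', got {arm!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    days = sorted(days)
    if drug_window is None:
        drug_window = (0.0, config.treatment_days)

    fracs = np.array([
        (initial_fractions or {}).get(c.clone_id, c.birth_ccf) if initial_fractions
        else c.birth_ccf
        for c in clones
    ])
    if fracs.sum() <= 0:
        raise ValueError("initial total volume must be positive")
    fracs = fracs / fracs.sum()
    a = config.v0 * fracs
    p = np.zeros_like(a)
    g = np.array([c.growth_rate for c in clones]) * rate_scale[0]
    s = np.array([c.kill_rate for c in clones]) * rate_scale[1]
    q_in = np.array([c.persister_entry_rate for c in clones])
    q_out = np.array([c.persister_exit_rate for c in clones])

    def conc(t0: float, t1: float) -> float:
        if arm != "treatment":
            return 0.0
        mid = 0.5 * (t0 + t1)
        return 1.0 if drug_window[0] <= mid < drug_window[1] else 0.0

    per_clone = [a + p]
    t_prev = days[0]
    for t in days[1:]:
        # split at the drug-off boundary so exposure is piecewise constant
        cut = drug_window[1]
        segments = ([(t_prev, cut), (cut, t)]
                    if t_prev < cut < t else [(t_prev, t)])
        for t0, t1 in segments:
            if t1 <= t0:
                continue
            a, p = _integrate(a, p, g, s, q_in, q_out, conc(t0, t1),
                              config.vmax, t0, t1, config.dt)
        dead = (a + p) < config.extinction_threshold
        a[dead] = 0.0
        p[dead] = 0.0
        per_clone.append(a + p)
        t_prev = t

    per_clone = np.array(per_clone)  # (n_days, n_clones)
    true_total = per_clone.sum(axis=1)
    if config.measurement_cv > 0:
        noise = rng.lognormal(0.0, config.measurement_cv, size=true_total.shape)
    else:
        noise = np.ones_like(true_total)
    observed = true_total * noise
    # emit equal caliper axes consistent with TV = 0.5 w^2 l
    axes = np.cbrt(2.0 * observed)
    measurements = [VolumeMeasurement(day=d, width=w, length=w)
                    for d, w in zip(days, axes)]
    return {"days": list(days), "true_total": true_total, "observed": observed,
            "per_clone": per_clone,
            "clone_ids": [c.clone_id for c in clones],
            "measurements": measurements}


# ---------------------------------------------------------------------------
# Archetype construction
# ---------------------------------------------------------------------------

def archetype_clones(archetype: str, case_id: str) -> list[SimClone]:
    """Clone population realizing a response archetype under the default
    trial schedule (drug days 0-21, monitoring to day 90)."""
    t53 = (f"TP53", "SNV")
    if archetype == "sensitive":
        return [SimClone(f"{case_id}_c0", birth_ccf=1.0, growth_rate=0.08,
                         kill_rate=0.5, driver_events=(t53,))]
    if archetype == "intrinsic":
        return [SimClone(f"{case_id}_c0", birth_ccf=1.0, growth_rate=0.08,
                         kill_rate=0.02,
                         driver_events=(("ANK3", "SNV"), ("ANKH", "AMP")))]
    if archetype == "acquired":
        return [
            SimClone(f"{case_id}_c0", birth_ccf=1.0, growth_rate=0.08,
                     kill_rate=0.5, driver_events=(t53,)),
            SimClone(f"{case_id}_c1", parent_id=f"{case_id}_c0",
                     birth_ccf=0.01, growth_rate=0.09, kill_rate=0.0,
                     driver_events=(("RAC1", "AMP"),)),
        ]
    if archetype == "dtp":
        return [SimClone(f"{case_id}_c0", birth_ccf=1.0, growth_rate=0.08,
                         kill_rate=0.5, persister_entry_rate=0.15,
                         persister_exit_rate=0.2, driver_events=(t53,))]
    if archetype in ("individual_differences", "unevaluable"):
        return [SimClone(f"{case_id}_c0", birth_ccf=1.0, growth_rate=0.08,
                         kill_rate=0.5, driver_events=(t53,))]
    raise ValueError(f"unknown archetype {archetype!r}")


#: Per-mouse kill-rate multipliers for the individual_differences archetype:
#: one responder, one refractory, one intermediate (cycled for more mice).
_IDIFF_KILL_SCALE = (1.0, 0.0, 0.1)


def _fractions_at(result: dict, day: float) -> dict[str, float]:
    idx = int(np.argmin(np.abs(np.array(result["days"]) - day)))
    vols = result["per_clone"][idx]
    total = vols.sum()
    if total <= 0:
        return {cid: 0.0 for cid in result["clone_ids"]}
    return {cid: float(v / total) for cid, v in zip(result["clone_ids"], vols)}


def simulate_case(archetype: str, case_id: str, config: SimConfig,
                  rng: np.random.Generator) -> tuple[CaseRecord, SimTruth,
                                                     list[SimClone]]:
    """Simulate one case: both arms, round 1 (with monitoring) and, on relapse
    of the noise-free case-level trajectory, a passaged round 2."""
    clones = archetype_clones(archetype, case_id)
    record = CaseRecord(case_id=case_id,
                        early_termination=(archetype == "unevaluable"))

    end_r1 = 10.0 if archetype == "unevaluable" else config.monitor_days
    sched_r1 = twice_weekly(end_r1)
    sched_short = twice_weekly(config.treatment_days)

    # noise-free case-level trajectory drives relapse truth and passaging
    noise_free = replace(config, measurement_cv=0.0)
    truth_r1 = simulate_volume_series(clones, "treatment", twice_weekly(config.monitor_days),
                                      noise_free, rng=np.random.default_rng(0))
    cutoffs = ResponseCutoffs(monitor_days=config.monitor_days)
    relapse = detect_relapse(truth_r1["days"], truth_r1["true_total"], cutoffs)
    has_round2 = (archetype in ("acquired", "dtp")) and relapse.relapse_day is not None
    on_day = relapse.relapse_day if relapse.relapse_day is not None else config.monitor_days
    on_fracs = _fractions_at(truth_r1, on_day)

    for m in range(config.mice_per_arm):
        jitter = rng.lognormal(0.0, config.mouse_jitter_cv, size=2)
        if archetype == "individual_differences":
            jitter = (jitter[0], jitter[1] * _IDIFF_KILL_SCALE[m % len(_IDIFF_KILL_SCALE)])
        res = simulate_volume_series(clones, "treatment", sched_r1, config,
                                     rng=rng, rate_scale=tuple(jitter))
        record.series.append(MouseSeries(mouse_id=f"{case_id}_m{m}",
                                         arm="treatment", round=1,
                                         measurements=res["measurements"]))
    for m in range(config.mice_per_arm):
        jitter = rng.lognormal(0.0, config.mouse_jitter_cv, size=2)
        res = simulate_volume_series(clones, "vehicle", sched_short, config,
                                     rng=rng, rate_scale=tuple(jitter))
        record.series.append(MouseSeries(mouse_id=f"{case_id}_v{m}",
                                         arm="vehicle", round=1,
                                         measurements=res["measurements"]))

    post_fracs = on_fracs
    if has_round2:
        truth_r2 = simulate_volume_series(clones, "treatment", sched_short,
                                          noise_free, rng=np.random.default_rng(0),
                                          initial_fractions=on_fracs)
        post_fracs = _fractions_at(truth_r2, config.treatment_days)
        for m in range(config.mice_per_arm):
            jitter = rng.lognormal(0.0, config.mouse_jitter_cv, size=2)
            res = simulate_volume_series(clones, "treatment", sched_short, config,
                                         rng=rng, rate_scale=tuple(jitter),
                                         initial_fractions=on_fracs)
            record.series.append(MouseSeries(mouse_id=f"{case_id}_m{m}",
                                             arm="treatment", round=2,
                                             measurements=res["measurements"]))

    pre_fracs = _fractions_at(truth_r1, 0.0)
    truth = SimTruth(case_id=case_id, archetype=archetype,
                     relapse_day=relapse.relapse_day, has_round2=has_round2,
                     clone_fractions={"pre": pre_fracs, "on": on_fracs,
                                      "post": post_fracs})
    return record, truth, clones


def _archetype_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n cases over the mix."""
    quotas = {a: mix[a] * n for a in mix}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    for a in sorted(quotas, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    return counts


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full PCT cohort; bit-identical for identical config + seed."""
    counts = _archetype_counts(config.archetype_mix, config.n_cases)
    labels = [a for a in ARCHETYPES for _ in range(counts.get(a, 0))]
    order_rng = np.random.default_rng([config.seed, 0xC0])
    labels = [labels[i] for i in order_rng.permutation(len(labels))]
    cases, truth, clone_map = [], {}, {}
    for idx, archetype in enumerate(labels):
        case_id = f"CASE_{idx:03d}"
        rng = np.random.default_rng([config.seed, idx])
        record, t, clones = simulate_case(archetype, case_id, config, rng)
        cases.append(record)
        truth[case_id] = t
        clone_map[case_id] = clones
    return Cohort(cases=cases, truth=truth, clones=clone_map, config=config)


# ---------------------------------------------------------------------------
# Variant tables, expression, dose matrices
# ---------------------------------------------------------------------------

def _descendants(clones: Sequence[SimClone]) -> dict[str, set[str]]:
    kids: dict[str, set[str]] = {c.clone_id: set() for c in clones}
    for c in clones:
        if c.parent_id in kids:
            kids[c.parent_id].add(c.clone_id)

    def collect(cid: str) -> set[str]:
        out = {cid}
        for k in kids[cid]:
            out |= collect(k)
        return out

    return {c.clone_id: collect(c.clone_id) for c in clones}


def simulate_variant_tables(clones: Sequence[SimClone],
                            ccf_by_timepoint: Mapping[str, Mapping[str, float]],
                            config: SimConfig,
                            rng: np.random.Generator,
                            n_passengers: int = 5) -> pd.DataFrame:
    """Binomial read sampling of driver + passenger mutations at each timepoint.

    A mutation's CCF is the summed prevalence of its clone's subtree; the
    expected VAF is CCF * purity * m / (purity*CN_t + (1-purity)*CN_n) with
    diploid heterozygous defaults.  Every driver event appears in the table.
    """
    _validate_clones(clones)
    subtree = _descendants(clones)
    muts: list[tuple[str, str]] = []  # (gene, owning clone)
    for c in clones:
        for gene, _kind in c.driver_events:
            muts.append((gene, c.clone_id))
        for i in range(n_passengers):
            muts.append((f"{c.clone_id}_p{i}", c.clone_id))
    rows = []
    for tp, ccfs in ccf_by_timepoint.items():
        for val in ccfs.values():
            if not (0.0 <= val <= 1.0 + 1e-9):
                raise ValueError(f"clone CCF {val} outside [0, 1] at {tp}")
        for k, (gene, owner) in enumerate(muts):
            phi = sum(ccfs.get(cid, 0.0) for cid in subtree[owner])
            phi = min(phi, 1.0)
            cn_t, cn_n, m = 2, 2, 1
            vaf = phi * config.purity * m / (config.purity * cn_t
                                             + (1 - config.purity) * cn_n)
            depth = config.seq_depth
            alt = int(rng.binomial(depth, vaf))
            rows.append({"gene": gene, "chrom": f"chr{1 + k % 22}",
                         "pos": 1_000_000 + 1000 * k, "ref": "A", "alt": "T",
                         "alt_reads": alt, "depth": depth, "cn_tumor": cn_t,
                         "cn_normal": cn_n, "purity": config.purity,
                         "timepoint": tp, "true_ccf": phi})
    return pd.DataFrame(rows)


def simulate_expression(labels: Mapping[str, str],
                        planted_markers: Sequence[str],
                        effect_size: float,
                        rng: np.random.Generator,
                        n_genes: int = 300) -> tuple[pd.DataFrame, dict]:
    """Gaussian log-expression with planted markers shifted in the resistant
    group by ``effect_size`` standard deviations."""
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    for grp in ("resistant", "sensitive"):
        if sum(1 for v in labels.values() if v == grp) < 2:
            raise ValueError(f"need at least two {grp} cases")
    samples = list(labels)
    genes = [f"GENE_{i:04d}" for i in range(n_genes)]
    for i, m in enumerate(planted_markers):
        genes[i] = m
    x = rng.normal(8.0, 1.0, size=(len(genes), len(samples)))
    res_idx = [j for j, s in enumerate(samples) if labels[s] == "resistant"]
    for i in range(len(planted_markers)):
        x[i, res_idx] += effect_size
    df = pd.DataFrame(x, index=genes, columns=samples)
    return df, {"planted": list(planted_markers), "effect_size": effect_size}


def _hill_dose_at(f: float, ec50: float, h: float) -> float:
    return ec50 * (f / (1.0 - f)) ** (1.0 / h)


def simulate_dose_matrix(hill1: tuple[float, float], hill2: tuple[float, float],
                         doses1: Sequence[float], doses2: Sequence[float],
                         interaction: str = "loewe_additive",
                         synergy_factor: float = 1.0,
                         noise_cv: float = 0.0,
                         rng: Optional[np.random.Generator] = None,
                         ) -> pd.DataFrame:
    """Viability grid (percent) under Loewe additivity or planted synergy.

    ``hill1``/``hill2`` are (EC50, h) of the full-range single-agent curves.
    The effect f of a combination solves d1/D1(f) + d2/D2(f) = alpha, where
    alpha = 1 under additivity and ``synergy_factor`` < 1 pulls isoboles
    inward; single-agent margins always follow their Hill curve exactly.
    """
    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    for name, d in (("doses1", d1), ("doses2", d2)):
        if d[0] != 0:
            raise ValueError(f"{name} must include a zero dose first")
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    if interaction == "loewe_additive":
        alpha = 1.0
    elif interaction == "synergy_factor":
        alpha = synergy_factor
        if alpha <= 0:
            raise ValueError("synergy_factor must be positive")
    else:
        raise ValueError(f"unknown interaction {interaction!r}")
    ec1, h1 = hill1
    ec2, h2 = hill2

    def effect(x1: float, x2: float) -> float:
        if x1 == 0 and x2 == 0:
            return 0.0
        target = alpha if (x1 > 0 and x2 > 0) else 1.0

        def g(f):
            return (x1 / _hill_dose_at(f, ec1, h1) if x1 > 0 else 0.0) \
                 + (x2 / _hill_dose_at(f, ec2, h2) if x2 > 0 else 0.0) - target

        return float(optimize.brentq(g, 1e-9, 1.0 - 1e-9))

    grid = np.array([[100.0 * (1.0 - effect(a, b)) for b in d2] for a in d1])
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        grid = grid * rng.lognormal(0.0, noise_cv, size=grid.shape)
    return pd.DataFrame(grid, index=d1, columns=d2)


def clone_tree(clones: Sequence[SimClone], case_id: str,
               timepoint: str, present: Optional[Mapping[str, float]] = None,
               presence_min: float = 0.01) -> CloneTree:
    """Clone tree of a simulated case, optionally pruned to clones present
    (prevalence >= presence_min) at a timepoint."""
    keep = {c.clone_id for c in clones}
    if present is not None:
        keep = {cid for cid in keep if present.get(cid, 0.0) >= presence_min}
        # keep ancestors of present clones so the tree stays connected
        by_id = {c.clone_id: c for c in clones}
        for cid in list(keep):
            cur = by_id[cid]
            while cur.parent_id != GL:
                keep.add(cur.parent_id)
                cur = by_id[cur.parent_id]
    parent = {c.clone_id: c.parent_id for c in clones if c.clone_id in keep}
    drivers = {c.clone_id: [g for g, _k in c.driver_events]
               for c in clones if c.clone_id in keep and c.driver_events}
    return CloneTree(case_id=case_id, timepoint=timepoint,
                     parent=parent, drivers=drivers)
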
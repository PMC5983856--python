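"""Inter-observer agreement battery: variance components, ICC, Dice
overlap, Fleiss kappa and Kruskal-Wallis.

The measurement model for class fractions is a two-way random-effects
layout: each nodule is segmented by each observer, and the observed percent
fraction of a voxel class decomposes as

    y_ij = mu + nodule_i + observer_j + e_ij,

with independent random effects of variance sigma2_nodule, sigma2_observer
and sigma2_residual. The intraclass correlation is the between-nodule share
of the total variance,

    ICC = sigma2_nodule / (sigma2_nodule + sigma2_observer + sigma2_residual),

i.e. ICC(2,1): two-way random effects, absolute agreement, single rater.
Components are estimated by ANOVA mean squares (method of moments); the 95%
confidence interval is the McGraw-Wong F-based interval, which is not
truncated at zero and can legitimately produce a negative lower bound.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (ParametricSignature, RiskCall, RiskRule,
                             classify_nodule, risk_characterize, signature_row)
from .errors import (AlignmentError, BalanceError, DegenerateDataError,
                     UndefinedStatisticError)
from .exemplar_model import ExemplarModel, PALETTE, VIRO_CLASSES
from .phantom import GroundTruth, ObserverJitter, simulate_observer_mask
from .volume_io import VoxelMask, check_aligned

#: Interpretation thresholds used in the reliability literature.
ICC_HIGH_AGREEMENT = 0.8
DSC_STRONG_OVERLAP = 0.7
KAPPA_BANDS = (
    (0.81, 1.01, "almost perfect agreement"),
    (0.61, 0.81, "substantial agreement"),
    (0.41, 0.61, "moderate agreement"),
    (0.21, 0.41, "fair agreement"),
    (0.0, 0.21, "slight agreement"),
    (-np.inf, 0.0, "poor agreement"),
)

OBSERVER_TABLE_COLUMNS = ("nodule", "observer", "voxel_class", "fraction_pct")


def _pivot(table: pd.DataFrame, voxel_class: str) -> pd.DataFrame:
    """Nodule-by-observer matrix of percent fractions for one class."""
    sub = table[table["voxel_class"] == voxel_class]
    if sub.empty:
        raise BalanceError(f"no rows for class {voxel_class!r}")
    if sub.duplicated(["nodule", "observer"]).any():
        raise BalanceError(f"duplicate (nodule, observer) rows for class {voxel_class!r}")
    piv = sub.pivot(index="nodule", columns="observer", values="fraction_pct")
    if piv.isna().any().any():
        raise BalanceError(
            f"incomplete nodule-by-observer crossing for class {voxel_class!r}")
    if piv.shape[0] < 2 or piv.shape[1] < 2:
        raise BalanceError(
            f"need >= 2 nodules and >= 2 observers, got {piv.shape}")
    return piv


def _anova_mean_squares(Y: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (no replication) mean squares: (MS_nodule, MS_observer, MSE, n, k)."""
    n, k = Y.shape
    grand = Y.mean()
    row = Y.mean(axis=1)
    col = Y.mean(axis=0)
    ms_nod = k * np.sum((row - grand) ** 2) / (n - 1)
    ms_obs = n * np.sum((col - grand) ** 2) / (k - 1)
    resid = Y - row[:, None] - col[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return float(ms_nod), float(ms_obs), float(mse), n, k


@dataclass
class VarianceComponents:
    """Method-of-moments variance decomposition (squared-percent units)."""

    sigma2_nodule: float
    sigma2_observer: float
    sigma2_residual: float
    truncated: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.sigma2_nodule + self.sigma2_observer + self.sigma2_residual


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_nodules: int
    n_observers: int
    components: VarianceComponents


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    category_counts: dict[str, int]
    interpretation: str


@dataclass
class KWResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: list[int]
    tie_corrected: bool


def variance_components(table: pd.DataFrame, voxel_class: str) -> VarianceComponents:
    """Decompose one class's fraction variance into nodule, observer and
    residual components; negative moment estimates are truncated to zero and
    flagged."""
    Y = _pivot(table, voxel_class).to_numpy(dtype=float)
    ms_nod, ms_obs, mse, n, k = _anova_mean_squares(Y)
    raw = {
        "nodule": (ms_nod - mse) / k,
        "observer": (ms_obs - mse) / n,
        "residual": mse,
    }
    truncated = [name for name, v in raw.items() if v < 0]
    return VarianceComponents(
        sigma2_nodule=max(raw["nodule"], 0.0),
        sigma2_observer=max(raw["observer"], 0.0),
        sigma2_residual=max(raw["residual"], 0.0),
        truncated=truncated,
    )


def icc(table: pd.DataFrame, voxel_class: str, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with McGraw-Wong 95% CI for one voxel class.

    The point estimate uses untruncated mean squares (so it can be slightly
    negative under the null); the CI is F-based with Satterthwaite degrees
    of freedom and is deliberately not clipped at zero.
    """
    Y = _pivot(table, voxel_class).to_numpy(dtype=float)
    ms_nod, ms_obs, mse, n, k = _anova_mean_squares(Y)
    if ms_nod == 0 and ms_obs == 0 and mse == 0:
        raise UndefinedStatisticError(
            f"zero total variance for class {voxel_class!r}: ICC undefined")
    comps = variance_components(table, voxel_class)

    denom = ms_nod + (k - 1) * mse + (k / n) * (ms_obs - mse)
    if denom == 0:
        raise UndefinedStatisticError(
            f"degenerate mean squares for class {voxel_class!r}")
    est = (ms_nod - mse) / denom

    if mse == 0 and ms_obs == 0:
        # perfect agreement: no observer or residual variance at all
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0, n_nodules=n,
                         n_observers=k, components=comps)

    a = k * est / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
    num = (a * ms_obs + b * mse) ** 2
    den = (a * ms_obs) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    c = k * ms_obs + (k * n - k - n) * mse
    low = n * (ms_nod - f_l * mse) / (f_l * c + n * ms_nod)
    high = n * (f_u * ms_nod - mse) / (c + n * f_u * ms_nod)
    return ICCResult(icc=float(est), ci_low=float(low), ci_high=float(high),
                     n_nodules=n, n_observers=k, components=comps)


def _viro_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Synthesize 'VIRO' rows by summing the V, I, R, O fractions per
    (nodule, observer) — the group is analyzed as its own measurement, not
    as an average of per-class statistics."""
    sub = table[table["voxel_class"].isin(VIRO_CLASSES)]
    grouped = (sub.groupby(["nodule", "observer"], as_index=False)["fraction_pct"]
               .sum())
    grouped["voxel_class"] = "VIRO"
    return grouped[list(OBSERVER_TABLE_COLUMNS)]


def icc_panel(table: pd.DataFrame,
              group_map: Mapping | None = None,
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-class ICC report: one row per palette class, plus 'VIRO'
    (computed on summed V+I+R+O fractions) and 'Avg.' (arithmetic mean of
    the nine per-class ICCs).

    ``group_map`` (nodule id -> stratum) optionally repeats the panel per
    stratum; strata with fewer than 2 nodules are skipped with a warning.
    Classes whose ICC is undefined (zero total variance) appear as NaN and
    are excluded from 'Avg.'.
    """
    if group_map is None:
        strata = {"all": table}
    else:
        strata = {}
        for g in sorted(set(group_map.values()), key=str):
            nodules = [nid for nid, grp in group_map.items() if grp == g]
            strata[g] = table[table["nodule"].isin(nodules)]

    rows = []
    for stratum, sub in strata.items():
        if sub["nodule"].nunique() < 2:
            warnings.warn(f"stratum {stratum!r} has < 2 nodules; skipped")
            continue
        aug = pd.concat([sub, _viro_rows(sub)], ignore_index=True)
        class_iccs = []
        for cls in list(PALETTE) + ["VIRO"]:
            try:
                r = icc(aug, cls, alpha=alpha)
                rec = {"group": stratum, "voxel_class": cls, "icc": r.icc,
                       "ci_low": r.ci_low, "ci_high": r.ci_high,
                       "n_nodules": r.n_nodules, "n_observers": r.n_observers}
            except UndefinedStatisticError:
                warnings.warn(f"ICC undefined for class {cls!r} in stratum "
                              f"{stratum!r}; reported as NaN")
                rec = {"group": stratum, "voxel_class": cls, "icc": np.nan,
                       "ci_low": np.nan, "ci_high": np.nan,
                       "n_nodules": sub["nodule"].nunique(),
                       "n_observers": sub["observer"].nunique()}
            if cls in PALETTE:
                class_iccs.append(rec["icc"])
            rows.append(rec)
        rows.append({"group": stratum, "voxel_class": "Avg.",
                     "icc": float(np.nanmean(class_iccs)),
                     "ci_low": np.nan, "ci_high": np.nan,
                     "n_nodules": sub["nodule"].nunique(),
                     "n_observers": sub["observer"].nunique()})
    return pd.DataFrame(rows)


def dsc(mask_a: VoxelMask, mask_b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two aligned masks.

    Values above ``DSC_STRONG_OVERLAP`` (0.7) are conventionally read as
    strong overlap. Undefined (error) when both masks are empty.
    """
    check_aligned(mask_a, mask_b)
    a = mask_a.values.astype(bool)
    b = mask_b.values.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise UndefinedStatisticError("Dice undefined: both masks are empty")
    return 2.0 * int((a & b).sum()) / denom


def fleiss_kappa(ratings: pd.DataFrame | np.ndarray,
                 categories: Sequence[str] = ("Good", "Intermediate", "Poor"),
                 alpha: float = 0.05) -> KappaResult:
    """Fleiss kappa for a subjects-by-raters table of categorical labels.

    kappa = (P_bar - P_e) / (1 - P_e), with the large-sample standard error
    of Fleiss, Nee & Landis for the CI. Raises when every rating falls in a
    single category (P_e = 1, kappa undefined).
    """
    R = np.asarray(ratings)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("ratings must be a 2-D subjects x raters table with >= 2 subjects")
    N, n = R.shape
    cats = list(categories)
    counts = np.zeros((N, len(cats)), dtype=float)
    for j, c in enumerate(cats):
        counts[:, j] = (R == c).sum(axis=1)
    if not np.all(counts.sum(axis=1) == n):
        raise ValueError("ratings contain labels outside the category set")

    p = counts.sum(axis=0) / (N * n)
    p_bar_e = float(np.sum(p ** 2))
    if p_bar_e >= 1.0:
        raise UndefinedStatisticError(
            "all ratings fall in one category: kappa undefined")
    P_i = (np.sum(counts ** 2, axis=1) - n) / (n * (n - 1))
    p_bar = float(P_i.mean())
    kappa = (p_bar - p_bar_e) / (1 - p_bar_e)

    q = 1 - p
    spq = float(np.sum(p * q))
    se = (np.sqrt(2.0) / (spq * np.sqrt(N * n * (n - 1)))
          * np.sqrt(spq ** 2 - float(np.sum(p * q * (q - p)))))
    z = stats.norm.ppf(1 - alpha / 2)
    band = next(desc for lo, hi, desc in KAPPA_BANDS if lo <= kappa < hi)
    cat_counts = {c: int(counts[:, j].sum()) for j, c in enumerate(cats)}
    return KappaResult(kappa=float(kappa), ci_low=float(kappa - z * se),
                       ci_high=float(kappa + z * se), se=float(se),
                       category_counts=cat_counts, interpretation=band)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups, chi-square p with
    (groups - 1) degrees of freedom."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        raise DegenerateDataError("all values identical: test degenerate")
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    ties = len(np.unique(flat)) < len(flat)
    return KWResult(statistic=float(h), df=len(groups) - 1, p_value=float(p),
                    group_sizes=[len(g) for g in groups], tie_corrected=ties)


def simulate_icc_table(n_nodules: int, n_observers: int,
                       sigma2_nodule: float, sigma2_observer: float,
                       sigma2_residual: float, seed: int = 0,
                       grand_mean: float = 50.0,
                       voxel_class: str = "X") -> pd.DataFrame:
    """Draw one observer table from the two-way random-effects model
    y_ij = mu + nodule_i + observer_j + e_ij — the generating model the ICC
    estimator assumes. Used for estimator-recovery and CI-calibration
    studies."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(sigma2_nodule), n_nodules)
    b = rng.normal(0, np.sqrt(sigma2_observer), n_observers)
    e = rng.normal(0, np.sqrt(sigma2_residual), (n_nodules, n_observers))
    Y = grand_mean + a[:, None] + b[None, :] + e
    rows = [{"nodule": i, "observer": j, "voxel_class": voxel_class,
             "fraction_pct": Y[i, j]}
            for i in range(n_nodules) for j in range(n_observers)]
    return pd.DataFrame(rows, columns=list(OBSERVER_TABLE_COLUMNS))


# --- end-to-end observer study ----------------------------------------------

@dataclass
class DSCSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    values: pd.DataFrame  # nodule, observer_a, observer_b, dsc


@dataclass
class ObserverStudyReport:
    """Everything the inter-observer analysis produces for one cohort."""

    table: pd.DataFrame            # long ObserverTable (fractions in %)
    signatures: pd.DataFrame       # one row per nodule-observer
    risk_calls: pd.DataFrame       # nodule x observer categories
    icc_panel: pd.DataFrame
    variance_decomposition: pd.DataFrame
    dsc_summary: DSCSummary
    kappa: KappaResult
    manifest: dict


def signatures_to_observer_table(signatures: pd.DataFrame) -> pd.DataFrame:
    """Convert wide per-nodule-observer signature rows to the long
    ObserverTable format (fractions on the percent scale)."""
    records = []
    for _, row in signatures.iterrows():
        for cls in PALETTE:
            records.append({"nodule": row["nodule"], "observer": row["observer"],
                            "voxel_class": cls, "fraction_pct": 100.0 * row[cls]})
    return pd.DataFrame(records, columns=list(OBSERVER_TABLE_COLUMNS))


def observer_study(cohort: Sequence[GroundTruth], model: ExemplarModel,
                   observers: Sequence[ObserverJitter],
                   rule: RiskRule | None = None) -> ObserverStudyReport:
    """Run the full inter-observer pipeline on a phantom cohort.

    Each simulated observer segments every nodule (jittered truth), every
    segmentation is classified into a parametric signature and risk call,
    and the agreement battery (per-class ICC panel, variance decomposition,
    pairwise Dice, Fleiss kappa on risk categories) is computed over the
    resulting nodule-by-observer tables. Deterministic given the cohort and
    the observers' seeds.
    """
    if len(observers) < 2:
        raise ValueError("need >= 2 observers")
    rule = rule or RiskRule()

    sig_rows, dsc_rows = [], []
    masks: dict[tuple[int, int], VoxelMask] = {}
    for nid, truth in enumerate(cohort):
        for oid, jitter in enumerate(observers):
            per_nodule = ObserverJitter(
                boundary_sd=jitter.boundary_sd,
                vessel_inclusion_prob=jitter.vessel_inclusion_prob,
                rng_seed=(jitter.rng_seed * 100003 + nid) % (2**31 - 1),
                field_correlation_mm=jitter.field_correlation_mm,
                vessel_attach_mm=jitter.vessel_attach_mm)
            mask = simulate_observer_mask(truth, per_nodule)
            masks[(nid, oid)] = mask
            _, sig = classify_nodule(truth.volume, mask, model)
            call = risk_characterize(sig, rule)
            sig_rows.append(signature_row(nid, oid, sig, call))
        for a, b in itertools.combinations(range(len(observers)), 2):
            dsc_rows.append({"nodule": nid, "observer_a": a, "observer_b": b,
                             "dsc": dsc(masks[(nid, a)], masks[(nid, b)])})

    signatures = pd.DataFrame(sig_rows)
    table = signatures_to_observer_table(signatures)
    panel = icc_panel(table)

    var_rows = []
    aug = pd.concat([table, _viro_rows(table)], ignore_index=True)
    for cls in list(PALETTE) + ["VIRO"]:
        comp = variance_components(aug, cls)
        var_rows.append({"voxel_class": cls,
                         "sigma2_nodule": comp.sigma2_nodule,
                         "sigma2_observer": comp.sigma2_observer,
                         "sigma2_residual": comp.sigma2_residual,
                         "truncated": ";".join(comp.truncated)})
    var_df = pd.DataFrame(var_rows)

    dsc_df = pd.DataFrame(dsc_rows)
    vals = dsc_df["dsc"].to_numpy()
    mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(vals))
    dsc_summary = DSCSummary(mean=mean, sd=sd, ci_low=mean - half,
                             ci_high=mean + half, values=dsc_df)

    risk = signatures.pivot(index="nodule", columns="observer", values="risk")
    kappa = fleiss_kappa(risk.to_numpy())

    manifest = {
        "n_nodules": len(cohort),
        "n_observers": len(observers),
        "observer_seeds": [o.rng_seed for o in observers],
        "boundary_sd_mm": [o.boundary_sd for o in observers],
        "risk_rule": {"t_good": rule.t_good, "t_poor": rule.t_poor},
    }
    return ObserverStudyReport(table=table, signatures=signatures,
                               risk_calls=risk.reset_index(),
                               icc_panel=panel, variance_decomposition=var_df,
                               dsc_summary=dsc_summary, kappa=kappa,
                               manifest=manifest)
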
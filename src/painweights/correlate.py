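"""Spearman correlation analyses: ROI pruning, hypothesis testing, FDR, power.

The pipeline relates participant-level model summaries (the three precision
weights, |eta| and mu) to per-participant mean ROI source activity in the
anticipation/post-stimulation windows, to the P2 peak amplitude, and to
questionnaire covariates. Hypothesised tests are corrected with
Benjamini-Hochberg FDR within one family per (parameter x time window);
the P2 trio {w_stim, |eta|, mu} forms its own family. Exploratory tests are
reported uncorrected and flagged as tentative.

Redundant ROIs — spheres on the same anatomical structure and window whose
activities rank-correlate above 0.7 — are pruned down to the sphere nearest
the structure's centre of mass before any hypothesis testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROIRecord",
    "HypothesisMap",
    "STRUCTURE_CENTROIDS",
    "SENSORY_STRUCTURES",
    "CUE_STRUCTURES",
    "spearman",
    "bh_fdr",
    "prune_redundant",
    "run_hypothesised",
    "run_exploratory",
    "power_corr",
    "simulate_power",
]

RESULT_COLUMNS = [
    "parameter",
    "target",
    "window",
    "rho",
    "p_raw",
    "p_adjusted",
    "family",
    "flag",
]

#: Structures hypothesised to track somatosensory processing (tested against
#: the somatosensory weight 1/beta2).
SENSORY_STRUCTURES = (
    "postcentral gyrus",
    "middle frontal gyrus",
    "posterior cingulate",
    "inferior parietal",
)

#: Structures hypothesised to track cue/expectation processing (tested
#: against the cue weight 1/rho2 and |eta|).
CUE_STRUCTURES = (
    "subgenual cingulate",
    "middle frontal gyrus",
    "superior frontal gyrus",
    "inferior frontal gyrus",
    "inferior temporal gyrus",
    "orbitofrontal cortex",
)

# Editable table of approximate MNI centres of mass (mm) per structure and
# hemisphere; override via the `centroids` argument of prune_redundant.
STRUCTURE_CENTROIDS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("postcentral gyrus", "L"): (-42.0, -25.0, 53.0),
    ("postcentral gyrus", "R"): (41.0, -25.0, 53.0),
    ("middle frontal gyrus", "L"): (-33.0, 33.0, 35.0),
    ("middle frontal gyrus", "R"): (38.0, 33.0, 34.0),
    ("posterior cingulate", "L"): (-5.0, -43.0, 25.0),
    ("posterior cingulate", "R"): (7.0, -42.0, 22.0),
    ("inferior parietal", "L"): (-43.0, -46.0, 47.0),
    ("inferior parietal", "R"): (46.0, -46.0, 50.0),
    ("subgenual cingulate", "L"): (-5.0, 25.0, -10.0),
    ("subgenual cingulate", "R"): (5.0, 25.0, -10.0),
    ("superior frontal gyrus", "L"): (-18.0, 35.0, 42.0),
    ("superior frontal gyrus", "R"): (22.0, 31.0, 44.0),
    ("inferior frontal gyrus", "L"): (-45.0, 30.0, 14.0),
    ("inferior frontal gyrus", "R"): (50.0, 30.0, 14.0),
    ("inferior temporal gyrus", "L"): (-50.0, -28.0, -23.0),
    ("inferior temporal gyrus", "R"): (54.0, -31.0, -22.0),
    ("orbitofrontal cortex", "L"): (-31.0, 32.0, -18.0),
    ("orbitofrontal cortex", "R"): (33.0, 33.0, -16.0),
    ("middle temporal gyrus", "L"): (-56.0, -34.0, -2.0),
    ("middle temporal gyrus", "R"): (57.0, -37.0, -1.0),
}


@dataclass
class ROIRecord:
    """A 10 mm spherical ROI with per-participant mean source activity."""

    structure: str
    hemisphere: str
    mni: tuple[float, float, float]
    window: str
    activity: np.ndarray
    diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be > 0")
        self.activity = np.asarray(self.activity, dtype=float)

    @property
    def name(self) -> str:
        x, y, z = self.mni
        return f"{self.structure} ({self.hemisphere}) [{x:g},{y:g},{z:g}]"


@dataclass(frozen=True)
class HypothesisMap:
    """Parameter -> set of (structure, window) pairs tested as hypothesised.

    ``p2_parameters`` lists the parameters hypothesised to correlate with
    the P2 amplitude. The parameter keyed ``abs_eta`` is tested on |eta|.
    """

    roi_map: dict[str, frozenset[tuple[str, str]]]
    p2_parameters: tuple[str, ...] = ("w_stim", "abs_eta", "mu")

    @classmethod
    def default(
        cls, windows: Sequence[str] = ("late_anticipation", "post_stimulation")
    ) -> "HypothesisMap":
        roi_map = {
            "w_stim": frozenset(
                (s, w) for s in SENSORY_STRUCTURES for w in windows
            ),
            "w_cue": frozenset((s, w) for s in CUE_STRUCTURES for w in windows),
            "abs_eta": frozenset((s, w) for s in CUE_STRUCTURES for w in windows),
        }
        return cls(roi_map=roi_map)


def _param_values(params_table: pd.DataFrame, parameter: str) -> np.ndarray:
    """Column lookup; ``abs_eta`` is the absolute value of the eta column."""
    if parameter == "abs_eta":
        return np.abs(params_table["eta"].to_numpy(dtype=float))
    return params_table[parameter].to_numpy(dtype=float)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float, tails: int) -> float:
    """Exact permutation p: enumerate all orderings of the y-ranks."""
    import itertools

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    count = total = 0
    for perm in itertools.permutations(ry):
        r = float(np.mean(rx * (np.asarray(perm) - ry.mean()) / ry.std()))
        if tails == 1:
            count += r >= rho - 1e-12
        else:
            count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return count / total


def spearman(
    x: np.ndarray, y: np.ndarray, tails: int = 2
) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided or one-sided p-value.

    For n <= 8 without ties the p-value is the exact permutation
    probability (all n! orderings enumerated); otherwise the
    t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom is used, as in the usual large-sample test. ``tails=1`` tests
    the one-sided alternative rho > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    alternative = "greater" if tails == 1 else "two-sided"
    res = stats.spearmanr(x, y, alternative=alternative)
    rho = float(res.statistic)
    no_ties = (
        np.unique(x).size == x.size and np.unique(y).size == y.size
    )
    if x.size <= 8 and no_ties:
        return rho, _exact_spearman_p(x, y, rho, tails)
    return rho, float(res.pvalue)


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def prune_redundant(
    rois: Sequence[ROIRecord],
    centroids: Optional[dict] = None,
    threshold: float = 0.7,
) -> tuple[list[ROIRecord], list[dict]]:
    """Collapse redundant same-structure/window ROIs to the most central one.

    Within each (structure, window) group, while any ROI pair's activity
    Spearman rho strictly exceeds the threshold, the pair with the highest
    rho is resolved by dropping the member farther (Euclidean) from the
    structure's centre of mass; distance ties drop the later-listed ROI
    (logged). Pairs at or below the threshold are all kept.
    """
    centroids = STRUCTURE_CENTROIDS if centroids is None else centroids
    if not rois:
        raise ValueError("no ROIs supplied")
    kept: list[ROIRecord] = []
    dropped: list[dict] = []
    groups: dict[tuple[str, str], list[tuple[int, ROIRecord]]] = {}
    for i, r in enumerate(rois):
        groups.setdefault((r.structure, r.window), []).append((i, r))
    for (structure, window), members in groups.items():
        active = list(members)
        while len(active) > 1:
            best = None
            for a in range(len(active)):
                for b in range(a + 1, len(active)):
                    rho, _ = spearman(active[a][1].activity, active[b][1].activity)
                    if rho > threshold and (best is None or rho > best[0]):
                        best = (rho, a, b)
            if best is None:
                break
            rho, a, b = best
            ra, rb = active[a][1], active[b][1]
            da = _centroid_distance(ra, centroids)
            db = _centroid_distance(rb, centroids)
            if da < db:
                drop_pos = b
            elif db < da:
                drop_pos = a
            else:
                drop_pos = b if active[b][0] > active[a][0] else a
                warnings.warn(
                    f"centroid-distance tie for {structure}/{window}; "
                    "dropping the later-listed ROI",
                    stacklevel=2,
                )
            idx, roi = active.pop(drop_pos)
            dropped.append(
                {
                    "structure": structure,
                    "window": window,
                    "roi": roi.name,
                    "rho": rho,
                    "reason": "redundant with a more central ROI",
                }
            )
        kept.extend(active)
    kept.sort(key=lambda pair: pair[0])
    return [r for _, r in kept], dropped


def _centroid_distance(roi: ROIRecord, centroids: dict) -> float:
    key = (roi.structure, roi.hemisphere)
    if key not in centroids:
        raise ValueError(f"no centre-of-mass entry for {key}")
    return float(np.linalg.norm(np.asarray(roi.mni) - np.asarray(centroids[key])))


def _roi_targets(rois: Sequence[ROIRecord]) -> list[tuple[str, str, np.ndarray]]:
    return [(r.name, r.window, r.activity) for r in rois]


def run_hypothesised(
    params_table: pd.DataFrame,
    rois: Sequence[ROIRecord],
    p2_table: Optional[pd.DataFrame],
    hmap: Optional[HypothesisMap] = None,
    tails: int = 2,
) -> pd.DataFrame:
    """Hypothesis-driven correlations with per-family BH-FDR.

    ROI tests form one FDR family per (parameter, time window); the P2 trio
    is its own family. The cue-uncertainty parameter enters as |eta|.
    """
    hmap = hmap or HypothesisMap.default()
    rows = []
    for parameter, pairs in hmap.roi_map.items():
        x = _param_values(params_table, parameter)
        # a mapped structure absent from the ROI table is fine: it simply
        # produced no significant source cluster in this dataset
        for roi in rois:
            if (roi.structure, roi.window) not in pairs:
                continue
            rho, p = spearman(x, roi.activity, tails=tails)
            rows.append(
                {
                    "parameter": parameter,
                    "target": roi.name,
                    "window": roi.window,
                    "rho": rho,
                    "p_raw": p,
                    "family": f"{parameter}|{roi.window}",
                    "flag": "hypothesised",
                }
            )
    if p2_table is not None:
        amp = p2_table["amplitude"].to_numpy(dtype=float)
        for parameter in hmap.p2_parameters:
            x = _param_values(params_table, parameter)
            rho, p = spearman(x, amp, tails=tails)
            rows.append(
                {
                    "parameter": parameter,
                    "target": "P2 amplitude",
                    "window": "post_stimulation",
                    "rho": rho,
                    "p_raw": p,
                    "family": "p2",
                    "flag": "hypothesised",
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    result["p_adjusted"] = np.nan
    for fam, idx in result.groupby("family").groups.items():
        result.loc[idx, "p_adjusted"] = bh_fdr(result.loc[idx, "p_raw"])
    return result[RESULT_COLUMNS]


DEFAULT_PARAMETERS = ("w_stim", "w_cue", "w_bias", "abs_eta", "mu")


def run_exploratory(
    params_table: pd.DataFrame,
    rois: Sequence[ROIRecord],
    p2_table: Optional[pd.DataFrame],
    hmap: Optional[HypothesisMap] = None,
    covariates: Optional[pd.DataFrame] = None,
    mean_rating: Optional[np.ndarray] = None,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    tails: int = 2,
) -> pd.DataFrame:
    """All parameter x target pairs not claimed by the hypothesis map.

    Uncorrected p-values only; results are flagged tentative. Together with
    :func:`run_hypothesised` this partitions the full parameter x target
    grid exactly once.
    """
    hmap = hmap or HypothesisMap.default()
    rows = []
    for parameter in parameters:
        x = _param_values(params_table, parameter)
        claimed = hmap.roi_map.get(parameter, frozenset())
        for roi in rois:
            if (roi.structure, roi.window) in claimed:
                continue
            rho, p = spearman(x, roi.activity, tails=tails)
            rows.append((parameter, roi.name, roi.window, rho, p))
        if p2_table is not None and parameter not in hmap.p2_parameters:
            amp = p2_table["amplitude"].to_numpy(dtype=float)
            rho, p = spearman(x, amp, tails=tails)
            rows.append((parameter, "P2 amplitude", "post_stimulation", rho, p))
        if covariates is not None:
            for col in covariates.columns:
                rho, p = spearman(
                    x, covariates[col].to_numpy(dtype=float), tails=tails
                )
                rows.append((parameter, col, "behaviour", rho, p))
        if mean_rating is not None:
            rho, p = spearman(x, np.asarray(mean_rating, float), tails=tails)
            rows.append((parameter, "mean rating", "behaviour", rho, p))
    result = pd.DataFrame(
        rows, columns=["parameter", "target", "window", "rho", "p_raw"]
    )
    result["p_adjusted"] = np.nan
    result["family"] = "exploratory"
    result["flag"] = "exploratory"
    return result[RESULT_COLUMNS]


def power_corr(n: int, rho: float, alpha: float = 0.05, tails: int = 1) -> float:
    """Closed-form power of a correlation test via the Fisher z approximation.

    power = Phi(atanh(rho) * sqrt(n - 3) - z_{1 - alpha/tails}).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    z_crit = stats.norm.ppf(1 - alpha / tails)
    return float(stats.norm.cdf(np.arctanh(rho) * np.sqrt(n - 3) - z_crit))


def simulate_power(
    n: int,
    rho: float,
    alpha: float = 0.05,
    tails: int = 1,
    reps: int = 20000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power: bivariate-normal samples, t-approximation test.

    Draws ``reps`` samples of size ``n`` with population correlation
    ``rho``, tests H0: rho <= 0 (one-tailed) or rho = 0 (two-tailed) on the
    Pearson correlation via t = r*sqrt((n-2)/(1-r^2)), and returns the
    rejection fraction. Agrees with :func:`power_corr` within Monte-Carlo
    error.
    """
    if n < 4 or not 0 < rho < 1 or not 0 < alpha < 1 or tails not in (1, 2):
        raise ValueError("invalid power-simulation settings")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n))
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt(
        (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
    )
    t = r * np.sqrt((n - 2) / (1 - r**2))
    if tails == 1:
        p = stats.t.sf(t, df=n - 2)
    else:
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return float(np.mean(p < alpha))
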
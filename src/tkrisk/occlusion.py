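"""Occlusion-map imaging-biomarker identification.

For each subject an occlusion map records, per voxel, the mean absolute
change in the pipeline's scalar TKR-risk output when a sliding block
containing that voxel is masked out. The top 5% of covered voxels form the
subject's "hotspots". Cases are paired with OA-matched, KOOS-pain-matched
true-negative controls, and for each atlas tissue a 2x2 table counts in how
many cases vs controls the tissue intersects a hotspot. The tissue's odds
ratio is reported with an exact conditional (Cornfield) 95% confidence
interval and a two-tailed Fisher exact p value; a tissue is significant only
if p < alpha AND the interval excludes 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from tkrisk.synthetic import SubjectRecord, TissueAtlas

__all__ = [
    "OcclusionConfig",
    "OcclusionMap",
    "ContingencyResult",
    "occlusion_map",
    "hotspot_mask",
    "match_controls",
    "tissue_hotspot_flags",
    "contingency_counts",
    "odds_ratio",
    "cornfield_ci",
    "fisher_exact_two_tailed",
    "biomarker_table",
]


@dataclass(frozen=True)
class OcclusionConfig:
    """Occluder geometry and hotspot/significance thresholds.

    Full-scale geometry is a 12 x 32 x 32 occluder with stride 12; the desk
    default is proportionally scaled for 24 x 48 x 48 grids.
    """

    voxel_shape: tuple[int, ...] = (6, 12, 12)
    stride: tuple[int, ...] = (6, 12, 12)
    fill_value: float = 0.0
    fill_mode: str = "constant"  # or "mean": occluder filled with volume mean
    hotspot_fraction: float = 0.05
    alpha: float = 0.05
    signed: bool = False
    # absolute output-change floor for the per-subject tissue flag: 0 means
    # any hotspot voxel in the tissue flags it
    min_response: float = 0.0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.stride):
            raise ValueError("stride must be >= 1")
        if not 0.0 < self.hotspot_fraction < 1.0:
            raise ValueError("hotspot_fraction must lie in (0, 1)")


@dataclass
class OcclusionMap:
    """Per-voxel mean |risk change| plus the coverage count per voxel."""

    values: np.ndarray
    coverage: np.ndarray
    subject_ref: tuple[str, float] = ("", 0.0)


@dataclass
class ContingencyResult:
    """2x2 hotspot counts for one tissue with OR, CI, p and significance."""

    tissue: str
    a: int  # cases flagged
    b: int  # cases not flagged
    c: int  # controls flagged
    d: int  # controls not flagged
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool
    note: str = ""


def occlusion_map(
    risk_fn: Callable[[np.ndarray], float],
    volume: np.ndarray,
    config: OcclusionConfig = OcclusionConfig(),
    vectorized: bool = False,
) -> OcclusionMap:
    """Slide the occluder over ``volume`` and record mean |risk changes|.

    Occluder positions start at offset 0 and advance by ``stride`` per axis,
    keeping the occluder fully inside the volume. At each position the block
    is replaced by the fill value and the absolute change in ``risk_fn``
    output recorded; each voxel's map value is the mean over all positions
    covering it. Voxels covered by no position get 0 and coverage 0 (they
    are excluded from hotspot ranking).

    With ``vectorized=True`` ``risk_fn`` must accept a stacked array of
    shape ``(n,) + volume.shape`` and return ``n`` scalars; occlusions are
    then evaluated in one call.
    """
    vol = np.asarray(volume, dtype=np.float64)
    shp = vol.shape
    occ = config.voxel_shape
    if len(occ) != vol.ndim:
        raise ValueError("occluder dimensionality must match the volume")
    if any(o > s for o, s in zip(occ, shp)):
        raise ValueError(f"occluder {occ} larger than volume {shp}")
    fill = vol.mean() if config.fill_mode == "mean" else config.fill_value

    offsets = [
        range(0, s - o + 1, st) for s, o, st in zip(shp, occ, config.stride)
    ]
    positions = [
        tuple(slice(i, i + o) for i, o in zip(corner, occ))
        for corner in np.stack(
            np.meshgrid(*offsets, indexing="ij"), axis=-1
        ).reshape(-1, vol.ndim)
    ]

    base = float(np.asarray(risk_fn(vol[None])).reshape(-1)[0]) if vectorized else float(
        risk_fn(vol)
    )
    if vectorized:
        batch = np.broadcast_to(vol, (len(positions),) + shp).copy()
        for i, pos in enumerate(positions):
            batch[(i, *pos)] = fill
        risks = np.asarray(risk_fn(batch), dtype=float).reshape(-1)
        if risks.size != len(positions):
            raise ValueError("vectorized risk_fn returned a wrong-length result")
    else:
        risks = np.empty(len(positions))
        for i, pos in enumerate(positions):
            occluded = vol.copy()
            occluded[pos] = fill
            risks[i] = float(risk_fn(occluded))

    deltas = risks - base
    if not config.signed:
        deltas = np.abs(deltas)
    total = np.zeros(shp)
    coverage = np.zeros(shp, dtype=np.int32)
    for pos, delta in zip(positions, deltas):
        total[pos] += delta
        coverage[pos] += 1
    values = np.zeros(shp)
    covered = coverage > 0
    values[covered] = total[covered] / coverage[covered]
    return OcclusionMap(values=values, coverage=coverage)


def hotspot_mask(omap: OcclusionMap, fraction: float = 0.05) -> np.ndarray:
    """Flag the top ``fraction`` of covered voxels by map value.

    Exactly ``floor(fraction * n_covered)`` voxels are flagged; ties at the
    cut are broken by ascending linear voxel index for determinism.
    """
    covered_idx = np.flatnonzero(omap.coverage.ravel() > 0)
    n_ranked = covered_idx.size
    if n_ranked == 0:
        raise ValueError("map has no covered voxels")
    n_flag = int(math.floor(fraction * n_ranked))
    if n_flag < 1:
        raise ValueError(
            f"fraction {fraction} of {n_ranked} ranked voxels flags no voxel"
        )
    vals = omap.values.ravel()[covered_idx]
    # sort by (-value, linear index): stable top-n with deterministic ties
    order = np.lexsort((covered_idx, -vals))
    flagged = covered_idx[order[:n_flag]]
    mask = np.zeros(omap.values.size, dtype=bool)
    mask[flagged] = True
    return mask.reshape(omap.values.shape)


def match_controls(
    cases: Sequence[SubjectRecord],
    control_pool: Sequence[SubjectRecord],
    seed: int = 0,
    alpha: float = 0.05,
    max_attempts: int = 1000,
) -> list[SubjectRecord]:
    """Sample OA-matched controls with comparable KOOS pain.

    Per stratum, exactly as many controls as cases are drawn without
    replacement from the pool, keeping the OA-status distribution identical.
    The draw is accepted iff a paired t-test on KOOS pain across the n
    matched pairs (n - 1 degrees of freedom) does not reject at ``alpha``;
    otherwise it is redrawn, up to ``max_attempts``. Returns the controls in
    pairing order (aligned with ``cases``).
    """
    cases = list(cases)
    by_stratum: dict[str, list[SubjectRecord]] = {}
    for r in control_pool:
        by_stratum.setdefault(r.stratum, []).append(r)
    need: dict[str, int] = {}
    for r in cases:
        need[r.stratum] = need.get(r.stratum, 0) + 1
    for stratum, n in need.items():
        if len(by_stratum.get(stratum, [])) < n:
            raise ValueError(
                f"stratum {stratum!r}: need {n} controls, pool has "
                f"{len(by_stratum.get(stratum, []))}"
            )
    rng = np.random.default_rng(seed)
    case_koos = np.array([r.koos_pain for r in cases])
    for _ in range(max_attempts):
        picked: dict[str, list[SubjectRecord]] = {}
        for stratum, n in need.items():
            pool = by_stratum[stratum]
            idx = rng.choice(len(pool), size=n, replace=False)
            picked[stratum] = [pool[i] for i in idx]
        controls: list[SubjectRecord] = []
        cursor = {s: 0 for s in need}
        for r in cases:
            controls.append(picked[r.stratum][cursor[r.stratum]])
            cursor[r.stratum] += 1
        ctrl_koos = np.array([r.koos_pain for r in controls])
        diffs = case_koos - ctrl_koos
        if len(diffs) < 2:
            p = 1.0  # a single pair cannot be tested; accept
        elif diffs.std(ddof=1) == 0.0:
            p = 1.0 if abs(diffs.mean()) < 1e-12 else 0.0
        else:
            p = float(sps.ttest_rel(case_koos, ctrl_koos).pvalue)
        if p >= alpha:
            return controls
    raise ValueError(
        f"no KOOS-matched control sample found in {max_attempts} attempts"
    )


def tissue_hotspot_flags(
    mask: np.ndarray,
    atlas: TissueAtlas,
    min_voxels: int = 1,
    min_fraction: Optional[float] = None,
    values: Optional[np.ndarray] = None,
    min_response: float = 0.0,
) -> dict[str, bool]:
    """Per-tissue flag: does the hotspot mask intersect the tissue region?

    By default a tissue is flagged when at least one hotspot voxel lies
    inside it; ``min_voxels`` or ``min_fraction`` (of the tissue's volume)
    raise that threshold. With ``values`` (the occlusion map) and
    ``min_response`` > 0, the flag additionally requires some hotspot voxel
    in the tissue to carry an occlusion response of at least
    ``min_response`` — a subject whose map is essentially flat (top
    percentile or not) then flags nothing, since a percentile of noise is
    still noise.
    """
    if mask.shape != atlas.label_grid.shape:
        raise ValueError("mask and atlas shapes differ")
    if values is not None and values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    flags: dict[str, bool] = {}
    for label in sorted(atlas.names):
        region = atlas.label_grid == label
        hot = mask & region
        hits = int(hot.sum())
        threshold = min_voxels
        if min_fraction is not None:
            threshold = max(threshold, min_fraction * region.sum())
        flagged = hits >= threshold
        if flagged and min_response > 0.0 and values is not None:
            flagged = bool(values[hot].max() >= min_response)
        flags[atlas.names[label]] = flagged
    return flags


def contingency_counts(
    case_flags: Sequence[bool], control_flags: Sequence[bool], tissue: str = ""
) -> tuple[int, int, int, int]:
    """2x2 counts (a, b, c, d): cases flagged/unflagged, controls likewise."""
    a = int(sum(bool(f) for f in case_flags))
    b = len(case_flags) - a
    c = int(sum(bool(f) for f in control_flags))
    d = len(control_flags) - c
    return a, b, c, d


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio (a*d)/(b*c) with boundary conventions.

    0 when ``a*d = 0`` and ``b*c > 0``; infinite when ``b*c = 0`` and
    ``a*d > 0``; undefined (error) when both products are 0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        raise ValueError("odds ratio undefined: both cross-products are zero")
    if bc == 0:
        return float("inf")
    return ad / bc


def _conditional_tails(a: int, b: int, c: int, d: int, log_psi: float):
    """Upper/lower tail P(X >= a), P(X <= a) of the conditional distribution.

    X is the count in cell (1,1) given all margins fixed, distributed as
    Fisher's noncentral hypergeometric with odds ``exp(log_psi)``.
    """
    M = a + b + c + d
    n_flag = a + c
    n_cases = a + b
    dist = sps.nchypergeom_fisher(M, n_flag, n_cases, np.exp(log_psi))
    return float(dist.sf(a - 1)), float(dist.cdf(a))


def cornfield_ci(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact conditional (Cornfield-style) confidence interval for the OR.

    The lower endpoint solves ``P(X >= a | psi) = (1 - level)/2`` and the
    upper endpoint ``P(X <= a | psi) = (1 - level)/2`` in the noncentral
    hypergeometric model with all margins fixed, by bracketed root-finding
    on log psi. Conventions: lower endpoint 0 when ``a = 0`` or ``d = 0``;
    upper endpoint infinite when ``b = 0`` or ``c = 0``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a zero margin leaves the odds ratio unidentified")
    target = (1.0 - level) / 2.0

    def solve(tail_index: int) -> float:
        # tail_index 0: upper tail (lower endpoint); 1: lower tail (upper endpoint)
        def f(log_psi: float) -> float:
            return _conditional_tails(a, b, c, d, log_psi)[tail_index] - target

        lo, hi = -40.0, 40.0
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            # no sign change: endpoint escapes to the boundary
            return 0.0 if tail_index == 0 else float("inf")
        root = brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)
        return float(np.exp(root))

    ci_low = 0.0 if (a == 0 or d == 0) else solve(0)
    ci_high = float("inf") if (b == 0 or c == 0) else solve(1)
    return ci_low, ci_high


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p by the point-probability method.

    Sums the central hypergeometric probabilities (margins fixed) of every
    table whose probability does not exceed that of the observed table,
    computed in exact integer arithmetic and capped at 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n_cases = a + b
    n_flag = a + c
    M = a + b + c + d
    lo = max(0, n_flag - (M - n_cases))
    hi = min(n_flag, n_cases)
    # unnormalized integer weights: C(n_cases, x) * C(M - n_cases, n_flag - x)
    weights = [
        math.comb(n_cases, x) * math.comb(M - n_cases, n_flag - x)
        for x in range(lo, hi + 1)
    ]
    observed = weights[a - lo]
    total = sum(weights)
    tail = sum(w for w in weights if w <= observed)
    return min(1.0, tail / total)


def biomarker_table(
    case_flags: Sequence[dict[str, bool]],
    control_flags: Sequence[dict[str, bool]],
    atlas: TissueAtlas,
    config: OcclusionConfig = OcclusionConfig(),
) -> list[ContingencyResult]:
    """Per-tissue odds-ratio table over matched case/control hotspot flags.

    One row per atlas tissue, sorted by tissue name. ``significant`` is set
    by the dual rule: Fisher p < alpha AND the Cornfield interval excludes 1.
    Tissues whose odds ratio is undefined (flagged in nobody or everybody)
    are emitted with a note rather than dropped.
    """
    if len(case_flags) != len(control_flags):
        raise ValueError("need equal numbers of cases and matched controls")
    results = []
    for tissue in sorted(atlas.names.values()):
        a, b, c, d = contingency_counts(
            [f[tissue] for f in case_flags],
            [f[tissue] for f in control_flags],
            tissue,
        )
        try:
            or_ = odds_ratio(a, b, c, d)
        except ValueError as exc:
            results.append(
                ContingencyResult(
                    tissue, a, b, c, d, float("nan"), float("nan"),
                    float("nan"), float("nan"), False, note=str(exc),
                )
            )
            continue
        p = fisher_exact_two_tailed(a, b, c, d)
        try:
            ci_low, ci_high = cornfield_ci(a, b, c, d)
            note = ""
        except ValueError as exc:
            ci_low, ci_high = float("nan"), float("nan")
            note = str(exc)
        excludes_one = not (np.isnan(ci_low) or np.isnan(ci_high)) and (
            ci_low > 1.0 or ci_high < 1.0
        )
        results.append(
            ContingencyResult(
                tissue, a, b, c, d, or_, ci_low, ci_high, p,
                significant=bool(p < config.alpha and excludes_one),
                note=note,
            )
        )
    return results
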
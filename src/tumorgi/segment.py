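"""Circular binary segmentation and five-state copy-number calling.

The tumor/control log2 ratio track is segmented per chromosome arm by
recursive circular binary segmentation (CBS): at each step the arc (i, j]
maximizing the standardized difference between the arc mean and the mean of
its complement is tested against a permutation null; accepted splits are
recursed into, and adjacent segments closer than ``undo_sd`` residual
standard deviations are merged back.  Segment means are re-anchored so the
modal (diploid) level sits at zero, then classified into the five canonical
states: double deletion (−2), single deletion (−1), diploid (0), single
amplification (+1) and high amplification (≥+2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SegmentProfile",
    "SexCall",
    "compute_log_ratio",
    "max_arc_statistic",
    "cbs_segment",
    "postsegment_normalize",
    "call_states",
    "residual_sd",
    "infer_sex",
    "STATE_LEVELS",
]

#: canonical log2 levels of the copy-number states on a diploid background
STATE_LEVELS = {
    -2: np.log2(0.5 / 2),  # capped double deletion
    -1: np.log2(1 / 2),
    0: 0.0,
    1: np.log2(3 / 2),
    2: np.log2(4 / 2),  # ">= +2": everything at or above this level
}


@dataclass
class SegmentProfile:
    """Per-arm segmentation of one tumor/control comparison.

    ``segments`` tiles the kept bins of each arm: columns chrom, start_bin /
    end_bin (half-open indices into that arm's kept-bin vector), start / end
    (bp, 0-based half-open on the genome), mean (log2 ratio), n_bins.
    """

    segments: pd.DataFrame
    tumor: str = ""
    control: str = ""
    masked: bool = False
    shift: float = 0.0  # applied by postsegment_normalize

    def with_segments(self, segments: pd.DataFrame, **kw) -> "SegmentProfile":
        out = SegmentProfile(segments=segments, tumor=self.tumor,
                             control=self.control, masked=self.masked,
                             shift=self.shift)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class SexCall:
    sample_id: str
    sex: str  # male | female | ambiguous
    x_autosome_ratio: float
    y_region_ratio: float


def compute_log_ratio(tumor: np.ndarray, control: np.ndarray,
                      eps: float = 0.5) -> np.ndarray:
    """Median-centered log2((tumor+eps)/(control+eps)) per bin.

    ``eps`` is a pseudo-count (default half a read per bin) guarding empty
    bins; the median centering absorbs any global scale difference between
    the two samples.
    """
    tumor = np.asarray(tumor, dtype=float)
    control = np.asarray(control, dtype=float)
    if tumor.shape != control.shape:
        raise ValueError("tumor and control are on different bin grids")
    ratio = np.log2((tumor + eps) / (control + eps))
    return ratio - np.median(ratio)


# ---------------------------------------------------------------------------
# CBS core


def max_arc_statistic(x: np.ndarray):
    """Maximum CBS arc statistic over all arcs (i, j] of ``x``.

    Returns ``(t_max, i, j)`` where ``t_max = |mean(arc) − mean(rest)| /
    (s·sqrt(1/k + 1/(n−k)))`` with ``s`` the sample SD of ``x``.  Arcs that
    wrap around the circle are equivalent to complements of linear arcs, so
    scanning linear arcs covers them all.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 bins")
    s = x.std()
    if s == 0:
        return 0.0, 0, n
    S = np.concatenate(([0.0], np.cumsum(x)))
    tot = S[-1]
    best_u, best_i, best_j = -1.0, 0, n
    for k in range(1, n):
        d = S[k:] - S[:-k]
        u = np.abs(d - tot * k / n) * np.sqrt(n / (k * (n - k)))
        i = int(np.argmax(u))
        if u[i] > best_u:
            best_u, best_i, best_j = float(u[i]), i, i + k
    return best_u / s, best_i, best_j


def _perm_exceedances(x, u_obs_scaled, n_perm, rng, alpha, batch=64):
    """Count permutations whose max arc statistic reaches the observed one.

    Works on the scale-free statistic (the sample SD is permutation
    invariant, so it cancels).  Stops early on either side of the decision:
    once enough exceedances rule out significance, or once zero exceedances
    over > 1/alpha permutations already put the Monte-Carlo p-value
    (count+1)/(done+1) below alpha.  Returns (exceedances, permutations done).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = np.sqrt(n / (np.arange(1, n) * (n - np.arange(1, n))))
    tot = x.sum()
    reject_at = int(np.ceil(alpha * (n_perm + 1)))
    accept_at = int(np.ceil(1.0 / alpha))  # done such that 1/(done+1) < alpha
    count = done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = rng.permuted(np.broadcast_to(x, (b, n)), axis=1)
        S = np.concatenate([np.zeros((b, 1)), np.cumsum(P, axis=1)], axis=1)
        best = np.zeros(b)
        for k in range(1, n):
            d = np.abs(S[:, k:] - S[:, :-k] - tot * k / n) * w[k - 1]
            np.maximum(best, d.max(axis=1), out=best)
        count += int((best >= u_obs_scaled - 1e-12).sum())
        done += b
        if count >= reject_at:
            break
        if count == 0 and done >= accept_at:
            break
    return count, done


def _segment_recursive(x, lo, hi, alpha, n_perm, rng, boundaries):
    n = hi - lo
    if n < 2:
        return
    t, i, j = max_arc_statistic(x[lo:hi])
    if t == 0.0:
        return
    # observed statistic on the permutation scale (SD cancels)
    u_scaled = t * x[lo:hi].std()
    count, done = _perm_exceedances(x[lo:hi], u_scaled, n_perm, rng, alpha)
    p = (count + 1) / (done + 1)
    if p >= alpha:
        return
    cuts = sorted({lo + i, lo + j} - {lo, hi})
    if not cuts:
        return
    boundaries.update(cuts)
    edges = [lo] + cuts + [hi]
    for a, b in zip(edges, edges[1:]):
        _segment_recursive(x, a, b, alpha, n_perm, rng, boundaries)


def _sd_undo(x, edges, undo_sd):
    """Merge adjacent segments whose means differ by < undo_sd * residual SD."""
    while len(edges) > 2:
        means = np.array([x[a:b].mean() for a, b in zip(edges, edges[1:])])
        resid = x - np.repeat(means, np.diff(edges))
        sd = residual_sd(resid)
        gaps = np.abs(np.diff(means))
        k = int(np.argmin(gaps))
        if sd == 0 or gaps[k] >= undo_sd * sd:
            break
        del edges[k + 1]
    return edges


def residual_sd(residuals: np.ndarray) -> float:
    """Robust residual SD: scaled median absolute deviation."""
    residuals = np.asarray(residuals, dtype=float)
    return float(1.4826 * np.median(np.abs(residuals - np.median(residuals))))


def cbs_segment(values: np.ndarray, alpha: float = 0.01, undo_sd: float = 3.0,
                n_perm: int = 1000, rng=None) -> pd.DataFrame:
    """Segment one arm's ratio vector by circular binary segmentation.

    Returns a DataFrame (start_bin, end_bin, mean, n_bins) tiling the
    vector.  ``alpha`` is the permutation p-value cutoff for accepting a
    split and ``undo_sd`` the minimum separation (in residual SDs) between
    adjacent segment means retained after splitting.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("empty arm")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation p-value")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    boundaries: set = set()
    if len(x) >= 2 and x.std() > 0:
        _segment_recursive(x, 0, len(x), alpha, n_perm, rng, boundaries)
    edges = [0] + sorted(boundaries) + [len(x)]
    edges = _sd_undo(x, edges, undo_sd)
    rows = [
        (a, b, float(x[a:b].mean()), b - a) for a, b in zip(edges, edges[1:])
    ]
    return pd.DataFrame(rows, columns=["start_bin", "end_bin", "mean", "n_bins"])


# ---------------------------------------------------------------------------
# post-processing and calling


def postsegment_normalize(profile: SegmentProfile) -> SegmentProfile:
    """Anchor the modal segment level at zero (the diploid baseline).

    The mode of the bin-weighted segment-mean distribution is located by
    evaluating a weighted Gaussian kernel density at the segment means
    themselves; all means are then shifted so that mode sits at 0.  The
    operation is invariant to a constant shift of the input profile.
    """
    seg = profile.segments
    if len(seg) == 0:
        raise ValueError("empty segment profile")
    means = seg["mean"].to_numpy(dtype=float)
    weights = seg["n_bins"].to_numpy(dtype=float)
    h = 0.05  # log2 units; narrow enough to separate copy-number levels
    dens = (weights[None, :] * np.exp(-0.5 * ((means[:, None] - means[None, :]) / h) ** 2)).sum(axis=1)
    mode = means[int(np.argmax(dens))]
    out = seg.copy()
    out["mean"] = means - mode
    return profile.with_segments(out, shift=float(-mode))


def call_states(profile: SegmentProfile, noise_sd: float,
                call_margin: float = 0.2, high_amp_level: float = 1.0,
                double_del_level: float = -1.5) -> pd.DataFrame:
    """Classify post-normalized segments into the five copy-number states.

    A segment leaves the diploid state only if ``|mean| >
    max(call_margin, 2·noise_sd/sqrt(n_bins))``.  Beyond that margin the
    call follows the sign, escalating to high amplification (+2, ≥ 4
    copies) at or above ``high_amp_level`` and to double deletion at or
    below ``double_del_level``.  Sign-based single-copy boundaries (rather
    than proximity to the canonical levels ±log2(3/2), −1) are deliberate:
    cross-sample normalization attenuates single-copy segments to a
    tumor-dependent fraction of their canonical level, which is why
    mixture-based callers fit the levels per sample instead of assuming
    them.  Only non-diploid segments are returned as calls (1-based
    inclusive coordinates for reporting).
    """
    seg = profile.segments
    rows = []
    for row in seg.itertuples(index=False):
        margin = max(call_margin, 2.0 * noise_sd / np.sqrt(row.n_bins))
        if abs(row.mean) <= margin:
            continue
        if row.mean >= high_amp_level:
            state = 2
        elif row.mean > 0:
            state = 1
        elif row.mean <= double_del_level:
            state = -2
        else:
            state = -1
        rows.append(
            (row.chrom if hasattr(row, "chrom") else "", int(row.start) + 1,
             int(row.end), state, int(row.n_bins), float(row.mean))
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "n_bins", "mean"]
    )


def stitch_calls(calls: pd.DataFrame, max_gap: int = 10_000) -> pd.DataFrame:
    """Merge same-state calls separated by at most ``max_gap`` bp.

    Quantile normalization can leave a few rank-junction bins inside a large
    event at an intermediate level, splitting one lesion into adjacent
    calls; stitching re-joins them (the gap also absorbs masked-bin holes).
    Means are recombined weighted by n_bins.
    """
    if len(calls) == 0:
        return calls
    out = []
    group_cols = [c for c in ("sample_id",) if c in calls.columns]
    for _, sub in calls.groupby(group_cols + ["chrom", "state"], sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            d = row._asdict()
            if cur is not None and d["start"] - cur["end"] - 1 <= max_gap:
                w = cur["n_bins"] + d["n_bins"]
                cur["mean"] = (cur["mean"] * cur["n_bins"] + d["mean"] * d["n_bins"]) / w
                cur["n_bins"] = w
                cur["end"] = d["end"]
            else:
                if cur is not None:
                    out.append(cur)
                cur = d
        out.append(cur)
    return (
        pd.DataFrame(out)[list(calls.columns)]
        .sort_values(group_cols + ["chrom", "start"])
        .reset_index(drop=True)
    )


def infer_sex(control_values: np.ndarray, model, sample_id: str = "",
              kept: np.ndarray | None = None) -> SexCall:
    """Call sample sex from X/autosome and Y-proxy coverage ratios.

    A male genome has one X (ratio ≈ 0.5) and a covered Y proxy region
    (ratio ≈ 0.5); a female has ratio ≈ 1 and an empty Y region.  The
    decision uses X/A < 0.75 with Y/A > 0.25 for male, X/A > 0.75 with
    Y/A < 0.1 for female, and flags everything else ambiguous.
    """
    values = np.asarray(control_values, dtype=float)
    use = model.mappability > 0
    if kept is not None:
        use = use & kept
    if "X" not in model.chrom_names or not use[model.arm_slice("X")].any():
        raise ValueError("no usable X-chromosome bins for sex inference")
    auto = np.zeros(model.n_bins_total, dtype=bool)
    for c in model.autosomes:
        auto[model.arm_slice(c)] = True
    a_mean = values[auto & use].mean()
    x_sl = model.arm_slice("X")
    x_mask = np.zeros_like(auto)
    x_mask[x_sl] = True
    x_ratio = values[x_mask & use].mean() / a_mean
    y_ratio = 0.0
    if model.y_region is not None:
        chrom, s, e = model.y_region
        idx = model.bins_in(chrom, s, e)
        y_ratio = values[idx][model.mappability[idx] > 0].mean() / a_mean
    if x_ratio < 0.75 and y_ratio > 0.25:
        sex = "male"
    elif x_ratio > 0.75 and y_ratio < 0.1:
        sex = "female"
    else:
        sex = "ambiguous"
    return SexCall(sample_id=sample_id, sex=sex,
                   x_autosome_ratio=float(x_ratio), y_region_ratio=float(y_ratio))
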
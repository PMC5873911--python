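"""CNV catalog summaries: burden, rates, turnover, group comparisons.

Call intervals are 1-based inclusive throughout this module (the reporting
convention, e.g. chr3R:20994001-27965000); BED output converts back to
0-based half-open.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "TurnoverRecord",
    "interval_overlap_length",
    "interval_length",
    "summarize_catalog",
    "cnv_rate_per_mb",
    "cnv_turnover",
    "mann_whitney",
    "match_calls",
]


@dataclass
class TurnoverRecord:
    line: str
    from_timepoint: int
    to_timepoint: int
    cnv_class: str  # dup | del
    n_prev: int
    n_passed: int
    n_new: int

    @property
    def n_lost(self) -> int:
        return self.n_prev - self.n_passed


def interval_length(a: tuple) -> int:
    """Length in bp of a 1-based inclusive interval (chrom, start, end)."""
    _, start, end = a
    return max(0, end - start + 1)


def interval_overlap_length(a: tuple, b: tuple) -> int:
    """Intersection length in bp of two 1-based inclusive intervals.

    Different chromosomes overlap by 0 (with a warning, since that usually
    signals a bookkeeping mistake upstream).
    """
    if a[0] != b[0]:
        warnings.warn(f"intervals on different chromosomes: {a[0]} vs {b[0]}")
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]) + 1)


def _gene_tree(genes: pd.DataFrame) -> dict:
    trees: dict = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end), getattr(row, "id", None)
        )
    return trees


def summarize_catalog(calls: pd.DataFrame, genes: pd.DataFrame | None = None):
    """Per-sample and cohort CNV summaries.

    Returns ``(per_sample, cohort)``: per sample the count of each state,
    total CNVs, Mb covered by gains and losses, and the number of genes
    overlapped (>= 1 bp) by gains and by losses (a gene counts once per
    sample even if hit twice); the cohort row carries means ± SD and the
    amplification:deletion ratio recomputed from the total counts.
    """
    states = [-2, -1, 1, 2]
    trees = _gene_tree(genes) if genes is not None and len(genes) else {}
    rows = []
    for sid, sub in calls.groupby("sample_id", sort=True):
        counts = {s: int((sub.state == s).sum()) for s in states}
        gains = sub[sub.state > 0]
        losses = sub[sub.state < 0]
        mb = {
            "mb_amplified": sum(e - s + 1 for s, e in zip(gains.start, gains.end)) / 1e6,
            "mb_deleted": sum(e - s + 1 for s, e in zip(losses.start, losses.end)) / 1e6,
        }
        genes_hit = {}
        for label, part in (("genes_amplified", gains), ("genes_deleted", losses)):
            hit = set()
            for r in part.itertuples(index=False):
                tree = trees.get(r.chrom)
                if tree is not None:
                    # calls are 1-based inclusive, trees 0-based half-open
                    hit |= {iv.data for iv in tree.overlap(r.start - 1, r.end)}
            genes_hit[label] = len(hit)
        rows.append({"sample_id": sid, **{f"n_state_{s}": counts[s] for s in states},
                     "n_total": int(len(sub)), **mb, **genes_hit})
    per_sample = pd.DataFrame(rows)
    if len(per_sample):
        n_amp = int(per_sample[["n_state_1", "n_state_2"]].to_numpy().sum())
        n_del = int(per_sample[["n_state_-1", "n_state_-2"]].to_numpy().sum())
        cohort = {
            "n_amplifications": n_amp,
            "n_deletions": n_del,
            "amp_del_ratio": (n_amp / n_del) if n_del else math.inf,
            "mean_total": float(per_sample.n_total.mean()),
            "sd_total": float(per_sample.n_total.std(ddof=1)) if len(per_sample) > 1 else 0.0,
        }
    else:
        cohort = {"n_amplifications": 0, "n_deletions": 0, "amp_del_ratio": math.nan,
                  "mean_total": 0.0, "sd_total": 0.0}
    return per_sample, cohort


def cnv_rate_per_mb(calls: pd.DataFrame, kept_mb: dict,
                    sex_of: dict | None = None) -> pd.DataFrame:
    """CNVs per kept Mb, per chromosome arm per sample.

    ``kept_mb`` maps arm -> analyzable (kept-bin) Mb; arms with zero kept
    length are skipped.  If ``sex_of`` maps sample_id -> sex, rates are also
    aggregated as mean ± SD per (arm, sex).
    """
    rows = []
    for sid, sub in calls.groupby("sample_id", sort=True):
        for arm, mb in kept_mb.items():
            if mb <= 0:
                continue
            n = int((sub.chrom == arm).sum())
            rows.append({
                "sample_id": sid, "chrom": arm, "n_cnvs": n,
                "rate_per_mb": n / mb,
                "sex": sex_of.get(sid) if sex_of else None,
            })
    return pd.DataFrame(rows)


def _greedy_match(prev: pd.DataFrame, nxt: pd.DataFrame, min_overlap: int) -> int:
    """1-1 matching of same-sign calls by decreasing overlap length."""
    cand = []
    for i, p in enumerate(prev.itertuples(index=False)):
        for j, q in enumerate(nxt.itertuples(index=False)):
            if p.chrom != q.chrom:
                continue
            ov = max(0, min(p.end, q.end) - max(p.start, q.start) + 1)
            if ov >= min_overlap:
                cand.append((ov, i, j))
    cand.sort(reverse=True)
    used_p: set = set()
    used_n: set = set()
    for _, i, j in cand:
        if i not in used_p and j not in used_n:
            used_p.add(i)
            used_n.add(j)
    return len(used_p)


def cnv_turnover(calls_prev: pd.DataFrame, calls_next: pd.DataFrame,
                 min_overlap: int = 1000, line: str = "",
                 from_timepoint: int = 0, to_timepoint: int = 0) -> list:
    """Count CNVs passed on between consecutive time points.

    A call at the later time point is passed on if it overlaps a same-sign
    call (gain with gain, loss with loss, regardless of magnitude) at the
    earlier time point by at least ``min_overlap`` bp, inclusive.  Matching
    is one-to-one so passed counts respect both time points' totals.
    Returns one TurnoverRecord per class (dup, del).
    """
    out = []
    for label, sign in (("dup", 1), ("del", -1)):
        prev = calls_prev[np.sign(calls_prev.state) == sign]
        nxt = calls_next[np.sign(calls_next.state) == sign]
        n_passed = _greedy_match(prev, nxt, min_overlap)
        out.append(TurnoverRecord(
            line=line, from_timepoint=from_timepoint, to_timepoint=to_timepoint,
            cnv_class=label, n_prev=len(prev), n_passed=n_passed,
            n_new=len(nxt) - n_passed,
        ))
    return out


def mann_whitney(group_a, group_b) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact by full enumeration of rank assignments (ties handled through
    midranks) when min(n) <= 8; tie-corrected normal approximation
    otherwise.  Identical constant groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    na, nb = len(a), len(b)
    if min(na, nb) > 8:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n = na + nb
    le = ge = total = 0
    for comb in itertools.combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return float(min(1.0, 2.0 * min(le, ge) / total))


def match_calls(truth: pd.DataFrame, calls: pd.DataFrame,
                reciprocal: float = 0.5, sign_match: bool = True):
    """Recall/precision of calls against truth by reciprocal overlap.

    ``truth`` uses 0-based half-open (chrom, start, end, state); ``calls``
    the 1-based inclusive reporting convention.  A pair matches if each
    interval covers >= ``reciprocal`` of the other and (optionally) the
    states have the same sign.  Returns (recall, precision, n_truth,
    n_calls).
    """
    t_iv = [(r.chrom, int(r.start) + 1, int(r.end), int(r.state))
            for r in truth.itertuples(index=False)]
    c_iv = [(r.chrom, int(r.start), int(r.end), int(r.state))
            for r in calls.itertuples(index=False)]
    matched_t: set = set()
    matched_c: set = set()
    for i, t in enumerate(t_iv):
        for j, c in enumerate(c_iv):
            if t[0] != c[0]:
                continue
            if sign_match and np.sign(t[3]) != np.sign(c[3]):
                continue
            ov = max(0, min(t[2], c[2]) - max(t[1], c[1]) + 1)
            if ov >= reciprocal * (t[2] - t[1] + 1) and ov >= reciprocal * (c[2] - c[1] + 1):
                matched_t.add(i)
                matched_c.add(j)
    recall = len(matched_t) / len(t_iv) if t_iv else 1.0
    precision = len(matched_c) / len(c_iv) if c_iv else 1.0
    return recall, precision, len(t_iv), len(c_iv)
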
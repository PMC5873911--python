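"""Somatic SNP statistics: filtering, spectra, clustering, rates, turnover.

Variants are rows of a DataFrame with columns chrom, pos (1-based), ref,
alt, aaf, f1r2, f2r1, region_class.  Substitutions are collapsed to the six
pyrimidine-reference classes (G>T counts as C>A, etc.), the convention under
which the oxidative-damage signature appears as an excess of C>A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "SIX_CLASSES",
    "FilterReport",
    "filter_snps",
    "substitution_spectrum",
    "cluster_test",
    "region_enrichment_test",
    "exome_rate",
    "snp_turnover",
    "orientation_bias_check",
]

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = set("ACGT")


def collapse_class(ref: str, alt: str) -> str | None:
    """Pyrimidine-reference class of a substitution, or None if malformed."""
    if ref not in _BASES or alt not in _BASES or ref == alt:
        return None
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class FilterReport:
    n_input: int
    n_masked: int
    n_low_aaf: int
    n_malformed: int
    n_kept: int


def _interval_trees(intervals: pd.DataFrame | None) -> dict:
    trees: dict = {}
    if intervals is not None:
        for row in intervals.itertuples(index=False):
            if int(row.end) > int(row.start):
                trees.setdefault(row.chrom, IntervalTree()).addi(
                    int(row.start), int(row.end)
                )
    return trees


def filter_snps(variants: pd.DataFrame, masks: pd.DataFrame | None = None,
                min_aaf: float = 0.0):
    """Drop masked (TE / low-complexity) and optionally low-AAF variants.

    ``masks`` is a BED-style table (0-based half-open).  ``min_aaf`` applies
    only when the downstream analysis requests it (exome-rate analyses use
    0.1; the spectrum keeps everything).  Malformed alleles (non-ACGT or
    indels) are rejected and counted.  Returns (filtered, FilterReport).
    """
    trees = _interval_trees(masks)
    ok_alleles = variants.apply(
        lambda r: collapse_class(str(r.ref), str(r.alt)) is not None, axis=1
    ) if len(variants) else pd.Series([], dtype=bool)
    n_malformed = int((~ok_alleles).sum()) if len(variants) else 0
    kept = variants[ok_alleles] if len(variants) else variants

    if trees:
        in_mask = kept.apply(
            lambda r: r.chrom in trees and bool(trees[r.chrom].overlap(r.pos - 1, r.pos)),
            axis=1,
        ) if len(kept) else pd.Series([], dtype=bool)
    else:
        in_mask = pd.Series(False, index=kept.index)
    n_masked = int(in_mask.sum())
    kept = kept[~in_mask]

    low = kept.aaf < min_aaf if min_aaf > 0 else pd.Series(False, index=kept.index)
    n_low = int(low.sum())
    kept = kept[~low]
    report = FilterReport(
        n_input=len(variants), n_masked=n_masked, n_low_aaf=n_low,
        n_malformed=n_malformed, n_kept=len(kept),
    )
    return kept.reset_index(drop=True), report


def substitution_spectrum(variants: pd.DataFrame):
    """Six-class substitution counts and fractions (strand-collapsed).

    Returns (counts, fractions, n_skipped); fractions are NaN for empty
    input (flagged by n == 0 rather than an arbitrary zero spectrum).
    """
    counts = {c: 0 for c in SIX_CLASSES}
    skipped = 0
    for row in variants.itertuples(index=False):
        cls = collapse_class(str(row.ref), str(row.alt))
        if cls is None:
            skipped += 1
        else:
            counts[cls] += 1
    total = sum(counts.values())
    fractions = {
        c: (counts[c] / total if total else float("nan")) for c in SIX_CLASSES
    }
    return counts, fractions, skipped


def cluster_test(variants: pd.DataFrame, window: int = 50_000,
                 n_eff: float = None, alpha: float = 1e-3) -> pd.DataFrame:
    """Binomial clustering test in a window around each SNP.

    For each SNP, k counts the SNPs (itself included) within ±window/2 on
    the same chromosome.  Under uniform placement over the ``n_eff``
    informative positions the k−1 *other* SNPs in the window follow
    Binomial(N−1, window/n_eff), so the reported p-value is the upper tail
    P(X >= k−1) with X ~ Binomial(N−1, window/n_eff) — conditioning on the
    focal SNP keeps the test calibrated at any SNP density.  Overlapping
    significant windows are merged into regions (region_id).
    """
    if n_eff is None or n_eff <= 0:
        raise ValueError("effective genome size n_eff must be positive")
    n_total = len(variants)
    if n_total > n_eff:
        raise ValueError("more SNPs than informative positions")
    p_hit = min(1.0, window / n_eff)
    half = window // 2
    rows = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = np.sort(sub.pos.to_numpy())
        for p in sub.pos.to_numpy():
            k = int(np.searchsorted(pos, p + half, side="right")
                    - np.searchsorted(pos, p - half, side="left"))
            pval = float(stats.binom.sf(k - 2, n_total - 1, p_hit))
            rows.append((chrom, int(p), k, pval, pval <= alpha))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "k", "p_value", "significant"])
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    # merge overlapping significant windows into regions
    region_ids = np.full(len(out), -1)
    rid = -1
    last_chrom, last_end = None, -1
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.significant:
            continue
        if row.chrom != last_chrom or row.pos - half > last_end:
            rid += 1
        region_ids[i] = rid
        last_chrom, last_end = row.chrom, row.pos + half
    out["region_id"] = region_ids
    return out


def region_enrichment_test(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    Evaluated in log space so that very small tails (P well below 1e-12)
    remain accurate.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("need 0 < p0 < 1")
    if k == 0:
        return 1.0
    return float(np.exp(stats.binom.logsf(k - 1, n, p0)))


def exome_rate(variants: pd.DataFrame, exome_intervals: pd.DataFrame,
               callable_exome_bp: float):
    """SNPs per Mb of callable exome, plus exonic/protein-affecting fractions.

    Expects variants already filtered to AAF >= 0.1.  Returns a dict with
    rate_per_mb, n_exonic, exonic_fraction (of all variants) and
    protein_affecting_fraction (of exonic variants, by region_class).
    """
    if callable_exome_bp <= 0:
        raise ValueError("callable exome size must be positive")
    trees = _interval_trees(exome_intervals)
    in_exome = variants.apply(
        lambda r: r.chrom in trees and bool(trees[r.chrom].overlap(r.pos - 1, r.pos)),
        axis=1,
    ) if len(variants) else pd.Series([], dtype=bool)
    n_ex = int(in_exome.sum())
    exonic = variants[in_exome] if len(variants) else variants
    n_nonsyn = int((exonic.region_class == "exonic-nonsyn").sum()) if len(exonic) else 0
    return {
        "rate_per_mb": n_ex / (callable_exome_bp / 1e6),
        "n_exonic": n_ex,
        "exonic_fraction": n_ex / len(variants) if len(variants) else float("nan"),
        "protein_affecting_fraction": n_nonsyn / n_ex if n_ex else float("nan"),
    }


def snp_turnover(set_prev: pd.DataFrame, set_next: pd.DataFrame) -> dict:
    """SNPs passed on between time points, by exact (chrom,pos,ref,alt) identity."""
    key = ["chrom", "pos", "ref", "alt"]
    prev_keys = set(map(tuple, set_prev[key].itertuples(index=False)))
    next_keys = set(map(tuple, set_next[key].itertuples(index=False)))
    n_passed = len(prev_keys & next_keys)
    return {
        "n_prev": len(prev_keys),
        "n_next": len(next_keys),
        "n_passed": n_passed,
        "n_new": len(next_keys - prev_keys),
        "fraction_passed": n_passed / len(prev_keys) if prev_keys else float("nan"),
    }


def orientation_bias_check(variants: pd.DataFrame, alpha: float = 0.01,
                           suspect_direction: str = "f1r2") -> dict:
    """Read-orientation artifact check for the pooled C>A (G>T) class.

    8-oxo-dG damage introduced during library preparation produces C>A calls
    whose alt-supporting reads pile up in one read orientation; genuine
    somatic C>A variants are orientation balanced.  Pools f1r2/f2r1 over all
    C>A-class variants and runs a two-sided exact binomial test against 0.5;
    the sample is flagged oxidation-suspect if p < alpha and the skew lies
    in ``suspect_direction``.
    """
    if len(variants) and not {"f1r2", "f2r1"}.issubset(variants.columns):
        return {"status": "skipped", "flagged": False,
                "warning": "orientation counts missing"}
    is_ca = variants.apply(
        lambda r: collapse_class(str(r.ref), str(r.alt)) == "C>A", axis=1
    ) if len(variants) else pd.Series([], dtype=bool)
    ca = variants[is_ca] if len(variants) else variants
    f1r2 = int(ca.f1r2.sum()) if len(ca) else 0
    f2r1 = int(ca.f2r1.sum()) if len(ca) else 0
    total = f1r2 + f2r1
    if total == 0:
        return {"status": "no data", "flagged": False, "n_variants": int(len(ca)),
                "f1r2": 0, "f2r1": 0, "p_value": float("nan")}
    p = float(stats.binomtest(f1r2, total, 0.5, alternative="two-sided").pvalue)
    skew = "f1r2" if f1r2 >= f2r1 else "f2r1"
    flagged = p < alpha and skew == suspect_direction
    return {"status": "ok", "flagged": bool(flagged), "n_variants": int(len(ca)),
            "f1r2": f1r2, "f2r1": f2r1, "p_value": p, "skew": skew}
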
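"""End-to-end CNV pipeline: correct, filter, normalize, segment, call.

Mirrors the analysis run on each tumor/control pair of an allograft series:
per-sample GC correction, shared bin filtering, cross-sample quantile
normalization, per-arm CBS on the tumor/control log2 ratio, modal
re-anchoring of segment means, five-state calling, and optionally the same
run on a reduced grid with under-replicated / repeat intervals masked out
(the mask-and-recall step that separates real somatic CNVs from polytene
under-replication artifacts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import filter_bins, fit_gc_correction, quantile_normalize
from .segment import (SegmentProfile, call_states, cbs_segment,
                      compute_log_ratio, postsegment_normalize, residual_sd,
                      stitch_calls)
from .sim import GenomeModel

__all__ = ["CnvPipelineResult", "run_cnv_pipeline", "mask_and_recall"]


@dataclass
class CnvPipelineResult:
    kept: np.ndarray  # boolean mask over the full bin grid
    profiles: dict  # tumor sample_id -> SegmentProfile (post-normalized)
    calls: pd.DataFrame  # sample_id, chrom, start (1-based), end, state, n_bins, mean
    noise_sd: dict = field(default_factory=dict)  # tumor sample_id -> residual SD
    masked: bool = False


def _analysis_arms(model: GenomeModel):
    # the Y proxy region is used for sex inference only
    return [c for c in model.chrom_names if c != "Y"]


def run_cnv_pipeline(model: GenomeModel, coverages: dict, pairs: list,
                     mask: pd.DataFrame | None = None, alpha: float = 0.01,
                     undo_sd: float = 3.0, n_perm: int = 1000,
                     eps: float = 0.5, gc_df: int = 10, gc_alpha: float = 0.0,
                     call_margin: float = 0.2, stitch_gap: int = 10_000,
                     seed: int = 0) -> CnvPipelineResult:
    """Run the full CNV analysis for ``pairs`` of (tumor, control) sample ids.

    ``coverages`` maps sample_id to a raw per-bin coverage vector on the
    model's grid.  ``mask`` is an optional interval table (chrom/start/end,
    0-based half-open) whose bins are dropped before segmentation; reported
    call coordinates always refer to original genome positions.
    """
    samples = sorted({s for pair in pairs for s in pair})
    missing = [s for s in samples if s not in coverages]
    if missing:
        raise ValueError(f"no coverage for samples: {missing}")

    # bins excluded from the analysis must not inform the bias model either:
    # a polytene control's under-replicated bins (or a female's empty Y
    # proxy) would otherwise drag its GC fit and manufacture recurrent
    # tumor/control differences after normalization
    fit_on = model.mappability > 0
    if "Y" in model.chrom_names:
        fit_on[model.arm_slice("Y")] = False
    if mask is not None and len(mask):
        fit_on &= ~model.interval_mask(mask)

    corrected = {}
    for sid in samples:
        vals = np.asarray(coverages[sid], dtype=float)
        if vals.shape[0] != model.n_bins_total:
            raise ValueError(f"sample {sid} is not on the model's bin grid")
        gcfit = fit_gc_correction(vals[fit_on], model.gc[fit_on], df=gc_df,
                                  alpha=gc_alpha)
        full = vals.copy()
        full[fit_on] = gcfit.corrected
        corrected[sid] = full

    kept = filter_bins(model.mappability, model.gc)
    if "Y" in model.chrom_names:
        kept[model.arm_slice("Y")] = False
    if mask is not None and len(mask):
        kept &= ~model.interval_mask(mask)
    masked = mask is not None and len(mask) > 0

    matrix = np.column_stack([corrected[s][kept] for s in samples])
    if len(samples) >= 2:
        matrix = quantile_normalize(matrix, sample_ids=samples)
    normalized = {s: matrix[:, i] for i, s in enumerate(samples)}

    kept_idx = np.flatnonzero(kept)
    profiles, noise, all_calls = {}, {}, []
    rng = np.random.default_rng([seed, 101])
    for tumor, control in pairs:
        ratio = compute_log_ratio(normalized[tumor], normalized[control], eps=eps)
        seg_rows = []
        resid_parts = []
        for chrom in _analysis_arms(model):
            sl = model.arm_slice(chrom)
            in_arm = (kept_idx >= sl.start) & (kept_idx < sl.stop)
            arm_pos = np.flatnonzero(in_arm)
            if len(arm_pos) == 0:
                warnings.warn(f"arm {chrom} has no usable bins; skipped")
                continue
            x = ratio[arm_pos]
            if len(x) < 2:
                seg = pd.DataFrame(
                    [(0, len(x), float(x.mean()), len(x))],
                    columns=["start_bin", "end_bin", "mean", "n_bins"],
                )
            else:
                seg = cbs_segment(x, alpha=alpha, undo_sd=undo_sd,
                                  n_perm=n_perm, rng=rng)
            bins = kept_idx[arm_pos]
            for r in seg.itertuples(index=False):
                seg_rows.append((
                    chrom, r.start_bin, r.end_bin,
                    int(model.bin_start[bins[r.start_bin]]),
                    int(model.bin_end[bins[r.end_bin - 1]]),
                    r.mean, r.n_bins,
                ))
                resid_parts.append(x[r.start_bin:r.end_bin] - r.mean)
        seg_df = pd.DataFrame(
            seg_rows,
            columns=["chrom", "start_bin", "end_bin", "start", "end", "mean", "n_bins"],
        )
        profile = SegmentProfile(segments=seg_df, tumor=tumor, control=control,
                                 masked=masked)
        profile = postsegment_normalize(profile)
        sd = residual_sd(np.concatenate(resid_parts)) if resid_parts else 0.0
        calls = call_states(profile, noise_sd=sd, call_margin=call_margin)
        calls.insert(0, "sample_id", tumor)
        calls = stitch_calls(calls, max_gap=stitch_gap)
        profiles[tumor] = profile
        noise[tumor] = sd
        all_calls.append(calls)
    calls = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(columns=["sample_id", "chrom", "start", "end",
                                   "state", "n_bins", "mean"])
    )
    return CnvPipelineResult(kept=kept, profiles=profiles, calls=calls,
                             noise_sd=noise, masked=masked)


def mask_and_recall(model: GenomeModel, coverages: dict, pairs: list,
                    masks: list, **kwargs) -> CnvPipelineResult:
    """Re-run the pipeline with bins overlapping any mask interval removed.

    ``masks`` is a list of interval tables (e.g. the model's UR and repeat
    intervals); a bin is dropped if it overlaps any interval by >= 1 bp.  An
    empty mask list reproduces the unmasked pipeline exactly.
    """
    frames = [m for m in masks if m is not None and len(m)]
    mask = (
        pd.concat([f[["chrom", "start", "end"]] for f in frames], ignore_index=True)
        if frames
        else None
    )
    return run_cnv_pipeline(model, coverages, pairs, mask=mask, **kwargs)
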
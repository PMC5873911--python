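"""Call CNVs on a simulated tumor/control pair, with and without UR masking.

The donor control is larval (polytene) gDNA, so under-replicated regions are
depleted in the control and masquerade as tumor gains.  The masked re-run
drops UR/repeat bins and reveals the true somatic lesions; recovery is scored
against the simulator's ground truth at >= 50% reciprocal overlap.
"""

import tumorgi as tgi

cfg = tgi.SimConfig(seed=11, sex="female", snp_rate_per_passage=0,
                    cnv_state_probs={1: 0.5, -1: 0.5})
model, truth, coverages = tgi.simulate_cohort(cfg)
pairs = [(s.sample_id, "L1-control") for s in truth.samples if s.role == "tumor"]

unmasked = tgi.run_cnv_pipeline(model, coverages, pairs, n_perm=300, seed=1)
masked = tgi.mask_and_recall(model, coverages, pairs,
                             masks=[model.ur_intervals, model.repeat_intervals],
                             n_perm=300, seed=1)

print(f"unmasked run: {len(unmasked.calls)} calls "
      f"({(unmasked.calls.state > 0).sum()} gains — mostly UR artifacts)")
print(f"masked run:   {len(masked.calls)} calls\n")
print(masked.calls.to_string(index=False))

for sid, _ in pairs:
    tr = truth.cnvs_for(sid)
    big = tr[(tr.end - tr.start >= 50_000) & (tr.state.abs() == 1)]
    r, p, nt, nc = tgi.match_calls(big, masked.calls[masked.calls.sample_id == sid])
    print(f"{sid}: recall {r:.2f} precision {p:.2f} "
          f"({nt} true single-copy events >= 50 kb, {nc} calls)")
print("\nThe unmasked gains cluster on UR intervals (the polytene-control")
print("artifact); after masking, calls correspond to injected lesions.")
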